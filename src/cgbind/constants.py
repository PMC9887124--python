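"""Physical constants and unit conventions.

Units are fixed package-wide: lengths in Å, times in fs, energies in
kcal/mol, masses in amu, temperatures in K, charges in elementary charges.
"""

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872

#: Vacuum Coulomb constant e²/(4πε0), kcal·Å/(mol·e²).
COULOMB = 332.06

#: Conversion from kcal/mol to the mechanical energy unit amu·Å²/fs².
#: Accelerations are a = F[kcal/(mol·Å)] · E2M / m[amu], in Å/fs².
E2M = 4.184e-4
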