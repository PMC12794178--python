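"""Physical constants and unit conventions.

Internal units follow the Amber convention: lengths in Angstrom, energies
in kcal/mol, masses in amu, charges in elementary charge units, angles in
radians internally (degrees at file boundaries), time in picoseconds.
"""

#: Electrostatic prefactor, kcal * Angstrom / (mol * e^2) (Amber convention).
COULOMB_CONSTANT = 332.0522

#: Boltzmann constant in kcal / (mol * K).
KB = 0.0019872041

#: Converts force/mass (kcal mol^-1 A^-1 / amu) into acceleration (A ps^-2).
ACCEL_UNIT = 418.4

#: Default divisor applied to 1-4 electrostatic interactions.
SCEE = 1.2

#: Default divisor applied to 1-4 Lennard-Jones interactions.
SCNB = 2.0

#: Ambient liquid-water number density at 300 K, molecules / A^3.
WATER_NUMBER_DENSITY = 0.0334
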