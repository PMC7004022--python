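"""Physical constants and unit conventions.

Internal unit system, chosen so no conversions appear in the integrator hot
loop except a single energy factor:

========  =========
length    angstrom (A)
time      femtosecond (fs)
mass      unified atomic mass unit (u = g/mol)
energy    kJ/mol
charge    elementary charge (e)
========  =========

One u*(A/fs)^2 equals exactly 1e4 kJ/mol (because u = (g/mol)/N_A), so kinetic
energy is ``0.5 * m * v**2 * EUNIT`` and acceleration is
``force / (m * EUNIT)``.
"""

# Boltzmann constant, kJ mol^-1 K^-1 (CODATA 2018, exact SI definition)
KB = 0.008314462618

# Coulomb energy factor e^2/(4 pi eps0), kJ mol^-1 A e^-2 (CODATA-derived)
COULOMB = 1389.35457644

# kJ/mol per u*(A/fs)^2; exact by definition of the dalton
EUNIT = 1.0e4

# conventional atomic masses, u
MASS_O = 15.999
MASS_H = 1.008

# gas-phase equilibrium monomer geometry used as the sampling seed
SEED_R_OH = 0.9619           # A
SEED_ANGLE_DEG = 105.05      # degrees

# speed of light, cm/fs (for reporting vibrational wavenumbers)
C_CM_FS = 2.99792458e-5
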