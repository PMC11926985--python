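"""Physical constants and unit conversions used across the package.

All unit conversions live here so that every module agrees on them:
doses are mGy at I/O boundaries and Gy inside curve fitting, dose-per-
fluence coefficients are pGy cm^2 per neutron, microscopic cross
sections are barns, lineal energies keV/um.
"""

from scipy.constants import Avogadro, electron_volt

N_AVOGADRO = Avogadro  # mol^-1

#: 1 keV in joule
KEV_IN_J = 1.0e3 * electron_volt

#: 1 barn in cm^2
BARN_IN_CM2 = 1.0e-24

#: 1 pGy in mGy
PGY_IN_MGY = 1.0e-9

#: thermal reference energy (2200 m/s neutrons), eV
E_THERMAL_EV = 0.0253

#: atomic masses (g/mol) of the elements handled by the dosimetry code
ATOMIC_MASS_G_MOL = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Si": 28.085,
}

SECONDS_PER_HOUR = 3600.0
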