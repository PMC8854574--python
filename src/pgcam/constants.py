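"""Physical constants and unit conventions.

All energies are keV, lengths mm, times ns throughout the package.
"""

# Electron rest energy, keV.
MEC2 = 511.0

# Speed of light, mm/ns.
C_MM_PER_NS = 299.792458

# Gaussian FWHM = 2 sqrt(2 ln 2) sigma.
FWHM_OVER_SIGMA = 2.3548200450309493

# Classical electron radius squared, barn (1 barn = 1e-24 cm^2).
RE2_BARN = 0.07940787
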