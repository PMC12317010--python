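"""Vendored isotope mass and abundance table.

Static copy of CODATA/NIST atomic masses and representative isotopic
abundances for the elements supported by the toolkit.  Bundled rather than
looked up at run time so that mass and isotope-pattern computations are
reproducible offline and across releases.

Masses are in unified atomic mass units (Da); abundances are mole fractions
summing to 1 per element.  Isotopes are listed lightest first; for every
supported element the lightest stable isotope is also the most abundant, so
``ISOTOPES[el][0]`` doubles as the monoisotopic species.
"""

from __future__ import annotations

# element symbol -> tuple of (isotope mass in Da, fractional abundance),
# sorted by increasing mass
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177785, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "F": ((18.99840316273, 1.0),),
    "Na": ((22.98976928, 1.0),),
    "Si": (
        (27.97692653465, 0.92223),
        (28.97649466490, 0.04685),
        (29.97377013507, 0.03092),
    ),
    "P": ((30.97376199842, 1.0),),
    "S": (
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ),
    "Cl": ((34.968852682, 0.7576), (36.965902602, 0.2424)),
    "K": ((38.9637064864, 0.932581), (39.96399817, 0.000117), (40.9618252579, 0.067302)),
    "Br": ((78.9183376, 0.5069), (80.9162897, 0.4931)),
    "I": ((126.9044719, 1.0),),
}

SUPPORTED_ELEMENTS = frozenset(ISOTOPES)

#: electron rest mass in Da (CODATA); subtracted/added when forming ions
ELECTRON_MASS = 0.000548579909

#: monoisotopic (lightest stable isotope) mass per element, Da
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}
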