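"""Pinned physical constants and atomic data.

Monoisotopic masses and isotopic abundances are taken from the NIST/CODATA
atomic weights and isotopic compositions tables (2021 adjustment) and are
committed here verbatim so that every mass in the test suite is bit-stable.
"""

from __future__ import annotations

#: Monoisotopic (principal-isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Isotope tables: element -> list of (mass Da, natural abundance).
#: First entry is the most abundant (principal) isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088982, 0.00364)],
    "O": [
        (15.9949146196, 0.99757),
        (16.9991317012, 0.00038),
        (17.9991596129, 0.00205),
    ],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
    "Na": [(22.9897692809, 1.0)],
    "K": [
        (38.96370668, 0.932581),
        (39.96399848, 0.000117),
        (40.96182576, 0.067302),
    ],
}

ELECTRON_MASS = 0.000548579909065
#: CODATA proton mass, used for deprotonation m/z.
PROTON_MASS = 1.007276466621

#: hc in eV*nm — photon energy E[eV] = HC_EV_NM / lambda[nm].
HC_EV_NM = 1239.841984

#: e^2 / (4 pi eps0) in eV*Angstrom — Coulomb constant for two unit charges.
COULOMB_EV_ANGSTROM = 14.39964

#: 34S - 32S mass difference, Da (the resolved fine-structure A+2 offset).
DELTA_34S = ISOTOPES["S"][2][0] - ISOTOPES["S"][0][0]
#: 2 x (13C - 12C), Da — the A+2 peak the 34S peak must be resolved from.
DELTA_2X13C = 2.0 * (ISOTOPES["C"][1][0] - ISOTOPES["C"][0][0])
#: 2 x (15N - 14N), Da — nearest A+2 fine neighbour below the 34S peak.
DELTA_2X15N = 2.0 * (ISOTOPES["N"][1][0] - ISOTOPES["N"][0][0])

#: Natural abundance ratio 34S/32S; one sulfur atom contributes this much
#: relative A+2 fine-peak intensity.
RATIO_34S_32S = ISOTOPES["S"][2][1] / ISOTOPES["S"][0][1]
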