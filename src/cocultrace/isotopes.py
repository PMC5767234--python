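"""Isotope masses and natural abundances.

Values are the IUPAC 2013 recommended atomic masses and representative
isotopic abundances for the elements handled by the formula grammar
(C, H, N, O, S, P). Embedding the constants keeps every mass and
isotopologue computation reproducible without an external source.
"""

from __future__ import annotations

# element -> ordered list of (isotope mass / Da, natural abundance fraction),
# masses strictly increasing; abundances per element sum to 1.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177812, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.0030740048, 0.99636), (15.0001088989, 0.00364)],
    "O": [(15.99491461956, 0.99757), (16.99913175650, 0.00038), (17.99915961286, 0.00205)],
    "P": [(30.97376163, 1.0)],
    "S": [
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ],
}

#: mass of a proton in Da (charge carrier for [M+H]+ / [M-H]-)
PROTON_MASS = 1.00727646688

#: nominal mass difference between 13C and 12C, used for isotopologue ladders
C13_C12_SPACING = 13.00335483507 - 12.0  # 1.003355 Da

#: natural abundance of 13C
C13_NATURAL_ABUNDANCE = 0.0107

TRACER_ELEMENT = "C"
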