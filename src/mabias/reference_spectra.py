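"""Reference mutation-spectrum dataset: an E. coli DNA-repair mutant panel.

Built-in worked dataset: per-strain mutation counts from mutation-accumulation
experiments on E. coli K-12 MG1655 and six DNA-repair deletion strains
spanning the full range of transition/transversion bias — the three
methyl-directed mismatch-repair knockouts (mutS, mutL, mutH; strongly
transition-biased), the damaged-pyrimidine repair double knockout (nth-nei),
and the 8-oxo-dGTP pathway knockouts (mutY, mutT; strongly
transversion-biased).  Counts are totals over all successfully sequenced MA
lines of each strain and feed the spectrum, bias, and mutation-rate
calculations of :mod:`mabias.catalog`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "STRAINS",
    "strain_counts",
    "GENERATIONS_PER_DAY",
]

#: generations elapsed per 24 h single-colony growth cycle on LB agar
GENERATIONS_PER_DAY = 27

_COLUMNS = [
    "strain", "lines_evolved", "lines_sequenced", "total_mutations",
    "single_mutation_lines", "BPS", "indels", "coding", "noncoding",
    "nonsynonymous", "synonymous", "transitions", "transversions",
    "AT_to_GC", "GC_to_AT", "gc_neutral",
    # days of MA evolution per line where uniform across blocks, else None
    "days_per_line",
]

_ROWS = [
    # strain      evolved seq  total singles BPS  ind  cod  non  nsyn syn  ts   tv   atgc gcat neut days
    ("mutS",      350,    345, 616,  91,     508, 108, 440, 68,  290, 150, 491, 17,  339, 162, 7,   1),
    ("mutL",      350,    344, 603,  97,     509, 94,  437, 72,  274, 163, 491, 18,  361, 143, 5,   1),
    ("mutH",      350,    346, 908,  100,    809, 99,  710, 99,  433, 277, 774, 35,  568, 229, 12,  1),
    ("nth-nei",   300,    285, 502,  102,    482, 20,  400, 82,  273, 127, 430, 52,  22,  438, 22,  8),
    ("WT",        98,     97,  426,  94,     387, 39,  282, 105, 183, 99,  206, 178, 118, 206, 60,  None),
    ("mutY",      430,    424, 798,  113,    787, 11,  684, 103, 489, 195, 69,  644, 24,  746, 17,  None),
    ("mutT",      300,    271, 789,  97,     783, 6,   657, 126, 462, 195, 12,  771, 775, 5,   3,   1),
]

STRAINS = pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("strain", drop=False)


def strain_counts(strain: str) -> dict:
    """Count row of one strain as a plain dict."""
    if strain not in STRAINS.index:
        raise KeyError(f"unknown strain {strain!r}; available: {list(STRAINS.index)}")
    return STRAINS.loc[strain].to_dict()
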