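"""Genome-wide beneficial mutation supply and deleterious load.

A strain producing mutations at genomic rate mu (per bp per generation) over
a genome of L bp, of which a fraction f_b are beneficial and f_d deleterious,
expects S_b = f_b * mu * L beneficial and L_d = f_d * mu * L deleterious
mutations per genome per generation.  Counterfactual columns recompute both
with the wild-type strain's DFE fractions, isolating the contribution of the
mutation rate from that of the DFE shift; relative columns divide by the
wild-type values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "GENOME_SIZE_BP",
    "SupplyLoadRecord",
    "beneficial_supply",
    "deleterious_load",
    "relative_to_wt",
    "supply_load_table",
]

#: E. coli K-12 MG1655 genome length used throughout
GENOME_SIZE_BP = 4_641_652


@dataclass
class SupplyLoadRecord:
    strain_id: str
    environment: str
    S_b: float
    L_d: float
    S_b_wt_dfe: float | None = None
    L_d_wt_dfe: float | None = None
    rel_S_b: float | None = None
    rel_L_d: float | None = None
    rel_S_b_wt_dfe: float | None = None
    rel_L_d_wt_dfe: float | None = None
    S_b_ci: float | None = None
    L_d_ci: float | None = None


def _fraction_times_mu(fraction: float, mu: float, genome_size: float, n_dfe: int | None):
    if fraction < 0 or mu < 0 or genome_size < 0:
        raise ValueError("inputs must be non-negative")
    if fraction > 1:
        raise ValueError("fraction must not exceed 1")
    value = fraction * mu * genome_size
    ci = None
    if n_dfe is not None and n_dfe > 0:
        # binomial sd of the fraction at the DFE's sample size, mu held fixed
        sd = math.sqrt(fraction * (1.0 - fraction) / n_dfe) * mu * genome_size
        ci = 1.96 * sd
    return value, ci


def beneficial_supply(
    f_b: float, mu: float, genome_size: float = GENOME_SIZE_BP, n_dfe: int | None = None
) -> tuple[float, float | None]:
    """S_b = f_b * mu * genome size, with 1.96-sd CI propagated from f_b.

    The CI treats mu as fixed and takes sd(f_b) = sqrt(f_b(1-f_b)/n) at the
    DFE's sample size n; it is None when n is not given.
    """
    return _fraction_times_mu(f_b, mu, genome_size, n_dfe)


def deleterious_load(
    f_d: float, mu: float, genome_size: float = GENOME_SIZE_BP, n_dfe: int | None = None
) -> tuple[float, float | None]:
    """L_d = f_d * mu * genome size; mirror of :func:`beneficial_supply`."""
    return _fraction_times_mu(f_d, mu, genome_size, n_dfe)


def relative_to_wt(records: Sequence[SupplyLoadRecord], wt_id: str) -> list[SupplyLoadRecord]:
    """Fill rel_* fields as ratios to the wild-type record per environment."""
    wt = {r.environment: r for r in records if r.strain_id == wt_id}
    if not wt:
        raise ValueError(f"wild-type strain {wt_id!r} not found among records")
    for r in records:
        ref = wt.get(r.environment)
        if ref is None:
            raise ValueError(f"no wild-type record for environment {r.environment!r}")
        r.rel_S_b = r.S_b / ref.S_b if ref.S_b > 0 else float("inf") if r.S_b > 0 else float("nan")
        r.rel_L_d = r.L_d / ref.L_d if ref.L_d > 0 else float("inf") if r.L_d > 0 else float("nan")
        if r.S_b_wt_dfe is not None and ref.S_b_wt_dfe:
            r.rel_S_b_wt_dfe = r.S_b_wt_dfe / ref.S_b_wt_dfe
        if r.L_d_wt_dfe is not None and ref.L_d_wt_dfe:
            r.rel_L_d_wt_dfe = r.L_d_wt_dfe / ref.L_d_wt_dfe
    return list(records)


def supply_load_table(
    strains: pd.DataFrame,
    wt_id: str,
    genome_size: float = GENOME_SIZE_BP,
) -> pd.DataFrame:
    """Full supply/load table with wild-type-DFE counterfactuals.

    ``strains`` needs columns strain, environment, f_b, f_d, mu, n_dfe.  The
    counterfactual columns use the wild type's f_b/f_d with each strain's own
    mu, so across strains they scale linearly with the mutation rate by
    construction.
    """
    required = {"strain", "environment", "f_b", "f_d", "mu", "n_dfe"}
    missing = required - set(strains.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wt_rows = strains[strains["strain"] == wt_id].set_index("environment")
    if wt_rows.empty:
        raise ValueError(f"wild-type strain {wt_id!r} not in table")

    records = []
    for row in strains.itertuples(index=False):
        wt = wt_rows.loc[row.environment]
        s_b, s_ci = beneficial_supply(row.f_b, row.mu, genome_size, int(row.n_dfe))
        l_d, l_ci = deleterious_load(row.f_d, row.mu, genome_size, int(row.n_dfe))
        s_b_wt, _ = beneficial_supply(wt["f_b"], row.mu, genome_size)
        l_d_wt, _ = deleterious_load(wt["f_d"], row.mu, genome_size)
        records.append(
            SupplyLoadRecord(
                strain_id=row.strain, environment=row.environment,
                S_b=s_b, L_d=l_d, S_b_wt_dfe=s_b_wt, L_d_wt_dfe=l_d_wt,
                S_b_ci=s_ci, L_d_ci=l_ci,
            )
        )
    relative_to_wt(records, wt_id)
    return pd.DataFrame(
        {
            "strain": [r.strain_id for r in records],
            "environment": [r.environment for r in records],
            "S_b": [r.S_b for r in records],
            "S_b_wt_dfe": [r.S_b_wt_dfe for r in records],
            "L_d": [r.L_d for r in records],
            "L_d_wt_dfe": [r.L_d_wt_dfe for r in records],
            "rel_S_b": [r.rel_S_b for r in records],
            "rel_S_b_wt_dfe": [r.rel_S_b_wt_dfe for r in records],
            "rel_L_d": [r.rel_L_d for r in records],
            "rel_L_d_wt_dfe": [r.rel_L_d_wt_dfe for r in records],
            "S_b_ci": [r.S_b_ci for r in records],
            "L_d_ci": [r.L_d_ci for r in records],
        }
    )
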