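"""Synthetic mutation-accumulation experiments with a known ground truth.

Generates datasets with the statistical structure the analysis pipeline
assumes: per-line mutation counts that are Poisson in mu * genome size *
generations, mutation classes drawn from a strain-specific spectrum,
class-conditional fitness effects in which transversions can be right-shifted
relative to transitions, within-colony selection bias injected through the
same enrichment model r(s) that the DFE module corrects with, and
plate-reader OD600 trajectories with logistic growth and Gaussian noise.
Every draw is recorded in a truth ledger so downstream estimates (spectra,
rates, f_b/f_n/f_d, s) can be scored without re-simulation, and every output
is bit-for-bit reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MUTATION_TABLE_COLUMNS
from .dfe import colony_sampling_weight
from .growth import GrowthCurve

__all__ = [
    "SpectrumProbs",
    "MASimConfig",
    "EffectGenConfig",
    "PlateSimConfig",
    "simulate_ma",
    "simulate_effects",
    "inject_colony_bias",
    "simulate_plate",
]

GENOME_SIZE_BP = 4_641_652


@dataclass(frozen=True)
class SpectrumProbs:
    """Mutation-class probabilities as a product of conditionals.

    Defaults emulate a wild-type-like E. coli spectrum: ~90% base-pair
    substitutions, a mild transition bias (Tv fraction ~0.46), transitions
    split between the two GC-changing directions, ~73% of substitutions in
    coding sequence with ~35% of those synonymous.
    """

    p_bps: float = 0.90
    p_tv_given_bps: float = 0.46
    p_gc_to_at_given_ts: float = 0.64
    # transversion direction conditionals (must sum to 1)
    p_gc_to_at_given_tv: float = 0.40
    p_at_to_gc_given_tv: float = 0.30
    p_no_change_given_tv: float = 0.30
    p_coding_given_bps: float = 0.73
    p_syn_given_coding: float = 0.35

    def __post_init__(self) -> None:
        for name in ("p_bps", "p_tv_given_bps", "p_gc_to_at_given_ts", "p_coding_given_bps", "p_syn_given_coding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} not a probability")
        tv_sum = self.p_gc_to_at_given_tv + self.p_at_to_gc_given_tv + self.p_no_change_given_tv
        if abs(tv_sum - 1.0) > 1e-9:
            raise ValueError("transversion direction probabilities must sum to 1")


@dataclass(frozen=True)
class MASimConfig:
    """Generative parameters of one strain's synthetic MA experiment.

    The per-line Poisson mean is mu * genome_size * generations_per_line.
    ``decoy_fraction`` plants additional variants that deliberately fail one
    of the read-support/frequency filters; ``background_mutations`` are
    (position, ref, alt) triples fixed in the ancestor and therefore present
    in the ancestor table and every offspring line.
    """

    strain_id: str = "sim"
    mu: float = 2.0e-8
    genome_size: int = GENOME_SIZE_BP
    n_lines: int = 100
    generations_per_line: int = 27
    spectrum: SpectrumProbs = field(default_factory=SpectrumProbs)
    background_mutations: tuple = ()
    decoy_fraction: float = 0.0
    seed: int = 0

    @property
    def per_line_mean(self) -> float:
        return self.mu * self.genome_size * self.generations_per_line


@dataclass(frozen=True)
class EffectGenConfig:
    """Class-conditional mixture of fitness effects.

    Each mutation is neutral (point mass at 0), beneficial (exponential with
    mean ``beneficial_mean``), or deleterious (negative gamma) with the given
    weights; ``tv_shift`` is added to every transversion's effect, producing
    the right-shifted transversion DFE the pipeline is designed to detect.
    ``noise_sd`` is the measurement noise a plate assay would add on top of
    the true effect (consumed by downstream simulators, not applied here).
    """

    weight_neutral: float = 0.45
    weight_beneficial: float = 0.15
    weight_deleterious: float = 0.40
    beneficial_mean: float = 0.04
    deleterious_shape: float = 1.5
    deleterious_scale: float = 0.06
    tv_shift: float = 0.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        total = self.weight_neutral + self.weight_beneficial + self.weight_deleterious
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class PlateSimConfig:
    """Plate-reader protocol parameters for the OD600 simulator.

    Defaults mirror a standard 96-well growth assay: readings every 15 min
    for 16 h; initial OD 0.03 (a 1:100 inoculum of a stationary overnight
    culture at OD ~3); additive read noise of 0.0005 OD, the repeatability of
    a bench plate reader.
    """

    interval_min: float = 15.0
    duration_h: float = 16.0
    carrying_capacity: float = 1.0
    initial_od: float = 0.03
    lag_h: float = 1.0
    od_noise_sd: float = 0.0005
    technical_replicates: int = 3
    n_blanks: int = 3

    def __post_init__(self) -> None:
        if self.duration_h * 60.0 / self.interval_min < 10:
            raise ValueError("protocol must yield at least 10 readings")
        if self.od_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


# ---------------------------------------------------------------------------

_TS_BY_DIRECTION = {"AT_to_GC": [("A", "G"), ("T", "C")], "GC_to_AT": [("G", "A"), ("C", "T")]}
_TV_BY_DIRECTION = {
    "AT_to_GC": [("A", "C"), ("T", "G")],
    "GC_to_AT": [("G", "T"), ("C", "A")],
    "no_change": [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")],
}


def _draw_mutation(rng: np.random.Generator, probs: SpectrumProbs) -> dict:
    """One mutation's class, alleles, and annotation."""
    if rng.random() < probs.p_bps:
        is_tv = rng.random() < probs.p_tv_given_bps
        if is_tv:
            direction = rng.choice(
                ["GC_to_AT", "AT_to_GC", "no_change"],
                p=[probs.p_gc_to_at_given_tv, probs.p_at_to_gc_given_tv, probs.p_no_change_given_tv],
            )
            ref, alt = _TV_BY_DIRECTION[direction][rng.integers(len(_TV_BY_DIRECTION[direction]))]
        else:
            direction = "GC_to_AT" if rng.random() < probs.p_gc_to_at_given_ts else "AT_to_GC"
            ref, alt = _TS_BY_DIRECTION[direction][rng.integers(2)]
        coding = rng.random() < probs.p_coding_given_bps
        if coding:
            effect = "synonymous" if rng.random() < probs.p_syn_given_coding else "nonsynonymous"
        else:
            effect = "not_applicable"
        return {
            "class": "BPS", "ref": ref, "alt": alt,
            "ts_tv": "transversion" if is_tv else "transition",
            "gc_direction": direction,
            "region": "coding" if coding else "noncoding",
            "coding_effect": effect,
        }
    # short indel; annotated, never classified by ts/tv
    if rng.random() < 0.5:
        ref, alt, cls = "A", "AT", "insertion"
    else:
        ref, alt, cls = "AT", "A", "deletion"
    return {
        "class": cls, "ref": ref, "alt": alt, "ts_tv": "indel", "gc_direction": "na",
        "region": "coding" if rng.random() < probs.p_coding_given_bps else "noncoding",
        "coding_effect": "not_applicable",
    }


def _support_fields(rng: np.random.Generator) -> dict:
    """Read support and frequency that pass the default filters."""
    return {
        "freq": float(rng.uniform(0.85, 1.0)),
        "reads_plus": int(4 + rng.poisson(16)),
        "reads_minus": int(4 + rng.poisson(16)),
    }


def _decoy_fields(rng: np.random.Generator) -> dict:
    """Support fields violating exactly one default filter."""
    mode = rng.integers(3)
    fields = _support_fields(rng)
    if mode == 0:  # sub-threshold frequency
        fields["freq"] = float(rng.uniform(0.2, 0.8))
    elif mode == 1:  # too few reads on one strand
        fields["reads_plus"] = int(rng.integers(1, 4))
    else:  # absent from one strand entirely
        fields["reads_minus"] = 0
    return fields


def simulate_ma(config: MASimConfig) -> dict:
    """Simulate one strain's MA experiment: per-line variant tables + truth.

    Per-line mutation counts are Poisson(mu * genome_size * generations);
    positions are uniform without collision within a line; read support and
    frequency are synthesized so the default filters pass, plus an optional
    fraction of filter-failing decoys.  Background mutations appear in the
    ancestor table and in every offspring line.  Returns a dict with keys
    ``lines`` (line_id -> DataFrame in the standard mutation-table dialect),
    ``ancestor`` (DataFrame), and ``truth`` (the ledger).
    """
    rng = np.random.default_rng(config.seed)
    lam = config.per_line_mean

    anc_rows = []
    for pos, ref, alt in config.background_mutations:
        anc_rows.append(
            {
                "strain": config.strain_id, "block": "B1", "line": "ancestor",
                "position": int(pos), "ref": ref, "alt": alt, "class": "BPS",
                **_support_fields(rng), "region": "noncoding",
                "coding_effect": "not_applicable", "gene": "",
            }
        )
    ancestor = pd.DataFrame(anc_rows, columns=MUTATION_TABLE_COLUMNS)

    lines: dict[str, pd.DataFrame] = {}
    truth_mutations = []
    per_line_counts = []
    n_decoys = 0
    for i in range(config.n_lines):
        line_id = f"{config.strain_id}_L{i + 1:04d}"
        n_mut = int(rng.poisson(lam))
        per_line_counts.append(n_mut)
        used_positions = {int(p) for p, _, _ in config.background_mutations}
        rows = []
        # background mutations reappear in every offspring line
        for pos, ref, alt in config.background_mutations:
            rows.append(
                {
                    "strain": config.strain_id, "block": "B1", "line": line_id,
                    "position": int(pos), "ref": ref, "alt": alt, "class": "BPS",
                    **_support_fields(rng), "region": "noncoding",
                    "coding_effect": "not_applicable", "gene": "",
                }
            )
        for j in range(n_mut):
            pos = int(rng.integers(1, config.genome_size + 1))
            while pos in used_positions:  # collisions resolved by redraw
                pos = int(rng.integers(1, config.genome_size + 1))
            used_positions.add(pos)
            drawn = _draw_mutation(rng, config.spectrum)
            row = {
                "strain": config.strain_id, "block": "B1", "line": line_id,
                "position": pos, "ref": drawn["ref"], "alt": drawn["alt"],
                "class": drawn["class"], **_support_fields(rng),
                "region": drawn["region"], "coding_effect": drawn["coding_effect"],
                "gene": "",
            }
            rows.append(row)
            truth_mutations.append(
                {
                    "line": line_id, "position": pos, "ref": drawn["ref"], "alt": drawn["alt"],
                    "class": drawn["class"], "ts_tv": drawn["ts_tv"],
                    "gc_direction": drawn["gc_direction"], "region": drawn["region"],
                    "coding_effect": drawn["coding_effect"],
                }
            )
        if config.decoy_fraction > 0:
            n_dec = int(rng.poisson(config.decoy_fraction * max(n_mut, 1)))
            for _ in range(n_dec):
                pos = int(rng.integers(1, config.genome_size + 1))
                while pos in used_positions:
                    pos = int(rng.integers(1, config.genome_size + 1))
                used_positions.add(pos)
                drawn = _draw_mutation(rng, config.spectrum)
                rows.append(
                    {
                        "strain": config.strain_id, "block": "B1", "line": line_id,
                        "position": pos, "ref": drawn["ref"], "alt": drawn["alt"],
                        "class": drawn["class"], **_decoy_fields(rng),
                        "region": drawn["region"], "coding_effect": drawn["coding_effect"],
                        "gene": "",
                    }
                )
                n_decoys += 1
        lines[line_id] = pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)

    truth_df = pd.DataFrame(
        truth_mutations,
        columns=["line", "position", "ref", "alt", "class", "ts_tv", "gc_direction", "region", "coding_effect"],
    )
    truth = {
        "config": {**asdict(config), "spectrum": asdict(config.spectrum)},
        "per_line_counts": per_line_counts,
        "n_true_mutations": len(truth_df),
        "n_decoys": n_decoys,
        "mutations": truth_df,
    }
    return {"lines": lines, "ancestor": ancestor, "truth": truth}


def simulate_effects(mutations: pd.DataFrame, config: EffectGenConfig, seed: int = 0) -> pd.DataFrame:
    """Draw a true selection coefficient for each mutation.

    Each mutation's effect comes from the neutral/beneficial/deleterious
    mixture; transversions then receive the additive ``tv_shift``.  Returns a
    copy of the table with an ``s_true`` column; deleterious draws are floored
    at -1 (complete loss of growth).
    """
    rng = np.random.default_rng(seed)
    n = len(mutations)
    component = rng.choice(
        ["neutral", "beneficial", "deleterious"],
        size=n,
        p=[config.weight_neutral, config.weight_beneficial, config.weight_deleterious],
    )
    s = np.zeros(n)
    n_ben = int((component == "beneficial").sum())
    n_del = int((component == "deleterious").sum())
    s[component == "beneficial"] = rng.exponential(config.beneficial_mean, size=n_ben)
    s[component == "deleterious"] = -rng.gamma(config.deleterious_shape, config.deleterious_scale, size=n_del)
    if "ts_tv" in mutations.columns and config.tv_shift != 0.0:
        s = s + np.where(mutations["ts_tv"].to_numpy() == "transversion", config.tv_shift, 0.0)
    s = np.maximum(s, -1.0 + 1e-6)
    out = mutations.copy()
    out["s_true"] = s
    out["effect_component"] = component
    return out


def inject_colony_bias(
    mutations: pd.DataFrame,
    G: int = 27,
    seed: int = 0,
    mode: str = "thin",
    s_col: str = "s_true",
) -> pd.DataFrame:
    """Forward-simulate within-colony selection bias on a mutation cohort.

    In ``thin`` mode each mutation is retained with probability proportional
    to r(s, G) (max-normalized over the cohort), producing an s-enriched
    subset; ``resample`` mode draws a same-size cohort with replacement with
    probability proportional to r(s, G).  G = 0 means no colony growth and
    uniform retention.  The returned table carries a ``retained`` flag (thin)
    or the resampled rows.
    """
    rng = np.random.default_rng(seed)
    s = mutations[s_col].to_numpy(dtype=float)
    if np.any(s <= -1.0):
        raise ValueError("all s must exceed -1")
    if G == 0:
        r = np.ones_like(s)
    else:
        r = np.atleast_1d(colony_sampling_weight(s, G))
    if mode == "thin":
        p = r / r.max() if r.max() > 0 else np.ones_like(r)
        keep = rng.random(s.size) < p
        out = mutations.copy()
        out["retained"] = keep
        return out
    if mode == "resample":
        p = r / r.sum()
        idx = rng.choice(s.size, size=s.size, replace=True, p=p)
        return mutations.iloc[idx].reset_index(drop=True)
    raise ValueError("mode must be 'thin' or 'resample'")


def simulate_plate(
    clones: pd.DataFrame,
    config: PlateSimConfig = PlateSimConfig(),
    seed: int = 0,
    plate_id: str = "P1",
    environment: str = "LB",
    ancestor_rate: float = 1.0,
    reference_rate: float = 1.0,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Simulate one plate: logistic OD600 trajectories plus a plate map.

    ``clones`` needs columns ``clone`` and ``rate`` (true maximum growth rate
    per hour).  Each clone gets ``technical_replicates`` wells; ancestor,
    reference, and blank wells are added automatically.  Trajectories follow

        OD(t) = K / (1 + ((K - OD0)/OD0) * exp(-r (t - lag)))   for t >= lag

    held at OD0 before the lag, with additive Gaussian noise.  Returns the
    curves and a plate-map DataFrame (well, clone, role).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, config.duration_h * 60.0 + 1e-9, config.interval_min)
    t_h = times / 60.0

    def trajectory(rate: float) -> np.ndarray:
        od0, K = config.initial_od, config.carrying_capacity
        shifted = np.maximum(t_h - config.lag_h, 0.0)
        od = K / (1.0 + ((K - od0) / od0) * np.exp(-rate * shifted))
        return od + rng.normal(0.0, config.od_noise_sd, size=od.shape)

    curves: list[GrowthCurve] = []
    plate_map = []
    well_no = 0

    def add_well(clone: str, role: str, rate: float | None, rep: int) -> None:
        nonlocal well_no
        well_no += 1
        well = f"{chr(ord('A') + (well_no - 1) // 12)}{(well_no - 1) % 12 + 1}"
        if role == "blank":
            od = rng.normal(0.0, config.od_noise_sd, size=times.shape)
        else:
            od = trajectory(rate)
        curves.append(GrowthCurve(plate_id, well, clone, role, environment, times, od, rep))
        plate_map.append({"plate": plate_id, "well": well, "clone": clone, "role": role, "replicate": rep})

    for row in clones.itertuples(index=False):
        for rep in range(config.technical_replicates):
            add_well(str(row.clone), "evolved", float(row.rate), rep)
    for rep in range(config.technical_replicates):
        add_well("ancestor", "ancestor", ancestor_rate, rep)
    for rep in range(config.technical_replicates):
        add_well("reference", "reference", reference_rate, rep)
    for b in range(config.n_blanks):
        add_well(f"blank{b + 1}", "blank", None, 0)

    return curves, pd.DataFrame(plate_map)
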