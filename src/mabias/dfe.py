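"""Distributions of fitness effects with colony-bottleneck bias correction.

During mutation accumulation, each daily transfer picks one cell from a
colony grown from a single founder.  A mutation arising during colony growth
with benefit s leaves a slightly larger sub-lineage than a neutral one, so the
sampled cell carries beneficial mutations slightly more often than deleterious
ones.  This module models that within-colony enrichment, r(s), corrects DFEs
by reweighting each mutation by 1/r(s), and provides the comparison machinery
used downstream: chi-squared tests on beneficial/neutral/deleterious
fractions with Benjamini-Hochberg adjustment, without-replacement
subsampling, class-wise Wilcoxon rank-sum batteries with compact letter
displays, and bias-versus-f_b regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DFEConfig",
    "DFE",
    "DFEComparison",
    "colony_sampling_weight",
    "build_dfe",
    "compare_dfe_fractions",
    "compare_dfe_batch",
    "subsample_dfe",
    "class_fitness_tests",
    "bias_fb_regression",
]

#: s at (or below) which a mutation is treated as lethal: it sits in the most
#: deleterious bin but is excluded from r(s) weighting (weight taken at the
#: deleterious floor just above -1).
LETHAL_S = -1.0
_DELETERIOUS_FLOOR = -1.0 + 1e-3


@dataclass(frozen=True)
class DFEConfig:
    """Binning and correction parameters of a DFE.

    The neutral zone |s| <= neutral_half_width absorbs measurement error
    (half-widths 0.05 in LB, 0.025 in glucose); the default bin width equals
    the neutral half-width so the neutral zone is exactly one bin on either
    side of zero.  colony_generations is the number of doublings G in the
    overnight colony between transfers.
    """

    bin_width: float = 0.05
    neutral_half_width: float = 0.05
    colony_generations: int = 27
    apply_correction: bool = True
    correction_mode: str = "per-mutation"  # or "binned"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.neutral_half_width < 0:
            raise ValueError("neutral_half_width must be non-negative")
        ratio = self.neutral_half_width / self.bin_width
        if self.neutral_half_width > 0 and abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("the neutral zone must be a whole number of bins")
        if self.correction_mode not in ("per-mutation", "binned"):
            raise ValueError("correction_mode must be 'per-mutation' or 'binned'")

    @classmethod
    def for_environment(cls, environment: str, **kwargs) -> "DFEConfig":
        """LB uses a +/-0.05 neutral zone; glucose a finer +/-0.025 one."""
        half = {"LB": 0.05, "glucose": 0.025}.get(environment)
        if half is None:
            raise ValueError(f"no default neutral zone for environment {environment!r}")
        kwargs.setdefault("neutral_half_width", half)
        kwargs.setdefault("bin_width", half)
        return cls(**kwargs)


@dataclass
class DFE:
    """A binned DFE with raw counts and bias-corrected weights."""

    strain_id: str
    environment: str
    bin_edges: np.ndarray
    raw_counts: np.ndarray
    corrected_weights: np.ndarray
    n_mutations: int
    f_b: float
    f_n: float
    f_d: float
    median_s: float
    s_values: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "environment": self.environment,
            "bin_edges": self.bin_edges.tolist(),
            "raw_counts": self.raw_counts.tolist(),
            "corrected_weights": self.corrected_weights.tolist(),
            "n_mutations": self.n_mutations,
            "f_b": self.f_b,
            "f_n": self.f_n,
            "f_d": self.f_d,
            "median_s": self.median_s,
        }


@dataclass
class DFEComparison:
    strain_pair: tuple[str, str]
    chisq_stat: float
    p_raw: float
    p_adjusted: float | None = None
    low_expected: bool = False


# ---------------------------------------------------------------------------
# colony sampling model

def colony_sampling_weight(s, G: int = 27):
    """Relative probability r(s) of sampling a mutation of effect s at transfer.

    Deterministic colony-growth model: over G doublings of the founding cell,
    a mutation arises at division generation t with probability proportional
    to the number of divisions at t (2^t, t = 0..G-1).  The mutant sub-lineage
    thereafter doubles (1+s) times per ancestral doubling, so when the colony
    is picked its mutant fraction is

        f(s, t) = 2^[(1+s)(G-t)] / (2^G - 2^(G-t) + 2^[(1+s)(G-t)])

    and r(s) = E_t[f(s, t)] / E_t[f(0, t)].  r(0) = 1 and r is strictly
    increasing in s: beneficial mutations are slightly over-sampled, which is
    exactly the enrichment the DFE correction divides out.

    Accepts a scalar or array of s values (each must exceed -1); G >= 1.
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr <= -1.0):
        raise ValueError("s must exceed -1 (lethal mutations are handled upstream)")
    if G < 1:
        raise ValueError("G must be >= 1")
    t = np.arange(G, dtype=float)
    w = np.power(2.0, t)
    w /= w.sum()
    rem = G - t  # doublings remaining after the mutation arises

    def mean_fraction(sv: np.ndarray) -> np.ndarray:
        mut = np.power(2.0, np.outer(1.0 + sv, rem))  # (n_s, G)
        denom = 2.0**G - np.power(2.0, rem)[None, :] + mut
        return (w[None, :] * mut / denom).sum(axis=1)

    r = mean_fraction(s_arr) / mean_fraction(np.zeros(1))[0]
    return r if np.ndim(s) else float(r[0])


def _mutation_weights(s: np.ndarray, config: DFEConfig, weight_fn) -> np.ndarray:
    """Normalized per-mutation correction weights 1/r(s)."""
    if not config.apply_correction:
        w = np.ones_like(s)
    else:
        s_eff = np.maximum(s, _DELETERIOUS_FLOOR)
        if weight_fn is None:
            r = colony_sampling_weight(s_eff, config.colony_generations)
        else:
            r = np.asarray(weight_fn(s_eff), dtype=float)
        w = 1.0 / np.asarray(r, dtype=float)
    return w / w.sum()


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def build_dfe(
    s_values: Sequence[float],
    config: DFEConfig,
    strain_id: str = "",
    environment: str = "",
    weight_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> DFE:
    """Bin selection coefficients into a DFE and correct for colony sampling.

    With correction enabled each mutation carries weight proportional to
    1/r(s) (per-mutation mode, the default) before binning; binned mode
    instead reweights whole bins by 1/r at the bin midpoint.  The correction
    changes weights only, never the measured s values.  Class fractions use
    the neutral zone: f_b is the corrected weight at s > +neutral_half_width,
    f_d at s < -neutral_half_width, f_n the remainder; f_b + f_n + f_d = 1.
    A custom enrichment model may be supplied as ``weight_fn`` mapping s to
    r(s).
    """
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("cannot build a DFE from zero mutations")
    if not np.all(np.isfinite(s)):
        raise ValueError("selection coefficients must be finite")

    bw = config.bin_width
    lo = np.floor(min(s.min(), -config.neutral_half_width) / bw) * bw
    hi = np.ceil(max(s.max(), config.neutral_half_width) / bw) * bw
    if hi <= lo:
        hi = lo + bw
    n_bins = int(round((hi - lo) / bw))
    edges = lo + bw * np.arange(n_bins + 1)
    raw_counts, _ = np.histogram(s, bins=edges)

    if config.correction_mode == "per-mutation" or not config.apply_correction:
        weights = _mutation_weights(s, config, weight_fn)
        corrected, _ = np.histogram(s, bins=edges, weights=weights)
        h = config.neutral_half_width
        f_b = float(weights[s > h].sum())
        f_d = float(weights[s < -h].sum())
        median_s = _weighted_median(s, weights)
    else:  # binned mode: reweight whole bins at their midpoints
        mids = np.maximum((edges[:-1] + edges[1:]) / 2.0, _DELETERIOUS_FLOOR)
        if weight_fn is None:
            r = colony_sampling_weight(mids, config.colony_generations)
        else:
            r = np.asarray(weight_fn(mids), dtype=float)
        corrected = raw_counts / np.asarray(r, dtype=float)
        corrected = corrected / corrected.sum()
        h = config.neutral_half_width
        f_b = float(corrected[edges[:-1] >= h].sum())
        f_d = float(corrected[edges[1:] <= -h].sum())
        # weighted median over bins, at midpoints
        median_s = _weighted_median((edges[:-1] + edges[1:]) / 2.0, corrected)

    # guard against float round-off at the [0, 1] boundaries
    f_b = min(max(f_b, 0.0), 1.0)
    f_d = min(max(f_d, 0.0), 1.0 - f_b)
    f_n = 1.0 - f_b - f_d
    return DFE(
        strain_id=strain_id,
        environment=environment,
        bin_edges=edges,
        raw_counts=raw_counts,
        corrected_weights=corrected,
        n_mutations=int(s.size),
        f_b=f_b,
        f_n=f_n,
        f_d=f_d,
        median_s=median_s,
        s_values=s,
    )


# ---------------------------------------------------------------------------
# DFE comparisons

def _fractions_to_counts(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Round n*f to integers, repairing the largest remainder so sums hold."""
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw + 0.5).astype(int)  # round half away from zero (all values >= 0)
    deficit = n - counts.sum()
    if deficit != 0:
        remainders = raw - np.floor(raw)
        order = np.argsort(-remainders if deficit > 0 else remainders, kind="stable")
        for i in range(abs(deficit)):
            counts[order[i % len(counts)]] += 1 if deficit > 0 else -1
    return counts


def compare_dfe_fractions(dfe_a: DFE, dfe_b: DFE) -> DFEComparison:
    """Chi-squared test of (beneficial, neutral, deleterious) composition.

    Corrected fractions are converted back to effective counts at each DFE's
    sample size, and a 3x2 chi-squared contingency test is run.  Identical
    compositions give statistic 0, p = 1.  Expected cells below 1 set the
    ``low_expected`` flag (an exact test should be preferred there).
    """
    a = _fractions_to_counts(dfe_a.n_mutations, [dfe_a.f_b, dfe_a.f_n, dfe_a.f_d])
    b = _fractions_to_counts(dfe_b.n_mutations, [dfe_b.f_b, dfe_b.f_n, dfe_b.f_d])
    table = np.column_stack([a, b])
    nonzero = table.sum(axis=1) > 0
    table = table[nonzero]
    if table.shape[0] < 2:
        return DFEComparison((dfe_a.strain_id, dfe_b.strain_id), 0.0, 1.0)
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    low = bool((expected < 1).any())
    if low:
        warnings.warn(
            f"comparison {dfe_a.strain_id} vs {dfe_b.strain_id}: expected cell < 1; "
            "consider an exact test",
            stacklevel=2,
        )
    return DFEComparison((dfe_a.strain_id, dfe_b.strain_id), float(stat), float(p), low_expected=low)


def compare_dfe_batch(dfes: Sequence[DFE]) -> pd.DataFrame:
    """All pairwise composition tests with Benjamini-Hochberg adjustment."""
    comps = []
    for i in range(len(dfes)):
        for j in range(i + 1, len(dfes)):
            comps.append(compare_dfe_fractions(dfes[i], dfes[j]))
    if not comps:
        return pd.DataFrame(columns=["strain_a", "strain_b", "chisq", "p_raw", "p_adjusted"])
    p_adj = multipletests([c.p_raw for c in comps], method="fdr_bh")[1]
    for c, p in zip(comps, p_adj):
        c.p_adjusted = float(p)
    return pd.DataFrame(
        {
            "strain_a": [c.strain_pair[0] for c in comps],
            "strain_b": [c.strain_pair[1] for c in comps],
            "chisq": [c.chisq_stat for c in comps],
            "p_raw": [c.p_raw for c in comps],
            "p_adjusted": [c.p_adjusted for c in comps],
        }
    )


def subsample_dfe(
    dfe_source_s: Sequence[float],
    target_n: int,
    config: DFEConfig,
    iterations: int = 100,
    seed: int = 0,
) -> dict:
    """f_b stability under without-replacement subsampling to target_n.

    Re-estimates the corrected f_b on ``iterations`` random subsamples and
    reports the mean and the 2.5-97.5 percentile interval; deterministic for
    a fixed seed.
    """
    s = np.asarray(dfe_source_s, dtype=float)
    if target_n > s.size:
        raise ValueError(f"target_n {target_n} exceeds available mutations {s.size}")
    rng = np.random.default_rng(seed)
    fbs = np.empty(iterations)
    for i in range(iterations):
        sub = np.sort(rng.choice(s, size=target_n, replace=False))  # order-stable summation
        fbs[i] = build_dfe(sub, config).f_b
    return {
        "f_b_values": fbs,
        "mean": float(fbs.mean()),
        "ci_low": float(np.percentile(fbs, 2.5)),
        "ci_high": float(np.percentile(fbs, 97.5)),
        "target_n": target_n,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# class-wise fitness tests

def _compact_letters(groups: Sequence[str], significant: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different; every
    significant pair is separated in every letter set.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in significant:
        new_sets = []
        for sset in sets:
            if a in sset and b in sset:
                new_sets.append(sset - {a})
                new_sets.append(sset - {b})
            else:
                new_sets.append(sset)
        # absorb subsets
        sets = []
        for sset in sorted(new_sets, key=len, reverse=True):
            if not any(sset <= other for other in sets):
                sets.append(sset)
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    ordered = sorted(sets, key=lambda sset: min(groups.index(g) for g in sset) if sset else len(groups))
    for letter, sset in zip(alphabet, ordered):
        for g in sset:
            letters[g] += letter
    return {g: "".join(sorted(l)) for g, l in letters.items()}


def class_fitness_tests(
    records: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "s",
    alpha: float = 0.05,
) -> dict:
    """Pairwise Wilcoxon rank-sum battery over mutation-class groups.

    Groups with fewer than 2 observations are excluded with a warning.  All
    pairwise contrasts are tested with Wilcoxon's rank-sum statistic and
    Benjamini-Hochberg adjusted within the battery; strains/classes receive a
    compact letter display (same letter = not significantly different at
    ``alpha`` after adjustment).  Returns {"tests": DataFrame, "letters":
    {group: letters}}.
    """
    sizes = records.groupby(group_col)[value_col].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 observations: {small}", stacklevel=2)
    groups = [g for g in sizes.index if g not in small]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x = records.loc[records[group_col] == groups[i], value_col].to_numpy()
            y = records.loc[records[group_col] == groups[j], value_col].to_numpy()
            stat, p = stats.ranksums(x, y)
            rows.append({"group_a": groups[i], "group_b": groups[j], "statistic": stat, "p_raw": p})
    tests = pd.DataFrame(rows)
    tests["p_adjusted"] = multipletests(tests["p_raw"], method="fdr_bh")[1]
    significant = {
        (r.group_a, r.group_b) for r in tests.itertuples() if r.p_adjusted < alpha
    }
    letters = _compact_letters(list(groups), significant)
    return {"tests": tests, "letters": letters}


def bias_fb_regression(points: Sequence[tuple[float, float]] | pd.DataFrame) -> dict:
    """OLS of f_b on a mutation-bias axis across strains.

    Accepts (x, y) pairs or a two-column DataFrame; returns slope, intercept,
    R^2 and the slope's p-value.  Also serves for f_b versus ancestral growth
    rate.  Requires at least 3 strains.
    """
    if isinstance(points, pd.DataFrame):
        x = points.iloc[:, 0].to_numpy(dtype=float)
        y = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if x.size < 3:
        raise ValueError("need at least 3 strains for a regression")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(x.size),
    }
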