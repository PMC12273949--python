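"""Mutation catalogue: filtering, classification, spectra, biases, and rates.

Mutation-accumulation (MA) experiments propagate many independent lines of a
strain through daily single-colony bottlenecks, so that mutations accumulate
nearly free of selection.  Whole-genome sequencing of the evolved clones and
their ancestors yields per-line variant tables; this module turns those tables
into a mutation catalogue and summarises it: transition/transversion and
GC-direction spectra, bias ratios with binomial confidence intervals, the
genomic mutation rate per bp per generation, and a Poisson goodness-of-fit
diagnostic on the per-line mutation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MutationRecord",
    "VariantFilterConfig",
    "SpectrumSummary",
    "BiasEstimate",
    "PoissonGOFResult",
    "InputFormatError",
    "apply_filters",
    "classify_bps",
    "compute_bias",
    "mutation_rate",
    "tally_spectrum",
    "poisson_gof",
    "recall_check",
    "gene_gc_table",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID_BASES = frozenset("ACGT")

#: canonical column order of the tab-separated mutation-table dialect
MUTATION_TABLE_COLUMNS = [
    "strain", "block", "line", "position", "ref", "alt", "class",
    "freq", "reads_plus", "reads_minus", "region", "coding_effect", "gene",
]

MUTATION_CLASSES = {"BPS", "insertion", "deletion", "large_indel", "duplication"}
SHORT_INDEL_CLASSES = {"insertion", "deletion"}
INDEL_CLASSES = {"insertion", "deletion", "large_indel"}


class InputFormatError(ValueError):
    """A variant table is missing required columns or is malformed."""


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation with read support, frequency, and annotation."""

    strain_id: str
    block_id: str
    line_id: str
    position: int  # 1-based, fully closed (VCF convention)
    ref_allele: str
    alt_allele: str
    mutation_class: str
    allele_frequency: float
    reads_plus: int
    reads_minus: int
    region: str  # coding | noncoding
    coding_effect: str  # synonymous | nonsynonymous | not_applicable
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency {self.allele_frequency} not in [0, 1]")
        if self.mutation_class not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")
        if self.reads_plus < 0 or self.reads_minus < 0:
            raise ValueError("read counts must be non-negative")
        if self.mutation_class == "BPS":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("BPS records must have single-nucleotide alleles")
            if self.ref_allele == self.alt_allele:
                raise ValueError("BPS ref and alt alleles must differ")
        expect_na = self.region == "noncoding" or self.mutation_class != "BPS"
        if expect_na != (self.coding_effect == "not_applicable"):
            raise ValueError(
                "coding_effect must be not_applicable iff the record is noncoding "
                "or not a base-pair substitution"
            )


@dataclass(frozen=True)
class VariantFilterConfig:
    """Read-support and frequency filters applied to raw variant calls.

    Defaults: a variant must be seen on both strands, by at least 4 reads per
    strand, and at a frequency strictly above 0.80.  The frequency filter
    removes mutations that arose late during colony growth or during stock
    preparation rather than during the MA propagation itself.
    """

    min_reads_per_strand: int = 4
    min_frequency: float = 0.80
    require_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_reads_per_strand < 0:
            raise ValueError("min_reads_per_strand must be >= 0")
        if not 0.0 <= self.min_frequency <= 1.0:
            raise ValueError("min_frequency must lie in [0, 1]")


@dataclass
class BiasEstimate:
    """A mutation-class bias a/(a+b) with a binomial 95% CI.

    The CI half-width is 1.96 * sqrt(p(1-p)/n_lines), with n_lines the number
    of successfully sequenced MA lines contributing mutations.
    """

    value: float
    ci_half_width: float
    count_a: int
    count_b: int
    n_lines: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


@dataclass
class SpectrumSummary:
    """Per-strain mutation counts, partitioned by class, with rate mu."""

    strain_id: str
    n_lines: int
    total_generations: float
    counts: dict[str, int]
    mu: float
    mu_ci_half_width: float | None  # None = unavailable (no per-line counts)


@dataclass
class PoissonGOFResult:
    """Chi-squared goodness of fit of per-line mutation counts to a Poisson."""

    lambda_hat: float
    observed: np.ndarray
    expected: np.ndarray
    categories: list[str]
    chisq_stat: float
    dof: int
    p_value: float


# ---------------------------------------------------------------------------
# filtering

_STRAND_COLS = ("reads_plus", "reads_minus")


def apply_filters(
    variants: pd.DataFrame,
    ancestor_variants: pd.DataFrame | None,
    config: VariantFilterConfig = VariantFilterConfig(),
) -> list[MutationRecord]:
    """Filter raw variant calls and subtract ancestral variants.

    Three filters are applied to the evolved-line table: representation on
    both strands, at least ``min_reads_per_strand`` reads on each strand, and
    allele frequency strictly greater than ``min_frequency``.  Any surviving
    variant whose (position, ref, alt) matches a row of ``ancestor_variants``
    is then removed; ancestral variants match at *any* frequency, since
    ancestors are deliberately called with a relaxed frequency filter to catch
    mutations segregating below the evolved-line threshold.

    The operation is idempotent and order-independent over input rows.
    """
    for col in _STRAND_COLS:
        if col not in variants.columns:
            raise InputFormatError(f"variant table lacks required column {col!r}")
    if "freq" not in variants.columns or "position" not in variants.columns:
        raise InputFormatError("variant table needs 'position' and 'freq' columns")
    if (variants[list(_STRAND_COLS)] < 0).any().any():
        raise ValueError("negative read counts in variant table")

    keep = variants["freq"] > config.min_frequency
    keep &= variants["reads_plus"] >= config.min_reads_per_strand
    keep &= variants["reads_minus"] >= config.min_reads_per_strand
    if config.require_both_strands:
        keep &= (variants["reads_plus"] > 0) & (variants["reads_minus"] > 0)
    passing = variants.loc[keep]

    if ancestor_variants is not None and len(ancestor_variants):
        anc_keys = set(
            zip(
                ancestor_variants["position"].astype(int),
                ancestor_variants["ref"].astype(str),
                ancestor_variants["alt"].astype(str),
            )
        )
        mask = [
            (int(p), str(r), str(a)) not in anc_keys
            for p, r, a in zip(passing["position"], passing["ref"], passing["alt"])
        ]
        passing = passing.loc[mask]

    return table_to_records(passing)


def table_to_records(table: pd.DataFrame) -> list[MutationRecord]:
    """Convert a mutation-table DataFrame into MutationRecord objects."""
    records = []
    for _, row in table.iterrows():
        gene = row.get("gene")
        if gene is not None and (pd.isna(gene) or str(gene) == ""):
            gene = None
        records.append(
            MutationRecord(
                strain_id=str(row.get("strain", "")),
                block_id=str(row.get("block", "")),
                line_id=str(row.get("line", "")),
                position=int(row["position"]),
                ref_allele=str(row["ref"]),
                alt_allele=str(row["alt"]),
                mutation_class=str(row.get("class", "BPS")),
                allele_frequency=float(row["freq"]),
                reads_plus=int(row["reads_plus"]),
                reads_minus=int(row["reads_minus"]),
                region=str(row.get("region", "noncoding")),
                coding_effect=str(row.get("coding_effect", "not_applicable")),
                gene_id=str(gene) if gene is not None else None,
            )
        )
    return records


def records_to_table(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Inverse of :func:`table_to_records`, in the canonical column order."""
    rows = [
        {
            "strain": r.strain_id, "block": r.block_id, "line": r.line_id,
            "position": r.position, "ref": r.ref_allele, "alt": r.alt_allele,
            "class": r.mutation_class, "freq": r.allele_frequency,
            "reads_plus": r.reads_plus, "reads_minus": r.reads_minus,
            "region": r.region, "coding_effect": r.coding_effect,
            "gene": r.gene_id if r.gene_id is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# classification

def classify_bps(ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """Classify a base-pair substitution as (transition|transversion, GC direction).

    Transitions are purine<->purine or pyrimidine<->pyrimidine changes.  The
    GC direction is strand-symmetric: G->A and its complement C->T both count
    as GC->AT.  A<->T and G<->C substitutions leave GC content unchanged and
    return "no_change".
    """
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"ambiguous or non-ACGT base in substitution {ref!r}->{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")

    same_family = (ref in PURINES) == (alt in PURINES)
    ts_tv = "transition" if same_family else "transversion"

    ref_gc = ref in "GC"
    alt_gc = alt in "GC"
    if ref_gc and not alt_gc:
        gc_direction = "GC_to_AT"
    elif alt_gc and not ref_gc:
        gc_direction = "AT_to_GC"
    else:
        gc_direction = "no_change"
    return ts_tv, gc_direction


def compute_bias(count_a: int, count_b: int, n_lines: int) -> BiasEstimate:
    """Bias of class A over classes A+B, with a binomial 95% CI.

    value = a / (a + b); ci = 1.96 * sqrt(value * (1 - value) / n_lines).
    With zero mutations of either class the bias is undefined (NaN value).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        return BiasEstimate(float("nan"), float("nan"), count_a, count_b, n_lines)
    value = count_a / total
    ci = 1.96 * math.sqrt(value * (1.0 - value) / n_lines)
    return BiasEstimate(value, ci, count_a, count_b, n_lines)


# ---------------------------------------------------------------------------
# mutation rate

def mutation_rate(
    total_mutations: int,
    genome_size: float,
    line_generations: Sequence[float],
    per_line_counts: Sequence[int] | None = None,
) -> tuple[float, float | None]:
    """Genomic mutation rate per bp per generation, with a t-based 95% CI.

    mu = total mutations / (genome size * total line-generations), where the
    total line-generations sum days-of-evolution x generations-per-day over
    all lines.  The CI is the margin of error of a t distribution over the
    per-line rates; it therefore needs per-line mutation counts, and is
    reported as unavailable (None) when only the strain total is known.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    gens = np.asarray(line_generations, dtype=float)
    if gens.size == 0 or gens.sum() <= 0:
        raise ValueError("total generations must be positive")
    mu = total_mutations / (genome_size * gens.sum())

    ci: float | None = None
    if per_line_counts is not None:
        counts = np.asarray(per_line_counts, dtype=float)
        if counts.size != gens.size:
            raise ValueError("per_line_counts and line_generations must align")
        n = counts.size
        if n >= 2:
            rates = counts / (genome_size * gens)
            t_crit = stats.t.ppf(0.975, df=n - 1)
            ci = float(t_crit * rates.std(ddof=1) / math.sqrt(n))
    return float(mu), ci


# ---------------------------------------------------------------------------
# spectrum tally

SPECTRUM_KEYS = [
    "BPS", "indels", "transitions", "transversions", "coding", "noncoding",
    "synonymous", "nonsynonymous", "AT_to_GC", "GC_to_AT", "gc_neutral",
]


def tally_spectrum(
    mutations: Sequence[MutationRecord],
    n_lines: int,
    total_generations: float,
    genome_size: float,
    per_line_counts: Sequence[int] | None = None,
    per_line_generations: Sequence[float] | None = None,
) -> SpectrumSummary:
    """Tally a strain's mutation list into the class counts of its spectrum.

    The counts partition cleanly: transitions + transversions = BPS,
    coding + noncoding = BPS, synonymous + nonsynonymous = coding (BPS), and
    AT->GC + GC->AT + gc_neutral = BPS.  Indels and larger events are counted
    separately.  mu is filled via :func:`mutation_rate`.
    """
    strain_ids = {m.strain_id for m in mutations}
    if len(strain_ids) > 1:
        raise ValueError(f"mixed strain_ids in mutation list: {sorted(strain_ids)}")
    strain_id = strain_ids.pop() if strain_ids else ""

    counts = dict.fromkeys(SPECTRUM_KEYS, 0)
    for m in mutations:
        if m.mutation_class == "BPS":
            counts["BPS"] += 1
            ts_tv, gc_dir = classify_bps(m.ref_allele, m.alt_allele)
            counts["transitions" if ts_tv == "transition" else "transversions"] += 1
            counts[{"AT_to_GC": "AT_to_GC", "GC_to_AT": "GC_to_AT", "no_change": "gc_neutral"}[gc_dir]] += 1
            counts["coding" if m.region == "coding" else "noncoding"] += 1
            if m.region == "coding":
                counts[m.coding_effect] = counts.get(m.coding_effect, 0) + 1
        elif m.mutation_class in INDEL_CLASSES or m.mutation_class == "duplication":
            counts["indels"] += 1

    total = counts["BPS"] + counts["indels"]
    if total_generations > 0:
        if per_line_generations is None:
            per_line_generations = [total_generations]
        mu, ci = mutation_rate(total, genome_size, per_line_generations, per_line_counts)
    else:
        mu, ci = 0.0, None
    return SpectrumSummary(
        strain_id=strain_id,
        n_lines=n_lines,
        total_generations=total_generations,
        counts=counts,
        mu=mu,
        mu_ci_half_width=ci,
    )


def spectrum_biases(summary: SpectrumSummary) -> dict[str, BiasEstimate]:
    """The five standard bias ratios of a spectrum summary.

    transversion: Tv/(Ts+Tv); indel: indels/(indels+BPS); noncoding:
    noncoding/BPS; synonymous: syn/(syn+nonsyn); gc_at: GC->AT/(GC->AT+AT->GC).
    """
    c = summary.counts
    n = summary.n_lines
    return {
        "transversion": compute_bias(c["transversions"], c["transitions"], n),
        "indel": compute_bias(c["indels"], c["BPS"], n),
        "noncoding": compute_bias(c["noncoding"], c["coding"], n),
        "synonymous": compute_bias(c["synonymous"], c["nonsynonymous"], n),
        "gc_at": compute_bias(c["GC_to_AT"], c["AT_to_GC"], n),
    }


# ---------------------------------------------------------------------------
# Poisson goodness of fit

def poisson_gof(per_line_counts: Sequence[int], min_expected: float = 5.0) -> PoissonGOFResult:
    """Chi-squared test of per-line mutation counts against Poisson(lambda_hat).

    Under the MA design, mutations should arrive independently at a constant
    rate, so per-line counts should be Poisson.  lambda_hat is the sample
    mean; count categories 0, 1, 2, ... have their right tail pooled until
    every expected count is at least ``min_expected``; dof = categories - 2
    (one for the estimated mean, one for the fixed total).

    Blocks evolved for different numbers of generations have different means
    and must be tested separately.
    """
    counts = np.asarray(per_line_counts, dtype=int)
    if counts.size < 2:
        raise ValueError("need at least 2 lines")
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    lam = counts.mean()
    if lam == 0:
        raise ValueError("degenerate input: all per-line counts are zero")
    n = counts.size

    kmax = counts.max()
    ks = np.arange(kmax + 1)
    expected = n * stats.poisson.pmf(ks, lam)
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    # open right tail: everything above kmax
    expected = np.append(expected, n * stats.poisson.sf(kmax, lam))
    observed = np.append(observed, 0.0)

    # pool the right tail until every expected count clears the threshold
    exp_list = list(expected)
    obs_list = list(observed)
    while len(exp_list) > 3 and exp_list[-1] < min_expected:
        tail_e, tail_o = exp_list.pop(), obs_list.pop()
        exp_list[-1] += tail_e
        obs_list[-1] += tail_o
    if len(exp_list) < 3:
        raise ValueError("too few count categories for a chi-squared test")
    expected = np.asarray(exp_list)
    observed = np.asarray(obs_list)

    categories = [str(k) for k in range(len(expected) - 1)] + [f">={len(expected) - 1}"]
    stat = float(((observed - expected) ** 2 / expected).sum())
    dof = len(expected) - 2
    p = float(stats.chi2.sf(stat, dof))
    return PoissonGOFResult(float(lam), observed, expected, categories, stat, dof, p)


# ---------------------------------------------------------------------------
# recall of known background mutations

def recall_check(
    mutation_lists: Mapping[str, pd.DataFrame],
    expected: Sequence[tuple[int, str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recall of known ancestral background mutations across evolved lines.

    Background mutations fixed in the common ancestor must reappear in every
    evolved line; their recall rate estimates the false-negative rate of the
    calling pipeline.  Returns (per-line table, per-mutation summary); the
    table has one row per line per expected mutation with its found flag and
    the called allele frequency (NaN when absent).
    """
    rows = []
    for line_id, table in mutation_lists.items():
        if len(table):
            keyed = {
                (int(p), str(r), str(a)): float(f)
                for p, r, a, f in zip(table["position"], table["ref"], table["alt"], table["freq"])
            }
        else:
            keyed = {}
        for pos, ref, alt in expected:
            key = (int(pos), str(ref), str(alt))
            found = key in keyed
            rows.append(
                {
                    "line": line_id, "position": int(pos), "ref": ref, "alt": alt,
                    "found": found, "freq": keyed.get(key, float("nan")),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        summary = (
            table.groupby(["position", "ref", "alt"], as_index=False)
            .agg(recall=("found", "mean"), n_lines=("found", "size"))
        )
    else:
        summary = pd.DataFrame(columns=["position", "ref", "alt", "recall", "n_lines"])
    return table, summary


# ---------------------------------------------------------------------------
# gene GC content

def gene_gc_table(genome_fasta: str, annotation_gff3: str) -> pd.DataFrame:
    """Per-gene GC fraction from a genome FASTA and GFF3 gene annotation.

    Returns a table (gene_id, seqid, start, end, length, gc_fraction,
    gc_class) where gc_class is "low" or "high" relative to the median gene
    GC fraction.  Coordinates are 1-based fully closed per GFF3.
    """
    import gffutils
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome_fasta, "fasta")}
    db = gffutils.create_db(
        str(annotation_gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in seqs:
            raise ValueError(f"unknown sequence {feat.seqid!r} in annotation")
        seq = seqs[feat.seqid]
        if feat.start < 1 or feat.end > len(seq) or feat.start > feat.end:
            raise ValueError(
                f"gene coordinates {feat.start}-{feat.end} outside sequence {feat.seqid!r}"
            )
        gene_id = feat.id or f"{feat.seqid}:{feat.start}-{feat.end}"
        sub = seq[feat.start - 1 : feat.end]
        gc = (sub.count("G") + sub.count("C")) / len(sub)
        rows.append(
            {
                "gene_id": gene_id, "seqid": feat.seqid, "start": feat.start, "end": feat.end,
                "length": feat.end - feat.start + 1, "gc_fraction": gc,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        median_gc = table["gc_fraction"].median()
        table["gc_class"] = np.where(table["gc_fraction"] < median_gc, "low", "high")
    else:
        table["gc_class"] = pd.Series(dtype=str)
    return table
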