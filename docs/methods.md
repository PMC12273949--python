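# Methods

## Mutation catalogue

Variant tables (one per evolved MA line, tab-separated) carry per-strand read
counts and an allele frequency per call.  Three filters are applied:
representation on both strands, at least 4 reads per strand, and frequency
strictly above 0.80.  The frequency cut is strict at the boundary (a call at
exactly 0.80 is removed); its purpose is to drop mutations that arose during
late colony growth or during stock preparation rather than during MA
propagation.  Ancestor subtraction matches on (position, ref, alt) exactly —
no fuzzy indel matching — and ancestral variants match at *any* frequency,
because ancestors are deliberately called with a relaxed frequency filter to
catch sub-threshold segregating mutations.  Coordinates are 1-based and fully
closed (the VCF convention of the upstream callers).  Filtering is idempotent
and order-independent.

Base-pair substitutions are classified strand-symmetrically: a G→A call and
its complement C→T both count as GC→AT, so reverse-strand calls fold onto the
six canonical substitution types.  A↔T and G↔C changes are GC-neutral.

**Biases.** Every bias is `count_A/(count_A+count_B)`.  The 95% CI is the
binomial form `1.96·√(p(1−p)/n)` with *n* the number of successfully
sequenced lines.  This form was reverse-engineered: it reproduces the
published interval of the reference panel in all seven strains to 3 decimal
places, which is the package's oracle for the convention.

**Mutation rate.** `μ = total mutations/(genome size × Σ line-generations)`,
with generations per line defaulting to days × 27 (the measured number of
generations in one 24 h colony cycle on LB agar); per-block overrides are
supported because blocks of the same strain can differ in length.  The CI is
the margin of error of a t distribution over per-line rates and therefore
requires per-line counts; when only strain totals are available the CI is
reported as unavailable rather than approximated.

**Poisson goodness of fit.** Under the MA design mutations arrive
independently at a constant rate, so per-line counts should be Poisson with
λ equal to the per-line mean.  The chi-squared test pools the right tail of
the count categories until every expected count is ≥ 5 (standard validity
practice; the pooling rule is this package's choice) and uses dof = k − 2.
Blocks evolved for different lengths have different means and must be tested
per block.  Calibration: on Poisson-simulated counts the test rejects at
~5% (measured 4.6% over 1,000 replicates in the suite).

**Gene GC.** Gene features are read from GFF3 via gffutils and sequences via
Biopython; genes are classed low/high GC against the median gene GC fraction.

## Growth-curve fitness

The published experimental protocol delegates rate fitting to external
software without parameters, so the fitter here is a documented, configurable
re-implementation: every contiguous window of 5 readings (1 h at 15-min
sampling) above the detection floor (OD 0.01 after blank subtraction) is fit
by least squares on ln OD600 versus time, and the steepest slope among
windows with R² ≥ 0.99 is the maximum growth rate (per hour).  Blank handling
subtracts the per-plate mean blank and clips at the floor.  The estimate is
exactly invariant to uniform OD scaling.  Relative fitness is the arithmetic
mean of the three technical replicates divided by the same-plate ancestor
rate (no outlier rejection), and `s` = relative fitness − 1.

Known behaviour: on a noiseless logistic curve the windowed fit underestimates
the intrinsic rate by ~2–3% (the window never sits entirely in the
vanishing-density limit); the bias is common to evolved and ancestor wells
and largely cancels in the ratio.  With additive read noise the max-slope
selection is slightly upward-biased and has an error sd of ~0.01 on `s` for a
single plate at the simulator's default noise; averages over replicate plates
are unbiased to well within ±0.01.

## DFE construction and colony-sampling correction

At each MA bottleneck one cell is sampled from a colony grown from a single
founder over G ≈ 27 doublings.  A mutation arising at division generation t
(probability ∝ 2^t) founds a sub-lineage that doubles (1+s) times per
ancestral doubling, so the sampled-cell enrichment of effect-s mutations is

    r(s) = E_t[f(s,t)] / E_t[f(0,t)],
    f(s,t) = 2^{(1+s)(G−t)} / (2^G − 2^{G−t} + 2^{(1+s)(G−t)}).

r(0) = 1 and r is strictly increasing, so beneficial mutations are
over-sampled and deleterious ones under-sampled.  This deterministic
expectation is a plug-in approximation to the fully stochastic colony: a
pure-birth (Yule) simulation at G = 12 agrees within 2–7% over |s| ≤ 0.3
(the Jensen gap of the ratio), which the suite checks at 10% tolerance.
`r` is pluggable — a user-supplied weight function can replace the built-in
model.

DFEs bin measured selection coefficients on edges aligned to multiples of the
bin width; by default the bin width equals the environment's neutral
half-width (0.05 in LB, 0.025 in glucose, reflecting the measurement-error
envelopes of the two assays) so the neutral zone is exactly one bin on either
side of zero.  With correction enabled each mutation carries weight
∝ 1/r(s) before binning (per-mutation mode); a bin-level mode that reweights
whole bins at their midpoints is available behind a flag, since it is
ambiguous whether the published procedure weights mutations or bins.  The
correction changes weights only — never the measured s values — and can only
decrease the beneficial fraction, since r(s) ≥ 1 exactly when s ≥ 0.
Fractions use the neutral zone strictly: f_b is the corrected weight at
s > +h, f_d at s < −h, f_n the rest.  Lethal isolates (no growth, s = −1)
sit in the most deleterious bin but are excluded from r(s) weighting; their
weight is evaluated at a deleterious floor just above −1.

Composition comparisons convert corrected fractions back to effective counts
(round half away from zero, largest-remainder repair so counts sum to n) and
run 3×2 chi-squared tests, Benjamini–Hochberg adjusted across the declared
family; expected cells below 1 raise a warning with an exact-test flag.
Class-wise fitness contrasts use Wilcoxon's rank-sum test, BH-adjusted, with
a compact letter display built by insert-and-absorb.  Subsampling draws
without replacement (100 iterations, percentile interval, deterministic under
a fixed seed).

## Supply and load

`S_b = f_b·μ·L` and `L_d = f_d·μ·L` with L = 4,641,652 bp (E. coli K-12
MG1655).  CIs propagate the binomial sd of the fraction at the DFE's sample
size with μ treated as fixed — a documented choice, since the propagation is
not otherwise specified.  Counterfactual columns recompute both with the
wild type's fractions and each strain's own μ, so across strains they are
exactly proportional to μ; the identity
`rel_S_b / rel_S_b(WT DFE) = f_b(strain)/f_b(WT)` holds by construction and
is tested.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular dataset:

- per-line mutation counts ~ Poisson(μ·L·generations); positions uniform,
  collisions redrawn; no hotspots (the Poisson diagnostic assumes none);
- classes drawn from a product of conditionals (BPS vs indel, Ts vs Tv, GC
  direction, coding vs noncoding, synonymous vs nonsynonymous); defaults
  emulate a wild-type-like spectrum;
- read support 4 + Poisson(16) per strand and frequency U(0.85, 1) so true
  mutations pass the default filters; an optional decoy fraction plants
  variants violating exactly one filter;
- fitness effects per class from a mixture of a neutral point mass (weight
  0.45), an exponential beneficial tail (weight 0.15, mean 0.04) and a
  negative gamma deleterious component (weight 0.40, shape 1.5, scale 0.06),
  with an additive right-shift for transversions.  The family and weights are
  generative choices giving beneficial fractions of the order seen in MA
  work (~0.05–0.4), not estimates of any real strain;
- within-colony bias injected through the same r(s): "thin" mode retains
  each mutation with probability r/max(r) (an s-enriched subset of random
  size), "resample" mode draws a same-size cohort with probability ∝ r(s) —
  the literal forward model of the bottleneck colony pick, used for
  round-trip calibration because it preserves the cohort size;
- plates: logistic OD600 trajectories, K = 1, initial OD 0.03 (a 1:100
  inoculum of a stationary overnight culture), 1 h lag, readings every
  15 min for 16 h, additive Gaussian read noise sd 0.0005 (bench plate-reader
  repeatability), three technical replicates per clone plus ancestor,
  reference, and blank wells.

Every output is bit-for-bit reproducible from (config, seed) and the truth
ledger records every draw, so downstream estimates are scored without
re-simulation.

What passing the synthetic tests does *not* show: the generator has no
sequencing-error structure (no alignment artefacts, no systematic
strand bias), no mutational hotspots, no biological well-to-well variability
beyond read noise, and independent effects across mutations (no epistasis).
Agreement on synthetic data validates the estimators' arithmetic and
calibration, not the biology of any real experiment.

## Numerical choices and degenerate inputs

- Bias with zero mutations of both classes is undefined (NaN + flag), not 0.
- The frequency filter boundary is strict; ancestor matching ignores the
  ancestor-side frequency.
- The f_b/f_d thresholds are strict inequalities; a shifted neutral point
  mass landing exactly on a zone boundary is therefore *not* counted
  beneficial — comparisons across strains should avoid placing generative
  atoms exactly on a boundary (the suite's headline comparison uses the
  glucose zone for this reason).
- Random numbers: one seeded generator per operation, substreams derived
  deterministically; seeds are recorded in outputs.
- Subsampled DFEs sort each subsample before binning so results are
  independent of draw order at the bit level.

## Scale of the shipped analyses

The `analysis/` drivers simulate 3 strains × 300 lines (~380 mutations per
strain, ~110 single-mutation clones) and ~14 plates of 96 wells — around one
third the scale of the motivating experiments, chosen so the complete
pipeline re-runs from scratch in well under a minute while every estimator
operates in its calibrated regime.

## Known limitations

- The deterministic r(s) is a plug-in expectation (few-percent Jensen gap at
  |s| ≳ 0.3); substitute a stochastic weight table via the pluggable hook if
  colony sizes are small.
- The printed mutation rates of strains whose MA blocks differ in length are
  not reproducible from strain-level totals with a uniform-days shortcut;
  per-block accounting is required, and the reference panel stores
  per-strain day counts only where uniform.
- The growth fitter reports the steepest qualifying window, which is mildly
  upward-biased under noise; rates are comparable within a study but not
  absolute doubling rates.
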