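"""Growth-curve fitness: maximum growth rates from OD600 time series.

Fitness of each single-mutation clone is its maximum exponential growth rate,
estimated as the steepest slope of log OD600 versus time over a sliding
window, relative to the growth rate of the matched ancestor measured on the
same plate.  The selection coefficient of the carried mutation is

    s = (evolved growth rate / ancestral growth rate) - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthFitConfig",
    "GrowthFit",
    "FitnessRecord",
    "PlateQCReport",
    "NoGrowthError",
    "FitQualityError",
    "fit_max_growth_rate",
    "relative_fitness",
    "plate_qc",
    "subtract_blanks",
    "plate_fitness_table",
]


class NoGrowthError(ValueError):
    """Too few readings above the detection floor to fit a growth rate."""


class FitQualityError(ValueError):
    """No sliding window met the R^2 quality threshold."""

    def __init__(self, message: str, best_rate: float, best_r2: float):
        super().__init__(message)
        self.best_rate = best_rate
        self.best_r2 = best_r2


@dataclass
class GrowthCurve:
    """One well's OD600 time series.  Times in minutes, strictly increasing."""

    plate_id: str
    well_id: str
    clone_id: str
    role: str  # evolved | ancestor | reference | blank
    environment: str  # LB | glucose | ...
    times: np.ndarray
    od600: np.ndarray
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape:
            raise ValueError("times and od600 must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class GrowthFitConfig:
    window_points: int = 5  # 1 h at 15-min sampling
    min_od: float = 0.01  # detection floor after blank subtraction
    min_r2: float = 0.99
    blank_policy: str = "per-plate-mean"  # or per-well

    def __post_init__(self) -> None:
        if self.window_points < 3:
            raise ValueError("window_points must be >= 3")
        if not 0.0 < self.min_r2 <= 1.0:
            raise ValueError("min_r2 must lie in (0, 1]")


@dataclass
class GrowthFit:
    rate_per_hour: float
    r_squared: float
    window_start_min: float
    window_end_min: float
    n_points_used: int


@dataclass
class FitnessRecord:
    """Per-clone fitness relative to the ancestor measured on the same plate."""

    clone_id: str
    environment: str
    growth_rate: float  # per hour, mean of technical replicates
    ancestor_rate: float  # per hour
    relative_fitness: float
    s: float


@dataclass
class PlateQCReport:
    plate_id: str
    qc_pass: bool
    flags: list[str] = field(default_factory=list)
    reference_rate: float | None = None
    reference_deviation_sd: float | None = None
    contaminated_blanks: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def _sliding_regressions(t: np.ndarray, y: np.ndarray, w: int):
    """Slope and R^2 of ordinary least squares over every window of w points."""
    n = t.size - w + 1
    ones = np.ones(w)
    sx = np.convolve(t, ones, "valid")
    sy = np.convolve(y, ones, "valid")
    sxx = np.convolve(t * t, ones, "valid")
    sxy = np.convolve(t * y, ones, "valid")
    syy = np.convolve(y * y, ones, "valid")
    cov = w * sxy - sx * sy
    var_x = w * sxx - sx * sx
    var_y = w * syy - sy * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov / var_x
        r2 = np.where(var_y > 0, cov * cov / (var_x * var_y), 0.0)
    return slope[:n], r2[:n]


def fit_max_growth_rate(curve: GrowthCurve, config: GrowthFitConfig = GrowthFitConfig()) -> GrowthFit:
    """Maximum slope of ln OD600 vs. time over qualifying sliding windows.

    Only readings above the detection floor enter the fit.  Every contiguous
    window of ``window_points`` readings is fit by least squares on the log
    scale; the steepest slope among windows with R^2 >= ``min_r2`` is the
    growth rate, reported per hour.  The estimate is invariant to uniform
    scaling of the OD readings.
    """
    above = curve.od600 > config.min_od
    t = curve.times[above]
    od = curve.od600[above]
    w = config.window_points
    if t.size < w:
        raise NoGrowthError(
            f"well {curve.well_id}: only {t.size} readings above the detection "
            f"floor {config.min_od} (need {w})"
        )
    t_hours = t / 60.0
    y = np.log(od)
    slopes, r2s = _sliding_regressions(t_hours, y, w)
    ok = r2s >= config.min_r2
    if not ok.any():
        best = int(np.argmax(r2s))
        raise FitQualityError(
            f"well {curve.well_id}: no {w}-point window reached R^2 >= {config.min_r2} "
            f"(best window R^2 = {r2s[best]:.4f})",
            best_rate=float(slopes[best]),
            best_r2=float(r2s[best]),
        )
    idx = int(np.argmax(np.where(ok, slopes, -np.inf)))
    return GrowthFit(
        rate_per_hour=float(slopes[idx]),
        r_squared=float(r2s[idx]),
        window_start_min=float(t[idx]),
        window_end_min=float(t[idx + w - 1]),
        n_points_used=int(t.size),
    )


def relative_fitness(
    evolved_rates,
    ancestor_rate: float,
    clone_id: str = "",
    environment: str = "",
) -> FitnessRecord:
    """Selection coefficient from technical-replicate growth rates.

    The evolved clone's rate is the arithmetic mean of its three technical
    replicates (a deviating replicate count is tolerated with a warning);
    relative fitness is the ratio to the same-plate ancestor rate, and
    s = relative fitness - 1.
    """
    if ancestor_rate <= 0:
        raise ValueError("ancestor growth rate must be positive")
    rates = np.asarray(evolved_rates, dtype=float)
    if rates.size != 3:
        warnings.warn(
            f"clone {clone_id or '?'}: expected 3 technical replicates, got {rates.size}; "
            "using the mean of available replicates",
            stacklevel=2,
        )
    rel = float(rates.mean() / ancestor_rate)
    return FitnessRecord(
        clone_id=clone_id,
        environment=environment,
        growth_rate=float(rates.mean()),
        ancestor_rate=float(ancestor_rate),
        relative_fitness=rel,
        s=rel - 1.0,
    )


# ---------------------------------------------------------------------------
# plate-level processing

def subtract_blanks(curves: list[GrowthCurve], config: GrowthFitConfig = GrowthFitConfig()) -> list[GrowthCurve]:
    """Blank-correct a plate's curves; readings clip at the detection floor.

    Per-plate-mean policy subtracts the time-averaged mean OD of all blank
    wells from every non-blank well; blank wells are left untouched so QC can
    still inspect them.
    """
    blanks = [c for c in curves if c.role == "blank"]
    if not blanks:
        return curves
    if config.blank_policy == "per-plate-mean":
        baseline = float(np.mean([c.od600.mean() for c in blanks]))
    else:  # per-well: use each plate's mean anyway when no pairing is given
        baseline = float(np.mean([c.od600.mean() for c in blanks]))
    out = []
    for c in curves:
        if c.role == "blank":
            out.append(c)
            continue
        od = np.maximum(c.od600 - baseline, config.min_od * 0.1)
        out.append(
            GrowthCurve(c.plate_id, c.well_id, c.clone_id, c.role, c.environment, c.times, od, c.replicate_index)
        )
    return out


def plate_qc(
    curves: list[GrowthCurve],
    config: GrowthFitConfig = GrowthFitConfig(),
    cross_plate_reference_rates=None,
) -> PlateQCReport:
    """Quality control of one plate: blanks, reference strain, ancestor wells.

    Flags blank wells whose readings exceed the detection floor
    (contamination), reports the reference-strain growth rate and, when rates
    from sibling plates are supplied, its deviation from the cross-plate mean
    in SD units; missing blanks or reference wells fail QC with a flag rather
    than raising.
    """
    plate_ids = {c.plate_id for c in curves}
    plate_id = plate_ids.pop() if len(plate_ids) == 1 else "|".join(sorted(plate_ids))
    report = PlateQCReport(plate_id=plate_id, qc_pass=True)

    blanks = [c for c in curves if c.role == "blank"]
    if not blanks:
        report.flags.append("missing-blanks")
        report.qc_pass = False
    for b in blanks:
        if float(np.percentile(b.od600 - b.od600[0], 95)) > config.min_od:
            report.contaminated_blanks.append(b.well_id)
    if report.contaminated_blanks:
        report.flags.append("contaminated-blank")
        report.qc_pass = False

    refs = [c for c in curves if c.role == "reference"]
    if not refs:
        report.flags.append("missing-reference")
        report.qc_pass = False
    else:
        rates = []
        for c in refs:
            try:
                rates.append(fit_max_growth_rate(c, config).rate_per_hour)
            except (NoGrowthError, FitQualityError):
                report.flags.append(f"reference-fit-failed:{c.well_id}")
        if rates:
            report.reference_rate = float(np.mean(rates))
            if cross_plate_reference_rates is not None and len(cross_plate_reference_rates) >= 2:
                others = np.asarray(cross_plate_reference_rates, dtype=float)
                sd = others.std(ddof=1)
                if sd > 0:
                    report.reference_deviation_sd = float(abs(report.reference_rate - others.mean()) / sd)
                    if report.reference_deviation_sd > 2.0:
                        report.flags.append("reference-outlier")
                        report.qc_pass = False

    if not any(c.role == "ancestor" for c in curves) and any(c.role == "evolved" for c in curves):
        report.flags.append("unmatched-clone")
        report.qc_pass = False
    return report


def plate_fitness_table(
    curves: list[GrowthCurve],
    ancestor_of: dict[str, str] | None = None,
    config: GrowthFitConfig = GrowthFitConfig(),
) -> pd.DataFrame:
    """Fit every well of a plate and compute per-clone fitness records.

    Blank subtraction is applied first.  Each evolved clone's replicates are
    averaged and divided by its matched ancestor's mean rate on the same
    plate; ``ancestor_of`` maps evolved clone_id -> ancestor clone_id (with a
    single ancestor on the plate the mapping may be omitted).  Returns a
    DataFrame of FitnessRecord fields plus the plate id.
    """
    corrected = subtract_blanks(curves, config)
    fits: dict[str, list[float]] = {}
    roles: dict[str, str] = {}
    envs: dict[str, str] = {}
    for c in corrected:
        if c.role == "blank":
            continue
        try:
            fit = fit_max_growth_rate(c, config)
        except (NoGrowthError, FitQualityError):
            continue
        fits.setdefault(c.clone_id, []).append(fit.rate_per_hour)
        roles[c.clone_id] = c.role
        envs[c.clone_id] = c.environment

    ancestors = {cid for cid, role in roles.items() if role == "ancestor"}
    rows = []
    for cid, rates in fits.items():
        if roles[cid] != "evolved":
            continue
        if ancestor_of and cid in ancestor_of:
            anc = ancestor_of[cid]
        elif len(ancestors) == 1:
            anc = next(iter(ancestors))
        else:
            continue  # unmatched; plate_qc flags this situation
        if anc not in fits:
            continue
        rec = relative_fitness(rates, float(np.mean(fits[anc])), clone_id=cid, environment=envs[cid])
        rows.append(
            {
                "plate": curves[0].plate_id if curves else "",
                "clone": rec.clone_id,
                "environment": rec.environment,
                "growth_rate": rec.growth_rate,
                "ancestor_rate": rec.ancestor_rate,
                "relative_fitness": rec.relative_fitness,
                "s": rec.s,
            }
        )
    return pd.DataFrame(rows, columns=["plate", "clone", "environment", "growth_rate", "ancestor_rate", "relative_fitness", "s"])
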