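"""Mortality estimation from two-filtrate serial dilution experiments.

A dilution experiment incubates whole seawater mixed with increasing
proportions of predator-free filtrate.  Two series are run in parallel:
the *protist* series uses 0.2 µm filtrate (protists removed, phages pass)
and the *combined* series uses 30 kDa filtrate (protists and phages
removed).  Apparent bacterial growth rate in each bottle is the log ratio
of final to initial abundance over the incubation.  Regressing that rate
on the whole-water fraction gives a slope whose magnitude measures
predation: ``-slope_protist`` estimates protistan grazing mortality and
the slope difference between the two series estimates phage lysis
mortality.

The module turns per-bottle initial/final concentrations into
per-experiment mortality estimates: apparent growth rates, the
two-standard-deviation replicate outlier filter, per-series ordinary
least squares slopes, and the phage-mortality decomposition with
propagated errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DilutionDesign",
    "BottleObservation",
    "SlopeFit",
    "ExperimentResult",
    "apparent_growth_rate",
    "filter_replicate_outliers",
    "fit_dilution_slope",
    "phage_mortality",
    "analyze_experiment",
    "analyze_experiments",
    "SERIES_PROTIST",
    "SERIES_COMBINED",
]

SERIES_PROTIST = "protist"
SERIES_COMBINED = "combined"
SERIES = (SERIES_PROTIST, SERIES_COMBINED)

#: Absolute floor (h^-1) below which a deviation from two identical
#: replicates is treated as float jitter rather than an outlier.
OUTLIER_FLOOR = 1e-6

BOTTLE_COLUMNS = [
    "experiment_id",
    "series",
    "whole_water_fraction",
    "replicate",
    "p0",
    "pt",
    "below_detection",
]


class DegenerateDesignError(ValueError):
    """All abscissa values identical; a slope cannot be fit."""


class InsufficientDataError(ValueError):
    """Fewer than two usable points for a regression."""


@dataclass(frozen=True)
class DilutionDesign:
    """Layout of one dilution experiment.

    Parameters
    ----------
    filtrate_fractions
        Proportion of filtrate in each dilution level.  The whole-water
        fraction is ``1 - filtrate_fraction``; a bottle of pure filtrate
        (fraction 1.0) contains no bacteria.
    replicates
        Bottles per (series, fraction) cell.
    duration_h
        Incubation time in hours.
    """

    filtrate_fractions: tuple[float, ...] = (0.0, 0.30, 0.70, 0.95, 1.00)
    replicates: int = 3
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        if len(self.filtrate_fractions) == 0:
            raise ValueError("design needs at least one filtrate fraction")
        fracs = tuple(float(f) for f in self.filtrate_fractions)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("filtrate fractions must lie in [0, 1]")
        if tuple(sorted(fracs)) != fracs:
            raise ValueError("filtrate fractions must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "filtrate_fractions", fracs)

    @property
    def whole_water_fractions(self) -> tuple[float, ...]:
        """Whole-water fraction x = 1 - filtrate fraction per level."""
        return tuple(1.0 - f for f in self.filtrate_fractions)


@dataclass(frozen=True)
class BottleObservation:
    """One bottle's initial and final concentration (total or per-ASV)."""

    experiment_id: str
    series: str
    whole_water_fraction: float
    replicate: int
    p0: float
    pt: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.series not in SERIES:
            raise ValueError(f"unknown series {self.series!r}")
        if not 0.0 <= self.whole_water_fraction <= 1.0:
            raise ValueError("whole_water_fraction must lie in [0, 1]")
        if self.p0 < 0 or self.pt < 0:
            raise ValueError("concentrations must be non-negative")


def bottles_to_frame(bottles) -> pd.DataFrame:
    """Assemble :class:`BottleObservation` records into the tidy bottle table."""
    return pd.DataFrame(
        [
            {
                "experiment_id": b.experiment_id,
                "series": b.series,
                "whole_water_fraction": b.whole_water_fraction,
                "replicate": b.replicate,
                "p0": b.p0,
                "pt": b.pt,
                "below_detection": b.below_detection,
            }
            for b in bottles
        ],
        columns=BOTTLE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# apparent growth rate
# ---------------------------------------------------------------------------

def apparent_growth_rate(p0, pt, t):
    """Apparent growth rate ``ln(pt / p0) / t`` in h^-1.

    Vectorised.  Non-positive abundances have no defined rate (the bottle
    is below detection) and yield NaN rather than raising.

    Parameters
    ----------
    p0, pt
        Initial and final abundance (cells/mL), scalars or arrays.
    t
        Incubation duration in hours; must be positive.
    """
    t = float(t)
    if t <= 0:
        raise ValueError("duration must be positive")
    p0 = np.asarray(p0, dtype=float)
    pt = np.asarray(pt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where((p0 > 0) & (pt > 0), np.log(pt / p0) / t, np.nan)
    if rate.ndim == 0:
        return float(rate)
    return rate


# ---------------------------------------------------------------------------
# replicate outlier filter
# ---------------------------------------------------------------------------

def _outlier_candidates(rates: np.ndarray, floor: float):
    """Deviation ratio of each member against the other two.

    Returns (flagged mask, deviation/threshold ratios).  A member is a
    candidate when its absolute deviation from the mean of the other two
    exceeds twice their sample standard deviation (or ``floor`` when the
    other two are identical).
    """
    n = len(rates)
    flagged = np.zeros(n, dtype=bool)
    ratio = np.zeros(n, dtype=float)
    for i in range(n):
        others = np.delete(rates, i)
        m = others.mean()
        sd = others.std(ddof=1)
        thr = max(2.0 * sd, floor)
        dev = abs(rates[i] - m)
        ratio[i] = dev / thr
        if dev > thr:
            flagged[i] = True
    return flagged, ratio


def filter_replicate_outliers(rates, floor: float = OUTLIER_FLOOR):
    """Apply the >2-SD replicate filter to one (series, fraction) cell.

    Each replicate is compared against the mean of the other two; it is
    discarded when its deviation exceeds twice their sample (n-1)
    standard deviation.  When the other two are identical a small
    absolute floor replaces the zero threshold so float jitter is never
    discarded.  With fewer than three finite rates no filtering occurs.
    At most one replicate is ever discarded: if several exceed their
    thresholds only the single worst offender (largest deviation-to-
    threshold ratio) goes, and exact ties keep everything, which makes
    the decision invariant to replicate order.

    Returns
    -------
    retained : ndarray of bool, same length as ``rates``
    record : dict or None
        ``{"index", "rate", "ratio"}`` for a discarded replicate.
    """
    rates = np.asarray(rates, dtype=float)
    retained = np.ones(len(rates), dtype=bool)
    finite = np.isfinite(rates)
    retained &= True  # NaNs handled by caller; keep mask aligned
    idx = np.flatnonzero(finite)
    if len(idx) < 3:
        return retained, None
    flagged, ratio = _outlier_candidates(rates[idx], floor)
    if not flagged.any():
        return retained, None
    cand = np.flatnonzero(flagged)
    if len(cand) > 1:
        best = cand[np.argmax(ratio[cand])]
        # exact ratio tie between distinct offenders: ambiguous, keep all
        ties = cand[np.isclose(ratio[cand], ratio[best], rtol=1e-12, atol=0.0)]
        if len(ties) > 1:
            return retained, None
        cand = np.array([best])
    drop = idx[cand[0]]
    retained[drop] = False
    record = {"index": int(drop), "rate": float(rates[drop]), "ratio": float(ratio[cand[0]])}
    return retained, record


# ---------------------------------------------------------------------------
# dilution slope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    se: float
    n: int


def fit_dilution_slope(x, rates) -> SlopeFit:
    """Ordinary least squares of apparent growth rate on whole-water fraction.

    A more negative slope indicates higher predation pressure.  Replicates
    are pooled as individual points.  The slope standard error is the
    standard OLS formula ``sqrt(RSS / (n-2) / Sxx)``; with exactly two
    points the fit is exact and the SE is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(rates, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >=2 points to fit a slope, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all whole-water fractions identical")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid**2))
    if n > 2:
        se = math.sqrt(max(rss, 0.0) / (n - 2) / sxx)
    else:
        se = 0.0
    return SlopeFit(slope=slope, intercept=intercept, se=se, n=n)


def fit_endpoint_difference(x, rates) -> SlopeFit:
    """Alternative estimator: mean rate at the largest x minus mean rate at
    the smallest x, normalised by the x span (comparable units to the OLS
    slope).  SE by propagation of the two cell means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(rates, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise InsufficientDataError("need >=2 points")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateDesignError("all whole-water fractions identical")
    ylo, yhi = y[x == lo], y[x == hi]
    span = hi - lo
    slope = (yhi.mean() - ylo.mean()) / span
    var = 0.0
    for arr in (ylo, yhi):
        if len(arr) > 1:
            var += arr.var(ddof=1) / len(arr)
    se = math.sqrt(var) / span
    intercept = ylo.mean() - slope * lo
    return SlopeFit(slope=slope, intercept=intercept, se=se, n=len(x))


# ---------------------------------------------------------------------------
# phage decomposition
# ---------------------------------------------------------------------------

def phage_mortality(
    slope_combined: float,
    se_combined: float,
    slope_protist: float,
    se_protist: float,
    convention: str = "predation-negative",
):
    """Phage lysis mortality as the slope difference between the series.

    Under the default ``predation-negative`` convention the value is
    ``slope_combined - slope_protist``, so phage predation shows up as a
    negative number (the combined series, which restores phages along
    with protists, loses cells faster).  The ``protist-minus-combined``
    convention flips the sign.  The error combines the two slope SEs in
    quadrature, treating the fits as independent (the bottles are
    distinct).
    """
    if convention == "predation-negative":
        value = slope_combined - slope_protist
    elif convention == "protist-minus-combined":
        value = slope_protist - slope_combined
    else:
        raise ValueError(f"unknown convention {convention!r}")
    error = math.sqrt(se_combined**2 + se_protist**2)
    return value, error


# ---------------------------------------------------------------------------
# whole-experiment pipeline
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-experiment mortality decomposition (one supplementary-table row)."""

    experiment_id: str
    slope_protist: float = math.nan
    se_protist: float = math.nan
    slope_combined: float = math.nan
    se_combined: float = math.nan
    phage_mortality: float = math.nan
    phage_error: float = math.nan
    n_bottles_used: dict = field(default_factory=dict)
    discarded: list = field(default_factory=list)
    calls: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "slope_combined": self.slope_combined,
            "se_combined": self.se_combined,
            "slope_protist": self.slope_protist,
            "se_protist": self.se_protist,
            "phage_mortality": self.phage_mortality,
            "phage_error": self.phage_error,
            "n_protist": self.n_bottles_used.get(SERIES_PROTIST, 0),
            "n_combined": self.n_bottles_used.get(SERIES_COMBINED, 0),
            "n_discarded": len(self.discarded),
            "call_protist": self.calls.get(SERIES_PROTIST, ""),
            "call_combined": self.calls.get(SERIES_COMBINED, ""),
            "flags": ";".join(self.flags),
        }


def analyze_experiment(
    bottles: pd.DataFrame,
    design: DilutionDesign | None = None,
    *,
    convention: str = "predation-negative",
    estimator: str = "ols",
    pool_replicates: bool = True,
    outlier_floor: float = OUTLIER_FLOOR,
) -> ExperimentResult:
    """Run the full per-experiment pipeline on one experiment's bottle table.

    Steps: apparent growth rates per bottle -> per-(series, fraction)
    replicate outlier filter -> per-series slope fit -> phage-mortality
    decomposition.  Bottles below detection, with non-positive counts,
    or at x = 0 (pure filtrate, no bacteria) are excluded up front.

    Parameters
    ----------
    bottles
        Tidy bottle table for a single experiment (columns
        ``experiment_id, series, whole_water_fraction, replicate, p0,
        pt`` and optionally ``below_detection``).
    design
        Experimental layout; supplies the incubation duration.
    estimator
        ``"ols"`` (default) or ``"endpoint"`` for the endpoint-difference
        alternative.
    pool_replicates
        Fit on individual bottles (default) or on replicate means.
    """
    design = design or DilutionDesign()
    ids = bottles["experiment_id"].unique()
    if len(ids) != 1:
        raise ValueError("analyze_experiment expects exactly one experiment")
    result = ExperimentResult(experiment_id=str(ids[0]))

    df = bottles.copy()
    if "below_detection" not in df.columns:
        df["below_detection"] = False
    usable = (
        (~df["below_detection"].astype(bool))
        & (df["p0"] > 0)
        & (df["pt"] > 0)
        & (df["whole_water_fraction"] > 0)
    )
    df = df[usable].copy()
    df["rate"] = apparent_growth_rate(df["p0"].to_numpy(), df["pt"].to_numpy(), design.duration_h)

    fit_fn = {"ols": fit_dilution_slope, "endpoint": fit_endpoint_difference}.get(estimator)
    if fit_fn is None:
        raise ValueError(f"unknown estimator {estimator!r}")

    fits: dict[str, SlopeFit] = {}
    for series in SERIES:
        sub = df[df["series"] == series]
        if sub.empty:
            result.flags.append(f"{series}_below_detection")
            continue
        xs, ys = [], []
        for x, cell in sub.groupby("whole_water_fraction"):
            rates = cell["rate"].to_numpy()
            retained, record = filter_replicate_outliers(rates, floor=outlier_floor)
            if record is not None:
                result.discarded.append(
                    {
                        "series": series,
                        "whole_water_fraction": float(x),
                        "replicate": int(cell["replicate"].to_numpy()[record["index"]]),
                        "rate": record["rate"],
                    }
                )
            kept = rates[retained & np.isfinite(rates)]
            if pool_replicates:
                xs.extend([x] * len(kept))
                ys.extend(kept.tolist())
            elif len(kept):
                xs.append(x)
                ys.append(float(kept.mean()))
        try:
            fit = fit_fn(xs, ys)
        except (InsufficientDataError, DegenerateDesignError) as exc:
            result.flags.append(f"{series}_unfit:{type(exc).__name__}")
            continue
        fits[series] = fit
        result.n_bottles_used[series] = fit.n
        result.calls[series] = "predation" if fit.slope < 0 else "growth"

    if SERIES_PROTIST in fits:
        result.slope_protist = fits[SERIES_PROTIST].slope
        result.se_protist = fits[SERIES_PROTIST].se
    if SERIES_COMBINED in fits:
        result.slope_combined = fits[SERIES_COMBINED].slope
        result.se_combined = fits[SERIES_COMBINED].se
    if len(fits) == 2:
        result.phage_mortality, result.phage_error = phage_mortality(
            result.slope_combined,
            result.se_combined,
            result.slope_protist,
            result.se_protist,
            convention=convention,
        )
    else:
        result.flags.append("phage_mortality_not_computed")
    return result


def analyze_experiments(bottles: pd.DataFrame, design: DilutionDesign | None = None, **kwargs) -> pd.DataFrame:
    """Apply :func:`analyze_experiment` per experiment id; tidy result table."""
    rows = []
    for _, sub in bottles.groupby("experiment_id", sort=True):
        rows.append(analyze_experiment(sub, design, **kwargs).to_row())
    return pd.DataFrame(rows)
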