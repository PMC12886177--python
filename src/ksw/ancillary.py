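"""Side computations: prophage-induction ANOVA, stratification proxy,
Shannon diversity.

The induction experiment incubates six tubes of seawater for 24 h, three
amended with mitomycin-C (which triggers lysogenised prophages to
replicate and lyse their hosts) and three untreated controls.  A rise in
virus-like-particle (VLP) concentration in the treated tubes relative to
controls indicates lysogeny; significance is assessed with a one-way
ANOVA on the per-tube VLP change (with two groups, F = t^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "InductionExperiment",
    "InductionResult",
    "induction_test",
    "stratification_proxy",
    "shannon_index",
]


@dataclass(frozen=True)
class InductionExperiment:
    """Start/end VLP concentrations (VLP/mL) for control and treated tubes."""

    control_start: tuple
    control_end: tuple
    treated_start: tuple
    treated_end: tuple
    duration_h: float = 24.0

    def __post_init__(self) -> None:
        for name in ("control_start", "control_end", "treated_start", "treated_end"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if (arr < 0).any():
                raise ValueError(f"{name}: concentrations must be >= 0")
        if len(self.control_start) != len(self.control_end):
            raise ValueError("control start/end lengths differ")
        if len(self.treated_start) != len(self.treated_end):
            raise ValueError("treated start/end lengths differ")
        if min(len(self.control_start), len(self.treated_start)) < 2:
            raise ValueError("need >=2 replicates per arm")

    @property
    def control_delta(self) -> np.ndarray:
        return np.asarray(self.control_end, dtype=float) - np.asarray(self.control_start, dtype=float)

    @property
    def treated_delta(self) -> np.ndarray:
        return np.asarray(self.treated_end, dtype=float) - np.asarray(self.treated_start, dtype=float)


@dataclass(frozen=True)
class InductionResult:
    f_statistic: float
    p_value: float
    lysogeny: bool
    control_mean_delta: float
    treated_mean_delta: float


def induction_test(
    experiment: InductionExperiment,
    *,
    alpha: float = 0.05,
    response: str = "delta",
) -> InductionResult:
    """One-way ANOVA of VLP response, treated vs control tubes.

    The response is the per-tube VLP change over the incubation
    (``"delta"``, default, so tube-to-tube baseline differences cancel)
    or the raw end concentration (``"endpoint"``).  Lysogeny is called
    when the treated mean exceeds the control mean at p < ``alpha``.
    Degenerate inputs: identical groups with zero variance give p = 1 by
    convention; differing means with zero within-group variance give
    p = 0 (infinite F).
    """
    if response == "delta":
        a, b = experiment.control_delta, experiment.treated_delta
    elif response == "endpoint":
        a = np.asarray(experiment.control_end, dtype=float)
        b = np.asarray(experiment.treated_end, dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")

    within_var = a.var(ddof=1) + b.var(ddof=1)
    if within_var == 0:
        if a.mean() == b.mean():
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
    else:
        f, p = stats.f_oneway(a, b)
        f, p = float(f), float(p)
    lysogeny = (b.mean() > a.mean()) and (p < alpha)
    return InductionResult(
        f_statistic=f,
        p_value=p,
        lysogeny=bool(lysogeny),
        control_mean_delta=float(a.mean()),
        treated_mean_delta=float(b.mean()),
    )


def stratification_proxy(t10: float, t50: float) -> float:
    """Water-column stratification proxy: |T(10 m) - T(50 m)| in deg C.

    A large temperature contrast between 10 and 50 m indicates a
    strongly stratified water column.  Symmetric in its arguments.
    """
    t10, t50 = float(t10), float(t50)
    if not (math.isfinite(t10) and math.isfinite(t50)):
        raise ValueError("temperatures must be finite")
    return abs(t10 - t50)


def shannon_index(rel_abund, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over non-zero proportions.

    Input abundances are renormalised internally, so raw counts work
    too.  Natural log by default (``base`` overrides); the uniform
    distribution over n taxa attains the maximum, log n.
    """
    p = np.asarray(rel_abund, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h
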