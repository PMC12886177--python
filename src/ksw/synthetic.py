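"""Ground-truth communities and simulation of the full observation process.

The generator plants a community with known per-taxon growth, grazing and
lysis rates and pushes it through the full observation process of the experimental
design: 24 h two-series dilution incubations with lognormal count
noise, multinomial amplicon read sampling at fixed depth, and Gaussian
event clouds for flow cytometry.  Every downstream estimator can then be
checked by parameter recovery.

Model assumptions
-----------------
* Predator encounter is linear in the whole-water fraction ``x``; there
  is no saturation or functional response.
* The 0.2 µm filtrate passes phages, so phage pressure in the protist
  series is constant at its whole-water level regardless of ``x``; the
  30 kDa filtrate removes phages too, so their pressure scales with
  ``x`` in the combined series.
* Filtrate contributes no bacteria: initial abundance in a bottle is
  ``x`` times the whole-water abundance, and ``x = 0`` bottles are below
  detection.

Hence the expected apparent growth rate of taxon *i* is::

    protist series :  mu_i - g_i * x - v_i
    combined series:  mu_i - (g_i + v_i) * x

so the protist-series slope in ``x`` is ``-g_i``, the combined-series
slope is ``-(g_i + v_i)``, and the slope difference (combined - protist)
is ``-v_i`` — the quantity reported as phage mortality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dilution import SERIES_COMBINED, SERIES_PROTIST, DilutionDesign

__all__ = [
    "CommunityTruth",
    "NoiseSpec",
    "GaussianPopulation",
    "SimulatedExperiment",
    "simulate_community",
    "expected_rate",
    "simulate_dilution_experiment",
    "simulate_experiments",
    "simulate_event_cloud",
    "write_simulation",
]

FLAG_SELECT_WINNER = "select-winner"
FLAG_SPARED_WINNER = "spared-winner"
FLAG_SLOW = "slow"
FLAG_BACKGROUND = "background"


@dataclass
class CommunityTruth:
    """Planted ground truth for a synthetic bacterial community.

    Rates are in h^-1 at full whole-water predator concentration,
    abundances in cells/mL, PRMDT (predicted relative minimal doubling
    time) in hours.
    """

    asv_ids: list
    mu: np.ndarray
    g: np.ndarray
    v: np.ndarray
    n0: np.ndarray
    prmdt: np.ndarray
    winner_flags: np.ndarray
    fast_threshold_h: float = 5.0

    def __post_init__(self) -> None:
        n = len(self.asv_ids)
        for name in ("mu", "g", "v", "n0", "prmdt", "winner_flags"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} taxa")
            setattr(self, name, arr)
        if (self.mu < 0).any() or (self.g < 0).any() or (self.v < 0).any():
            raise ValueError("rates must be non-negative")
        if (self.n0 <= 0).any() or (self.prmdt <= 0).any():
            raise ValueError("abundances and PRMDT must be positive")

    @property
    def n_asv(self) -> int:
        return len(self.asv_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "asv_id": self.asv_ids,
                "mu_h": self.mu,
                "g_h": self.g,
                "v_h": self.v,
                "n0_cells_ml": self.n0,
                "prmdt_h": self.prmdt,
                "winner_flag": self.winner_flags,
            }
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise for the simulated measurement process.

    ``count_cv`` is the coefficient of variation of the multiplicative
    lognormal noise on every measured concentration (0 = exact).
    ``read_depth`` is the multinomial amplicon depth per sample; ``None``
    disables sequencing noise and reports exact compositions.
    """

    count_cv: float = 0.0
    read_depth: int | None = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_cv < 0:
            raise ValueError("count_cv must be >= 0")
        if self.read_depth is not None and self.read_depth <= 0:
            raise ValueError("read_depth must be positive")


def simulate_community(
    n_asv: int,
    *,
    seed: int,
    frac_select_winners: float = 0.15,
    frac_spared_winners: float = 0.15,
    frac_slow: float = 0.10,
    mu_range: tuple[float, float] = (0.0, 0.1),
    grazing_rate: float = 0.05,
    lysis_rate: float = 0.05,
    fast_prmdt_range: tuple[float, float] = (1.0, 4.5),
    slow_prmdt_range: tuple[float, float] = (6.0, 12.0),
    fast_threshold_h: float = 5.0,
    n0_median: float = 2e4,
    n0_sigma: float = 1.0,
) -> CommunityTruth:
    """Generate a community with planted kill-select-winner structure.

    Four taxon classes are planted:

    * ``select-winner`` — fast predicted growth (PRMDT below the fast
      threshold) and full grazing + lysis pressure,
    * ``spared-winner`` — fast predicted growth but background (zero)
      predation,
    * ``slow`` — slow predicted growth yet full predation pressure (the
      high-turnover *Pelagibacter*-like case),
    * ``background`` — slow predicted growth, background predation.

    Class sizes are deterministic (``round(frac * n_asv)``); assignment
    to taxa is a seeded shuffle.  ``grazing_rate`` / ``lysis_rate`` give
    the predation mortality of active taxa at 100 % whole water; initial
    abundances are lognormal around ``n0_median``.
    """
    if n_asv < 2:
        raise ValueError("n_asv must be >= 2")
    for name, f in (
        ("frac_select_winners", frac_select_winners),
        ("frac_spared_winners", frac_spared_winners),
        ("frac_slow", frac_slow),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if mu_range[0] < 0 or mu_range[1] < mu_range[0]:
        raise ValueError("invalid mu_range")
    if grazing_rate < 0 or lysis_rate < 0:
        raise ValueError("predation rates must be >= 0")

    n_sw = int(round(frac_select_winners * n_asv))
    n_sp = int(round(frac_spared_winners * n_asv))
    n_slow = int(round(frac_slow * n_asv))
    if n_sw + n_sp + n_slow > n_asv:
        raise ValueError("class fractions exceed the community size")

    rng = np.random.default_rng(seed)
    flags = np.array(
        [FLAG_SELECT_WINNER] * n_sw
        + [FLAG_SPARED_WINNER] * n_sp
        + [FLAG_SLOW] * n_slow
        + [FLAG_BACKGROUND] * (n_asv - n_sw - n_sp - n_slow)
    )
    rng.shuffle(flags)

    mu = rng.uniform(*mu_range, size=n_asv)
    fast = (flags == FLAG_SELECT_WINNER) | (flags == FLAG_SPARED_WINNER)
    prmdt = np.where(
        fast,
        rng.uniform(*fast_prmdt_range, size=n_asv),
        rng.uniform(*slow_prmdt_range, size=n_asv),
    )
    active = (flags == FLAG_SELECT_WINNER) | (flags == FLAG_SLOW)
    g = np.where(active, grazing_rate, 0.0)
    v = np.where(active, lysis_rate, 0.0)
    n0 = n0_median * np.exp(rng.normal(0.0, n0_sigma, size=n_asv))
    asv_ids = [f"asv{i:04d}" for i in range(n_asv)]
    return CommunityTruth(
        asv_ids=asv_ids,
        mu=mu,
        g=g,
        v=v,
        n0=n0,
        prmdt=prmdt,
        winner_flags=flags,
        fast_threshold_h=fast_threshold_h,
    )


def expected_rate(truth: CommunityTruth, asv: int, x: float, series: str) -> float:
    """Closed-form expected apparent growth rate of one taxon at dilution x."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("whole-water fraction x must lie in [0, 1]")
    if series == SERIES_COMBINED:
        phage = x
    elif series == SERIES_PROTIST:
        phage = 1.0
    else:
        raise ValueError(f"unknown series {series!r}")
    return float(truth.mu[asv] - truth.g[asv] * x - truth.v[asv] * phage)


def _expected_rates(truth: CommunityTruth, x: float, series: str) -> np.ndarray:
    phage = x if series == SERIES_COMBINED else 1.0
    return truth.mu - truth.g * x - truth.v * phage


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


@dataclass
class SimulatedExperiment:
    """Bottle table plus per-sample amplicon observations for experiments."""

    bottles: pd.DataFrame
    reads: pd.DataFrame  # samples x ASVs; integer counts, or exact abundances when depth is None
    sample_meta: pd.DataFrame  # sample_id, experiment_id, role, series, x, replicate, total_cells_ml
    truth: CommunityTruth


def simulate_dilution_experiment(
    truth: CommunityTruth,
    design: DilutionDesign | None = None,
    noise: NoiseSpec | None = None,
    *,
    experiment_id: str = "exp-001",
    rng: np.random.Generator | None = None,
) -> SimulatedExperiment:
    """Simulate one two-series dilution experiment end to end.

    Produces per-bottle total counts (initial/final, with lognormal
    measurement noise), triplicate whole-water start samples for the
    amplicon baseline, and a per-sample read matrix at the specified
    multinomial depth.  With ``count_cv = 0`` and ``read_depth = None``
    all observations equal their closed-form expectations exactly.
    """
    design = design or DilutionDesign()
    noise = noise or NoiseSpec()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t = design.duration_h
    cv = noise.count_cv
    n_asv = truth.n_asv

    bottle_rows = []
    read_rows = {}
    meta_rows = []

    def _reads(abund: np.ndarray) -> np.ndarray:
        total = abund.sum()
        if noise.read_depth is None or total <= 0:
            return abund.copy()
        return rng.multinomial(noise.read_depth, abund / total).astype(float)

    # triplicate whole-water start samples (amplicon baseline + start total)
    for rep in range(1, design.replicates + 1):
        obs = truth.n0 * _lognormal_factor(rng, cv, n_asv)
        sid = f"{experiment_id}:start:{rep}"
        read_rows[sid] = _reads(obs)
        meta_rows.append(
            {
                "sample_id": sid,
                "experiment_id": experiment_id,
                "role": "start",
                "series": "",
                "whole_water_fraction": 1.0,
                "replicate": rep,
                "total_cells_ml": obs.sum(),
            }
        )

    for series in (SERIES_PROTIST, SERIES_COMBINED):
        for x in design.whole_water_fractions:
            rates = _expected_rates(truth, x, series)
            for rep in range(1, design.replicates + 1):
                init_true = x * truth.n0
                final_true = init_true * np.exp(rates * t)
                below = x == 0.0
                if below:
                    p0_obs = np.zeros(n_asv)
                    pt_obs = np.zeros(n_asv)
                else:
                    p0_obs = init_true * _lognormal_factor(rng, cv, n_asv)
                    pt_obs = final_true * _lognormal_factor(rng, cv, n_asv)
                sid = f"{experiment_id}:{series}:x{x:.2f}:{rep}"
                bottle_rows.append(
                    {
                        "experiment_id": experiment_id,
                        "series": series,
                        "whole_water_fraction": x,
                        "replicate": rep,
                        "p0": p0_obs.sum(),
                        "pt": pt_obs.sum(),
                        "below_detection": bool(below),
                    }
                )
                read_rows[sid] = _reads(pt_obs)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "experiment_id": experiment_id,
                        "role": "end",
                        "series": series,
                        "whole_water_fraction": x,
                        "replicate": rep,
                        "total_cells_ml": pt_obs.sum(),
                    }
                )

    reads = pd.DataFrame.from_dict(read_rows, orient="index", columns=truth.asv_ids)
    reads.index.name = "sample_id"
    if noise.read_depth is not None:
        reads = reads.astype(np.int64)
    return SimulatedExperiment(
        bottles=pd.DataFrame(bottle_rows),
        reads=reads,
        sample_meta=pd.DataFrame(meta_rows),
        truth=truth,
    )


def simulate_experiments(
    truth: CommunityTruth,
    n_experiments: int,
    design: DilutionDesign | None = None,
    noise: NoiseSpec | None = None,
    *,
    seed: int | None = None,
) -> SimulatedExperiment:
    """Simulate a season of independent experiments on the same community."""
    if n_experiments < 1:
        raise ValueError("need at least one experiment")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    parts = [
        simulate_dilution_experiment(
            truth, design, noise, experiment_id=f"exp-{i + 1:03d}", rng=rng
        )
        for i in range(n_experiments)
    ]
    return SimulatedExperiment(
        bottles=pd.concat([p.bottles for p in parts], ignore_index=True),
        reads=pd.concat([p.reads for p in parts]),
        sample_meta=pd.concat([p.sample_meta for p in parts], ignore_index=True),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# cytometry event clouds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPopulation:
    """One cytometry population: Gaussian cloud in channel space."""

    mean: tuple
    cov: object
    expected_events: float
    label: str = ""


def simulate_event_cloud(
    populations,
    *,
    seed: int,
    channel_names: list | None = None,
) -> pd.DataFrame:
    """Draw a labelled synthetic event table from Gaussian populations.

    Event counts per population are Poisson around ``expected_events``;
    events are multivariate normal draws.  The true label is kept in a
    ``label`` column for accuracy scoring — a luxury real cytometry data
    does not have.
    """
    pops = [p if isinstance(p, GaussianPopulation) else GaussianPopulation(*p) for p in populations]
    if not pops:
        raise ValueError("need at least one population")
    dim = len(pops[0].mean)
    if dim < 2:
        raise ValueError("need >=2 channels (scatter + fluorescence)")
    rng = np.random.default_rng(seed)
    frames = []
    names = channel_names or [f"ch{i}" for i in range(dim)]
    for i, pop in enumerate(pops):
        mean = np.asarray(pop.mean, dtype=float)
        cov = np.asarray(pop.cov, dtype=float)
        if mean.shape != (dim,) or cov.shape != (dim, dim):
            raise ValueError("population dimensions disagree")
        # reject non-PD covariances up front
        np.linalg.cholesky(cov)
        n = rng.poisson(pop.expected_events)
        ev = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        df = pd.DataFrame(ev, columns=names)
        df["label"] = pop.label or f"pop{i}"
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_simulation(sim: SimulatedExperiment, outdir, *, noise: NoiseSpec | None = None, params: dict | None = None) -> dict:
    """Write bottle, read, truth and metadata tables as TSV + a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.bottles.to_csv(outdir / "bottles.tsv", sep="\t", index=False)
    sim.reads.to_csv(outdir / "asv_reads.tsv", sep="\t")
    sim.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    sim.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "n_asv": sim.truth.n_asv,
        "n_bottles": int(len(sim.bottles)),
        "noise": {
            "count_cv": noise.count_cv if noise else None,
            "read_depth": noise.read_depth if noise else None,
            "seed": noise.seed if noise else None,
        },
        "params": params or {},
        "files": ["bottles.tsv", "asv_reads.tsv", "sample_meta.tsv", "truth.tsv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
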