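"""Flow-cytometry population gating with a toroidal SOM plus k-means.

Events (one row per particle, one column per channel: scatter and
fluorescence intensities) are quantised by a self-organising map trained
on a 41 x 41 toroidal grid, the codebook is clustered with k-means into a
small number of populations (k = 4 for autofluorescence, SYBR-stained,
RedoxSensor-Green and virus samples, k = 5 for Lysotracker samples), and
every event inherits the cluster of its best-matching unit (BMU).
Population event counts are converted to concentrations from the
acquisition volume (flow rate x run time) and any sample dilution.

The SOM trainer is the classic online algorithm: per presented event,
find the BMU by Euclidean distance in channel space and pull every node
within the current neighbourhood radius (toroidal grid distance, bubble
neighbourhood) toward the event by the current learning rate, with both
schedules decaying linearly over training.  The inner loop is
numba-compiled; given a seed the result is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from sklearn.cluster import KMeans

__all__ = [
    "Acquisition",
    "SOMGrid",
    "PopulationCounts",
    "toroidal_distance",
    "train_som",
    "cluster_codebook",
    "classify_events",
    "events_to_concentration",
    "derived_bacteria_stats",
]

#: conventional k-means cluster counts per cytometry sample type.
DEFAULT_K = {"AF": 4, "LSG": 5, "RSG": 4, "SG": 4, "VLP": 4}


@dataclass(frozen=True)
class Acquisition:
    """Cytometer acquisition metadata needed for volume conversion."""

    flow_rate_ul_min: float
    run_time_min: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate_ul_min <= 0 or self.run_time_min <= 0:
            raise ValueError("flow rate and run time must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")

    @property
    def volume_ul(self) -> float:
        return self.flow_rate_ul_min * self.run_time_min


def toroidal_distance(a, b, rows: int, cols: int) -> float:
    """Euclidean distance between grid nodes with per-axis wrap-around.

    Per axis the distance is ``min(|delta|, size - |delta|)``, so on a
    41 x 41 grid nodes (0, 0) and (40, 0) are adjacent.
    """
    (ar, ac), (br, bc) = a, b
    if not (0 <= ar < rows and 0 <= br < rows and 0 <= ac < cols and 0 <= bc < cols):
        raise ValueError("node coordinates out of range")
    dr = abs(ar - br)
    dc = abs(ac - bc)
    dr = min(dr, rows - dr)
    dc = min(dc, cols - dc)
    return math.hypot(dr, dc)


@dataclass
class SOMGrid:
    """Trained SOM codebook over a toroidal rows x cols grid.

    ``codebook`` has shape (rows * cols, n_channels), node index
    ``r * cols + c``.  ``cluster_labels`` (after k-means) maps each node
    to a population id.  ``transform`` records the channel preprocessing
    (log10 mask, z-score mean/std) so classification applies the same
    mapping as training.
    """

    rows: int
    cols: int
    codebook: np.ndarray
    channels: list
    training_meta: dict = field(default_factory=dict)
    cluster_labels: np.ndarray | None = None
    transform: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_coords(self, idx: int) -> tuple[int, int]:
        return divmod(idx, self.cols)

    # -- portable text serialisation -------------------------------------
    def to_json(self) -> str:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "channels": list(self.channels),
            "codebook": self.codebook.tolist(),
            "training_meta": self.training_meta,
            "cluster_labels": None if self.cluster_labels is None else self.cluster_labels.tolist(),
            "transform": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.transform.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SOMGrid":
        d = json.loads(text)
        transform = {
            k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d["transform"].items()
        }
        labels = d["cluster_labels"]
        return cls(
            rows=d["rows"],
            cols=d["cols"],
            codebook=np.asarray(d["codebook"], dtype=float),
            channels=d["channels"],
            training_meta=d["training_meta"],
            cluster_labels=None if labels is None else np.asarray(labels, dtype=int),
            transform=transform,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SOMGrid":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# training kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _som_pass(X, codebook, order, grid_d2, step0, total_steps, lr0, lr1, r0, r1):
    """One pass of online updates; schedules interpolated on global step."""
    n_nodes, dim = codebook.shape
    denom = total_steps - 1 if total_steps > 1 else 1
    for s in range(order.shape[0]):
        frac = (step0 + s) / denom
        lr = lr0 + (lr1 - lr0) * frac
        radius = r0 + (r1 - r0) * frac
        r2 = radius * radius
        xi = X[order[s]]
        best = 0
        bestd = np.inf
        for j in range(n_nodes):
            d = 0.0
            for c in range(dim):
                diff = xi[c] - codebook[j, c]
                d += diff * diff
            if d < bestd:
                bestd = d
                best = j
        for j in range(n_nodes):
            if grid_d2[best, j] <= r2:
                for c in range(dim):
                    codebook[j, c] += lr * (xi[c] - codebook[j, c])


@njit(cache=False)
def _bmu_indices(X, codebook):
    n = X.shape[0]
    n_nodes, dim = codebook.shape
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        best = 0
        bestd = np.inf
        for j in range(n_nodes):
            d = 0.0
            for c in range(dim):
                diff = X[i, c] - codebook[j, c]
                d += diff * diff
            if d < bestd:
                bestd = d
                best = j
        out[i] = best
    return out


def _grid_distance2(rows: int, cols: int) -> np.ndarray:
    """Squared toroidal grid distance between every node pair."""
    r = np.arange(rows)
    c = np.arange(cols)
    dr = np.abs(r[:, None] - r[None, :])
    dr = np.minimum(dr, rows - dr)
    dc = np.abs(c[:, None] - c[None, :])
    dc = np.minimum(dc, cols - dc)
    d2 = (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(np.float64)
    return d2.reshape(rows * cols, rows * cols)


def _apply_transform(X: np.ndarray, transform: dict) -> np.ndarray:
    X = np.asarray(X, dtype=float).copy()
    log_mask = transform.get("log10_mask")
    if log_mask is not None:
        m = np.asarray(log_mask, dtype=bool)
        X[:, m] = np.log10(np.clip(X[:, m], 1.0, None))
    mean = transform.get("mean")
    std = transform.get("std")
    if mean is not None:
        X = (X - np.asarray(mean)) / np.asarray(std)
    return X


def _as_matrix(events, channels=None):
    if isinstance(events, pd.DataFrame):
        cols = channels or [c for c in events.columns if c != "label"]
        return events[cols].to_numpy(dtype=float), list(cols)
    X = np.asarray(events, dtype=float)
    return X, channels or [f"ch{i}" for i in range(X.shape[1])]


def train_som(
    events,
    rows: int = 41,
    cols: int = 41,
    *,
    n_passes: int = 100,
    lr_schedule: tuple[float, float] = (0.05, 0.01),
    radius_schedule: tuple[float, float] | None = None,
    seed: int = 0,
    channels: list | None = None,
    standardize: bool = True,
    log10_channels: list | None = None,
    init_codebook: np.ndarray | None = None,
    return_history: bool = False,
):
    """Train a toroidal SOM on an event table.

    Defaults follow common practice for this map size: 100 passes over
    the training events in random (seeded) order, learning rate decaying
    linearly 0.05 -> 0.01 and bubble-neighbourhood radius decaying
    linearly from two thirds of the larger grid dimension to 1.
    Channels named in ``log10_channels`` are log10-transformed (floored
    at 1) and, when ``standardize`` is on, all channels are z-scored;
    the transform is stored on the grid so classification repeats it.

    Returns the trained :class:`SOMGrid` (and, with ``return_history``,
    a list of codebook snapshots taken after every pass).
    """
    X, chan_names = _as_matrix(events, channels)
    if X.shape[0] == 0:
        raise ValueError("empty event table")
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    lr0, lr1 = lr_schedule
    if lr1 > lr0 or lr0 <= 0:
        raise ValueError("learning-rate schedule must decay")
    if radius_schedule is None:
        radius_schedule = (2.0 * max(rows, cols) / 3.0, 1.0)
    r0, r1 = radius_schedule
    if r1 > r0 or r0 <= 0:
        raise ValueError("radius schedule must decay")

    transform: dict = {}
    if log10_channels:
        transform["log10_mask"] = np.array([c in log10_channels for c in chan_names])
    if standardize:
        Xt = _apply_transform(X, transform)
        std = Xt.std(axis=0)
        std[std == 0] = 1.0
        transform["mean"] = Xt.mean(axis=0)
        transform["std"] = std
    X = np.ascontiguousarray(_apply_transform(X, transform))

    rng = np.random.default_rng(seed)
    n_nodes = rows * cols
    if init_codebook is not None:
        if init_codebook.shape != (n_nodes, X.shape[1]):
            raise ValueError("init_codebook shape mismatch")
        codebook = np.ascontiguousarray(np.asarray(init_codebook, dtype=float).copy())
    else:
        init_idx = rng.integers(0, X.shape[0], size=n_nodes)
        codebook = np.ascontiguousarray(X[init_idx].copy())
    grid_d2 = _grid_distance2(rows, cols)

    n_events = X.shape[0]
    total_steps = n_passes * n_events
    history = []
    step0 = 0
    for _ in range(n_passes):
        order = rng.permutation(n_events)
        _som_pass(X, codebook, order, grid_d2, step0, total_steps, lr0, lr1, float(r0), float(r1))
        step0 += n_events
        if return_history:
            history.append(codebook.copy())

    grid = SOMGrid(
        rows=rows,
        cols=cols,
        codebook=codebook,
        channels=chan_names,
        training_meta={
            "n_passes": n_passes,
            "n_events": int(n_events),
            "lr_schedule": [lr0, lr1],
            "radius_schedule": [float(r0), float(r1)],
            "seed": seed,
        },
        transform=transform,
    )
    if return_history:
        return grid, history
    return grid


def cluster_codebook(grid: SOMGrid, k: int, *, seed: int = 0, n_restarts: int = 25) -> SOMGrid:
    """Label SOM nodes by k-means on the codebook vectors.

    Lloyd's algorithm in channel space (grid geometry is not used), with
    ``n_restarts`` seeded restarts keeping the lowest-inertia solution.
    Returns the same grid with ``cluster_labels`` filled in.
    """
    if not 2 <= k <= grid.n_nodes:
        raise ValueError(f"k must lie in [2, {grid.n_nodes}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    grid.cluster_labels = km.fit_predict(grid.codebook).astype(int)
    grid.training_meta["kmeans"] = {"k": k, "seed": seed, "n_restarts": n_restarts, "inertia": float(km.inertia_)}
    return grid


@dataclass
class PopulationCounts:
    """Event counts and concentrations per gated population for one sample."""

    sample_type: str
    events: dict
    cells_per_ml: dict
    total_events: int
    bmu: np.ndarray | None = None
    labels: np.ndarray | None = None


def classify_events(
    events,
    grid: SOMGrid,
    *,
    acquisition: Acquisition | None = None,
    sample_type: str = "SG",
    label_map: dict | None = None,
    bead_correction: float = 1.0,
) -> PopulationCounts:
    """Assign each event the population of its best-matching SOM node.

    ``label_map`` renames k-means cluster indices to population names
    (e.g. ``{0: "HNA", 1: "LNA"}``); unmapped indices keep their integer
    id.  With ``acquisition`` given, per-population concentrations are
    computed via :func:`events_to_concentration`; ``bead_correction`` is
    an optional multiplicative QC factor (expected / observed bead
    concentration).
    """
    if grid.cluster_labels is None:
        raise ValueError("grid has no cluster labels; run cluster_codebook first")
    X, chans = _as_matrix(events, grid.channels if isinstance(events, pd.DataFrame) else None)
    if X.shape[1] != grid.codebook.shape[1]:
        raise ValueError(
            f"channel dimension mismatch: events have {X.shape[1]}, grid has {grid.codebook.shape[1]}"
        )
    if X.shape[0] == 0:
        names = sorted({label_map.get(int(c), int(c)) if label_map else int(c) for c in np.unique(grid.cluster_labels)}, key=str)
        return PopulationCounts(sample_type, {n: 0 for n in names}, {}, 0, np.empty(0, dtype=int), np.empty(0, dtype=object))

    Xt = np.ascontiguousarray(_apply_transform(X, grid.transform))
    bmu = _bmu_indices(Xt, np.ascontiguousarray(grid.codebook))
    clusters = grid.cluster_labels[bmu]
    labels = np.array([label_map.get(int(c), int(c)) if label_map else int(c) for c in clusters], dtype=object)

    counts: dict = {}
    for c in np.unique(grid.cluster_labels):
        name = label_map.get(int(c), int(c)) if label_map else int(c)
        counts[name] = int(np.sum(clusters == c))
    conc = {}
    if acquisition is not None:
        for name, n in counts.items():
            conc[name] = (
                events_to_concentration(
                    n, acquisition.flow_rate_ul_min, acquisition.run_time_min, acquisition.dilution_factor
                )
                * bead_correction
            )
    return PopulationCounts(sample_type, counts, conc, int(X.shape[0]), bmu, labels)


def events_to_concentration(
    event_count: float,
    flow_rate_ul_min: float,
    run_time_min: float,
    dilution_factor: float = 1.0,
) -> float:
    """Convert gated event counts to cells/mL.

    ``cells/mL = events / (flow rate x run time) x 1000 x dilution``;
    e.g. 660 events over 66 µL/min x 3 min is 660 / 198 µL ≈ 3333 cells/mL.
    """
    if flow_rate_ul_min <= 0 or run_time_min <= 0:
        raise ValueError("acquisition volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if event_count < 0:
        raise ValueError("event count must be >= 0")
    volume_ul = flow_rate_ul_min * run_time_min
    return event_count / volume_ul * 1000.0 * dilution_factor


def derived_bacteria_stats(hna_cells_ml: float, lna_cells_ml: float, high_rsg_cells_ml: float | None = None):
    """Total bacteria (HNA + LNA) and, when available, the fraction of
    actively respiring cells (high RSG / total)."""
    if hna_cells_ml < 0 or lna_cells_ml < 0:
        raise ValueError("counts must be non-negative")
    total = hna_cells_ml + lna_cells_ml
    if high_rsg_cells_ml is None:
        return total, None
    if total == 0:
        raise ZeroDivisionError("total bacterial count is zero; pct_rsg undefined")
    return total, high_rsg_cells_ml / total
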