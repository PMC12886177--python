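"""ASV-level mortality estimation and kill-select-winner classification.

The bulk dilution analysis (``ksw.dilution``) works on total bacterial
counts.  Here the same estimator is applied per amplicon sequence
variant (ASV): each sample's relative abundances are scaled by its total
bacterial concentration to absolute abundances (cells/mL), apparent
growth rates are computed per ASV per bottle, and the full
filter / slope / phage-decomposition pipeline runs per ASV.

Across a season of experiments each ASV is then summarised by six
averages — the mean of its negative per-experiment values and the mean
of its positive per-experiment values for each of the three
experimental conditions (combined slope, protist slope, phage
mortality).  An ASV's *activity* (the largest predation-side average
magnitude) is compared with its predicted relative minimal doubling
time (PRMDT, a codon-usage growth proxy in hours) to sort taxa into
kill-select-winner classes:

* ``winner-killed`` — predicted fast grower with high predation activity,
* ``winner-spared`` — predicted fast grower with little activity,
* ``slow-high-turnover`` — predicted slow grower that is nonetheless
  heavily preyed upon (the *Pelagibacter* case),
* ``background`` — slow and quiet.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import dilution as dil
from .dilution import (
    SERIES_COMBINED,
    SERIES_PROTIST,
    DilutionDesign,
    filter_replicate_outliers,
    fit_dilution_slope,
)
from .synthetic import (
    FLAG_BACKGROUND,
    FLAG_SELECT_WINNER,
    FLAG_SLOW,
    FLAG_SPARED_WINNER,
    CommunityTruth,
)

__all__ = [
    "absolute_abundance",
    "asv_experiment_slopes",
    "asv_season_slopes",
    "summarize_asv",
    "classify_ksw",
    "ksw_recovery_score",
    "CLASS_WINNER_KILLED",
    "CLASS_WINNER_SPARED",
    "CLASS_SLOW_HIGH_TURNOVER",
    "CLASS_BACKGROUND",
    "CLASS_UNCLASSIFIED",
]

CLASS_WINNER_KILLED = "winner-killed"
CLASS_WINNER_SPARED = "winner-spared"
CLASS_SLOW_HIGH_TURNOVER = "slow-high-turnover"
CLASS_BACKGROUND = "background"
CLASS_UNCLASSIFIED = "unclassified"

#: planted truth flag -> expected downstream class
TRUTH_TO_CLASS = {
    FLAG_SELECT_WINNER: CLASS_WINNER_KILLED,
    FLAG_SPARED_WINNER: CLASS_WINNER_SPARED,
    FLAG_SLOW: CLASS_SLOW_HIGH_TURNOVER,
    FLAG_BACKGROUND: CLASS_BACKGROUND,
}

CONDITIONS = ("combined", "protist", "phage")


def absolute_abundance(rel, total):
    """Absolute abundance: relative abundance times total cell count.

    Vectorised; per sample the absolute abundances of all ASVs sum back
    to the total (the relative abundances sum to 1).
    """
    rel = np.asarray(rel, dtype=float)
    total = np.asarray(total, dtype=float)
    if (rel < 0).any() or (rel > 1).any():
        raise ValueError("relative abundances must lie in [0, 1]")
    if (total < 0).any():
        raise ValueError("total counts must be >= 0")
    out = rel * total
    if out.ndim == 0:
        return float(out)
    return out


def _relative(reads: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Row-normalise a read matrix; all-zero rows stay zero."""
    reads = np.asarray(reads, dtype=float) + pseudocount
    totals = reads.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, reads / totals, 0.0)
    return rel


def asv_experiment_slopes(
    reads: pd.DataFrame,
    sample_meta: pd.DataFrame,
    design: DilutionDesign | None = None,
    *,
    convention: str = "predation-negative",
    pseudocount: float = 0.0,
    outlier_floor: float = dil.OUTLIER_FLOOR,
) -> pd.DataFrame:
    """Per-ASV mortality decomposition for one dilution experiment.

    The starting composition is the mean of the triplicate whole-water
    start samples, scaled by the mean start total count; each bottle's
    initial per-ASV abundance is that composition times the bottle's
    whole-water fraction (filtrate carries no cells).  Final per-ASV
    abundance is the bottle's relative abundance times its total count.
    Rates that would need the log of zero (ASV absent at start or in a
    bottle) are skipped, not pseudocounted, unless ``pseudocount`` is
    set.

    Parameters
    ----------
    reads
        Sample x ASV count matrix (rows indexed by sample id).
    sample_meta
        One row per sample: ``sample_id, experiment_id, role`` ("start"
        or "end"), ``series, whole_water_fraction, replicate,
        total_cells_ml``.

    Returns
    -------
    DataFrame with one row per ASV: slopes, SEs, phage mortality and
    error, bottle counts and flags.
    """
    design = design or DilutionDesign()
    meta = sample_meta.set_index("sample_id")
    exp_ids = meta["experiment_id"].unique()
    if len(exp_ids) != 1:
        raise ValueError("asv_experiment_slopes expects one experiment")
    exp_id = str(exp_ids[0])

    start_ids = meta.index[meta["role"] == "start"]
    end_meta = meta[meta["role"] == "end"]
    if len(start_ids) == 0 or len(end_meta) == 0:
        raise ValueError("experiment needs start samples and end bottles")

    asv_ids = list(reads.columns)
    rel_start = _relative(reads.loc[start_ids].to_numpy(), pseudocount)
    comp0 = rel_start.mean(axis=0)
    total0 = float(meta.loc[start_ids, "total_cells_ml"].mean())

    end_ids = [s for s in end_meta.index if s in reads.index]
    xs = end_meta.loc[end_ids, "whole_water_fraction"].to_numpy(dtype=float)
    series = end_meta.loc[end_ids, "series"].to_numpy()
    totals = end_meta.loc[end_ids, "total_cells_ml"].to_numpy(dtype=float)
    rel_end = _relative(reads.loc[end_ids].to_numpy(), pseudocount)

    # per-bottle per-ASV abundances and rates
    p0 = xs[:, None] * comp0[None, :] * total0
    pt = rel_end * totals[:, None]
    t = design.duration_h
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where((p0 > 0) & (pt > 0) & (xs[:, None] > 0), np.log(pt / p0) / t, np.nan)

    # (series, x) cells shared by every ASV
    cells = []
    for s in (SERIES_PROTIST, SERIES_COMBINED):
        for x in np.unique(xs[(series == s) & (xs > 0)]):
            cells.append((s, float(x), np.flatnonzero((series == s) & (xs == x))))

    rows = []
    for a, asv_id in enumerate(asv_ids):
        row = {
            "experiment_id": exp_id,
            "asv_id": asv_id,
            "slope_combined": math.nan,
            "se_combined": math.nan,
            "slope_protist": math.nan,
            "se_protist": math.nan,
            "phage_mortality": math.nan,
            "phage_error": math.nan,
            "n_combined": 0,
            "n_protist": 0,
            "n_discarded": 0,
            "flags": "",
        }
        flags = []
        if comp0[a] == 0 and not np.isfinite(rates[:, a]).any():
            flags.append("absent")
            row["flags"] = ";".join(flags)
            rows.append(row)
            continue
        fits = {}
        for s in (SERIES_PROTIST, SERIES_COMBINED):
            xs_fit, ys_fit = [], []
            for cs, x, idx in cells:
                if cs != s:
                    continue
                r = rates[idx, a]
                retained, record = filter_replicate_outliers(r, floor=outlier_floor)
                if record is not None:
                    row["n_discarded"] += 1
                kept = r[retained & np.isfinite(r)]
                xs_fit.extend([x] * len(kept))
                ys_fit.extend(kept.tolist())
            try:
                fits[s] = fit_dilution_slope(xs_fit, ys_fit)
            except (dil.InsufficientDataError, dil.DegenerateDesignError) as exc:
                flags.append(f"{s}_unfit:{type(exc).__name__}")
        if SERIES_PROTIST in fits:
            row["slope_protist"] = fits[SERIES_PROTIST].slope
            row["se_protist"] = fits[SERIES_PROTIST].se
            row["n_protist"] = fits[SERIES_PROTIST].n
        if SERIES_COMBINED in fits:
            row["slope_combined"] = fits[SERIES_COMBINED].slope
            row["se_combined"] = fits[SERIES_COMBINED].se
            row["n_combined"] = fits[SERIES_COMBINED].n
        if len(fits) == 2:
            row["phage_mortality"], row["phage_error"] = dil.phage_mortality(
                row["slope_combined"], row["se_combined"], row["slope_protist"], row["se_protist"], convention=convention
            )
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)


def asv_season_slopes(
    reads: pd.DataFrame,
    sample_meta: pd.DataFrame,
    design: DilutionDesign | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`asv_experiment_slopes` for every experiment and stack."""
    frames = []
    for exp_id, sub in sample_meta.groupby("experiment_id", sort=True):
        sub_reads = reads.loc[reads.index.intersection(sub["sample_id"])]
        frames.append(asv_experiment_slopes(sub_reads, sub, design, **kwargs))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# six-average summary and classification
# ---------------------------------------------------------------------------

def _sign_mean(values: np.ndarray, sign: int):
    """Mean of strictly negative (sign=-1) or strictly positive (sign=+1)
    finite values; (nan, 0) when none contribute."""
    vals = values[np.isfinite(values)]
    sel = vals[vals < 0] if sign < 0 else vals[vals > 0]
    if len(sel) == 0:
        return math.nan, 0
    return float(sel.mean()), int(len(sel))


def summarize_asv(per_experiment: pd.DataFrame) -> pd.DataFrame:
    """Six per-ASV averages over all dilution experiments.

    For each of the three conditions (combined slope, protist slope,
    phage mortality) the strictly negative per-experiment values are
    averaged and the strictly positive values are averaged; zeros count
    toward neither, and an average with no contributing experiments is
    missing (NaN), not zero.  Also reports ``activity``, the largest
    magnitude among the three negative averages — the predation-side
    score used for classification.  Invariant to experiment order.
    """
    cond_col = {"combined": "slope_combined", "protist": "slope_protist", "phage": "phage_mortality"}
    rows = []
    for asv_id, sub in per_experiment.groupby("asv_id", sort=True):
        row = {"asv_id": asv_id, "n_experiments": int(len(sub))}
        for cond, col in cond_col.items():
            vals = sub[col].to_numpy(dtype=float)
            neg, n_neg = _sign_mean(vals, -1)
            pos, n_pos = _sign_mean(vals, +1)
            row[f"neg_avg_{cond}"] = neg
            row[f"pos_avg_{cond}"] = pos
            row[f"n_neg_{cond}"] = n_neg
            row[f"n_pos_{cond}"] = n_pos
        negs = np.array([row[f"neg_avg_{c}"] for c in CONDITIONS], dtype=float)
        row["activity"] = float(np.nanmax(np.abs(negs))) if np.isfinite(negs).any() else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def classify_ksw(
    summary: pd.DataFrame,
    prmdt: pd.Series | dict,
    *,
    fast_threshold_h: float = 5.0,
    activity_threshold: float = 0.01,
) -> pd.DataFrame:
    """Assign kill-select-winner classes from activity vs PRMDT.

    An ASV is a predicted fast grower when its PRMDT is below
    ``fast_threshold_h`` (default 5 h) and *active* when its
    predation-side activity exceeds ``activity_threshold`` (default
    0.01 h^-1).  Fast + active = ``winner-killed``; fast + quiet =
    ``winner-spared``; slow + active = ``slow-high-turnover``; slow +
    quiet = ``background``.  ASVs without a PRMDT are ``unclassified``.
    """
    prmdt = pd.Series(prmdt)
    out = summary.copy()
    out["prmdt_h"] = out["asv_id"].map(prmdt)
    classes = []
    for _, row in out.iterrows():
        p = row["prmdt_h"]
        if not np.isfinite(p):
            classes.append(CLASS_UNCLASSIFIED)
            continue
        activity = row["activity"] if np.isfinite(row["activity"]) else 0.0
        fast = p < fast_threshold_h
        active = activity > activity_threshold
        if fast and active:
            classes.append(CLASS_WINNER_KILLED)
        elif fast:
            classes.append(CLASS_WINNER_SPARED)
        elif active:
            classes.append(CLASS_SLOW_HIGH_TURNOVER)
        else:
            classes.append(CLASS_BACKGROUND)
    out["ksw_class"] = classes
    return out


def ksw_recovery_score(truth: CommunityTruth, classified: pd.DataFrame) -> dict:
    """Score recovered classes against the planted truth.

    Returns overall accuracy, the confusion matrix (truth rows x
    predicted columns) and per-class precision/recall.
    """
    if truth.n_asv == 0 or len(classified) == 0:
        raise ValueError("empty community or classification")
    pred = classified.set_index("asv_id")["ksw_class"]
    missing = [a for a in truth.asv_ids if a not in pred.index]
    if missing:
        raise ValueError(f"classified table lacks {len(missing)} truth ASVs (e.g. {missing[0]})")
    expected = pd.Series(
        [TRUTH_TO_CLASS[f] for f in truth.winner_flags], index=truth.asv_ids, name="expected"
    )
    predicted = pred.loc[truth.asv_ids]
    accuracy = float((expected.to_numpy() == predicted.to_numpy()).mean())
    labels = sorted(set(expected) | set(predicted))
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for e, p in zip(expected, predicted):
        confusion.loc[e, p] += 1
    per_class = {}
    for lab in labels:
        tp = int(confusion.loc[lab, lab])
        fn = int(confusion.loc[lab].sum()) - tp
        fp = int(confusion[lab].sum()) - tp
        per_class[lab] = {
            "precision": tp / (tp + fp) if tp + fp else math.nan,
            "recall": tp / (tp + fn) if tp + fn else math.nan,
            "support": tp + fn,
        }
    return {"accuracy": accuracy, "confusion": confusion, "per_class": per_class}
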