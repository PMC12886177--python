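"""Table formats, configuration, validation and pipeline orchestration.

All tables are UTF-8, tab-delimited with a header row; missing values
are empty fields.  Output tables carry a ``# config_hash=...`` comment
line so any result file can be traced to the configuration that
produced it.  Fractions are stored as decimals in [0, 1], dates as
ISO-8601 strings.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancillary, asv, dilution, synthetic
from .dilution import DilutionDesign

__all__ = [
    "RunConfig",
    "read_table",
    "write_table",
    "validate_bottles",
    "validate_reads",
    "validate_prmdt",
    "validate_tables",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, *, config_hash: str | None = None, index: bool = False) -> None:
    """Write a tab-delimited table, optionally stamped with the config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="")


def read_table(path, *, index_col=None) -> pd.DataFrame:
    """Read a tab-delimited table, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_config_hash(path) -> str | None:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        return first.strip().split("=", 1)[1]
    return None


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _violation(table, row, column, rule, message):
    return {"table": table, "row": row, "column": column, "rule": rule, "message": message}


def validate_bottles(df: pd.DataFrame, max_violations: int = 50) -> list[dict]:
    """Schema check for the bottle table."""
    out: list[dict] = []
    required = {"experiment_id", "series", "whole_water_fraction", "replicate", "p0", "pt"}
    missing = required - set(df.columns)
    for col in sorted(missing):
        out.append(_violation("bottles", None, col, "required-column", f"missing column {col!r}"))
    if missing:
        return out
    for i, row in df.iterrows():
        if len(out) >= max_violations:
            break
        if row["series"] not in dilution.SERIES:
            out.append(_violation("bottles", i, "series", "series-domain", f"unknown series {row['series']!r}"))
        x = row["whole_water_fraction"]
        if not 0 <= x <= 1:
            out.append(_violation("bottles", i, "whole_water_fraction", "fraction-range", f"{x} outside [0, 1]"))
        for col in ("p0", "pt"):
            if row[col] < 0:
                out.append(_violation("bottles", i, col, "non-negative", f"{col} = {row[col]} < 0"))
    key = ["experiment_id", "series", "whole_water_fraction", "replicate"]
    dups = df[df.duplicated(key, keep=False)]
    for i in dups.index[: max(0, max_violations - len(out))]:
        out.append(_violation("bottles", i, ",".join(key), "duplicate-key", "duplicate bottle key"))
    return out


def validate_reads(df: pd.DataFrame, max_violations: int = 50, tol: float = 1e-9) -> list[dict]:
    """Schema check for a sample x ASV abundance matrix.

    Integer matrices are taken as read counts (non-negative); float
    matrices as relative abundances (rows must sum to 1 within ``tol``).
    """
    out: list[dict] = []
    vals = df.to_numpy()
    if (vals < 0).any():
        rows = np.unique(np.nonzero(vals < 0)[0])
        for r in rows[:max_violations]:
            out.append(_violation("reads", df.index[r], None, "non-negative", "negative abundance"))
        return out
    if np.issubdtype(vals.dtype, np.floating):
        sums = vals.sum(axis=1)
        bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > tol))
        for r in bad[:max_violations]:
            out.append(
                _violation("reads", df.index[r], None, "normalization", f"relative abundances sum to {sums[r]:.6g}, not 1")
            )
    return out


def validate_prmdt(df: pd.DataFrame, max_violations: int = 50) -> list[dict]:
    out: list[dict] = []
    for col in ("asv_id", "prmdt_h"):
        if col not in df.columns:
            out.append(_violation("prmdt", None, col, "required-column", f"missing column {col!r}"))
    if out:
        return out
    bad = df[df["prmdt_h"] <= 0]
    for i in bad.index[:max_violations]:
        out.append(_violation("prmdt", i, "prmdt_h", "positive", "PRMDT must be > 0 hours"))
    return out


def validate_tables(tables: dict) -> list[dict]:
    """Validate any of {"bottles", "reads", "prmdt"} tables; return the
    combined machine-readable violation list (empty = clean)."""
    validators = {"bottles": validate_bottles, "reads": validate_reads, "prmdt": validate_prmdt}
    out: list[dict] = []
    for name, df in tables.items():
        fn = validators.get(name)
        if fn is None:
            raise KeyError(f"no validator for table {name!r}")
        out.extend(fn(df))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable, hashable.

    With ``simulate = True`` the inputs are generated by the synthetic
    module; otherwise ``bottles_path`` (and optionally ``reads_path`` /
    ``sample_meta_path`` / ``prmdt_path``) point at input tables.
    """

    outdir: str = "ksw-run"
    seed: int = 0
    simulate: bool = True
    # synthetic-community parameters
    n_asv: int = 40
    n_experiments: int = 12
    count_cv: float = 0.05
    read_depth: int | None = 100_000
    frac_select_winners: float = 0.15
    frac_spared_winners: float = 0.15
    frac_slow: float = 0.10
    # design
    filtrate_fractions: tuple = (0.0, 0.30, 0.70, 0.95, 1.00)
    replicates: int = 3
    duration_h: float = 24.0
    # analysis
    convention: str = "predation-negative"
    estimator: str = "ols"
    fast_threshold_h: float = 5.0
    activity_threshold: float = 0.01
    # external inputs (used when simulate = False)
    bottles_path: str | None = None
    reads_path: str | None = None
    sample_meta_path: str | None = None
    prmdt_path: str | None = None
    induction_path: str | None = None

    def design(self) -> DilutionDesign:
        return DilutionDesign(
            filtrate_fractions=tuple(self.filtrate_fractions),
            replicates=self.replicates,
            duration_h=self.duration_h,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filtrate_fractions"] = list(self.filtrate_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "filtrate_fractions" in d:
            d["filtrate_fractions"] = tuple(d["filtrate_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate (optional) -> dilution -> ASV -> ancillary -> report.

    Writes every stage's output table plus ``manifest.json`` into
    ``config.outdir`` and returns the manifest.  Deterministic stages
    reproduce bit-identically under the same config and inputs; partial
    outputs are removed when a stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    written: list[str] = []
    warnings: list[str] = []

    def _write(df, name, **kw):
        write_table(df, outdir / name, config_hash=h, **kw)
        written.append(name)

    try:
        design = config.design()
        prmdt = None
        truth = None
        if config.simulate:
            truth = synthetic.simulate_community(
                config.n_asv,
                seed=config.seed,
                frac_select_winners=config.frac_select_winners,
                frac_spared_winners=config.frac_spared_winners,
                frac_slow=config.frac_slow,
                fast_threshold_h=config.fast_threshold_h,
            )
            noise = synthetic.NoiseSpec(
                count_cv=config.count_cv, read_depth=config.read_depth, seed=config.seed
            )
            sim = synthetic.simulate_experiments(truth, config.n_experiments, design, noise)
            bottles, reads, sample_meta = sim.bottles, sim.reads, sim.sample_meta
            prmdt = pd.Series(truth.prmdt, index=truth.asv_ids)
            _write(bottles, "bottles.tsv")
            _write(reads, "asv_reads.tsv", index=True)
            _write(sample_meta, "sample_meta.tsv")
            _write(truth.to_frame(), "truth.tsv")
        else:
            if config.bottles_path is None:
                raise ValueError("simulate=False requires bottles_path")
            bottles = read_table(config.bottles_path)
            bad = validate_bottles(bottles)
            if bad:
                raise ValueError(f"bottle table invalid: {bad[:3]}")
            reads = sample_meta = None
            if config.reads_path and config.sample_meta_path:
                reads = read_table(config.reads_path, index_col=0)
                sample_meta = read_table(config.sample_meta_path)
            if config.prmdt_path:
                ptab = read_table(config.prmdt_path)
                bad = validate_prmdt(ptab)
                if bad:
                    raise ValueError(f"PRMDT table invalid: {bad[:3]}")
                prmdt = ptab.set_index("asv_id")["prmdt_h"]

        # dilution stage: per-experiment mortality decomposition
        results = dilution.analyze_experiments(
            bottles, design, convention=config.convention, estimator=config.estimator
        )
        _write(results, "experiment_results.tsv")

        # ASV stage
        summary = None
        if reads is not None and sample_meta is not None:
            per_exp = asv.asv_season_slopes(reads, sample_meta, design, convention=config.convention)
            _write(per_exp, "asv_experiment_results.tsv")
            summary = asv.summarize_asv(per_exp)
            if prmdt is None:
                warnings.append("no PRMDT table: ksw_class set to unclassified")
                prmdt = pd.Series(dtype=float)
            summary = asv.classify_ksw(
                summary,
                prmdt,
                fast_threshold_h=config.fast_threshold_h,
                activity_threshold=config.activity_threshold,
            )
            _write(summary, "asv_summary.tsv")

        # ancillary stage: induction tests, if provided
        if config.induction_path:
            ind = read_table(config.induction_path)
            rows = []
            for date, sub in ind.groupby("date"):
                ctrl = sub[sub["arm"] == "control"]
                trt = sub[sub["arm"] == "treated"]
                res = ancillary.induction_test(
                    ancillary.InductionExperiment(
                        tuple(ctrl["vlp_start"]), tuple(ctrl["vlp_end"]),
                        tuple(trt["vlp_start"]), tuple(trt["vlp_end"]),
                    )
                )
                rows.append(
                    {
                        "date": date,
                        "f_statistic": res.f_statistic,
                        "p_value": res.p_value,
                        "lysogeny": res.lysogeny,
                    }
                )
            _write(pd.DataFrame(rows), "induction_results.tsv")

        # report stage: tidy tables behind the standard figures
        fig4 = results[
            ["experiment_id", "slope_combined", "slope_protist", "phage_mortality", "call_combined", "call_protist"]
        ].copy()
        _write(fig4, "report_experiment_slopes.tsv")
        if summary is not None:
            fig5b = summary[
                ["asv_id", "neg_avg_combined", "neg_avg_protist", "neg_avg_phage",
                 "pos_avg_combined", "pos_avg_protist", "pos_avg_phage", "prmdt_h", "ksw_class"]
            ].copy()
            _write(fig5b, "report_asv_activity.tsv")

        manifest = {
            "config": config.to_dict(),
            "config_hash": h,
            "outputs": written,
            "warnings": warnings,
            "n_experiments": int(results.shape[0]),
        }
        if truth is not None and summary is not None:
            score = asv.ksw_recovery_score(truth, summary)
            manifest["ksw_recovery_accuracy"] = score["accuracy"]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception:
        for name in written:
            (outdir / name).unlink(missing_ok=True)
        raise


def clean_outdir(path) -> None:
    shutil.rmtree(path, ignore_errors=True)
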