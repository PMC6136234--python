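"""End-to-end pipeline: simulate (or load) -> QC -> per-subject metrics ->
cohort statistics -> report bundle.

Everything is deterministic given the run configuration and seed; the
manifest written alongside the outputs records the package version, the
configuration hash, and every analysis toggle in effect, so a bundle can be
reproduced from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from glucodyn import __version__
from glucodyn.cgm_io import read_cgm_csv, write_cgm_csv
from glucodyn.cohort import records_to_frame, join_cohort_table
from glucodyn.complexity import MSEParams, mse_index
from glucodyn.dfa import (
    DEFAULT_LONG_RANGE,
    DEFAULT_MIN_BOX,
    DEFAULT_SHORT_RANGE,
    dfa_exponents,
)
from glucodyn.errors import ConfigError, GlucodynError
from glucodyn.gv import DEFAULT_RANGE, compute_gv
from glucodyn.poincare import DEFAULT_LAG_MIN, poincare_descriptors
from glucodyn.series import GlucoseSeries
from glucodyn.simulate import CohortSpec, cohort_spec_from_dict, generate_cohort
from glucodyn.stats import compare_groups, spearman_matrix

logger = logging.getLogger("glucodyn")

#: Metric columns produced per subject, in output order.
METRIC_COLUMNS = (
    "mean_glucose",
    "sd",
    "cv_percent",
    "tir_hours_per_day",
    "sd1",
    "sd2",
    "sfe",
    "afe",
    "complexity_index",
    "alpha1",
    "alpha2",
    "fit_r2_short",
    "fit_r2_long",
)

#: Index columns entering the cross-domain correlation matrix.
INDEX_COLUMNS = ("sd1", "sd2", "sfe", "afe", "complexity_index", "alpha1", "alpha2")


@dataclass
class RunConfig:
    """All tunables of one pipeline run. Exactly one input source is set."""

    cohort: CohortSpec | dict | None = None
    input_dir: str | Path | None = None
    lag_min: float = DEFAULT_LAG_MIN
    mse: MSEParams = field(default_factory=MSEParams)
    dfa_short_range: tuple[int, int] = DEFAULT_SHORT_RANGE
    dfa_long_range: tuple[int, int] = DEFAULT_LONG_RANGE
    dfa_min_box: int = DEFAULT_MIN_BOX
    tir_low: float = DEFAULT_RANGE[0]
    tir_high: float = DEFAULT_RANGE[1]
    stats_metrics: tuple[str, ...] = METRIC_COLUMNS
    seed: int = 0
    outdir: str | Path = "results/run"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ConfigError("set exactly one of 'cohort' and 'input_dir'")
        if isinstance(self.cohort, dict):
            cohort = dict(self.cohort)
            cohort.setdefault("seed", self.seed)
            self.cohort = cohort_spec_from_dict(cohort)
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ConfigError(f"input directory {self.input_dir} does not exist")


def subject_metrics(
    series: GlucoseSeries,
    lag_min: float = DEFAULT_LAG_MIN,
    mse_params: MSEParams = MSEParams(),
    dfa_short_range: tuple[int, int] = DEFAULT_SHORT_RANGE,
    dfa_long_range: tuple[int, int] = DEFAULT_LONG_RANGE,
    dfa_min_box: int = DEFAULT_MIN_BOX,
    tir_low: float = DEFAULT_RANGE[0],
    tir_high: float = DEFAULT_RANGE[1],
) -> dict:
    """All per-subject metrics for one series as a flat record."""
    gv = compute_gv(series, low=tir_low, high=tir_high)
    pc = poincare_descriptors(series, lag_min=lag_min)
    mse = mse_index(series, params=mse_params)
    dfa = dfa_exponents(
        series,
        short_range=dfa_short_range,
        long_range=dfa_long_range,
        min_box=dfa_min_box,
    )
    return {
        "subject_id": series.subject_id,
        "group": series.group,
        "mean_glucose": gv.mean_glucose,
        "sd": gv.sd,
        "cv_percent": gv.cv_percent,
        "tir_hours_per_day": gv.tir_hours_per_day,
        "sd1": pc.sd1,
        "sd2": pc.sd2,
        "sfe": pc.sfe,
        "afe": pc.afe,
        "complexity_index": mse.complexity_index,
        "alpha1": dfa.alpha1,
        "alpha2": dfa.alpha2,
        "fit_r2_short": dfa.fit_r2_short,
        "fit_r2_long": dfa.fit_r2_long,
        "mse_partial": mse.partial,
    }


def metrics_table(series_list: list[GlucoseSeries], config: RunConfig) -> pd.DataFrame:
    rows = [
        subject_metrics(
            s,
            lag_min=config.lag_min,
            mse_params=config.mse,
            dfa_short_range=config.dfa_short_range,
            dfa_long_range=config.dfa_long_range,
            dfa_min_box=config.dfa_min_box,
            tir_low=config.tir_low,
            tir_high=config.tir_high,
        )
        for s in series_list
    ]
    return pd.DataFrame(rows)


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["outdir"] = str(d["outdir"])
    if d["input_dir"] is not None:
        d["input_dir"] = str(d["input_dir"])
    if isinstance(config.cohort, CohortSpec):
        d["cohort"] = {
            "groups": [
                {**asdict(prof), "n_subjects": n} for prof, n in config.cohort.groups
            ],
            "n_points": config.cohort.n_points,
            "interval_min": config.cohort.interval_min,
            "seed": config.cohort.seed,
        }
    return d


def _stage(name: str):
    """Context manager logging stage timing and naming the stage on failure."""

    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            if isinstance(exc, GlucodynError) and not str(exc).startswith(f"[{name}]"):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Stage()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the output bundle under ``config.outdir``.

    Returns a dict with the in-memory tables (``metrics``, ``cohort``,
    ``group_comparisons``, ``spearman_rho``) and the manifest. Files written:
    ``metrics.csv``, ``subjects.csv`` (simulated runs), ``group_comparisons.csv``,
    ``spearman_rho.csv``, ``manifest.json``, plus one CGM CSV per simulated
    subject under ``series/``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    covariates = None
    with _stage("input"):
        if config.cohort is not None:
            series_list, records = generate_cohort(config.cohort)
            covariates = records_to_frame(records)
            series_dir = outdir / "series"
            series_dir.mkdir(exist_ok=True)
            for s in series_list:
                write_cgm_csv(s, series_dir / f"{s.subject_id}.csv")
            covariates.to_csv(outdir / "subjects.csv", index=False, float_format="%.4f")
        else:
            paths = sorted(Path(config.input_dir).glob("*.csv"))
            if not paths:
                raise ConfigError(f"no CSV series found under {config.input_dir}")
            series_list = [read_cgm_csv(p) for p in paths]

    with _stage("metrics"):
        metrics = metrics_table(series_list, config)
        metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")

    cohort_table = metrics
    if covariates is not None:
        with _stage("join"):
            cohort_table = join_cohort_table(covariates, metrics)
            cohort_table.to_csv(outdir / "cohort.csv", index=False, float_format="%.6f")

    comparisons = None
    rho = None
    groups = metrics["group"].dropna().unique()
    group_sizes = metrics["group"].value_counts()
    if len(groups) >= 2 and (group_sizes >= 2).all():
        with _stage("stats"):
            rows = []
            for metric in config.stats_metrics:
                if metric not in metrics.columns:
                    continue
                col = metrics[metric].to_numpy(dtype=float)
                if not np.isfinite(col).all() or np.ptp(col) == 0.0:
                    continue  # constant or undefined metric: no comparison
                cmp_res = compare_groups(metrics, metric)
                for _, pr in cmp_res.pairwise.iterrows():
                    rows.append(
                        {
                            "metric": metric,
                            "anova_f": cmp_res.anova_f,
                            "anova_p": cmp_res.anova_p,
                            **pr.to_dict(),
                        }
                    )
            comparisons = pd.DataFrame(rows)
            comparisons.to_csv(
                outdir / "group_comparisons.csv", index=False, float_format="%.6g"
            )
            index_cols = [c for c in INDEX_COLUMNS if c in metrics.columns]
            rho, _ = spearman_matrix(metrics.dropna(subset=index_cols), index_cols)
            rho.to_csv(outdir / "spearman_rho.csv", float_format="%.4f")

    with _stage("manifest"):
        cfg = _config_dict(config)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        manifest = {
            "package_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": config.seed,
            "n_subjects": int(len(metrics)),
            "n_points": int(len(series_list[0])) if series_list else 0,
            "mse_coarse_lengths": {
                str(tau): len(series_list[0]) // tau
                for tau in range(1, config.mse.max_scale + 1)
            }
            if series_list
            else {},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "metrics": metrics,
        "cohort": cohort_table,
        "group_comparisons": comparisons,
        "spearman_rho": rho,
        "manifest": manifest,
    }
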