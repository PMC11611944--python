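"""Tabular I/O and per-subject pipeline orchestration.

Canonical input is a long-format CSV/TSV with one row per subject x tract:
``subject_id, tract_id, length_mm, <metric>`` (plus optional
``n_streamlines``). The pipeline fits the three candidate models per
subject, averages them by Akaike weight, and emits the adjusted table plus a
JSON-serialisable fit report per subject. Outputs are byte-stable given
identical inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import (
    DegenerateWeightsError,
    EmptyRunError,
    InsufficientDataError,
    SchemaError,
)
from .averaging import AdjustedTable, AveragedModel, average_subject, residuals_and_adjust
from .data import SubjectTractTable
from .models import DEFAULT_WINDOW, GRID_STEP_MM, REFINE_TOL_MM, CandidateFit, fit_all

__all__ = [
    "RunConfig",
    "SubjectFitReport",
    "IngestResult",
    "read_tract_table",
    "run_pipeline",
    "write_outputs",
    "adjusted_tables_to_frame",
]

log = logging.getLogger("tractadjust")

REQUIRED_COLUMNS = ("subject_id", "tract_id", "length_mm")


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a pipeline run besides the data."""

    metric: str = "FA"
    quantile: float = 0.5  # fixed: median regression
    window_pct: tuple[float, float] = DEFAULT_WINDOW
    grid_step_mm: float = GRID_STEP_MM
    refine_tol_mm: float = REFINE_TOL_MM
    n_boot: int = 1000
    seed: int = 0
    min_tracts: int = 5
    out_dir: str = "tractadjust_out"

    def __post_init__(self) -> None:
        if self.quantile != 0.5:
            raise ValueError("only median (tau = 0.5) regression is supported")
        if min(self.grid_step_mm, self.refine_tol_mm) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_tracts < 5:
            raise ValueError("min_tracts must be >= 5 (piecewise fit needs 5)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window_pct" in raw:
            raw["window_pct"] = tuple(raw["window_pct"])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_pct"] = list(self.window_pct)
        return d


@dataclass
class SubjectFitReport:
    """Per-subject result: candidate fits, averaged model, adjustment, and
    diagnostics. ``skipped_reason`` is set (and the rest None) for subjects
    the pipeline could not model."""

    subject_id: str
    n_tracts: int
    fits: dict[str, CandidateFit] | None = None
    averaged: AveragedModel | None = None
    adjusted: AdjustedTable | None = None
    skipped_reason: str | None = None

    def to_dict(self) -> dict:
        out: dict = {"subject_id": self.subject_id, "n_tracts": self.n_tracts}
        if self.skipped_reason is not None:
            out["skipped_reason"] = self.skipped_reason
            return out
        assert self.fits is not None and self.averaged is not None
        out["models"] = {
            kind: {
                "params": {
                    k: v
                    for k, v in dataclasses.asdict(f.params).items()
                    if v is not None
                },
                "sum_abs_resid": f.sum_abs_resid,
                "n": f.n,
                "k": f.k,
                "aicc": f.aicc,
            }
            for kind, f in self.fits.items()
        }
        out["akaike_weights"] = dict(zip(("linear", "blackman", "piecewise"),
                                         self.averaged.weights))
        out["rescaled_weights"] = dict(zip(("blackman", "piecewise"),
                                           self.averaged.rescaled_weights))
        out["averaged"] = {
            "inflection_mm": self.averaged.inflection_mm,
            "value_at_inflection": self.averaged.value_at_inflection,
            "slope1": self.averaged.slope1_avg,
            "slope2": self.averaged.slope2_avg,
        }
        return out


@dataclass
class IngestResult:
    tables: list[SubjectTractTable]
    n_dropped_rows: int = 0
    dropped_subjects: list[str] = field(default_factory=list)


def read_tract_table(path: str | Path, metric: str = "FA") -> IngestResult:
    """Read a long-format tract table (CSV, or TSV by extension).

    Rows with a missing length or metric are dropped and counted; a
    duplicated (subject, tract) pair is a hard error. Subjects left with
    fewer than 2 distinct lengths are dropped and recorded.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    missing = [c for c in (*REQUIRED_COLUMNS, metric) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing} in {path.name}; "
            f"found header {list(df.columns)}"
        )
    for col in ("length_mm", metric):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    dup = df.duplicated(subset=["subject_id", "tract_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "tract_id"]].drop_duplicates()
        raise SchemaError(
            "duplicate (subject, tract) rows: "
            + ", ".join(f"({r.subject_id}, {r.tract_id})" for r in pairs.itertuples())
        )

    ok = df["length_mm"].notna() & df[metric].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d row(s) with missing length or %s", n_dropped, metric)
    df = df[ok]

    tables, dropped_subjects = [], []
    for sid, grp in df.groupby("subject_id", sort=True):
        try:
            tables.append(SubjectTractTable.from_frame(grp, metric_name=metric))
        except ValueError as exc:
            log.warning("dropping subject %r: %s", sid, exc)
            dropped_subjects.append(str(sid))
    return IngestResult(tables, n_dropped, dropped_subjects)


def run_pipeline(
    config: RunConfig, tables: list[SubjectTractTable]
) -> list[SubjectFitReport]:
    """Fit, average and adjust every subject.

    Subjects with too few tracts, a failed fit, or no weight on the
    breakpoint models are reported with a ``skipped_reason`` instead of
    being imputed.
    """
    if not tables:
        raise EmptyRunError("no usable subjects in the input")
    reports: list[SubjectFitReport] = []
    for table in tables:
        rep = SubjectFitReport(subject_id=table.subject_id, n_tracts=table.n)
        if table.n < config.min_tracts:
            rep.skipped_reason = (
                f"only {table.n} tracts (< min_tracts = {config.min_tracts})"
            )
            log.warning("skipping %s: %s", table.subject_id, rep.skipped_reason)
            reports.append(rep)
            continue
        try:
            fits = fit_all(
                table,
                window_pct=config.window_pct,
                grid_step=config.grid_step_mm,
                refine_tol=config.refine_tol_mm,
            )
            averaged = average_subject(fits)
        except (InsufficientDataError, DegenerateWeightsError) as exc:
            rep.skipped_reason = str(exc)
            log.warning("skipping %s: %s", table.subject_id, rep.skipped_reason)
            reports.append(rep)
            continue
        rep.fits = fits
        rep.averaged = averaged
        rep.adjusted = residuals_and_adjust(table, averaged)
        reports.append(rep)
    if all(r.skipped_reason is not None for r in reports):
        raise EmptyRunError("every subject was skipped; nothing to adjust")
    return reports


def adjusted_tables_to_frame(
    reports: list[SubjectFitReport], metric: str = "FA"
) -> pd.DataFrame:
    """Long-format adjusted table across all modelled subjects."""
    frames = []
    for rep in reports:
        if rep.adjusted is None:
            continue
        adj = rep.adjusted
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": adj.subject_id,
                    "tract_id": adj.tract_ids,
                    "length_mm": adj.lengths_mm,
                    metric: adj.observed,
                    "residual": adj.residuals,
                    "adjusted": adj.adjusted,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    reports: list[SubjectFitReport],
    config: RunConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the adjusted CSV, per-subject JSON fit reports, and a run log.

    The run log records the configuration, seed and package version; nothing
    time-dependent is written, so reruns are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "adjusted": out / "adjusted.csv",
        "reports": out / "fit_reports.json",
        "log": out / "run_log.json",
    }
    adjusted_tables_to_frame(reports, metric=config.metric).to_csv(
        paths["adjusted"], index=False
    )
    paths["reports"].write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, sort_keys=True,
                   allow_nan=True)
        + "\n"
    )
    versions = {"tractadjust": __version__, "numpy": np.__version__,
                "pandas": pd.__version__}
    paths["log"].write_text(
        json.dumps(
            {"config": config.to_dict(), "seed": config.seed, "versions": versions,
             "n_subjects": len(reports),
             "n_skipped": sum(r.skipped_reason is not None for r in reports)},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return paths
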