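"""Theoretical streamline-profile model and the synthetic-cohort generator.

The generative thought experiment: along a streamline, a quantitative metric
(FA-like, bounded in [0, 1]) ramps up linearly from the tractography
termination threshold at each end until it reaches the range ceiling, and is
constant in between. Averaging the profile over the whole streamline then
makes the tract-mean metric rise linearly with streamline length while both
ends' ramps overlap, and approach the ceiling as a power law once a central
plateau exists. Real tissue never attains the theoretical ceiling: each
specimen (brain) has its own asymptote A, so the empirical mean curve is
capped at A — a linear-plateau (Blackman) shape, which is what the fitting
pipeline assumes.

The synthetic-cohort generator draws per-subject Blackman curves around this
picture and is the test bed for the whole adjustment pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SubjectTractTable
from .models import ModelParams, eval_model

__all__ = [
    "TheoreticalProfileParams",
    "SyntheticCohortSpec",
    "CohortGroundTruth",
    "profile_value",
    "theoretical_mean",
    "specimen_mean",
    "terminal_section_proportion",
    "simulate_subject",
    "simulate_cohort",
    "cohort_to_frame",
    "per_tract_tables",
]


@dataclass(frozen=True)
class TheoreticalProfileParams:
    """Parameters of the along-streamline profile model.

    threshold
        Termination magnitude threshold: the profile value at a streamline
        end (default 0.2, a typical FA termination criterion).
    ramp_rate
        Slope of the terminal ramp, metric units per unit length
        (default 0.016, i.e. an increase of 1.6 per 100 length units).
    ceiling
        Upper limit of the metric's range (1 for FA-like metrics).
    specimen_asymptote
        The largest value real tissue of a given specimen attains
        (default 0.7); threshold < asymptote <= ceiling.
    """

    threshold: float = 0.2
    ramp_rate: float = 0.016
    ceiling: float = 1.0
    specimen_asymptote: float = 0.7

    def __post_init__(self) -> None:
        if not (self.threshold < self.specimen_asymptote <= self.ceiling):
            raise ValueError("need threshold < specimen_asymptote <= ceiling")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")

    @property
    def terminal_length(self) -> float:
        """Distance from a streamline end at which the ramp reaches the
        ceiling: L = (ceiling − threshold) / ramp_rate (50 units with the
        defaults)."""
        return (self.ceiling - self.threshold) / self.ramp_rate


def profile_value(params: TheoreticalProfileParams, d) -> np.ndarray | float:
    """Profile value at distance ``d`` from the nearer streamline end:
    min(threshold + ramp_rate·d, ceiling)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance from the streamline end must be >= 0")
    out = np.minimum(params.threshold + params.ramp_rate * d, params.ceiling)
    return out if out.ndim else float(out)


def _mean_of_capped_profile(t0: float, s: float, cap: float, l: np.ndarray) -> np.ndarray:
    """Mean over [0, l] of min(t0 + s·min(x, l−x), cap), closed form.

    For l <= 2(cap−t0)/s the two ramps meet below the cap and the mean is
    t0 + s·l/4; beyond, two full ramps of length (cap−t0)/s flank a plateau
    at cap, giving cap − (cap−t0)²/(s·l). Continuous at the junction.
    """
    two_l = 2.0 * (cap - t0) / s
    return np.where(
        l <= two_l,
        t0 + s * l / 4.0,
        cap - (cap - t0) ** 2 / (s * l),
    )


def theoretical_mean(params: TheoreticalProfileParams, l) -> np.ndarray | float:
    """Streamline-averaged metric as a function of streamline length.

    Linear (slope s/4) while the streamline consists only of the two
    terminal ramps, then a power-law approach to the ceiling.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("streamline length must be positive")
    out = _mean_of_capped_profile(params.threshold, params.ramp_rate, params.ceiling, l)
    return out if out.ndim else float(out)


def specimen_mean(
    params: TheoreticalProfileParams, l, cap: str = "mean"
) -> np.ndarray | float:
    """Empirical mean curve for a real specimen with asymptote A.

    ``cap="mean"`` (default): min(theoretical_mean(l), A) — the mean curve
    rises and then stays exactly at A (slope zero past the crossing length).
    ``cap="profile"``: the per-position profile is capped at A instead, which
    yields a smooth asymptotic approach to A rather than a hard plateau.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("streamline length must be positive")
    A = params.specimen_asymptote
    if cap == "mean":
        out = np.minimum(
            _mean_of_capped_profile(params.threshold, params.ramp_rate, params.ceiling, l),
            A,
        )
    elif cap == "profile":
        out = _mean_of_capped_profile(params.threshold, params.ramp_rate, A, l)
    else:
        raise ValueError(f"cap must be 'mean' or 'profile', got {cap!r}")
    return out if out.ndim else float(out)


def terminal_section_proportion(params: TheoreticalProfileParams, l) -> np.ndarray | float:
    """Proportion p̂ = min(2L, l)/l of a streamline occupied by the terminal
    ramps; 1 for l <= 2L, decaying as 2L/l beyond."""
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("streamline length must be positive")
    out = np.minimum(2.0 * params.terminal_length, l) / l
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-condition parameters for the synthetic cohort.

    Defaults emulate the cohort geometry the pipeline was designed around:
    43 subjects, 82 tracts resolved per subject out of an atlas of 120, tract
    lengths spanning roughly 50–170 mm with a mean within-subject length
    range near 106 mm and a mean per-tract across-subject range near 64 mm
    (per-tract ranges much narrower than per-subject ranges). Each subject's
    metric follows a Blackman curve — inflection near 102 mm, initial slope
    near 0.004 per mm, plateau near 0.45 for FA — plus symmetric noise.
    """

    n_subjects: int = 43
    n_tracts_atlas: int = 120
    tracts_per_subject: int = 82
    nominal_length_min_mm: float = 74.0
    nominal_length_max_mm: float = 134.0
    length_jitter_sd_mm: float = 16.0
    inflection_mean_mm: float = 102.0
    inflection_sd_mm: float = 8.0
    slope_mean: float = 0.004
    slope_sd: float = 0.0008
    plateau_mean: float = 0.45
    plateau_sd: float = 0.03
    noise_sd: float = 0.03
    noise: str = "gaussian"  # or "laplace"
    curve: str = "blackman"  # or "specimen" (theoretical specimen mean curve)
    metric_name: str = "FA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("gaussian", "laplace"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.curve not in ("blackman", "specimen"):
            raise ValueError(f"unknown generating curve {self.curve!r}")
        if self.tracts_per_subject > self.n_tracts_atlas:
            raise ValueError("tracts_per_subject cannot exceed the atlas size")
        if min(self.length_jitter_sd_mm, self.noise_sd, self.inflection_sd_mm,
               self.slope_sd, self.plateau_sd) < 0:
            raise ValueError("dispersions must be nonnegative")
        if self.nominal_length_min_mm <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class SubjectTruth:
    subject_id: str
    inflection_mm: float
    slope: float
    plateau: float
    intercept: float


@dataclass(frozen=True)
class CohortGroundTruth:
    """Generating parameters, for parameter-recovery tests."""

    spec: SyntheticCohortSpec
    nominal_lengths_mm: np.ndarray
    subjects: list[SubjectTruth] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "inflection_mm": s.inflection_mm,
                    "slope": s.slope,
                    "plateau": s.plateau,
                    "intercept": s.intercept,
                }
                for s in self.subjects
            ]
        )


def _nominal_lengths(spec: SyntheticCohortSpec) -> np.ndarray:
    """Atlas tract lengths: an even spread over the nominal span. The atlas
    layout is shared by all subjects; subject-level variation comes from the
    length jitter."""
    return np.linspace(
        spec.nominal_length_min_mm, spec.nominal_length_max_mm, spec.n_tracts_atlas
    )


def _subject_truth(spec: SyntheticCohortSpec, rng: np.random.Generator,
                   subject_id: str) -> SubjectTruth:
    c = float(np.clip(rng.normal(spec.inflection_mean_mm, spec.inflection_sd_mm),
                      60.0, 150.0))
    b = float(max(rng.normal(spec.slope_mean, spec.slope_sd), 5e-4))
    plateau = float(rng.normal(spec.plateau_mean, spec.plateau_sd))
    return SubjectTruth(subject_id, c, b, plateau, plateau - b * c)


def simulate_subject(
    spec: SyntheticCohortSpec, subject_index: int
) -> tuple[SubjectTractTable, SubjectTruth]:
    """Simulate one subject's tract table; reproducible given
    (spec.seed, subject_index)."""
    if not 0 <= subject_index:
        raise ValueError("subject_index must be nonnegative")
    rng = np.random.default_rng([int(spec.seed), int(subject_index)])
    subject_id = f"sub-{subject_index:03d}"
    truth = _subject_truth(spec, rng, subject_id)

    nominal = _nominal_lengths(spec)
    chosen = np.sort(
        rng.choice(spec.n_tracts_atlas, size=spec.tracts_per_subject, replace=False)
    )
    lengths = nominal[chosen] + rng.normal(0.0, spec.length_jitter_sd_mm, chosen.size)
    lengths = np.maximum(lengths, 1.0)

    if spec.curve == "blackman":
        params = ModelParams("blackman", truth.intercept, truth.slope,
                             truth.inflection_mm)
        clean = np.asarray(eval_model(params, lengths))
    else:
        # specimen mean curve with the subject's plateau as asymptote
        tp = TheoreticalProfileParams(
            specimen_asymptote=min(truth.plateau, 0.999),
            ramp_rate=4.0 * truth.slope,  # mean-curve initial slope is s/4
        )
        clean = np.asarray(specimen_mean(tp, lengths))

    if spec.noise_sd > 0:
        if spec.noise == "gaussian":
            noise = rng.normal(0.0, spec.noise_sd, lengths.size)
        else:
            noise = rng.laplace(0.0, spec.noise_sd / np.sqrt(2.0), lengths.size)
    else:
        noise = np.zeros(lengths.size)
    metric = clean + noise
    if spec.metric_name.lower() == "fa":
        metric = np.clip(metric, 0.0, 1.0)

    table = SubjectTractTable(
        subject_id=subject_id,
        tract_ids=[f"tract-{j:03d}" for j in chosen],
        lengths_mm=lengths,
        metrics=metric,
        metric_name=spec.metric_name,
    )
    return table, truth


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[SubjectTractTable], CohortGroundTruth]:
    """Simulate the full cohort plus its ground-truth record."""
    tables, truths = [], []
    for i in range(spec.n_subjects):
        t, g = simulate_subject(spec, i)
        tables.append(t)
        truths.append(g)
    return tables, CohortGroundTruth(spec, _nominal_lengths(spec), truths)


def cohort_to_frame(tables: list[SubjectTractTable]) -> pd.DataFrame:
    """Long-format frame (one row per subject x tract) for the cohort."""
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def per_tract_tables(
    tables: list[SubjectTractTable], min_subjects: int = 3
) -> dict[str, SubjectTractTable]:
    """Regroup a cohort by tract: one across-subject table per tract label.

    Used to contrast per-tract with per-subject modelling — per-tract length
    ranges are typically too narrow to characterise the length-metric curve.
    The returned tables reuse the SubjectTractTable container with the tract
    label in the subject slot and subject labels in the tract slot.
    """
    frame = cohort_to_frame(tables)
    metric = tables[0].metric_name
    out: dict[str, SubjectTractTable] = {}
    for tract_id, grp in frame.groupby("tract_id", sort=True):
        if len(grp) < min_subjects or grp["length_mm"].nunique() < 2:
            # a tract whose length never varies across subjects cannot
            # characterise the length-metric relationship
            continue
        out[str(tract_id)] = SubjectTractTable(
            subject_id=str(tract_id),
            tract_ids=[str(s) for s in grp["subject_id"]],
            lengths_mm=grp["length_mm"].to_numpy(),
            metrics=grp[metric].to_numpy(),
            metric_name=metric,
        )
    return out


def length_range_summary(tables: list[SubjectTractTable]) -> dict[str, float]:
    """Mean within-subject length range and mean per-tract across-subject
    length range (mm) — the two geometry statistics that motivate modelling
    per subject rather than per tract."""
    within = float(np.mean([t.lengths_mm.max() - t.lengths_mm.min() for t in tables]))
    per_tract = per_tract_tables(tables, min_subjects=2)
    across = float(
        np.mean([t.lengths_mm.max() - t.lengths_mm.min() for t in per_tract.values()])
    )
    return {"mean_within_subject_range_mm": within,
            "mean_per_tract_range_mm": across}
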