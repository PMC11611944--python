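"""In-memory containers for per-subject tract observations.

The canonical unit of analysis is one subject's table of tracts, each tract
contributing a single (mean streamline length, tract-averaged metric) pair.
Tracts whose streamlines were not resolved are simply absent — they are never
zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import SchemaError

__all__ = ["TractObservation", "SubjectTractTable"]

#: metric column names validated against the [0, 1] range of fractional
#: anisotropy (case-insensitive match)
FA_LIKE_NAMES = frozenset({"fa", "fractional_anisotropy"})


@dataclass(frozen=True)
class TractObservation:
    """One tract's observation for one subject.

    Parameters
    ----------
    subject_id, tract_id
        Opaque labels (e.g. ``"sub-07"``, ``"L_CMA-L_PMd"``).
    length_mm
        Mean streamline length of the tract, in millimetres. Must be > 0.
    metric
        Tract-averaged metric value (FA, AFD, RD, MD ...). FA is
        dimensionless in [0, 1]; diffusivities are nonnegative.
    n_streamlines
        Optional streamline count for the tract.
    """

    subject_id: str
    tract_id: str
    length_mm: float
    metric: float
    n_streamlines: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.length_mm) or self.length_mm <= 0:
            raise ValueError(
                f"length_mm must be positive and finite, got {self.length_mm!r} "
                f"({self.subject_id}/{self.tract_id})"
            )
        if not np.isfinite(self.metric):
            raise ValueError(
                f"metric must be finite, got {self.metric!r} "
                f"({self.subject_id}/{self.tract_id})"
            )
        if self.n_streamlines is not None and self.n_streamlines < 0:
            raise ValueError("n_streamlines must be nonnegative")


@dataclass
class SubjectTractTable:
    """All tract observations for one subject and one metric.

    Arrays are aligned: ``lengths_mm[i]`` and ``metrics[i]`` belong to
    ``tract_ids[i]``. Order is preserved as given.
    """

    subject_id: str
    tract_ids: list[str]
    lengths_mm: np.ndarray
    metrics: np.ndarray
    metric_name: str = "FA"
    n_streamlines: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        self.metrics = np.asarray(self.metrics, dtype=float)
        n = len(self.tract_ids)
        if self.lengths_mm.shape != (n,) or self.metrics.shape != (n,):
            raise SchemaError(
                f"misaligned table for subject {self.subject_id!r}: "
                f"{n} tracts vs {self.lengths_mm.shape} lengths / "
                f"{self.metrics.shape} metrics"
            )
        if len(set(self.tract_ids)) != n:
            dupes = {t for t in self.tract_ids if self.tract_ids.count(t) > 1}
            raise SchemaError(
                f"duplicate tract rows for subject {self.subject_id!r}: {sorted(dupes)}"
            )
        if np.any(~np.isfinite(self.lengths_mm)) or np.any(self.lengths_mm <= 0):
            raise ValueError(f"nonpositive or nonfinite length for {self.subject_id!r}")
        if np.any(~np.isfinite(self.metrics)):
            raise ValueError(f"nonfinite metric for {self.subject_id!r}")
        if self.metric_name.lower() in FA_LIKE_NAMES and (
            self.metrics.min() < 0 or self.metrics.max() > 1
        ):
            raise ValueError(
                f"{self.metric_name} values outside [0, 1] for {self.subject_id!r}"
            )
        if self.n_distinct_lengths < 2:
            raise ValueError(
                f"subject {self.subject_id!r} needs >= 2 distinct streamline lengths"
            )

    @property
    def n(self) -> int:
        return len(self.tract_ids)

    @property
    def n_distinct_lengths(self) -> int:
        return np.unique(self.lengths_mm).size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "tract_id": self.tract_ids,
                "length_mm": self.lengths_mm,
                self.metric_name: self.metrics,
            }
        )
        if self.n_streamlines is not None:
            df["n_streamlines"] = self.n_streamlines
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric_name: str = "FA") -> "SubjectTractTable":
        """Build a table from a single-subject long-format frame."""
        subjects = df["subject_id"].unique()
        if len(subjects) != 1:
            raise SchemaError(f"expected one subject, got {list(subjects)}")
        kwargs = {}
        if "n_streamlines" in df.columns:
            kwargs["n_streamlines"] = df["n_streamlines"].to_numpy()
        return cls(
            subject_id=str(subjects[0]),
            tract_ids=[str(t) for t in df["tract_id"]],
            lengths_mm=df["length_mm"].to_numpy(dtype=float),
            metrics=df[metric_name].to_numpy(dtype=float),
            metric_name=metric_name,
            **kwargs,
        )
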