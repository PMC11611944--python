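"""AICc-based multimodel averaging and the length-adjusted metric.

Per subject, the three candidate fits are combined through Akaike weights
computed from AICc differences. The averaged prediction at each observed
length is the weight-convex combination of the candidates' predictions. The
two breakpoint models additionally yield an averaged inflection point and the
metric value there (weights rescaled to exclude the linear model, which
carries no inflection); that value v̄ is the subject-specific reference the
adjustment is anchored to:

    residual_t = observed_t − averaged_fitted_t
    adjusted_t = v̄ + residual_t

Adjusted values preserve the within-subject rank order of the residuals and,
by construction, carry no remaining dependence on streamline length beyond
what the averaged model failed to capture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import DegenerateWeightsError, NoValidModelError
from .data import SubjectTractTable
from .models import CandidateFit, eval_model, _laplace_aicc

__all__ = [
    "AveragedModel",
    "AdjustedTable",
    "aicc",
    "akaike_weights",
    "average_predictions",
    "average_breakpoint_params",
    "average_subject",
    "residuals_and_adjust",
    "predict_on_grid",
]

_MODEL_ORDER = ("linear", "blackman", "piecewise")


@dataclass(frozen=True)
class AveragedModel:
    """Per-subject model-averaged fit.

    ``weights`` follows the candidate order (linear, blackman, piecewise) and
    sums to 1; ``rescaled_weights`` is the (blackman, piecewise) pair rescaled
    to sum to 1 for averaging the inflection-point parameters.
    """

    weights: tuple[float, float, float]
    rescaled_weights: tuple[float, float]
    averaged_fitted: np.ndarray
    inflection_mm: float
    value_at_inflection: float
    slope1_avg: float
    slope2_avg: float


@dataclass(frozen=True)
class AdjustedTable:
    """Residuals and length-adjusted metric values for one subject."""

    subject_id: str
    tract_ids: list[str]
    lengths_mm: np.ndarray
    observed: np.ndarray
    residuals: np.ndarray
    adjusted: np.ndarray
    reference_value: float  # v̄, the averaged metric at the inflection point


def aicc(sum_abs_resid: float, n: int, k: int) -> float:
    """Small-sample-corrected Akaike information criterion for a median fit.

    The L1 objective is the negative profile log-likelihood of a Laplace
    error model up to constants: with scale MLE b̂ = SAR/n the log-likelihood
    is −n(ln(2 b̂) + 1), AIC = 2k − 2 loglik and
    AICc = AIC + 2k(k+1)/(n − k − 1).

    A perfect fit (SAR = 0) returns −inf (the model takes all the weight
    unless another model also fits perfectly); n − k − 1 < 1 returns +inf
    with a warning (model excluded from averaging).
    """
    out = _laplace_aicc(sum_abs_resid, n, k)
    if math.isinf(out) and out > 0:
        warnings.warn(
            f"AICc undefined for n={n}, k={k} (n-k-1 < 1); model excluded",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def akaike_weights(aiccs) -> np.ndarray:
    """Akaike weights w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2), Δ_i = AICc_i − min.

    Weights lie in [0, 1] and sum to 1. −inf entries signal perfect fits and
    split the whole weight equally among themselves; +inf entries (excluded
    models) receive weight 0.
    """
    a = np.asarray(aiccs, dtype=float)
    if np.any(np.isnan(a)):
        raise ValueError("AICc values must not be NaN")
    w = np.zeros_like(a)
    perfect = np.isneginf(a)
    if perfect.any():
        w[perfect] = 1.0 / perfect.sum()
        return w
    finite = np.isfinite(a)
    if not finite.any():
        raise NoValidModelError("all candidate models excluded (AICc infinite)")
    delta = a[finite] - a[finite].min()
    ew = np.exp(-delta / 2.0)
    w[finite] = ew / ew.sum()
    return w


def average_predictions(fits: list[CandidateFit], weights) -> np.ndarray:
    """Pointwise convex combination of candidate predictions.

    All fits must share the same observation order; the result lies within
    the candidates' pointwise [min, max] envelope.
    """
    weights = np.asarray(weights, dtype=float)
    if len(fits) != weights.size:
        raise ValueError("one weight per candidate fit required")
    ref = fits[0].lengths_mm
    for f in fits[1:]:
        if f.lengths_mm.shape != ref.shape or not np.array_equal(f.lengths_mm, ref):
            raise ValueError("candidate fits are not aligned on the same lengths")
    return np.sum([w * f.fitted for w, f in zip(weights, fits)], axis=0)


def average_breakpoint_params(
    blackman: CandidateFit, piecewise: CandidateFit, weights
) -> tuple[float, float, float, float, tuple[float, float]]:
    """Model-averaged inflection point and associated parameters.

    ``weights`` is the full (linear, blackman, piecewise) triple; the
    blackman/piecewise pair is rescaled to sum to 1. The averaged value at
    the inflection, v̄, averages each model's value at its *own* inflection.

    Returns (c̄, v̄, slope1_avg, slope2_avg, rescaled (w'_B, w'_P)).
    """
    _, w_b, w_p = (float(w) for w in weights)
    tot = w_b + w_p
    if tot <= 0.0:
        raise DegenerateWeightsError(
            "breakpoint models carry zero weight; no inflection point defined"
        )
    wb, wp = w_b / tot, w_p / tot
    c_b = blackman.params.breakpoint
    c_p = piecewise.params.breakpoint
    c_bar = wb * c_b + wp * c_p
    v_bar = wb * eval_model(blackman.params, c_b) + wp * eval_model(
        piecewise.params, c_p
    )
    slope1 = wb * blackman.params.slope1 + wp * piecewise.params.slope1
    slope2 = wp * (piecewise.params.slope2 or 0.0)
    return float(c_bar), float(v_bar), float(slope1), float(slope2), (wb, wp)


def average_subject(fits: dict[str, CandidateFit]) -> AveragedModel:
    """Combine a subject's three candidate fits into an AveragedModel."""
    ordered = [fits[k] for k in _MODEL_ORDER]
    w = akaike_weights([f.aicc for f in ordered])
    avg_fitted = average_predictions(ordered, w)
    c_bar, v_bar, s1, s2, (wb, wp) = average_breakpoint_params(
        fits["blackman"], fits["piecewise"], w
    )
    return AveragedModel(
        weights=(float(w[0]), float(w[1]), float(w[2])),
        rescaled_weights=(wb, wp),
        averaged_fitted=avg_fitted,
        inflection_mm=c_bar,
        value_at_inflection=v_bar,
        slope1_avg=s1,
        slope2_avg=s2,
    )


def residuals_and_adjust(
    table: SubjectTractTable, averaged: AveragedModel
) -> AdjustedTable:
    """Residuals from the averaged fit and length-adjusted metric values.

    observed = averaged_fitted + residual exactly; adjusted − residual is the
    constant v̄ within the subject.
    """
    if averaged.averaged_fitted.shape != table.metrics.shape:
        raise ValueError("averaged fit is not aligned with the table")
    residuals = table.metrics - averaged.averaged_fitted
    adjusted = averaged.value_at_inflection + residuals
    return AdjustedTable(
        subject_id=table.subject_id,
        tract_ids=list(table.tract_ids),
        lengths_mm=table.lengths_mm.copy(),
        observed=table.metrics.copy(),
        residuals=residuals,
        adjusted=adjusted,
        reference_value=averaged.value_at_inflection,
    )


def predict_on_grid(
    fits: dict[str, CandidateFit], weights, lengths_mm
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-average predictions at nominal lengths (e.g. a 1 mm grid).

    Predictions outside the subject's observed length range are computed but
    flagged: returns (predictions, extrapolated mask) and emits a warning
    when any grid point extrapolates.
    """
    grid = np.asarray(lengths_mm, dtype=float)
    if grid.size == 0:
        raise ValueError("empty prediction grid")
    weights = np.asarray(weights, dtype=float)
    ordered = [fits[k] for k in _MODEL_ORDER]
    preds = np.sum(
        [w * np.asarray(eval_model(f.params, grid)) for w, f in zip(weights, ordered)],
        axis=0,
    )
    obs = ordered[0].lengths_mm
    extrapolated = (grid < obs.min()) | (grid > obs.max())
    if extrapolated.any():
        warnings.warn(
            f"{int(extrapolated.sum())} grid length(s) outside the observed "
            f"range [{obs.min():.1f}, {obs.max():.1f}] mm; predictions flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    return preds, extrapolated
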