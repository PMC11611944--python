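"""Candidate models of metric-vs-length and their median-regression fits.

Three candidate curves describe how a tract-averaged diffusion metric (FA,
AFD, RD, MD) varies with mean streamline length within one subject:

* ``linear``     — y = a + b·l
* ``blackman``   — linear-plateau: y = a + b·min(l, c); flat beyond the
                   breakpoint c by construction
* ``piecewise``  — continuous two-segment line: y = a + b·min(l, c)
                   + d·max(l − c, 0)

All three are fitted by median (tau = 0.5 quantile) regression, i.e. by
minimising the sum of absolute residuals. For a fixed breakpoint the model is
linear in its regressors, so each fit reduces to an exact L1 linear
regression, solved here as a linear program; the breakpoint is profiled over
a grid and refined by golden-section search.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from ._exceptions import InsufficientDataError, InvalidModelError
from .data import SubjectTractTable

__all__ = [
    "ModelParams",
    "CandidateFit",
    "eval_model",
    "l1_objective",
    "fit_linear",
    "fit_blackman",
    "fit_piecewise",
    "fit_all",
    "MODEL_KINDS",
    "K_PARAMS",
]

MODEL_KINDS = ("linear", "blackman", "piecewise")

#: AICc parameter counts: regression parameters + 1 for the Laplace error
#: scale. Penalises complexity in the nesting order linear < blackman <
#: piecewise.
K_PARAMS = {"linear": 3, "blackman": 4, "piecewise": 5}

#: default admissible breakpoint window, as percentiles of observed lengths
DEFAULT_WINDOW = (10.0, 90.0)
#: coarse profiling grid spacing (mm) and golden-section tolerance (mm)
GRID_STEP_MM = 1.0
REFINE_TOL_MM = 0.01

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one candidate curve.

    ``breakpoint`` (mm) and ``slope2`` are ``None`` for the linear model;
    ``slope2`` is identically 0 for the blackman model.
    """

    kind: str
    intercept: float
    slope1: float
    breakpoint: float | None = None
    slope2: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise InvalidModelError(f"unknown model kind {self.kind!r}")
        if self.kind != "linear" and self.breakpoint is None:
            raise InvalidModelError(f"{self.kind} model requires a breakpoint")
        if self.kind == "blackman" and self.slope2 not in (None, 0.0):
            raise InvalidModelError("blackman second slope is 0 by construction")


@dataclass(frozen=True)
class CandidateFit:
    """One fitted candidate model for one subject.

    ``fitted`` is aligned with the observation order of the table the model
    was fitted to; ``lengths_mm`` is retained for alignment checks and grid
    prediction. ``aicc`` is −inf for a perfect (zero-residual) fit and +inf
    when n − k − 1 < 1 (model excluded from averaging).
    """

    params: ModelParams
    lengths_mm: np.ndarray
    fitted: np.ndarray
    sum_abs_resid: float
    n: int
    k: int
    aicc: float


def eval_model(params: ModelParams, length) -> np.ndarray | float:
    """Evaluate a candidate curve at one or more lengths (mm).

    Continuous in length at the breakpoint for blackman/piecewise.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be positive")
    a, b = params.intercept, params.slope1
    if params.kind == "linear":
        out = a + b * length
    elif params.kind == "blackman":
        out = a + b * np.minimum(length, params.breakpoint)
    elif params.kind == "piecewise":
        d = 0.0 if params.slope2 is None else params.slope2
        out = (
            a
            + b * np.minimum(length, params.breakpoint)
            + d * np.maximum(length - params.breakpoint, 0.0)
        )
    else:  # pragma: no cover - guarded in ModelParams
        raise InvalidModelError(f"unknown model kind {params.kind!r}")
    return out if out.ndim else float(out)


def l1_objective(observed, fitted) -> float:
    """Sum of absolute residuals, Σ|observed_i − fitted_i|.

    The check loss of quantile regression at tau = 0.5 is half this quantity;
    minimisers coincide.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError(f"shape mismatch: {observed.shape} vs {fitted.shape}")
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(fitted))):
        raise ValueError("l1_objective requires finite inputs")
    return float(np.abs(observed - fitted).sum())


def _l1_regression(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact L1 (least absolute deviations) linear regression.

    Minimise Σ|y − Xβ| over β, as the LP
        min Σt  s.t.  Xβ − t ≤ y,  −Xβ − t ≤ −y,  t ≥ 0
    with β free. Returns (β, objective).
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.ones(n)])
    A_ub = np.block([[X, -np.eye(n)], [-X, -np.eye(n)]])
    b_ub = np.concatenate([y, -y])
    bounds = [(None, None)] * p + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"L1 regression LP failed: {res.message}")
    return res.x[:p], float(res.fun)


def _laplace_aicc(sum_abs_resid: float, n: int, k: int) -> float:
    """AICc under the Laplace error model at the MLE scale b̂ = SAR/n.

    log-likelihood = −n(ln(2 b̂) + 1); AIC = 2k − 2 loglik;
    AICc = AIC + 2k(k+1)/(n − k − 1).

    Returns −inf for a perfect fit and +inf when the small-sample correction
    is undefined (n − k − 1 < 1).
    """
    if sum_abs_resid < 0:
        raise ValueError("sum of absolute residuals must be nonnegative")
    if n - k - 1 < 1:
        return math.inf
    if sum_abs_resid == 0.0:
        return -math.inf
    b_hat = sum_abs_resid / n
    loglik = -n * (math.log(2.0 * b_hat) + 1.0)
    aic = 2.0 * k - 2.0 * loglik
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _make_fit(kind: str, beta, table: SubjectTractTable, objective: float) -> CandidateFit:
    if kind == "linear":
        params = ModelParams("linear", float(beta[0]), float(beta[1]))
    elif kind == "blackman":
        params = ModelParams("blackman", float(beta[0]), float(beta[1]), float(beta[2]))
    else:
        params = ModelParams(
            "piecewise", float(beta[0]), float(beta[1]), float(beta[2]), float(beta[3])
        )
    fitted = np.asarray(eval_model(params, table.lengths_mm))
    sar = l1_objective(table.metrics, fitted)
    # trust the LP objective; re-evaluation can differ at float epsilon
    sar = min(sar, objective) if abs(sar - objective) < 1e-7 else sar
    k = K_PARAMS[kind]
    return CandidateFit(
        params=params,
        lengths_mm=table.lengths_mm.copy(),
        fitted=fitted,
        sum_abs_resid=sar,
        n=table.n,
        k=k,
        aicc=_laplace_aicc(sar, table.n, k),
    )


def fit_linear(table: SubjectTractTable) -> CandidateFit:
    """L1-optimal (median regression) straight line."""
    if table.n < 3:
        raise InsufficientDataError(
            f"linear fit needs >= 3 observations, got {table.n}"
        )
    X = np.column_stack([np.ones(table.n), table.lengths_mm])
    beta, obj = _l1_regression(X, table.metrics)
    return _make_fit("linear", beta, table, obj)


def _breakpoint_window(
    kind: str, lengths: np.ndarray, window_pct: tuple[float, float]
) -> tuple[float, float]:
    """Admissible breakpoint interval.

    The percentile window is clipped so that at least two observations
    inform each segment at the window edges and neither segment can
    degenerate to a single point. For the blackman model the upper edge may
    reach the largest length (an empty plateau just reproduces the line);
    the piecewise second slope additionally needs a point beyond the
    breakpoint, so its window stops at the 2nd-largest length.
    """
    lo_p, hi_p = np.percentile(lengths, window_pct)
    s = np.sort(lengths)
    lo = max(float(lo_p), float(s[1]))
    hi = min(float(hi_p), float(s[-1] if kind == "blackman" else s[-2]))
    if not hi > lo:
        raise InsufficientDataError(
            f"empty breakpoint window [{lo:.3f}, {hi:.3f}] mm"
        )
    return lo, hi


def _design(kind: str, lengths: np.ndarray, c: float) -> np.ndarray:
    cols = [np.ones(lengths.size), np.minimum(lengths, c)]
    if kind == "piecewise":
        cols.append(np.maximum(lengths - c, 0.0))
    return np.column_stack(cols)


def _profiled(kind: str, table: SubjectTractTable, c: float):
    beta, obj = _l1_regression(_design(kind, table.lengths_mm, c), table.metrics)
    return obj, beta


def _profile_breakpoint(
    kind: str,
    table: SubjectTractTable,
    window_pct: tuple[float, float],
    grid_step: float,
    refine_tol: float,
) -> tuple[float, np.ndarray, float]:
    """Grid-then-golden-section minimisation of the profiled L1 objective.

    Ties break to the smallest breakpoint.
    """
    lo, hi = _breakpoint_window(kind, table.lengths_mm, window_pct)
    grid = np.arange(lo, hi, grid_step)
    grid = np.append(grid, hi)

    cache: dict[float, tuple[float, np.ndarray]] = {}

    def g(c: float) -> float:
        if c not in cache:
            cache[c] = _profiled(kind, table, c)
        return cache[c][0]

    objs = np.array([g(float(c)) for c in grid])
    i = int(np.argmin(objs + 1e-12 * np.arange(grid.size)))  # smallest-c tie-break
    best_c, best_obj = float(grid[i]), float(objs[i])

    # golden-section refinement in the bracket around the best grid point
    a = float(grid[max(i - 1, 0)])
    b = float(grid[min(i + 1, grid.size - 1)])
    while b - a > refine_tol:
        x1 = b - _INVPHI * (b - a)
        x2 = a + _INVPHI * (b - a)
        if g(x1) <= g(x2):
            b = x2
        else:
            a = x1
    for c in (a, (a + b) / 2.0, b):
        obj = g(float(c))
        if obj < best_obj - 1e-12 or (abs(obj - best_obj) <= 1e-12 and c < best_c):
            best_c, best_obj = float(c), obj
    return best_c, cache[best_c][1], best_obj


def fit_blackman(
    table: SubjectTractTable,
    window_pct: tuple[float, float] = DEFAULT_WINDOW,
    grid_step: float = GRID_STEP_MM,
    refine_tol: float = REFINE_TOL_MM,
) -> CandidateFit:
    """Linear-plateau (Blackman) fit by profiled L1 regression.

    The breakpoint is searched on a coarse grid over the admissible window
    and refined by golden section; the initial slope is not sign-constrained.
    """
    if table.n < 4:
        raise InsufficientDataError(
            f"blackman fit needs >= 4 observations, got {table.n}"
        )
    c, beta, obj = _profile_breakpoint(
        "blackman", table, window_pct, grid_step, refine_tol
    )
    return _make_fit("blackman", [beta[0], beta[1], c], table, obj)


def fit_piecewise(
    table: SubjectTractTable,
    window_pct: tuple[float, float] = DEFAULT_WINDOW,
    grid_step: float = GRID_STEP_MM,
    refine_tol: float = REFINE_TOL_MM,
) -> CandidateFit:
    """Continuous two-segment piecewise-linear fit by profiled L1 regression."""
    if table.n < 5:
        raise InsufficientDataError(
            f"piecewise fit needs >= 5 observations, got {table.n}"
        )
    c, beta, obj = _profile_breakpoint(
        "piecewise", table, window_pct, grid_step, refine_tol
    )
    return _make_fit("piecewise", [beta[0], beta[1], c, beta[2]], table, obj)


def fit_all(
    table: SubjectTractTable,
    window_pct: tuple[float, float] = DEFAULT_WINDOW,
    grid_step: float = GRID_STEP_MM,
    refine_tol: float = REFINE_TOL_MM,
) -> dict[str, CandidateFit]:
    """Fit all three candidate models to one subject's table.

    Enforces the nesting invariant numerically: the piecewise optimum cannot
    exceed the blackman optimum, so if independent breakpoint refinement
    leaves it slightly above, the piecewise model is re-profiled at the
    blackman breakpoint and the better fit kept.
    """
    fits = {
        "linear": fit_linear(table),
        "blackman": fit_blackman(table, window_pct, grid_step, refine_tol),
        "piecewise": fit_piecewise(table, window_pct, grid_step, refine_tol),
    }
    bm, pw = fits["blackman"], fits["piecewise"]
    if pw.sum_abs_resid > bm.sum_abs_resid:
        c = bm.params.breakpoint
        obj, beta = _profiled("piecewise", table, c)
        if obj < pw.sum_abs_resid:
            fits["piecewise"] = _make_fit(
                "piecewise", [beta[0], beta[1], c, beta[2]], table, obj
            )
        if fits["piecewise"].sum_abs_resid > bm.sum_abs_resid + 1e-9:
            warnings.warn(
                f"nesting violated for subject {table.subject_id!r}: "
                "piecewise objective above blackman after re-profiling",
                RuntimeWarning,
                stacklevel=2,
            )
    return fits
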