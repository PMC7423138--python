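"""Sparse canonical correlation analysis by alternating L1-constrained updates.

The estimator maximizes u' X' Y v subject to ||u||_2 <= 1, ||v||_2 <= 1,
||u||_1 <= c1, ||v||_1 <= c2, i.e. the penalized-matrix-decomposition form of
sparse CCA in which the within-set covariance matrices are approximated by
the identity. That diagonal approximation is the standard treatment when the
feature count exceeds the subject count (X' X is singular) and makes each
alternating update an exactly solvable problem: the constrained maximizer of
a linear function is an elementwise soft-threshold of X' Y v (resp. Y' X u),
rescaled to unit L2 norm, with the threshold found by bisection as the
smallest value meeting the L1 budget.

Loadings are sign-fixed (largest-|u| entry positive, v following so the
objective stays nonnegative) because canonical directions are only defined
up to a joint sign flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "PenaltyPair",
    "ColumnScaler",
    "SccaSolution",
    "standardize_columns",
    "scca_fit",
    "canonical_correlation",
]

#: entries below this fraction of the largest loading magnitude are snapped
#: to exact zero, so "selected feature" is a crisp notion
PRUNE_REL = 1e-12
N_BISECT = 60


@dataclass(frozen=True)
class PenaltyPair:
    """L1 budgets (c1 for u over regions, c2 for v over questions).

    Budgets below 1 are rejected: with the unit-L2 scale constraint the
    feasible set collapses (even a single unit coordinate has L1 norm 1).
    Budgets at sqrt(dim) or above leave the L1 constraint inactive.
    """

    c1: float
    c2: float

    def __post_init__(self):
        if self.c1 < 1 or self.c2 < 1:
            raise ConfigError(f"penalty budgets must be >= 1, got c1={self.c1}, c2={self.c2}")


@dataclass(frozen=True)
class ColumnScaler:
    """Column means/scales learned on training data, applicable to held-out data."""

    mean_: np.ndarray
    scale_: np.ndarray
    kept_: np.ndarray  # boolean mask over original columns
    columns_: list | None = None

    @property
    def n_dropped(self) -> int:
        return int((~self.kept_).sum())

    def transform(self, M) -> np.ndarray:
        M = _as_array(M)
        if M.shape[1] != self.kept_.size:
            raise DataError(
                f"matrix has {M.shape[1]} columns, scaler was fit on {self.kept_.size}"
            )
        return (M[:, self.kept_] - self.mean_) / self.scale_

    def expand(self, loading: np.ndarray) -> np.ndarray:
        """Map a loading vector over kept columns back to the original columns."""
        full = np.zeros(self.kept_.size)
        full[self.kept_] = loading
        return full


@dataclass
class SccaSolution:
    """Fitted sparse canonical pair.

    ``u`` and ``v`` live on the original (pre-drop) feature axes; dropped
    constant columns carry zero loading. ``delta_u`` / ``delta_v`` are the
    final soft-threshold levels, i.e. the implied Lagrange weights of the
    penalty-form objective.
    """

    u: np.ndarray
    v: np.ndarray
    rho: float
    objective_trace: list[float]
    n_iter: int
    converged: bool
    penalties: PenaltyPair
    delta_u: float = 0.0
    delta_v: float = 0.0
    region_ids: list | None = None
    question_ids: list | None = None

    @property
    def selected_regions(self) -> np.ndarray:
        return np.flatnonzero(self.u)

    @property
    def selected_questions(self) -> np.ndarray:
        return np.flatnonzero(self.v)

    def selected_region_ids(self) -> list:
        idx = self.selected_regions
        return [self.region_ids[i] for i in idx] if self.region_ids is not None else list(idx)

    def selected_question_ids(self) -> list:
        idx = self.selected_questions
        return [self.question_ids[i] for i in idx] if self.question_ids is not None else list(idx)


def _as_array(M) -> np.ndarray:
    # C-contiguous materialization: BLAS kernel choice depends on memory
    # layout, and the determinism contract requires bit-identical results
    # whether a table arrived from memory or from a parsed file
    if isinstance(M, pd.DataFrame):
        return np.ascontiguousarray(M.to_numpy(dtype=float))
    return np.ascontiguousarray(np.asarray(M, dtype=float))


def standardize_columns(M, drop_constant: bool = False) -> tuple[np.ndarray, ColumnScaler]:
    """Center each column and scale it to unit sample variance (ddof=1).

    Constant columns are dropped with a warning when ``drop_constant`` is
    set, and rejected otherwise. Returns the standardized matrix over kept
    columns and the :class:`ColumnScaler` holding the fitted parameters.
    """
    columns = list(M.columns) if isinstance(M, pd.DataFrame) else None
    A = _as_array(M)
    if A.ndim != 2:
        raise DataError("expected a 2-D subject x feature matrix")
    if np.isnan(A).any():
        raise DataError("NaN values in input matrix")
    sd = A.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.all():
        raise DataError("all columns are constant; nothing to standardize")
    if constant.any():
        if not drop_constant:
            bad = np.flatnonzero(constant).tolist()
            raise DataError(f"constant columns at indices {bad} (set drop_constant to drop them)")
        warnings.warn(f"dropping {int(constant.sum())} constant column(s)", stacklevel=2)
    kept = ~constant
    scaler = ColumnScaler(
        mean_=A[:, kept].mean(axis=0), scale_=sd[kept], kept_=kept, columns_=columns
    )
    return scaler.transform(A), scaler


def _l1_constrained_direction(a: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    """argmax_u a'u  s.t. ||u||_2 <= 1, ||u||_1 <= c.

    The maximizer is soft(a, delta) / ||soft(a, delta)||_2 with delta the
    smallest soft-threshold level whose normalized result meets the L1
    budget; delta is located by bisection on [0, max|a|]. Returns the
    direction and the threshold level used (the implied Lagrange weight).
    """
    a = np.asarray(a, dtype=float)
    abs_a = np.abs(a)
    amax = abs_a.max()
    if amax == 0:
        return np.zeros_like(a), 0.0

    # the L1/L2 ratio is invariant to the signs, so bisection runs on the
    # nonnegative shrunk magnitudes and signs are applied once at the end
    l2 = np.sqrt(a @ a)
    if abs_a.sum() <= c * l2:
        return _prune(a / l2), 0.0

    lo, hi = 0.0, amax * (1.0 - 1e-12)
    s = np.maximum(abs_a - hi, 0.0)
    l2sq = s @ s
    if l2sq == 0 or s.sum() > c * np.sqrt(l2sq):
        # only possible under exact ties at the maximum; fall back to the
        # hard 1-sparse vertex, always feasible for c >= 1
        best = np.zeros_like(a)
        j = int(np.argmax(abs_a))
        best[j] = np.sign(a[j])
        return best, float(amax)
    best_delta = hi
    for _ in range(N_BISECT):
        mid = (lo + hi) / 2.0
        s = np.maximum(abs_a - mid, 0.0)
        l2sq = s @ s
        if l2sq > 0 and s.sum() <= c * np.sqrt(l2sq):
            best_delta, hi = mid, mid
        else:
            lo = mid
    s = np.maximum(abs_a - best_delta, 0.0)
    u = np.sign(a) * s
    u /= np.sqrt(u @ u)
    return _prune(u), float(best_delta)


def _prune(u: np.ndarray) -> np.ndarray:
    """Snap numerically negligible entries to exact zero and renormalize."""
    mx = np.max(np.abs(u))
    if mx == 0:
        return u
    u = np.where(np.abs(u) < PRUNE_REL * mx, 0.0, u)
    return u / np.linalg.norm(u)


def scca_fit(
    X,
    Y,
    penalties: PenaltyPair,
    max_iter: int = 200,
    tol: float = 1e-6,
    covariance: str = "diagonal",
    cov_alpha: float = 0.1,
    seed=None,
) -> SccaSolution:
    """Fit one sparse canonical pair on standardized X (n x p) and Y (n x q).

    v is initialized at the leading right singular vector of X' Y, so the fit
    is deterministic; ``seed`` is accepted for interface symmetry with the
    data generators and has no effect. ``covariance="regularized"`` replaces
    the unit-L2 scale constraint by u' B u <= 1 with
    B = (1 - cov_alpha) I + cov_alpha (X'X / n), a sensitivity knob for the
    diagonal approximation.
    """
    region_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    question_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = _as_array(X)
    Y = _as_array(Y)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise DataError(f"X {X.shape} and Y {Y.shape} must share the subject axis")
    if X.shape[0] < 4:
        raise DataError("need at least 4 subjects")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise DataError("NaN values in input matrices")
    if covariance not in ("diagonal", "regularized"):
        raise ConfigError(f"unknown covariance mode {covariance!r}")

    M = X.T @ Y
    if covariance == "regularized":
        n = X.shape[0]
        Bx = (1 - cov_alpha) * np.eye(X.shape[1]) + cov_alpha * (X.T @ X) / n
        By = (1 - cov_alpha) * np.eye(Y.shape[1]) + cov_alpha * (Y.T @ Y) / n
    else:
        Bx = By = None

    # deterministic multi-start: the alternating scheme is a coordinate
    # ascent and can stall in a local basin when the L1 budget binds hard,
    # so it is run from five data-derived starting points and the highest
    # objective wins. The leading right singular vector of X'Y is exact in
    # the unpenalized limit; the normalized top rows of X'Y are exact in
    # the 1-sparse limit; the top-column indicators cover basins the other
    # starts miss on strongly anisotropic problems.
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    starts = [Vt[0]]
    row_norms = np.linalg.norm(M, axis=1)
    for j in np.argsort(-row_norms)[:2]:
        if row_norms[j] > 0:
            starts.append(M[j] / row_norms[j])
    col_norms = np.linalg.norm(M, axis=0)
    for k in np.argsort(-col_norms)[:2]:
        e_k = np.zeros(M.shape[1])
        e_k[k] = 1.0
        starts.append(e_k)

    best = None
    for v0 in starts:
        result = _alternate(M, penalties, v0, max_iter, tol, Bx, By)
        if best is None or result[2][-1] > best[2][-1] + 1e-12:
            best = result
    u, v, trace, n_iter, converged, delta_u, delta_v = best

    # sign convention: largest-|u| entry positive; v follows via the objective
    if u.any():
        j = int(np.argmax(np.abs(u)))
        if u[j] < 0:
            u, v = -u, -v
    if u @ M @ v < 0:
        v = -v

    rho = _safe_rho(X @ u, Y @ v)
    return SccaSolution(
        u=u,
        v=v,
        rho=rho,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        penalties=penalties,
        delta_u=delta_u,
        delta_v=delta_v,
        region_ids=region_ids,
        question_ids=question_ids,
    )


def _alternate(M, penalties, v0, max_iter, tol, Bx, By):
    """One run of the alternating L1-constrained updates from start v0."""
    v = v0
    u = np.zeros(M.shape[0])
    delta_u = delta_v = 0.0
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        u_old, v_old = u, v
        u, delta_u = _l1_constrained_direction(M @ v, penalties.c1)
        if Bx is not None:
            u = _b_rescale(u, Bx)
        v, delta_v = _l1_constrained_direction(M.T @ u, penalties.c2)
        if By is not None:
            v = _b_rescale(v, By)
        trace.append(float(u @ M @ v))
        if max(np.max(np.abs(u - u_old)), np.max(np.abs(v - v_old))) < tol:
            converged = True
            break
    return u, v, trace, n_iter, converged, delta_u, delta_v


def _b_rescale(u: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rescale a direction so u' B u = 1 (regularized-covariance scale)."""
    nrm = float(u @ B @ u)
    return u if nrm == 0 else u / np.sqrt(nrm)


def _safe_rho(s: np.ndarray, t: np.ndarray) -> float:
    if s.std() == 0 or t.std() == 0:
        return float("nan")
    return float(np.corrcoef(s, t)[0, 1])


def canonical_correlation(X, Y, u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of the canonical variates X u and Y v."""
    X = _as_array(X)
    Y = _as_array(Y)
    s = X @ np.asarray(u, dtype=float)
    t = Y @ np.asarray(v, dtype=float)
    if s.std() == 0 or t.std() == 0:
        raise DataError("canonical variate has zero variance; correlation undefined")
    return float(np.corrcoef(s, t)[0, 1])
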