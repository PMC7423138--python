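"""Penalty tuning by k-fold cross-validation and bootstrap stability selection.

Cross-validation: subjects are partitioned into k seeded folds; for every
candidate penalty pair the model is fit on the training portion (with
training-only standardization) and scored by the canonical correlation of
the held-out fold's variates. The per-fold best pairs (ties broken toward
the sparser model) are averaged component-wise into the final penalties.

Stability selection: the model is refit at fixed penalties on many random
subject subsamples (80% without replacement by default; an optional flag
switches to classical bootstrap draws with replacement) and each feature is
scored by how often it receives a nonzero loading. The frequently selected
features are compared against the full-data fit's selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .scca import PenaltyPair, SccaSolution, canonical_correlation, scca_fit, standardize_columns

__all__ = [
    "CvReport",
    "BootstrapReport",
    "make_penalty_grid",
    "tune_penalties",
    "fit_full",
    "bootstrap_stability",
]


@dataclass
class CvReport:
    grid: list[PenaltyPair]
    per_fold_best: list[PenaltyPair]
    final_penalties: PenaltyPair
    per_fold_heldout_rho: np.ndarray  # folds x grid
    fold_assignment: np.ndarray       # subject -> fold index
    k_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k_folds": self.k_folds,
            "seed": self.seed,
            "grid": [[g.c1, g.c2] for g in self.grid],
            "per_fold_best": [[g.c1, g.c2] for g in self.per_fold_best],
            "final_penalties": [self.final_penalties.c1, self.final_penalties.c2],
            "per_fold_heldout_rho": self.per_fold_heldout_rho.tolist(),
        }


@dataclass
class BootstrapReport:
    n_boot: int
    frac: float
    n_subsample: int
    with_replacement: bool
    region_freq: np.ndarray
    question_freq: np.ndarray
    region_mean_abs_loading: np.ndarray
    question_mean_abs_loading: np.ndarray
    overlap_regions: dict = field(default_factory=dict)
    overlap_questions: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_boot": self.n_boot,
            "frac": self.frac,
            "n_subsample": self.n_subsample,
            "with_replacement": self.with_replacement,
            "seed": self.seed,
            "region_freq": self.region_freq.tolist(),
            "question_freq": self.question_freq.tolist(),
            "overlap_regions": self.overlap_regions,
            "overlap_questions": self.overlap_questions,
        }


def make_penalty_grid(p: int, q: int, n_c1: int = 12, n_c2: int = 12) -> list[PenaltyPair]:
    """Log-spaced budget grid over [1, sqrt(p)] x [1, sqrt(q)].

    sqrt(dim) is the largest budget at which the L1 constraint can still
    bind under the unit-L2 scale constraint.
    """
    c1s = np.geomspace(1.0, np.sqrt(p), n_c1)
    c2s = np.geomspace(1.0, np.sqrt(q), n_c2)
    grid = [PenaltyPair(float(c1), float(c2)) for c1 in c1s for c2 in c2s]
    # ascending total budget so that argmax tie-breaking prefers sparser models
    grid.sort(key=lambda g: (g.c1 + g.c2, g.c1))
    return grid


def _fold_assignment(n: int, k_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k_folds)):
        assignment[chunk] = fold
    return assignment


def tune_penalties(
    X,
    Y,
    grid: list[PenaltyPair] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    se_rule: float = 0.75,
    **fit_kwargs,
) -> CvReport:
    """Pick L1 budgets by k-fold cross-validated held-out canonical correlation.

    X and Y are raw (unstandardized) subject x feature tables; each training
    fold is standardized on its own rows and the learned means/scales are
    applied to the held-out block, so no held-out information enters the fit.

    Each fold's best penalty pair is the sparsest grid point whose held-out
    correlation comes within ``se_rule`` standard errors of the fold's
    maximum (SE from the Fisher variance of a sample correlation,
    (1 - rho^2) / sqrt(n_test - 3)). The held-out curve is nearly flat past
    the optimal sparsity, so a plain argmax drifts into dense models on
    sampling noise; the parsimony band counters that. ``se_rule=0`` recovers
    the plain argmax (exact ties still resolve to the sparser model).
    """
    import pandas as pd

    n = X.shape[0]
    if k_folds < 2:
        raise ConfigError(f"k_folds must be >= 2, got {k_folds}")
    if n < 2 * k_folds:
        raise DataError(f"need at least {2 * k_folds} subjects for {k_folds}-fold CV, got {n}")
    if grid is None:
        grid = make_penalty_grid(X.shape[1], Y.shape[1])
    if not grid:
        raise ConfigError("empty penalty grid")
    grid = sorted(grid, key=lambda g: (g.c1 + g.c2, g.c1))

    Xa = np.ascontiguousarray(X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X, dtype=float)
    Ya = np.ascontiguousarray(Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else Y, dtype=float)

    assignment = _fold_assignment(n, k_folds, seed)
    heldout = np.full((k_folds, len(grid)), -np.inf)
    per_fold_best: list[PenaltyPair] = []
    for fold in range(k_folds):
        test = assignment == fold
        Xtr, x_scaler = standardize_columns(Xa[~test], drop_constant=True)
        Ytr, y_scaler = standardize_columns(Ya[~test], drop_constant=True)
        Xte = x_scaler.transform(Xa[test])
        Yte = y_scaler.transform(Ya[test])
        for gi, pen in enumerate(grid):
            sol = scca_fit(Xtr, Ytr, pen, **fit_kwargs)
            s, t = Xte @ sol.u, Yte @ sol.v
            if s.std() == 0 or t.std() == 0:
                continue  # degenerate held-out variate stays at -inf
            heldout[fold, gi] = np.corrcoef(s, t)[0, 1]
        best = heldout[fold].max()
        n_test = int(test.sum())
        band = se_rule * (1.0 - best**2) / np.sqrt(max(n_test - 3, 1))
        # grid is sorted by total budget: the first point inside the band is
        # the sparsest acceptable model
        best_gi = next(
            gi for gi in range(len(grid)) if heldout[fold, gi] >= best - band
        )
        per_fold_best.append(grid[best_gi])

    final = PenaltyPair(
        float(np.mean([g.c1 for g in per_fold_best])),
        float(np.mean([g.c2 for g in per_fold_best])),
    )
    return CvReport(
        grid=grid,
        per_fold_best=per_fold_best,
        final_penalties=final,
        per_fold_heldout_rho=heldout,
        fold_assignment=assignment,
        k_folds=k_folds,
        seed=seed,
    )


def fit_full(X, Y, penalties: PenaltyPair, **fit_kwargs) -> SccaSolution:
    """Standardize the full tables and fit at fixed penalties.

    Loadings are mapped back to the original feature axes (dropped constant
    columns carry zero loading) so they are comparable across subsamples.
    """
    import pandas as pd

    region_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    question_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xs, x_scaler = standardize_columns(X, drop_constant=True)
    Ys, y_scaler = standardize_columns(Y, drop_constant=True)
    sol = scca_fit(Xs, Ys, penalties, **fit_kwargs)
    sol.u = x_scaler.expand(sol.u)
    sol.v = y_scaler.expand(sol.v)
    sol.region_ids = region_ids
    sol.question_ids = question_ids
    return sol


def bootstrap_stability(
    X,
    Y,
    penalties: PenaltyPair,
    n_boot: int = 1000,
    frac: float = 0.8,
    seed: int = 0,
    with_replacement: bool = False,
    full_fit: SccaSolution | None = None,
    **fit_kwargs,
) -> BootstrapReport:
    """Selection frequencies over random subject subsamples at fixed penalties.

    Each replicate draws floor(frac * n) subjects (without replacement by
    default), refits, and marks features with nonzero loadings as selected.
    The top-k most frequently selected features (k = the full-data fit's
    selection size, ties broken by larger mean |loading| across replicates)
    are compared with the full-data selection.
    """
    import pandas as pd

    if not (0 < frac < 1):
        raise ConfigError(f"frac must be in (0, 1), got {frac}")
    if n_boot < 1:
        raise ConfigError(f"n_boot must be >= 1, got {n_boot}")
    n = X.shape[0]
    m = int(np.floor(frac * n))
    if m < 4:
        raise DataError(f"subsample size {m} too small (need >= 4 subjects)")

    Xa = np.ascontiguousarray(X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else X, dtype=float)
    Ya = np.ascontiguousarray(Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else Y, dtype=float)
    p, q = Xa.shape[1], Ya.shape[1]

    rng = np.random.default_rng(seed)
    region_counts = np.zeros(p)
    question_counts = np.zeros(q)
    region_absload = np.zeros(p)
    question_absload = np.zeros(q)
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=with_replacement)
        Xs, x_scaler = standardize_columns(Xa[idx], drop_constant=True)
        Ys, y_scaler = standardize_columns(Ya[idx], drop_constant=True)
        sol = scca_fit(Xs, Ys, penalties, **fit_kwargs)
        u = x_scaler.expand(sol.u)
        v = y_scaler.expand(sol.v)
        region_counts += u != 0
        question_counts += v != 0
        region_absload += np.abs(u)
        question_absload += np.abs(v)

    region_freq = region_counts / n_boot
    question_freq = question_counts / n_boot
    region_mean_abs = region_absload / n_boot
    question_mean_abs = question_absload / n_boot

    if full_fit is None:
        full_fit = fit_full(X, Y, penalties, **fit_kwargs)
    overlap_regions = _overlap(full_fit.selected_regions, region_freq, region_mean_abs)
    overlap_questions = _overlap(full_fit.selected_questions, question_freq, question_mean_abs)

    return BootstrapReport(
        n_boot=n_boot,
        frac=frac,
        n_subsample=m,
        with_replacement=with_replacement,
        region_freq=region_freq,
        question_freq=question_freq,
        region_mean_abs_loading=region_mean_abs,
        question_mean_abs_loading=question_mean_abs,
        overlap_regions=overlap_regions,
        overlap_questions=overlap_questions,
        seed=seed,
    )


def _overlap(full_selected: np.ndarray, freq: np.ndarray, mean_abs: np.ndarray) -> dict:
    """Overlap of the full-data selection with the top-k most frequent features."""
    k = int(full_selected.size)
    if k == 0:
        return {"k": 0, "count": 0, "percentage": 0.0, "top_k": []}
    # sort by (frequency desc, mean |loading| desc); lexsort keys are read last-first
    order = np.lexsort((-mean_abs, -freq))
    top_k = order[:k]
    count = int(np.intersect1d(top_k, full_selected).size)
    return {
        "k": k,
        "count": count,
        "percentage": 100.0 * count / k,
        "top_k": np.sort(top_k).tolist(),
    }
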