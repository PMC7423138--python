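"""Synthetic data with planted sparse canonical structure.

The generators here emulate the three inputs of the analysis pipeline:

* a subject x region betweenness-centrality matrix ``X`` whose columns on a
  sparse "support" set carry a shared latent factor,
* a subject x question response matrix ``Y`` (binary 0/1 or ordinal 0-3)
  whose support columns are monotone discretizations of the same latent, and
* per-subject clinical scores with an exactly controlled sample correlation
  to the mean centrality of designated regions.

Because the true loading vectors are known (``PlantedTruth``), recovery of
the planted structure by the sparse CCA pipeline can be measured directly.
Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "PlantedTruth",
    "RoiTimeSeriesPanel",
    "generate_coupled_dataset",
    "generate_roi_timeseries",
    "generate_clinical_scores",
]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted sparse canonical pair.

    ``u_true`` / ``v_true`` are unit-norm loading vectors over all regions /
    questions, zero off the support. ``latent`` is the per-subject latent
    factor z that both sides load on; it is exposed so tests can measure how
    faithfully linear combinations of the generated data track the factor.
    """

    region_support: np.ndarray
    question_support: np.ndarray
    u_true: np.ndarray
    v_true: np.ndarray
    latent_strength: float
    seed: int
    latent: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class RoiTimeSeriesPanel:
    """Per-subject ROI time series, all sharing region count and order.

    ``data`` has shape (subjects, timepoints, regions); each region column is
    zero-mean within subject.
    """

    data: np.ndarray
    subject_ids: list[str]
    region_ids: list[str]

    def __post_init__(self):
        n, t, r = self.data.shape
        if t < 3:
            raise DataError("time series need at least 3 timepoints")
        if len(self.subject_ids) != n or len(self.region_ids) != r:
            raise DataError("id lists do not match panel shape")

    def subject(self, i: int) -> pd.DataFrame:
        return pd.DataFrame(self.data[i], columns=self.region_ids)


def _ids(prefix: str, count: int) -> list[str]:
    width = len(str(count))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(count)]


def _sparse_unit_vector(rng: np.random.Generator, size: int, support: np.ndarray) -> np.ndarray:
    # magnitudes uniform in [0.7, 1] with random signs: every support feature
    # carries comparable signal, so the planted directions stay recoverable
    # even after the monotone discretization of the response side (which
    # compresses loading magnitudes toward equality at strong signal)
    vec = np.zeros(size)
    vals = rng.uniform(0.7, 1.0, size=support.size) * rng.choice([-1.0, 1.0], size=support.size)
    vec[support] = vals / np.linalg.norm(vals)
    return vec


def generate_coupled_dataset(
    n: int,
    p: int,
    q: int,
    k_x: int,
    k_y: int,
    latent_strength: float,
    noise_sd: float,
    response_mode: str = "binary",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate a (centrality, responses, truth) triple with planted coupling.

    A latent factor z_i ~ N(0,1) is drawn per subject. Support columns of X
    equal ``latent_strength * u_j * z`` plus N(0, noise_sd^2) noise;
    off-support columns are pure N(0, noise_sd^2) noise. Support columns of Y
    are the same construction on the question side, discretized by a median
    split (binary 0/1) or quartile binning (ordinal 0-3); off-support
    question columns discretize independent noise.

    Parameters
    ----------
    latent_strength : effect size lambda >= 0 multiplying the latent factor.
    noise_sd : standard deviation of the additive Gaussian noise (>= 0).
    response_mode : "binary" or "ordinal".
    """
    if not (0 < k_x <= p):
        raise ConfigError(f"k_x must satisfy 0 < k_x <= p, got k_x={k_x}, p={p}")
    if not (0 < k_y <= q):
        raise ConfigError(f"k_y must satisfy 0 < k_y <= q, got k_y={k_y}, q={q}")
    if n < 4:
        raise ConfigError(f"need at least 4 subjects, got n={n}")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if latent_strength < 0:
        raise ConfigError("latent_strength must be >= 0")
    if response_mode not in ("binary", "ordinal"):
        raise ConfigError(f"response_mode must be 'binary' or 'ordinal', got {response_mode!r}")

    rng = np.random.default_rng(seed)
    region_support = np.sort(rng.choice(p, size=k_x, replace=False))
    question_support = np.sort(rng.choice(q, size=k_y, replace=False))
    u_true = _sparse_unit_vector(rng, p, region_support)
    v_true = _sparse_unit_vector(rng, q, question_support)

    z = rng.standard_normal(n)
    X = noise_sd * rng.standard_normal((n, p))
    X[:, region_support] += latent_strength * np.outer(z, u_true[region_support])

    latent_Y = noise_sd * rng.standard_normal((n, q))
    latent_Y[:, question_support] += latent_strength * np.outer(z, v_true[question_support])
    Y = _discretize(latent_Y, response_mode)

    subject_ids = _ids("S", n)
    X_df = pd.DataFrame(X, index=pd.Index(subject_ids, name="subject_id"), columns=_ids("R", p))
    Y_df = pd.DataFrame(Y, index=pd.Index(subject_ids, name="subject_id"), columns=_ids("Q", q))
    truth = PlantedTruth(
        region_support=region_support,
        question_support=question_support,
        u_true=u_true,
        v_true=v_true,
        latent_strength=float(latent_strength),
        seed=int(seed),
        latent=z,
    )
    return X_df, Y_df, truth


def _discretize(latent: np.ndarray, mode: str) -> np.ndarray:
    """Column-wise monotone discretization of a continuous latent matrix."""
    out = np.empty(latent.shape, dtype=np.int64)
    for j in range(latent.shape[1]):
        col = latent[:, j]
        if mode == "binary":
            out[:, j] = (col > np.median(col)).astype(np.int64)
        else:  # ordinal: quartile bins -> 0..3
            cuts = np.quantile(col, [0.25, 0.5, 0.75])
            out[:, j] = np.digitize(col, cuts)
    return out


def generate_roi_timeseries(
    n: int,
    r: int,
    t: int,
    n_modules: int,
    within_corr: float,
    seed: int = 0,
) -> RoiTimeSeriesPanel:
    """Generate modular ROI time series with a target within-module correlation.

    Regions are split into ``n_modules`` equal blocks. Regions in a module
    share a latent signal weighted so the expected pairwise correlation inside
    a module equals ``within_corr``; modules are mutually independent. Each
    region column is demeaned within subject.
    """
    if r % n_modules != 0:
        raise ConfigError(f"r={r} not divisible into {n_modules} modules")
    if not (0 <= within_corr < 1):
        raise ConfigError(f"within_corr must be in [0, 1), got {within_corr}")
    if t < 10:
        raise ConfigError(f"need at least 10 timepoints, got t={t}")

    rng = np.random.default_rng(seed)
    block = r // n_modules
    a = np.sqrt(within_corr)          # shared-signal weight: corr of two members = a^2
    b = np.sqrt(1.0 - within_corr)
    data = np.empty((n, t, r))
    for i in range(n):
        signals = rng.standard_normal((t, n_modules))
        noise = rng.standard_normal((t, r))
        shared = np.repeat(signals, block, axis=1)
        ts = a * shared + b * noise
        data[i] = ts - ts.mean(axis=0, keepdims=True)
    return RoiTimeSeriesPanel(data=data, subject_ids=_ids("S", n), region_ids=_ids("R", r))


def generate_clinical_scores(
    X: pd.DataFrame,
    target_regions: list | np.ndarray,
    rho: float,
    seed: int = 0,
    name: str = "score",
) -> pd.Series:
    """Generate a clinical score with exact sample correlation to region centrality.

    The score is ``rho * m_hat + sqrt(1 - rho^2) * e_hat`` where ``m_hat`` is
    the centered, unit-norm mean centrality over ``target_regions`` and
    ``e_hat`` is a centered noise vector orthogonalized against ``m_hat``.
    The sample Pearson correlation with the target-region mean therefore
    equals ``rho`` exactly (up to floating point), not merely in expectation.
    """
    if abs(rho) > 1:
        raise ConfigError(f"|rho| must be <= 1, got {rho}")
    target_regions = list(target_regions)
    if not target_regions:
        raise ConfigError("target_regions must be nonempty")
    missing = [c for c in target_regions if c not in X.columns]
    if missing:
        raise DataError(f"target regions absent from centrality table: {missing}")

    m = X[target_regions].to_numpy().mean(axis=1)
    mc = m - m.mean()
    norm = np.linalg.norm(mc)
    if norm == 0:
        raise DataError("target-region mean centrality is constant; correlation undefined")
    m_hat = mc / norm

    rng = np.random.default_rng(seed)
    g = rng.standard_normal(len(m))
    g = g - g.mean()
    e = g - (g @ m_hat) * m_hat
    e_norm = np.linalg.norm(e)
    if e_norm == 0:  # pragma: no cover - measure-zero draw
        raise DataError("degenerate noise draw; retry with another seed")
    e_hat = e / e_norm
    score = rho * m_hat + np.sqrt(max(0.0, 1.0 - rho * rho)) * e_hat
    return pd.Series(score, index=X.index, name=name)
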