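"""Post-hoc correlation of identified regions with clinical scores.

The analysis proceeds at two levels. Stage 1 averages the centrality of the
selected regions within each behavioral domain (cognition, reward, ...) and
correlates the domain averages with each clinical score (e.g. BMI, WHR),
adjusting p-values by Benjamini-Hochberg FDR within each score's family of
domain tests. Stage 2 follows up each significant (domain, score) pair at
region level, testing that domain's selected regions against that score with
FDR within the family. The gatekeeping rule (only significant domains
proceed to stage 2) can be switched off, and the stage-1 families can be
pooled across scores instead of per-score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = ["domain_average", "pearson_with_p", "fdr_bh", "run_posthoc"]


def domain_average(
    X: pd.DataFrame, selected_regions: list, domain_map: dict[str, str]
) -> pd.DataFrame:
    """Mean centrality of the selected regions per behavioral domain.

    Returns a subject x domain table. Domains in the map that contain no
    selected region are dropped with a warning.
    """
    selected_regions = list(selected_regions)
    missing_cols = [r for r in selected_regions if r not in X.columns]
    if missing_cols:
        raise DataError(f"selected regions absent from centrality table: {missing_cols}")
    unmapped = [r for r in selected_regions if r not in domain_map]
    if unmapped:
        raise DataError(f"selected regions missing from the domain map: {unmapped}")

    by_domain: dict[str, list] = {}
    for r in selected_regions:
        by_domain.setdefault(domain_map[r], []).append(r)
    empty = sorted(set(domain_map.values()) - set(by_domain))
    if empty:
        warnings.warn(f"domains with no selected region dropped: {empty}", stacklevel=2)

    cols = {dom: X[regions].mean(axis=1) for dom, regions in sorted(by_domain.items())}
    return pd.DataFrame(cols, index=X.index)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value (t reference, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DataError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i} (m * p_(j) / j) capped at 1, where p_(1) <= ... <=
    p_(m) are the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("expected a 1-D vector of p-values")
    if np.any(p < 0) or np.any(p > 1) or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def run_posthoc(
    X: pd.DataFrame,
    selected_regions: list,
    domain_map: dict[str, str],
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    gatekeep: bool = True,
    pooled_stage1: bool = False,
) -> pd.DataFrame:
    """Two-level association of selected regions with clinical scores.

    ``clinical`` is a subject x score table sharing X's subject index.
    Returns a tidy report with one row per test: columns level ("domain" or
    "region"), unit, score, r, p_raw, p_fdr, significant.
    """
    if len(clinical) != len(X):
        raise DataError(
            f"clinical table has {len(clinical)} subjects, centrality table {len(X)}"
        )
    domains = domain_average(X, selected_regions, domain_map)

    rows = []
    # stage 1: domain-level, FDR within each score family (or pooled)
    stage1 = []
    for score in clinical.columns:
        for dom in domains.columns:
            r, p = pearson_with_p(domains[dom], clinical[score])
            stage1.append({"level": "domain", "unit": dom, "score": score, "r": r, "p_raw": p})
    if pooled_stage1:
        families = {None: stage1}
    else:
        families = {}
        for row in stage1:
            families.setdefault(row["score"], []).append(row)
    for fam in families.values():
        adj = fdr_bh([row["p_raw"] for row in fam])
        for row, a in zip(fam, adj):
            row["p_fdr"] = float(a)
            row["significant"] = bool(a < alpha)
    rows.extend(stage1)

    # stage 2: region-level follow-up of significant (domain, score) pairs
    by_domain: dict[str, list] = {}
    for r_id in selected_regions:
        by_domain.setdefault(domain_map[r_id], []).append(r_id)
    stage1_pairs = [
        (row["unit"], row["score"]) for row in stage1 if row["significant"] or not gatekeep
    ]
    for dom, score in stage1_pairs:
        fam_rows = []
        for r_id in by_domain[dom]:
            r, p = pearson_with_p(X[r_id], clinical[score])
            fam_rows.append(
                {"level": "region", "unit": r_id, "score": score, "domain": dom,
                 "r": r, "p_raw": p}
            )
        adj = fdr_bh([row["p_raw"] for row in fam_rows])
        for row, a in zip(fam_rows, adj):
            row["p_fdr"] = float(a)
            row["significant"] = bool(a < alpha)
        rows.extend(fam_rows)

    report = pd.DataFrame(rows)
    return report[
        [c for c in ["level", "unit", "domain", "score", "r", "p_raw", "p_fdr", "significant"]
         if c in report.columns]
    ]
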