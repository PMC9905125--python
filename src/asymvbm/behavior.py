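"""Cluster-level brain-behavior and brain-age regressions.

Mean AI within each significant between-group cluster is regressed on a
symptom score (covariates: age, gender, site) or on age (covariates:
gender, site). The reported effect size is the partial correlation derived
from the predictor's t-statistic, r = sign(t) * sqrt(t^2 / (t^2 + df)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import AIMap
from .grf import ClusterResult

__all__ = [
    "ClusterAISeries",
    "extract_cluster_means",
    "partial_correlation",
    "run_brain_behavior",
]


@dataclass
class ClusterAISeries:
    cluster_id: int
    subject_ids: list[str]
    values: np.ndarray  # mean AI within the cluster mask, one per subject


def extract_cluster_means(
    ai_maps: list[AIMap],
    cluster_mask: np.ndarray,
    subject_ids: list[str] | None = None,
    cluster_id: int = 0,
) -> ClusterAISeries:
    """Arithmetic mean of each subject's AI over the cluster mask voxels."""
    mask = np.asarray(cluster_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cluster mask")
    vals = []
    for m in ai_maps:
        if m.data.shape != mask.shape:
            raise ValueError("AI map geometry does not match the cluster mask")
        vals.append(float(m.data[mask].mean()))
    ids = subject_ids or [f"subj{i}" for i in range(len(ai_maps))]
    return ClusterAISeries(cluster_id, list(ids), np.asarray(vals))


def partial_correlation(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial correlation of y with x given covariates, via OLS.

    Fits ``y ~ x + covariates + intercept`` and converts the predictor's t
    to ``r = sign(t) sqrt(t^2/(t^2+df))`` with its two-sided p. With no
    covariates this equals the Pearson correlation.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    n = len(y)
    if len(x) != n:
        raise ValueError("y and x must have equal length")
    if x.std() == 0:
        raise ValueError("predictor has zero variance")
    if covariates is None:
        covariates = np.empty((n, 0))
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match y")
    if n <= cov.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")
    xs = (x - x.mean()) / x.std()
    for j in range(cov.shape[1]):
        col = cov[:, j]
        if col.std() > 0 and np.allclose((col - col.mean()) / col.std(), xs):
            raise ValueError(f"covariate {j} is identical to the predictor")

    X = np.column_stack([x, cov, np.ones(n)])
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient covariates; fitting with the pseudo-inverse",
            stacklevel=2,
        )
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    df = n - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    cvar = float(np.sum(pinv[0] ** 2) * sigma2)
    if cvar == 0:
        return 0.0, 1.0
    t = beta[0] / np.sqrt(cvar)
    r = np.sign(t) * np.sqrt(t**2 / (t**2 + df))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def _covariate_matrix(pheno: pd.DataFrame, include_age: bool) -> np.ndarray:
    cols = []
    if include_age:
        age = pheno["AGE_AT_SCAN"].to_numpy(dtype=np.float64)
        cols.append(age - age.mean())
    cols.append((pheno["SEX"].to_numpy() == 2).astype(np.float64))
    sites = pheno["SITE_ID"].astype(str).to_numpy()
    levels = sorted(set(sites))
    for site in levels[1:]:  # drop-first coding: intercept is in the model
        cols.append((sites == site).astype(np.float64))
    return np.column_stack(cols) if cols else np.empty((len(pheno), 0))


def run_brain_behavior(
    clusters: ClusterResult,
    ai_maps: list[AIMap],
    pheno: pd.DataFrame,
    predictor: str,
) -> pd.DataFrame:
    """Per-cluster partial correlation between mean AI and a predictor.

    ``predictor`` is either a score column (e.g. ``ADOS_SOCIAL``; age,
    gender and site are covariates) or ``"age"`` (gender and site are
    covariates). Rows of ``pheno`` align with ``ai_maps``; subjects missing
    the predictor are dropped per cluster. Returns a table with columns
    cluster, predictor, n, r, p.
    """
    if predictor == "age":
        series = pheno["AGE_AT_SCAN"]
        include_age_cov = False
    else:
        if predictor not in pheno.columns:
            raise KeyError(f"predictor column {predictor!r} not in phenotype table")
        series = pheno[predictor]
        include_age_cov = True
    present = series.notna().to_numpy()
    if not present.any():
        raise ValueError(f"predictor {predictor!r} is missing for all subjects")
    y = series.to_numpy(dtype=np.float64)[present]
    if np.std(y) == 0:
        raise ValueError(f"predictor {predictor!r} is constant")
    sub = pheno.loc[present]
    cov = _covariate_matrix(sub, include_age=include_age_cov)
    kept_maps = [m for m, keep in zip(ai_maps, present) if keep]

    rows = []
    for cid, mask in clusters.masks.items():
        series_ai = extract_cluster_means(kept_maps, mask, cluster_id=cid)
        r, p = partial_correlation(y, series_ai.values, cov)
        rows.append(
            {"cluster": cid, "predictor": predictor, "n": len(y), "r": r, "p": p}
        )
    return pd.DataFrame(rows, columns=["cluster", "predictor", "n", "r", "p"])
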