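"""Mass-univariate general linear models on asymmetry-index maps.

The design follows the site-as-covariate convention: one indicator column
per site (a subject's own site = 1, all others = 0), plus a case/control
group indicator, centered age, and a gender indicator. Because the site
indicators sum to the constant column, the design is fit with the
Moore-Penrose pseudo-inverse and the effective rank is reported; the group
contrast itself stays estimable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asymmetry import AIMap, HemisphereMask

__all__ = ["DesignMatrix", "TMap", "build_design", "fit_glm_voxelwise"]


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n x p
    labels: list[str]
    contrast: np.ndarray  # length p
    rank: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.contrast) != self.matrix.shape[1]:
            raise ValueError("contrast length must equal the number of columns")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def df(self) -> int:
        return self.n - self.rank


@dataclass
class TMap:
    """Voxel-wise t-statistics with the pieces needed for GRF inference."""

    data: np.ndarray  # 3-D lattice, zero off-mask
    affine: np.ndarray
    mask: HemisphereMask
    df: int
    residuals: np.ndarray  # n x V standardized residuals (mask scan order)
    case_mean: np.ndarray  # V group-mean AI (cases)
    control_mean: np.ndarray  # V group-mean AI (controls)
    zero_variance: np.ndarray  # V flags: voxels with no residual variance

    @property
    def values(self) -> np.ndarray:
        return self.data[self.mask.data]


def build_design(
    pheno: pd.DataFrame,
    group_labels: np.ndarray,
    covariates: bool = True,
) -> DesignMatrix:
    """Group indicator + centered age + gender + full one-hot site columns.

    ``group_labels`` is a 0/1 vector aligned with the rows of ``pheno``
    (1 = case). The contrast selects the group column, i.e. the adjusted
    case-minus-control difference. With ``covariates=False`` the design is
    just an intercept and the group column (two-sample t equivalence).
    """
    labels = np.asarray(group_labels, dtype=np.float64)
    n = len(pheno)
    if len(labels) != n:
        raise ValueError("group_labels must align with pheno rows")
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    cols: list[np.ndarray] = [labels]
    names = ["group"]
    if covariates:
        age = pheno["AGE_AT_SCAN"].to_numpy(dtype=np.float64)
        cols.append(age - age.mean())
        names.append("age_centered")
        sex = pheno["SEX"].to_numpy()
        cols.append((sex == 2).astype(np.float64))  # 0 = male, 1 = female
        names.append("gender_female")
        sites = pheno["SITE_ID"].astype(str).to_numpy()
        for site in sorted(set(sites)):
            if (sites == site).sum() == 0:
                raise ValueError(f"site {site} has no subjects")
            cols.append((sites == site).astype(np.float64))
            names.append(f"site_{site}")
    else:
        cols.append(np.ones(n))
        names.append("intercept")
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    rank = int(np.linalg.matrix_rank(X))
    return DesignMatrix(X, names, contrast, rank)


def fit_glm_voxelwise(ai_maps: list[AIMap], design: DesignMatrix) -> TMap:
    """Ordinary least squares per mask voxel; t for the design's contrast.

    t = c'beta / sqrt(sigma2 * c'(X'X)^- c) with sigma2 = RSS / (n - rank).
    Standardized residuals (residual / sigma-hat) are retained for
    smoothness estimation; per-group mean AI is retained for direction
    reporting. Voxels with zero residual variance get t = 0 and a flag.
    """
    if len(ai_maps) != design.n:
        raise ValueError("need one AI map per design row")
    mask = ai_maps[0].mask
    for m in ai_maps[1:]:
        if m.mask.data.shape != mask.data.shape or not np.array_equal(
            m.mask.data, mask.data
        ):
            raise ValueError("all AI maps must share one mask")
    if design.df <= 0:
        raise ValueError(f"non-positive residual df ({design.df})")

    Y = np.stack([m.values for m in ai_maps])  # n x V
    X = design.matrix
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / design.df
    cvar = float(np.sum((pinv.T @ design.contrast) ** 2))  # c'(X'X)^- c
    eff = design.contrast @ beta
    # zero-variance voxels: rss at round-off level relative to the data scale
    scale2 = np.maximum((Y**2).mean(axis=0), np.finfo(np.float64).tiny)
    zero_var = rss <= len(ai_maps) * (100 * np.finfo(np.float64).eps) ** 2 * scale2
    denom = np.sqrt(np.where(zero_var, 1.0, sigma2 * cvar))
    t = np.where(zero_var, 0.0, eff / denom)

    sd = np.sqrt(np.where(zero_var, 1.0, sigma2))
    std_resid = resid / sd
    std_resid[:, zero_var] = 0.0

    case = np.asarray(design.matrix[:, 0], dtype=bool)
    tdata = np.zeros(mask.data.shape)
    tdata[mask.data] = t
    return TMap(
        data=tdata,
        affine=ai_maps[0].affine,
        mask=mask,
        df=design.df,
        residuals=std_resid,
        case_mean=Y[case].mean(axis=0),
        control_mean=Y[~case].mean(axis=0),
        zero_variance=zero_var,
    )
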