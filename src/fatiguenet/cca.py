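"""Canonical correlation analysis of tongue vs pulse parameter blocks.

Classical CCA from first principles: both blocks are z-scored, the
correlations are the singular values of the whitened cross-covariance
(obtained via thin SVDs of the centred blocks), variates are scaled to unit
sample variance, and per-dimension significance uses Bartlett's chi-square
approximation to Wilks' lambda, with a subject-permutation test available as
a distribution-free alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10


@dataclass
class CCAResult:
    """Fitted canonical correlation analysis.

    ``x_weights[:, k]`` applied to the z-scored X block gives the k-th
    canonical variate U_{k+1} with unit sample variance (same for Y / V).
    Loadings are the correlations of each original variable with its own
    block's variates. The sign of each dimension is fixed so that the
    largest-magnitude X loading is positive.
    """

    correlations: np.ndarray
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_loadings: pd.DataFrame
    y_loadings: pd.DataFrame
    wilks_lambda: np.ndarray
    chi_square: np.ndarray
    dof: np.ndarray
    p_values: np.ndarray
    n: int

    @property
    def p(self) -> int:
        return self.x_weights.shape[0]

    @property
    def q(self) -> int:
        return self.y_weights.shape[0]


def _as_frame(M, prefix: str) -> pd.DataFrame:
    if isinstance(M, pd.DataFrame):
        return M
    M = np.asarray(M, float)
    if M.ndim == 1:
        M = M[:, None]
    return pd.DataFrame(M, columns=[f"{prefix}{j}" for j in range(M.shape[1])])


def _standardize(df: pd.DataFrame, name: str) -> np.ndarray:
    Z = df.to_numpy(float)
    sd = Z.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(df.columns[sd == 0])
        raise ValueError(f"{name} block has constant columns {bad}; remove them before fitting")
    return (Z - Z.mean(axis=0)) / sd


def bartlett_test(correlations: np.ndarray, n: int, p: int, q: int) -> pd.DataFrame:
    """Sequential Bartlett chi-square tests on Wilks' lambda.

    Row k tests H0: canonical correlations k..m are all zero, via
    chi2 = -(n - 1 - (p + q + 1)/2) * ln(Lambda_k) with
    (p - k)(q - k) degrees of freedom (0-based k).
    """
    if n <= p + q:
        raise ValueError(f"need n > p + q for the significance test (n={n}, p={p}, q={q})")
    r2 = np.asarray(correlations, float) ** 2
    m = len(r2)
    lam = np.array([np.prod(1.0 - r2[k:]) for k in range(m)])
    factor = n - 1 - (p + q + 1) / 2.0
    with np.errstate(divide="ignore"):
        chi2 = -factor * np.log(lam)
    dof = np.array([(p - k) * (q - k) for k in range(m)])
    pvals = stats.chi2.sf(chi2, dof)
    return pd.DataFrame({
        "dimension": np.arange(1, m + 1),
        "correlation": correlations,
        "wilks_lambda": lam,
        "chi_square": chi2,
        "dof": dof,
        "p_value": pvals,
    })


def fit_cca(X, Y) -> CCAResult:
    """Fit classical CCA between two blocks of continuous variables.

    Accepts DataFrames (column names preserved) or arrays. Requires
    n > p + q, no constant columns, and full column rank in each block.
    """
    Xf, Yf = _as_frame(X, "x"), _as_frame(Y, "y")
    if len(Xf) != len(Yf):
        raise ValueError("X and Y must have the same number of subjects")
    n, p = Xf.shape
    q = Yf.shape[1]
    if n <= p + q:
        raise ValueError(f"need n > p + q subjects (n={n}, p={p}, q={q})")

    Zx, Zy = _standardize(Xf, "X"), _standardize(Yf, "Y")
    Ux, Sx, Vxt = np.linalg.svd(Zx, full_matrices=False)
    Uy, Sy, Vyt = np.linalg.svd(Zy, full_matrices=False)
    for name, S, cols in (("X", Sx, Xf.columns), ("Y", Sy, Yf.columns)):
        if S[-1] <= _RANK_RTOL * S[0]:
            raise ValueError(
                f"{name} block is rank-deficient (collinear columns among {list(cols)}); "
                "remove linearly dependent columns before fitting")

    U, d, Vt = np.linalg.svd(Ux.T @ Uy)
    m = min(p, q)
    corr = np.clip(d[:m], 0.0, 1.0)

    scale = np.sqrt(n - 1)
    A = Vxt.T @ ((U[:, :m]) / Sx[:, None]) * scale        # p x m weights on z-scored X
    B = Vyt.T @ ((Vt.T[:, :m]) / Sy[:, None]) * scale     # q x m
    # loadings: correlation of each z-scored column with the unit-variance variate
    Lx = Zx.T @ (Ux @ U[:, :m]) / scale
    Ly = Zy.T @ (Uy @ Vt.T[:, :m]) / scale

    # sign convention: largest |loading| of each x-variate made positive,
    # flipping both blocks so the correlation is untouched
    for k in range(m):
        j = int(np.argmax(np.abs(Lx[:, k])))
        if Lx[j, k] < 0:
            A[:, k] *= -1
            B[:, k] *= -1
            Lx[:, k] *= -1
            Ly[:, k] *= -1

    test = bartlett_test(corr, n, p, q)
    dims = [f"dim{k + 1}" for k in range(m)]
    return CCAResult(
        correlations=corr,
        x_weights=pd.DataFrame(A, index=Xf.columns, columns=dims),
        y_weights=pd.DataFrame(B, index=Yf.columns, columns=dims),
        x_loadings=pd.DataFrame(Lx, index=Xf.columns, columns=dims),
        y_loadings=pd.DataFrame(Ly, index=Yf.columns, columns=dims),
        wilks_lambda=test["wilks_lambda"].to_numpy(),
        chi_square=test["chi_square"].to_numpy(),
        dof=test["dof"].to_numpy(),
        p_values=test["p_value"].to_numpy(),
        n=n,
    )


def structure_loadings(result: CCAResult, X, Y, dimension: int = 1) -> pd.DataFrame:
    """Per-variable correlations with the own-block canonical variate.

    Returns one row per variable (variable, block, loading, rank) sorted by
    |loading| descending — the layout of a CCA structure diagram. Constant
    columns get a missing loading and a warning.
    """
    Xf, Yf = _as_frame(X, "x"), _as_frame(Y, "y")
    dim = f"dim{dimension}"
    rows = []
    for frame, weights, block in ((Xf, result.x_weights, "tongue"), (Yf, result.y_weights, "pulse")):
        Z = frame.to_numpy(float)
        sd = Z.std(axis=0, ddof=1)
        Zs = np.where(sd > 0, (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
        variate = Zs @ weights[dim].to_numpy()
        vs = variate.std(ddof=1)
        for j, col in enumerate(frame.columns):
            if sd[j] == 0:
                warnings.warn(f"structure_loadings: column {col!r} is constant; loading undefined")
                loading = np.nan
            else:
                loading = float(np.dot(Zs[:, j], variate) / ((len(Z) - 1) * vs))
            rows.append({"variable": col, "block": block, "loading": loading})
    out = pd.DataFrame(rows)
    out["abs_loading"] = out["loading"].abs()
    out = out.sort_values(["abs_loading", "variable"], ascending=[False, True],
                          kind="mergesort").drop(columns="abs_loading").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def significance_test(result: CCAResult, n: int | None = None) -> pd.DataFrame:
    """Bartlett chi-square tests for each canonical dimension (see :func:`bartlett_test`)."""
    return bartlett_test(result.correlations, n or result.n, result.p, result.q)


def permutation_test(X, Y, n_permutations: int = 500, seed: int = 0) -> float:
    """Permutation p-value for the first canonical correlation.

    Refits CCA with Y's subject order permuted; the p-value is the
    add-one-corrected fraction of permuted first correlations at least as
    large as the observed one.
    """
    Xf, Yf = _as_frame(X, "x"), _as_frame(Y, "y")
    observed = fit_cca(Xf, Yf).correlations[0]
    rng = np.random.default_rng(seed)
    yvals = Yf.to_numpy(float)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(yvals))
        r = fit_cca(Xf, pd.DataFrame(yvals[perm], columns=Yf.columns)).correlations[0]
        exceed += r >= observed
    return (1 + exceed) / (1 + n_permutations)
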