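"""Ordination: principal coordinates of distance matrices, PCA of residual
or presence/absence matrices, and the top-axes phenotype scan."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .fdr import qvalues


@dataclass
class OrdinationResult:
    """Per-sample coordinates with eigenvalues and variance fractions.

    Only axes with positive eigenvalues are kept (at most n - 1).
    """

    coords: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    source: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(
                1.0, abs(self.eigenvalues[0]) if self.eigenvalues.size else 1)):
            raise ValueError("eigenvalues must be non-increasing")
        if self.coords.shape[1] > len(self.coords) - 1:
            raise ValueError("more axes than n - 1")


def pcoa(dm: DistanceMatrix, k: int | None = None,
         source: str = "pcoa") -> OrdinationResult:
    """Classical scaling (metric MDS): double-center -D^2/2, eigendecompose,
    scale eigenvectors by sqrt(eigenvalue). Axes with non-positive
    eigenvalues are dropped with a warning."""
    n = dm.shape[0]
    if k is None:
        k = n - 1
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigs
        res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.values
    pos = eig > max(eig.max(), 0) * 1e-12
    if (~pos).any() and (eig < -1e-9 * max(eig.max(), 1)).any():
        warnings.warn("negative PCoA eigenvalues dropped", stacklevel=2)
    n_keep = min(k, int(pos.sum()))
    coords = res.samples.values[:, :n_keep]
    eig_kept = eig[:n_keep]
    frac = eig_kept / eig[pos].sum()
    df = pd.DataFrame(coords, index=list(dm.ids),
                      columns=[f"PC{i+1}" for i in range(n_keep)])
    return OrdinationResult(df, eig_kept, frac, source)


def pca(matrix: pd.DataFrame, k: int | None = None,
        source: str = "pca") -> OrdinationResult:
    """Column-centered SVD scores with variance fractions from the singular
    values."""
    n, m = matrix.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if m < 1:
        raise ValueError("PCA needs at least 1 column")
    x = matrix.values.astype(float)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > (s[0] if s.size else 0) * 1e-12).sum())
    n_keep = min(k if k is not None else n - 1, rank, n - 1)
    scores = u[:, :n_keep] * s[:n_keep]
    eig = (s[:n_keep] ** 2) / (n - 1)
    frac = (s[:n_keep] ** 2) / (s ** 2).sum()
    df = pd.DataFrame(scores, index=matrix.index,
                      columns=[f"PC{i+1}" for i in range(n_keep)])
    return OrdinationResult(df, eig, frac, source)


def pc_phenotype_scan(ordination: OrdinationResult, phenotype: pd.Series,
                      n_axes: int = 100,
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Regress each of the top axes on a categorical phenotype.

    Per axis, an ordinary linear model axis ~ phenotype indicators is fit
    and the overall F-test p-value recorded; q-values are computed across
    the scanned axes. Samples with missing phenotype ('missing'/'unknown'/
    NaN) are excluded. Fewer than ``n_axes`` available axes -> all are used.
    """
    coords = ordination.coords
    pheno = phenotype.reindex(coords.index)
    ok = pheno.notna() & ~pheno.isin(["missing", "unknown"])
    if pheno[ok].nunique() < 2:
        raise ValueError("phenotype has fewer than 2 levels")
    y_all = coords.loc[ok]
    groups = pd.get_dummies(pheno[ok], drop_first=True, dtype=float).values
    x = np.column_stack([np.ones(len(y_all)), groups])
    if covariates is not None:
        cov = covariates.reindex(coords.index).loc[ok].values.astype(float)
        x = np.column_stack([x, cov])
    n, p_full = x.shape
    df_num = groups.shape[1]
    df_den = n - p_full
    q_mat, _ = np.linalg.qr(x)
    x0 = x[:, [0] + list(range(1 + df_num, p_full))]  # intercept + covariates
    q0, _ = np.linalg.qr(x0)
    rows = []
    n_scan = min(n_axes, y_all.shape[1])
    for a in range(n_scan):
        y = y_all.values[:, a]
        if np.ptp(y) == 0:
            warnings.warn(f"constant axis {a + 1}; p set to 1", stacklevel=2)
            rows.append((a + 1, np.nan, 1.0))
            continue
        tot = y @ y
        rss_full = max(tot - (q_mat.T @ y) @ (q_mat.T @ y), 0.0)
        rss_red = max(tot - (q0.T @ y) @ (q0.T @ y), 0.0)
        if rss_full <= tot * 1e-14:  # numerically perfect fit
            rows.append((a + 1, np.inf, 0.0))
            continue
        f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
        p = float(stats.f.sf(f, df_num, df_den))
        rows.append((a + 1, float(f), p))
    out = pd.DataFrame(rows, columns=["axis", "F", "p"])
    out["q"] = qvalues(out["p"].values)
    return out
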