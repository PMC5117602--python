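"""OTU-table processing: rarefaction, prevalence filtering, taxonomy
collapse, Box-Cox transformation, and covariate residualization.

The analysis-ready matrix for abundance models is built by rarefying to a
fixed depth, keeping taxa seen in at least half of a reference sample set,
Box-Cox transforming counts (+1 offset, per-taxon maximum-likelihood
lambda), and regressing technical covariates (sequencing depth, age, sex,
shipment batch, technician) out of each taxon column by OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable, RANKS


def rarefy(table: OtuTable, depth: int = 10000,
           seed: int = 0) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped; a sample exactly at
    depth is returned unchanged. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError("every sample is below the rarefaction depth")
    rng = np.random.default_rng(seed)
    counts = table.counts.loc[keep]
    out = np.empty(counts.shape, dtype=np.int64)
    vals = counts.values
    for i in range(vals.shape[0]):
        row = vals[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return OtuTable(df, table.taxonomy, rarefied_depth=depth)


def prevalence_filter(table: OtuTable, min_fraction: float = 0.5,
                      reference_samples=None) -> list[str]:
    """Taxon IDs with a nonzero count in at least ceil(min_fraction * n) of
    the reference samples (default: all samples of the table)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    counts = table.counts
    if reference_samples is not None:
        counts = counts.loc[list(reference_samples)]
    n = len(counts)
    if n == 0:
        raise ValueError("empty reference sample set")
    need = ceil(min_fraction * n)
    prev = (counts.values > 0).sum(axis=0)
    return [t for t, p in zip(counts.columns, prev) if p >= need]


def collapse_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts within taxonomy groups at ``rank`` (genus ... phylum).

    Per-sample totals are conserved; OTUs unassigned at the rank are grouped
    as ``unclassified-<nearest assigned parent>``.
    """
    groups = table.lineage_at(rank)  # raises on unknown rank
    collapsed = table.counts.T.groupby(groups.values).sum().T
    collapsed.columns = [str(c) for c in collapsed.columns]
    taxonomy = pd.Series(collapsed.columns, index=collapsed.columns)
    return OtuTable(collapsed, taxonomy, table.rarefied_depth)


def collapse_all_ranks(table: OtuTable) -> dict[str, OtuTable]:
    """Collapsed tables for every rank from genus up to phylum."""
    return {rank: collapse_taxonomy(table, rank) for rank in RANKS}


def boxcox_transform(y: np.ndarray, offset: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """Box-Cox transform y -> ((y+offset)^lambda - 1) / lambda with lambda
    maximizing the profile log-likelihood; lambda = 0 is the log limit."""
    y = np.asarray(y, dtype=float) + offset
    if np.any(y <= 0):
        raise ValueError("y + offset must be positive")
    if np.ptp(y) == 0:
        raise ValueError("constant vector: Box-Cox lambda undefined")
    transformed, lam = stats.boxcox(y)
    return float(lam), transformed


@dataclass
class ResidualMatrix:
    """Box-Cox residuals per (sample, taxon) with fitted lambdas and the
    covariates removed."""

    values: pd.DataFrame
    lambdas: pd.Series
    covariates_removed: list[str]


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric covariates + treatment-coded categoricals."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        v = covariates[col]
        if pd.api.types.is_numeric_dtype(v):
            parts.append(v.astype(float))
        else:
            dummies = pd.get_dummies(v, prefix=col, drop_first=True,
                                     dtype=float)
            parts.append(dummies)
    x = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(x.values)
    if rank < x.shape[1]:
        # name the offending columns for the error message
        bad = []
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(x.values[:, trial]) == len(trial):
                keep = trial
            else:
                bad.append(x.columns[j])
        raise ValueError(f"collinear covariate design; offending columns: {bad}")
    return x


def residualize(matrix: pd.DataFrame,
                covariates: pd.DataFrame) -> ResidualMatrix:
    """OLS residuals of each column of ``matrix`` on the covariate design.

    ``matrix`` may be raw counts (then Box-Cox is applied per column first)
    or already-transformed values when ``lambdas`` are not needed; this
    function always Box-Cox transforms, matching the abundance pipeline.
    """
    covariates = covariates.loc[matrix.index]
    x = _design_matrix(covariates).values
    resid = np.empty(matrix.shape)
    lambdas = np.empty(matrix.shape[1])
    q, _ = np.linalg.qr(x)
    vals = matrix.values
    for j in range(matrix.shape[1]):
        lam, ty = boxcox_transform(vals[:, j])
        lambdas[j] = lam
        resid[:, j] = ty - q @ (q.T @ ty)
    out = pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)
    return ResidualMatrix(out, pd.Series(lambdas, index=matrix.columns),
                          list(covariates.columns))


def residualize_values(matrix: pd.DataFrame,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of already-transformed columns (no Box-Cox step)."""
    covariates = covariates.loc[matrix.index]
    x = _design_matrix(covariates).values
    q, _ = np.linalg.qr(x)
    vals = matrix.values.astype(float)
    resid = vals - q @ (q.T @ vals)
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def presence_absence(table: OtuTable) -> pd.DataFrame:
    """Binary sample-by-taxon matrix: 1 iff count > 0."""
    return (table.counts > 0).astype(np.int8)


TECHNICAL_COVARIATES = ["seq_depth", "age", "sex", "shipment_batch",
                        "technician"]


def technical_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """The standard technical covariate set regressed out of abundances and
    alpha diversity before association testing."""
    return cohort[TECHNICAL_COVARIATES].copy()
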