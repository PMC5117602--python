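"""Alpha diversity (averaged over repeated rarefactions) and beta-diversity
distance matrices.

Alpha metrics follow the QIIME 1 conventions of the 16S toolchain this
pipeline mirrors: Shannon diversity in bits (log base 2), Chao1 in its
classic form S + F1^2/(2 F2) with the bias-corrected fallback when no
doubletons exist, Faith's phylogenetic diversity including the branch path
to the root, and the Gini index computed on relative abundances over the
full taxon set (zeros included) as an evenness measure.

Beta diversity (unweighted/weighted UniFrac, Bray-Curtis) is computed on a
rarefied table; weighted UniFrac is normalized by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import faith_pd as _faith_pd
from skbio.diversity.alpha import shannon as _shannon

from .otu import OtuTable
from .taxa import rarefy

ALPHA_METRICS = ("faith_pd", "observed_otus", "chao1", "gini", "shannon")
BETA_METRICS = ("unweighted_unifrac", "weighted_unifrac", "bray_curtis")


# ---------------------------------------------------------------------------
# alpha metrics on one count vector

def observed_otus(counts: np.ndarray) -> float:
    return float((counts > 0).sum())


def chao1(counts: np.ndarray) -> float:
    """Classic Chao1, S + F1^2/(2 F2); bias-corrected form
    S + F1(F1-1)/(2(F2+1)) when there are no doubletons."""
    s = (counts > 0).sum()
    f1 = (counts == 1).sum()
    f2 = (counts == 2).sum()
    if f2 > 0:
        return float(s + f1 * f1 / (2.0 * f2))
    return float(s + f1 * (f1 - 1) / 2.0)


def gini_index(counts: np.ndarray, population: bool = True) -> float:
    """Gini index of relative abundances over the full taxon set.

    ``population=True`` uses the population denominator 2 S^2 mean(p)
    (range [0, 1 - 1/S]); False uses the sample form 2 S (S - 1) mean(p).
    """
    p = np.asarray(counts, dtype=float)
    total = p.sum()
    if total == 0:
        raise ValueError("sample with zero total count")
    p = p / total
    s = p.size
    diff_sum = np.abs(p[:, None] - p[None, :]).sum()
    denom = 2.0 * s * s * p.mean() if population \
        else 2.0 * s * (s - 1) * p.mean()
    return float(diff_sum / denom)


def shannon(counts: np.ndarray) -> float:
    return float(_shannon(counts, base=2))


def _alpha_one(metric: str, counts: np.ndarray, taxa, tree) -> float:
    if metric == "faith_pd":
        return float(_faith_pd(counts, taxa, tree))
    if metric == "observed_otus":
        return observed_otus(counts)
    if metric == "chao1":
        return chao1(counts)
    if metric == "gini":
        return gini_index(counts)
    if metric == "shannon":
        return shannon(counts)
    raise ValueError(f"unknown alpha metric {metric!r}")


def alpha_diversity(table: OtuTable, metric: str,
                    tree: TreeNode | None = None,
                    n_rarefactions: int = 100, depth: int = 10000,
                    seed: int = 0) -> pd.Series:
    """Per-sample alpha diversity averaged over independent rarefactions.

    Samples below the rarefaction depth are dropped. ``tree`` is required
    (and only used) for Faith's PD.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}")
    if metric == "faith_pd" and tree is None:
        raise ValueError("faith_pd requires a tree")
    taxa = table.taxon_ids
    acc: pd.Series | None = None
    for r in range(n_rarefactions):
        rt = rarefy(table, depth=depth, seed=np.random.SeedSequence(
            [seed, r]).generate_state(1)[0])
        vals = pd.Series(
            [_alpha_one(metric, row, taxa, tree) for row in rt.counts.values],
            index=rt.counts.index)
        acc = vals if acc is None else acc + vals
    return acc / n_rarefactions


def alpha_diversity_all(table: OtuTable, tree: TreeNode,
                        n_rarefactions: int = 100, depth: int = 10000,
                        seed: int = 0) -> pd.DataFrame:
    """All five alpha metrics from a shared set of rarefactions (long-format
    averaging done metric-wise; one rarefaction stream reused for all)."""
    taxa = table.taxon_ids
    acc = {m: None for m in ALPHA_METRICS}
    for r in range(n_rarefactions):
        rt = rarefy(table, depth=depth, seed=np.random.SeedSequence(
            [seed, r]).generate_state(1)[0])
        for m in ALPHA_METRICS:
            vals = pd.Series(
                [_alpha_one(m, row, taxa, tree) for row in rt.counts.values],
                index=rt.counts.index)
            acc[m] = vals if acc[m] is None else acc[m] + vals
    return pd.DataFrame({m: acc[m] / n_rarefactions for m in ALPHA_METRICS})


# ---------------------------------------------------------------------------
# beta diversity

def beta_diversity(table: OtuTable, metric: str,
                   tree: TreeNode | None = None,
                   require_rarefied: bool = True,
                   normalized_weighted: bool = True) -> DistanceMatrix:
    """Sample-by-sample dissimilarity matrix.

    Bray-Curtis: 1 - 2 sum(min(x, y)) / (sum x + sum y). Unweighted UniFrac:
    branch length unique to one sample over total observed branch length.
    Weighted UniFrac: abundance-weighted branch-length difference,
    normalized by default.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown beta metric {metric!r}")
    if require_rarefied and table.rarefied_depth is None:
        raise ValueError("beta diversity expects a rarefied table")
    if (table.counts.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total count")
    counts = table.counts.values
    ids = table.sample_ids
    if metric == "bray_curtis":
        return _skbio_beta("braycurtis", counts, ids=ids)
    if tree is None:
        raise ValueError(f"{metric} requires a tree")
    kwargs = dict(taxa=table.taxon_ids, tree=tree)
    if metric == "weighted_unifrac":
        kwargs["normalized"] = normalized_weighted
        return _skbio_beta("weighted_unifrac", counts, ids=ids, **kwargs)
    return _skbio_beta("unweighted_unifrac", counts, ids=ids, **kwargs)
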