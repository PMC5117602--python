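"""Twin-structure-preserving permutations and empirical p-values.

The scheme splits the cohort into MZ twin pairs, DZ twin pairs, and
unrelated individuals. Phenotypes of unrelated individuals are permuted
among the unrelated; within the MZ group and within the DZ group
separately, each family's ordered phenotype pair is reassigned intact to
another family of the same zygosity, so within-pair phenotype concordance
patterns are preserved exactly.

Two simpler permutations support the relatedness tests: family IDs permuted
across all individuals (twin-vs-unrelated null) and zygosity labels permuted
across twin pairs (MZ-vs-DZ null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PermutationPlan:
    """Strata bookkeeping for twin-aware phenotype permutation.

    ``mz_pairs`` and ``dz_pairs`` hold ordered (member1, member2) positional
    index pairs into ``samples``; ``unrelated`` holds positional indices.
    A sample with a missing phenotype is excluded and its co-twin treated
    as unrelated, keeping the strata well-formed.
    """

    samples: list[str]
    mz_pairs: np.ndarray  # (n_mz, 2) int
    dz_pairs: np.ndarray  # (n_dz, 2) int
    unrelated: np.ndarray  # (n_unrel,) int
    seed: int = 0
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        used = np.concatenate([self.mz_pairs.ravel(), self.dz_pairs.ravel(),
                               self.unrelated]).astype(int)
        if len(np.unique(used)) != len(used):
            raise ValueError("strata overlap: a sample appears twice")


def build_plan(cohort: pd.DataFrame, phenotype: pd.Series | None = None,
               n_permutations: int = 1000, seed: int = 0) -> PermutationPlan:
    """Derive the permutation strata from cohort zygosity and family IDs.

    If ``phenotype`` is given, samples with missing values ('missing',
    'unknown', NaN) are dropped and broken pairs downgraded to unrelated.
    """
    samples = list(cohort.index)
    pos = {s: i for i, s in enumerate(samples)}
    if phenotype is not None:
        pheno = phenotype.reindex(cohort.index)
        ok = pheno.notna() & ~pheno.isin(["missing", "unknown"])
    else:
        ok = pd.Series(True, index=cohort.index)
    mz, dz, unrel = [], [], []
    for fam, members in cohort.groupby("family_id", sort=False):
        mids = [s for s in members.index if ok[s]]
        zyg = members["zygosity"].iloc[0]
        if zyg in ("MZ", "DZ") and len(mids) == 2:
            (mz if zyg == "MZ" else dz).append((pos[mids[0]], pos[mids[1]]))
        else:
            unrel.extend(pos[s] for s in mids)
    return PermutationPlan(
        samples,
        np.array(mz, dtype=int).reshape(-1, 2),
        np.array(dz, dtype=int).reshape(-1, 2),
        np.array(unrel, dtype=int),
        seed=seed, n_permutations=n_permutations)


def included_mask(plan: PermutationPlan) -> np.ndarray:
    mask = np.zeros(len(plan.samples), dtype=bool)
    mask[plan.mz_pairs.ravel()] = True
    mask[plan.dz_pairs.ravel()] = True
    mask[plan.unrelated] = True
    return mask


def permute_phenotypes(phenotype: pd.Series, plan: PermutationPlan,
                       draw_index: int) -> pd.Series:
    """One twin-aware permutation draw of a phenotype vector.

    Fully determined by (plan.seed, draw_index). Samples outside the plan's
    strata keep their original value (they are excluded from analyses).
    """
    pheno = phenotype.reindex(plan.samples)
    out = pheno.values.copy()
    rng = np.random.default_rng([plan.seed, draw_index])
    for pairs in (plan.mz_pairs, plan.dz_pairs):
        if len(pairs):
            perm = rng.permutation(len(pairs))
            vals = pheno.values[pairs]          # (n_pairs, 2), ordered
            out[pairs[:, 0]] = vals[perm, 0]
            out[pairs[:, 1]] = vals[perm, 1]
    if len(plan.unrelated):
        perm = rng.permutation(len(plan.unrelated))
        out[plan.unrelated] = pheno.values[plan.unrelated][perm]
    return pd.Series(out, index=plan.samples, name=phenotype.name)


def permute_family_ids(cohort: pd.DataFrame, draw_index: int,
                       seed: int = 0) -> pd.DataFrame:
    """Permute family labels uniformly across all individuals (breaks twin
    pairing); the label multiset is preserved."""
    rng = np.random.default_rng([seed, draw_index, 1])
    out = cohort.copy()
    out["family_id"] = rng.permutation(cohort["family_id"].values)
    return out


def permute_zygosity(cohort: pd.DataFrame, draw_index: int,
                     seed: int = 0) -> pd.DataFrame:
    """Permute MZ/DZ labels at the twin-pair level; each pair keeps its
    membership and receives a pair-level label from the shuffled multiset."""
    twins = cohort[cohort["zygosity"].isin(["MZ", "DZ"])]
    if twins.empty:
        raise ValueError("cohort contains no twin pairs")
    fams = twins.groupby("family_id", sort=False)["zygosity"].first()
    rng = np.random.default_rng([seed, draw_index, 2])
    shuffled = pd.Series(rng.permutation(fams.values), index=fams.index)
    out = cohort.copy()
    is_twin = out["zygosity"].isin(["MZ", "DZ"])
    out.loc[is_twin, "zygosity"] = out.loc[is_twin, "family_id"].map(shuffled)
    return out


def empirical_p(observed: float, null_draws, direction: str = "ge") -> float:
    """Permutation p-value: the fraction of null draws at least as extreme
    as the observed statistic (ties count as extreme; p can be 0)."""
    null = np.asarray(list(null_draws), dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "ge":
        return float((null >= observed).mean())
    if direction == "le":
        return float((null <= observed).mean())
    raise ValueError("direction must be 'ge' or 'le'")
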