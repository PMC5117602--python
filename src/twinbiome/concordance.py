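"""Stratified mean beta diversity: twin-vs-unrelated and MZ-vs-DZ
relatedness tests, and phenotype concordance/discordance comparisons, all
with permutation significance.

Sign convention: the reported statistic is mean(stratum A) - mean(stratum
B) with A the hypothesized more-similar stratum (twins, MZ pairs,
concordant pairs), so a negative statistic means "more similar", and the
default permutation direction is one-sided 'le'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .permutation import (PermutationPlan, build_plan, empirical_p,
                          included_mask, permute_family_ids,
                          permute_phenotypes, permute_zygosity)


@dataclass
class PairStratification:
    """Labels for every unordered sample pair of one analysis.

    ``i``, ``j`` are positional index arrays into ``samples`` (i < j) and
    ``labels`` the per-pair stratum names.
    """

    samples: list[str]
    i: np.ndarray
    j: np.ndarray
    labels: np.ndarray
    phenotype: str = ""
    mode: str = "all"


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def relatedness_strata(cohort: pd.DataFrame) -> PairStratification:
    """Label every pair MZ-pair, DZ-pair, or unrelated-pair (any pair not
    sharing a family counts as unrelated, including cross-family twins)."""
    samples = list(cohort.index)
    n = len(samples)
    i, j = _pair_indices(n)
    fam = cohort["family_id"].values
    zyg = cohort["zygosity"].values
    same_fam = fam[i] == fam[j]
    labels = np.where(same_fam & (zyg[i] == "MZ"), "MZ-pair",
                      np.where(same_fam & (zyg[i] == "DZ"), "DZ-pair",
                               "unrelated-pair"))
    return PairStratification(samples, i, j, labels)


def one_twin_per_family(cohort: pd.DataFrame) -> pd.Index:
    """Deterministic one-member-per-family subset: the lexicographically
    smallest sample ID of each family."""
    keep = (pd.Series(cohort.index, index=cohort.index)
            .groupby(cohort["family_id"]).min())
    return pd.Index(sorted(keep.values))


def concordance_strata(cohort: pd.DataFrame, phenotype: pd.Series,
                       mode: str = "all") -> PairStratification:
    """Label pairs concordant/discordant for a phenotype.

    Samples with missing phenotype are excluded; in mode
    'one_twin_per_family' only one member per family is retained first.
    """
    if mode not in ("all", "one_twin_per_family"):
        raise ValueError(f"unknown mode {mode!r}")
    pheno = phenotype.reindex(cohort.index)
    ok = pheno.notna() & ~pheno.isin(["missing", "unknown"])
    sub = cohort.loc[ok]
    if mode == "one_twin_per_family":
        sub = sub.loc[sub.index.intersection(one_twin_per_family(sub))]
    vals = pheno.loc[sub.index].values
    if len(pd.unique(vals)) < 2:
        raise ValueError("phenotype has a single level among included "
                         "samples")
    samples = list(sub.index)
    i, j = _pair_indices(len(samples))
    labels = np.where(vals[i] == vals[j], "concordant", "discordant")
    return PairStratification(samples, i, j, labels,
                              phenotype=str(phenotype.name), mode=mode)


def stratified_mean_beta(dm: DistanceMatrix,
                         strat: PairStratification) -> pd.DataFrame:
    """Arithmetic mean distance and pair count per stratum."""
    d = dm.filter(strat.samples).data
    vals = d[strat.i, strat.j]
    rows = []
    for lab in pd.unique(strat.labels):
        mask = strat.labels == lab
        if not mask.any():
            raise ValueError(f"empty stratum {lab!r}")
        rows.append({"stratum": lab, "mean": float(vals[mask].mean()),
                     "n_pairs": int(mask.sum())})
    return pd.DataFrame(rows).set_index("stratum")


def _pair_means_by_family(d: np.ndarray, cohort: pd.DataFrame
                          ) -> dict[str, float]:
    """Mean within-co-twin-pair distance per zygosity plus the mean over
    all other (unrelated) pairs."""
    fam = cohort["family_id"].values
    zyg = cohort["zygosity"].values
    n = len(fam)
    order = np.argsort(fam, kind="stable")
    sums = {"MZ": [], "DZ": []}
    paired = []
    k = 0
    while k < len(order) - 1:
        a, b = order[k], order[k + 1]
        if fam[a] == fam[b]:
            paired.append(d[a, b])
            # pair-level zygosity only meaningful when both members agree
            # (family-ID permutation can join mismatched labels)
            if zyg[a] == zyg[b] and zyg[a] in sums:
                sums[zyg[a]].append(d[a, b])
            k += 2
        else:
            k += 1
    twin_vals = np.array(paired)
    total_sum = d.sum() / 2.0
    n_pairs = n * (n - 1) // 2
    n_twin = twin_vals.size
    out = {
        "mz_mean": float(np.mean(sums["MZ"])) if sums["MZ"] else np.nan,
        "dz_mean": float(np.mean(sums["DZ"])) if sums["DZ"] else np.nan,
        "twin_mean": float(twin_vals.mean()) if n_twin else np.nan,
        "unrelated_mean": float((total_sum - twin_vals.sum())
                                / (n_pairs - n_twin)),
    }
    return out


def relatedness_test(dm: DistanceMatrix, cohort: pd.DataFrame,
                     comparison: str = "twin_vs_unrelated",
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Permutation test that related pairs have smaller distances.

    twin_vs_unrelated: statistic = mean(co-twin pairs) - mean(unrelated
    pairs); null from permuting family IDs across individuals.
    mz_vs_dz: statistic = mean(MZ pairs) - mean(DZ pairs); null from
    permuting zygosity labels across twin pairs. One-sided ('le') empirical
    p; ties count as extreme.
    """
    if comparison not in ("twin_vs_unrelated", "mz_vs_dz"):
        raise ValueError(f"unknown comparison {comparison!r}")
    if not cohort["zygosity"].isin(["MZ", "DZ"]).any():
        raise ValueError("cohort contains no twin pairs")
    d = dm.filter(list(cohort.index)).data

    def stat_of(c: pd.DataFrame) -> float:
        m = _pair_means_by_family(d, c)
        if comparison == "twin_vs_unrelated":
            return m["twin_mean"] - m["unrelated_mean"]
        return m["mz_mean"] - m["dz_mean"]

    observed = stat_of(cohort)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = (permute_family_ids(cohort, b, seed)
                if comparison == "twin_vs_unrelated"
                else permute_zygosity(cohort, b, seed))
        null[b] = stat_of(perm)
    return {"statistic": observed, "p": empirical_p(observed, null, "le"),
            "null": null, "comparison": comparison,
            "means": _pair_means_by_family(d, cohort)}


def _concordant_discordant_means(d: np.ndarray, vals: np.ndarray
                                 ) -> tuple[float, float]:
    """Mean distance over equal-phenotype and unequal-phenotype pairs via
    per-level indicator sums (O(k n^2))."""
    n = d.shape[0]
    total = d.sum() / 2.0
    n_pairs = n * (n - 1) / 2.0
    conc_sum = 0.0
    n_conc = 0.0
    for lvl in pd.unique(vals):
        mask = vals == lvl
        m = mask.sum()
        conc_sum += d[np.ix_(mask, mask)].sum() / 2.0
        n_conc += m * (m - 1) / 2.0
    if n_conc == 0 or n_conc == n_pairs:
        raise ValueError("concordant or discordant stratum is empty")
    return (conc_sum / n_conc,
            (total - conc_sum) / (n_pairs - n_conc))


def concordance_test(dm: DistanceMatrix, cohort: pd.DataFrame,
                     phenotype: pd.Series, mode: str = "all",
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Are phenotype-concordant pairs more similar than discordant pairs?

    Statistic = mean(concordant) - mean(discordant); null built by
    twin-aware phenotype permutation on the included samples; one-sided
    ('le') empirical p. In 'one_twin_per_family' mode one member per family
    is kept (lexicographically smallest sample ID) before pairing.
    """
    strat = concordance_strata(cohort, phenotype, mode)
    sub = cohort.loc[strat.samples]
    d = dm.filter(strat.samples).data
    pheno = phenotype.reindex(strat.samples)
    plan = build_plan(sub, pheno, n_permutations=n_perm, seed=seed)
    inc = included_mask(plan)

    vals = pheno.values
    conc, disc = _concordant_discordant_means(d, vals)
    observed = conc - disc
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = permute_phenotypes(pheno, plan, b).values
        c, dd = _concordant_discordant_means(d, perm)
        null[b] = c - dd
    assert inc.all()  # plan built after exclusion: everyone included
    return {"statistic": observed, "p": empirical_p(observed, null, "le"),
            "null": null, "concordant_mean": conc, "discordant_mean": disc,
            "mode": mode}
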