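#!/usr/bin/env python
"""Relatedness and phenotype-concordance comparisons of beta diversity.

Twins should have more similar microbiomes than unrelated pairs and MZ
twins more similar than DZ twins (the heritability signature built into
the generator); phenotype-concordant pairs should look like discordant
pairs because the injected phenotype effect touches a single OTU.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, SEED

import pandas as pd

from twinbiome.concordance import (concordance_test, relatedness_strata,
                                   relatedness_test, stratified_mean_beta)
from twinbiome.io import read_distance_matrix, read_metadata

N_PERM = 500


def main() -> None:
    cohort = read_metadata(RESULTS / "phenotypes.tsv")
    rows = []
    for metric in ("unweighted_unifrac", "bray_curtis"):
        dm = read_distance_matrix(RESULTS / f"beta_{metric}.tsv")
        coh = cohort.loc[list(dm.ids)]
        means = stratified_mean_beta(dm, relatedness_strata(coh))
        print(f"[{metric}] stratum means:")
        print(means.round(4).to_string())
        for comparison in ("twin_vs_unrelated", "mz_vs_dz"):
            res = relatedness_test(dm, coh, comparison, n_perm=N_PERM,
                                   seed=SEED)
            rows.append({"metric": metric, "test": comparison,
                         "statistic": res["statistic"], "p": res["p"]})
            print(f"[{metric}] {comparison}: delta = "
                  f"{res['statistic']:+.4f}, permutation p = {res['p']:.4f}")
        for pheno_name in ("abo", "secretor"):
            for mode in ("all", "one_twin_per_family"):
                res = concordance_test(dm, coh, coh[pheno_name], mode,
                                       n_perm=N_PERM, seed=SEED)
                rows.append({"metric": metric,
                             "test": f"concordance_{pheno_name}_{mode}",
                             "statistic": res["statistic"], "p": res["p"]})
                print(f"[{metric}] {pheno_name} concordance ({mode}): "
                      f"delta = {res['statistic']:+.4f}, "
                      f"p = {res['p']:.4f}")
    pd.DataFrame(rows).to_csv(RESULTS / "beta_comparisons.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
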