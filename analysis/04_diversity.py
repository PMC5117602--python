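#!/usr/bin/env python
"""Alpha and beta diversity of the rarefied demo cohort.

Alpha metrics are averaged over repeated rarefactions and residualized on
technical covariates; beta diversity is computed as unweighted/weighted
UniFrac and Bray-Curtis distance matrices for the downstream ordination
and relatedness analyses.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RAREFACTION_DEPTH, RESULTS, SEED

from twinbiome.diversity import alpha_diversity_all, beta_diversity
from twinbiome.io import (read_metadata, read_tree, write_distance_matrix)
from twinbiome.otu import OtuTable
from twinbiome.taxa import residualize_values, technical_covariates


def main() -> None:
    rt = OtuTable.read_tsv(RESULTS / "otu_table_rarefied.tsv",
                           rarefied_depth=RAREFACTION_DEPTH)
    tree = read_tree(RESULTS / "tree.nwk")
    cohort = read_metadata(RESULTS / "phenotypes.tsv").loc[rt.sample_ids]

    alpha = alpha_diversity_all(rt, tree, n_rarefactions=25,
                                depth=RAREFACTION_DEPTH, seed=SEED)
    alpha.to_csv(RESULTS / "alpha_diversity.tsv", sep="\t")
    ares = residualize_values(alpha, technical_covariates(cohort))
    ares.to_csv(RESULTS / "alpha_residuals.tsv", sep="\t")
    print("alpha diversity (25 rarefactions), cohort means:")
    print(alpha.mean().round(3).to_string())

    for metric in ("unweighted_unifrac", "weighted_unifrac", "bray_curtis"):
        dm = beta_diversity(rt, metric, tree)
        write_distance_matrix(dm, RESULTS / f"beta_{metric}.tsv")
        tri = dm.condensed_form()
        print(f"{metric}: mean pairwise distance "
              f"{tri.mean():.3f} (n={dm.shape[0]} samples)")


if __name__ == "__main__":
    main()
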