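#!/usr/bin/env python
"""Build the analysis-ready abundance matrices.

Rarefies the raw OTU table, applies the 50% (common taxa) and 10%
(presence/absence) prevalence filters, collapses counts by taxonomy from
genus to phylum, Box-Cox transforms, and regresses out technical
covariates.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RAREFACTION_DEPTH, RESULTS, SEED

import pandas as pd

from twinbiome.io import read_metadata
from twinbiome.otu import OtuTable
from twinbiome.taxa import (collapse_all_ranks, presence_absence,
                            prevalence_filter, rarefy, residualize,
                            technical_covariates)


def main() -> None:
    table = OtuTable.read_tsv(RESULTS / "otu_table_raw.tsv")
    cohort = read_metadata(RESULTS / "phenotypes.tsv")

    rt = rarefy(table, depth=RAREFACTION_DEPTH, seed=SEED)
    dropped = set(table.sample_ids) - set(rt.sample_ids)
    print(f"rarefied to {RAREFACTION_DEPTH} reads/sample; dropped "
          f"{len(dropped)} samples below depth")
    rt.write_tsv(RESULTS / "otu_table_rarefied.tsv")
    coh = cohort.loc[rt.sample_ids]

    collapsed = collapse_all_ranks(rt)
    rank_sizes = {r: t.shape[1] for r, t in collapsed.items()}
    print(f"collapsed taxa per rank: {rank_sizes}")

    common_otus = prevalence_filter(rt, 0.5)
    # common collapsed groups enter the association scans alongside OTUs
    frames = [rt.counts[common_otus]]
    for rank, ct in collapsed.items():
        keep = prevalence_filter(ct, 0.5)
        frames.append(ct.counts[keep].add_prefix(f"{rank}|"))
    combined = pd.concat(frames, axis=1)
    print(f"common taxa (>=50% prevalence): {len(common_otus)} OTUs, "
          f"{combined.shape[1]} taxa including collapsed groups")

    res = residualize(combined, technical_covariates(coh))
    res.values.to_csv(RESULTS / "residuals_common_taxa.tsv", sep="\t")
    res.lambdas.to_csv(RESULTS / "boxcox_lambdas.tsv", sep="\t",
                       header=["lambda"])
    print(f"Box-Cox lambdas span [{res.lambdas.min():.2f}, "
          f"{res.lambdas.max():.2f}]; covariates removed: "
          f"{res.covariates_removed}")

    pa_otus = prevalence_filter(rt, 0.1)
    pa = presence_absence(rt)[pa_otus]
    pa.to_csv(RESULTS / "presence_absence.tsv", sep="\t")
    print(f"presence/absence matrix: {pa.shape[1]} OTUs at >=10% "
          "prevalence")


if __name__ == "__main__":
    main()
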