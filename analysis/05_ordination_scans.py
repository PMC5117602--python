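#!/usr/bin/env python
"""Ordination and the top-PC phenotype scans.

PCoA of each beta-diversity matrix and PCA of the residual-abundance and
presence/absence matrices; the leading axes of every ordination are then
regressed on ABO status, secretor status, and ABO status in secretors
only. ABO scans should be null; the secretor scans may flag a few axes,
since the positive-control effect sits on the cohort's most abundant OTU
and abundant taxa load heavily on leading axes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS

import pandas as pd

from twinbiome.io import read_distance_matrix, read_metadata
from twinbiome.ordination import pc_phenotype_scan, pca, pcoa

N_AXES = 100


def phenotype_sets(cohort):
    abo = cohort["abo"]
    sec = cohort["secretor"]
    abo_in_sec = abo.where(sec == "S", other="missing")
    return {"abo": abo, "secretor": sec, "abo_in_secretors": abo_in_sec}


def main() -> None:
    cohort = read_metadata(RESULTS / "phenotypes.tsv")
    ordinations = {}
    for metric in ("unweighted_unifrac", "weighted_unifrac", "bray_curtis"):
        dm = read_distance_matrix(RESULTS / f"beta_{metric}.tsv")
        ordinations[f"pcoa_{metric}"] = pcoa(dm, source=metric)
    residuals = pd.read_csv(RESULTS / "residuals_common_taxa.tsv",
                            sep="\t", index_col=0)
    ordinations["pca_residuals"] = pca(residuals, source="residuals")
    pa = pd.read_csv(RESULTS / "presence_absence.tsv", sep="\t",
                     index_col=0)
    ordinations["pca_presence"] = pca(pa, source="presence_absence")

    rows = []
    for name, ordn in ordinations.items():
        ordn.coords.iloc[:, :10].to_csv(RESULTS / f"{name}_axes.tsv",
                                        sep="\t")
        for pheno_name, pheno in phenotype_sets(
                cohort.loc[ordn.coords.index]).items():
            scan = pc_phenotype_scan(ordn, pheno, n_axes=N_AXES)
            scan.insert(0, "ordination", name)
            scan.insert(1, "phenotype", pheno_name)
            rows.append(scan)
            n_sig = int((scan["q"] <= 0.05).sum())
            print(f"{name} ~ {pheno_name}: {len(scan)} axes scanned, "
                  f"{n_sig} with q <= 0.05")
    out = pd.concat(rows, ignore_index=True)
    out.to_csv(RESULTS / "pc_phenotype_scans.tsv", sep="\t", index=False)
    total_sig = int((out["q"] <= 0.05).sum())
    print(f"total significant axis-phenotype pairs at q <= 0.05: "
          f"{total_sig} of {len(out)}")


if __name__ == "__main__":
    main()
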