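#!/usr/bin/env python
"""Per-taxon association models.

Runs the nine twin linear mixed models (m1-m9) over the common-taxon
residual matrix with per-model q-values, repeats the scan with ancestry
PCs as covariates, reruns the positive-control and bifidobacterial taxa
with the LCT genotype adjustment, fits the alpha-diversity models, and
runs the presence/absence chi-squared scan with twin-aware permutation
p-values. The injected secretor-associated OTU (and the collapsed groups
containing it) should surface in the secretor-contrast models (m5, m8,
m9) and the ABO-only models should stay clean; a single cohort
realization can additionally show sporadic chance associations, which is
exactly why the replicate-level calibration lives in the test suite.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import RESULTS, SEED

import pandas as pd

from twinbiome.genotypes import ancestry_pca, filter_variants, ld_prune
from twinbiome.io import read_metadata, read_vcf
from twinbiome.models import (alpha_models, bifido_lct_scan,
                              presence_absence_scan, run_taxa_scan)
from twinbiome.permutation import build_plan


def main() -> None:
    cohort = read_metadata(RESULTS / "phenotypes.tsv")
    residuals = pd.read_csv(RESULTS / "residuals_common_taxa.tsv",
                            sep="\t", index_col=0)
    coh = cohort.loc[residuals.index]
    abo, sec = coh["abo"], coh["secretor"]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scan = run_taxa_scan(residuals, coh, abo, sec)
    scan.drop(columns="estimates").to_csv(
        RESULTS / "taxa_scan_m1_m9.tsv", sep="\t", index=False)
    hits = scan[scan["q"] <= 0.1]
    print(f"m1-m9 scan: {residuals.shape[1]} taxa x 9 models; "
          f"{len(hits)} taxon-model pairs at q <= 0.1")
    if len(hits):
        print(hits[["taxon", "model", "p", "q"]].to_string(index=False))

    # ancestry adjustment: MAF/HWE filter, LD-prune, genotype PCA
    geno = read_vcf(RESULTS / "genotypes.vcf")
    bg = [s for s in geno.snp_ids if s.startswith("bg_")]
    dosage = geno.dosage(bg).loc[coh.index]
    kept = filter_variants(dosage, maf_min=0.05, hwe_p_min=0.001)
    pos = [geno.pos[geno.snp_index(s)] for s in kept]
    pruned = ld_prune(dosage[kept], pos)
    pcs = ancestry_pca(dosage[pruned], k=5)
    print(f"ancestry: {len(bg)} -> {len(kept)} post-QC -> {len(pruned)} "
          f"post-LD-prune SNPs; top 5 PCs explain "
          f"{100 * pcs.variance_fraction.sum():.1f}% of variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adj = run_taxa_scan(residuals, coh, abo, sec,
                            ancestry_pcs=pcs.coords)
    adj.drop(columns="estimates").to_csv(
        RESULTS / "taxa_scan_ancestry_adjusted.tsv", sep="\t", index=False)
    r2 = {}
    for m in scan["model"].unique():
        a = scan[scan["model"] == m].set_index("taxon")["p"]
        b = adj[adj["model"] == m].set_index("taxon")["p"]
        r2[m] = round(a.corr(b.loc[a.index]) ** 2, 3)
    print(f"p-value r^2 with vs without ancestry PCs per model: {r2}")

    # LCT-adjusted rerun on the positive-control taxon (standing in for
    # the bifidobacterial set) using the rs1446585 dosage
    lct = geno.dosage(["rs1446585"])["rs1446585"].loc[coh.index]
    target = hits["taxon"].iloc[0] if len(hits) else residuals.columns[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lct_scan = bifido_lct_scan(residuals[[target]], coh, abo, sec, lct)
    lct_scan.drop(columns="estimates").to_csv(
        RESULTS / "taxa_scan_lct_adjusted.tsv", sep="\t", index=False)
    m5 = lct_scan[lct_scan["model"] == "m5"]
    print(f"LCT-adjusted m5 on {target}: p = {float(m5['p'].iloc[0]):.2e}")

    # alpha-diversity models m1/m5/m6 + within-ABO-class secretor models
    ares = pd.read_csv(RESULTS / "alpha_residuals.tsv", sep="\t",
                       index_col=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        am = alpha_models(ares, coh.loc[ares.index], abo.loc[ares.index],
                          sec.loc[ares.index])
    am.to_csv(RESULTS / "alpha_models.tsv", sep="\t", index=False)
    sig = am[(am["p"] < 0.05) & am["p"].notna()]
    print(f"alpha-diversity models: {len(am)} fits, {len(sig)} with "
          "p < 0.05 (no multiplicity correction)")

    # presence/absence chi-squared with twin-aware permutations
    pa = pd.read_csv(RESULTS / "presence_absence.tsv", sep="\t",
                     index_col=0)
    plan = build_plan(coh.loc[pa.index], sec.loc[pa.index], seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pas = presence_absence_scan(pa, sec.loc[pa.index], plan,
                                    n_perm=500)
    pas.to_csv(RESULTS / "presence_absence_scan.tsv", sep="\t",
               index=False)
    print(f"presence/absence scan vs secretor: {len(pas)} OTUs, "
          f"{int((pas['q'] <= 0.1).sum())} at q <= 0.1")


if __name__ == "__main__":
    main()
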