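"""Replicate-level study drivers: null calibration, power, and
heritability-signature experiments on synthetic cohorts.

These functions run the full pipeline (simulate -> phenotype -> rarefy ->
residualize -> test) over replicate cohorts and return tidy result tables.
They are the workhorses behind the analysis scripts and the validation
suite. Problem sizes default to the cohort-scale study conditions; smaller
values are for quick exploration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .concordance import concordance_test, relatedness_test
from .config import EffectSpec, SimConfig
from .diversity import beta_diversity
from .genotypes import infer_phenotypes, resolve_abo
from .lmm import build_design, fit_lmm
from .models import run_taxa_scan
from .permutation import build_plan
from .simulate import generate_cohort, simulate_cohort
from .taxa import (prevalence_filter, rarefy, residualize,
                   technical_covariates)


def _derive_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0]
               % (2 ** 31))


def prepare_cohort(config: SimConfig, depth: int = 10000,
                   min_prevalence: float = 0.5):
    """Simulate one cohort and build the analysis-ready residual matrix.

    Returns (cohort-with-phenotypes, abo, secretor, rarefied table,
    residual matrix over common taxa).
    """
    sim = simulate_cohort(config)
    coh = infer_phenotypes(sim.cohort, sim.genotypes)
    rt = rarefy(sim.otu_table, depth=depth,
                seed=_derive_seed(config.seed, 11))
    coh = coh.loc[rt.sample_ids]
    common = prevalence_filter(rt, min_prevalence)
    res = residualize(rt.counts[common], technical_covariates(coh))
    return sim, coh, resolve_abo(coh), coh["secretor"], rt, res.values


def common_taxon_index(config: SimConfig, depth: int = 10000,
                       min_prevalence: float = 0.5) -> int:
    """Index of the most prevalent OTU of the matched no-effect cohort.

    Injecting an effect does not perturb the generator's random streams, so
    the same seed reproduces identical latents; this picks a taxon that is
    guaranteed common under that seed.
    """
    null_cfg = dataclasses.replace(config, effect_spec=[])
    sim = simulate_cohort(null_cfg)
    rt = rarefy(sim.otu_table, depth=depth,
                seed=_derive_seed(config.seed, 11))
    prev = (rt.counts > 0).mean(axis=0)
    taxon = prev.idxmax()
    return rt.counts.columns.get_loc(taxon)


def null_scan_replicates(n_replicates: int = 20, seed: int = 0,
                         config: SimConfig | None = None,
                         model_ids=None) -> pd.DataFrame:
    """m1-m9 LRT scans on replicate cohorts with zero phenotype effects.

    Returns the concatenated long result tables with a ``replicate``
    column; p-values should be uniform and q <= 0.1 discoveries rare.
    """
    if config is None:
        config = SimConfig()
    frames = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, effect_spec=[],
                                  seed=_derive_seed(seed, 1, r))
        _, coh, abo, sec, rt, res = prepare_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_taxa_scan(res, coh, abo, sec,
                                model_ids=model_ids or
                                tuple(f"m{i}" for i in range(1, 10)))
        out["replicate"] = r
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def secretor_power_replicates(effect_size: float = 0.5,
                              n_replicates: int = 20, seed: int = 0,
                              config: SimConfig | None = None,
                              q_threshold: float = 0.1) -> pd.DataFrame:
    """Detection of an injected secretor effect on one common OTU by the
    m5 scan.

    Returns one row per replicate with the target taxon's m5 p and q and
    a ``detected`` flag (q <= threshold).
    """
    if config is None:
        config = SimConfig()
    rows = []
    for r in range(n_replicates):
        rep_seed = _derive_seed(seed, 2, r)
        base = dataclasses.replace(config, effect_spec=[], seed=rep_seed)
        if effect_size != 0.0:
            taxon_idx = common_taxon_index(base)
            spec = [EffectSpec(taxon=taxon_idx, phenotype="secretor",
                               level="NS", size=effect_size)]
            cfg = dataclasses.replace(base, effect_spec=spec)
            sim, coh, abo, sec, rt, res = prepare_cohort(cfg)
        else:
            # a zero effect leaves the cohort identical to the base config,
            # so the target taxon can be read off the same realization
            cfg = base
            sim, coh, abo, sec, rt, res = prepare_cohort(cfg)
            prev = (rt.counts > 0).mean(axis=0)
            taxon_idx = rt.counts.columns.get_loc(prev.idxmax())
        target = sim.otu_table.counts.columns[taxon_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_taxa_scan(res, coh, abo, sec, model_ids=("m5",))
        row = out.set_index("taxon").loc[target]
        rows.append({"replicate": r, "taxon": target,
                     "p": float(row["p"]), "q": float(row["q"]),
                     "detected": bool(row["q"] <= q_threshold)})
    return pd.DataFrame(rows)


def variance_recovery_replicates(n_replicates: int = 20, seed: int = 0,
                                 n_mz_pairs: int = 500,
                                 n_dz_pairs: int = 500,
                                 sd_fam: float = 1.0, sd_mz: float = 1.0,
                                 sd_e: float = 1.0) -> pd.DataFrame:
    """Direct variance-component recovery of the twin LMM on data simulated
    from its own generative model."""
    rows = []
    for r in range(n_replicates):
        rng = np.random.default_rng(_derive_seed(seed, 3, r))
        cfg = SimConfig(n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs,
                        n_unrelated=0, seed=_derive_seed(seed, 4, r))
        coh = generate_cohort(cfg)
        n = len(coh)
        famc = coh.groupby("family_id", sort=False).ngroup().values
        mz_fam = pd.factorize(np.where(coh["zygosity"] == "MZ",
                                       coh["family_id"], coh.index))[0]
        y = (sd_fam * rng.normal(size=famc.max() + 1)[famc]
             + sd_mz * rng.normal(size=mz_fam.max() + 1)[mz_fam]
             + sd_e * rng.normal(size=n))
        design = build_design(coh)
        x = pd.DataFrame({"intercept": np.ones(n)}, index=coh.index)
        fit = fit_lmm(y, x, design)
        rows.append({"replicate": r,
                     "sd_fam": np.sqrt(fit.sigma2_fam),
                     "sd_mz": np.sqrt(fit.sigma2_mz),
                     "sd_e": np.sqrt(fit.sigma2_e)})
    return pd.DataFrame(rows)


def heritability_replicates(n_replicates: int = 20, seed: int = 0,
                            additive_sd: float = 1.0,
                            family_sd: float = 0.3,
                            n_mz_pairs: int = 315, n_dz_pairs: int = 314,
                            n_unrelated: int = 245, n_otus: int = 150,
                            n_perm: int = 200,
                            metric: str = "bray_curtis"
                            ) -> pd.DataFrame:
    """Twin-vs-unrelated and MZ-vs-DZ beta-diversity permutation tests on
    replicate cohorts; with additive genetic sharing both contrasts should
    reject, with none the MZ/DZ contrast should be null."""
    rows = []
    for r in range(n_replicates):
        cfg = SimConfig(n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs,
                        n_unrelated=n_unrelated, n_otus=n_otus,
                        additive_sd=additive_sd, family_sd=family_sd,
                        mean_depth=6000, n_background_snps=0,
                        seed=_derive_seed(seed, 5, r))
        sim = simulate_cohort(cfg)
        rt = rarefy(sim.otu_table, depth=3000,
                    seed=_derive_seed(cfg.seed, 11))
        coh = sim.cohort.loc[rt.sample_ids]
        dm = beta_diversity(rt, metric, sim.tree)
        tw = relatedness_test(dm, coh, "twin_vs_unrelated",
                              n_perm=n_perm, seed=_derive_seed(cfg.seed, 6))
        md = relatedness_test(dm, coh, "mz_vs_dz",
                              n_perm=n_perm, seed=_derive_seed(cfg.seed, 7))
        rows.append({
            "replicate": r,
            "twin_stat": tw["statistic"], "twin_p": tw["p"],
            "mzdz_stat": md["statistic"], "mzdz_p": md["p"],
            "mz_mean": md["means"]["mz_mean"],
            "dz_mean": md["means"]["dz_mean"],
            "unrelated_mean": md["means"]["unrelated_mean"],
        })
    return pd.DataFrame(rows)


def concordance_null_pvalues(n_replicates: int = 100, seed: int = 0,
                             n_mz_pairs: int = 30, n_dz_pairs: int = 30,
                             n_unrelated: int = 20, n_otus: int = 60,
                             n_perm: int = 200) -> np.ndarray:
    """Concordance-test permutation p-values on replicate cohorts where the
    phenotype does not influence the microbiome (calibration check)."""
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = SimConfig(n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs,
                        n_unrelated=n_unrelated, n_otus=n_otus,
                        mean_depth=3000, n_background_snps=0,
                        secretor_unknown_fraction=0.0,
                        seed=_derive_seed(seed, 8, r))
        sim = simulate_cohort(cfg)
        rt = rarefy(sim.otu_table, depth=1500,
                    seed=_derive_seed(cfg.seed, 11))
        coh = sim.cohort.loc[rt.sample_ids]
        dm = beta_diversity(rt, "bray_curtis")
        res = concordance_test(dm, coh, coh["secretor"], "all",
                               n_perm=n_perm,
                               seed=_derive_seed(cfg.seed, 9))
        ps[r] = res["p"]
    return ps


def dapc_null_pvalues(n_replicates: int = 100, seed: int = 0,
                      n_mz_pairs: int = 15, n_dz_pairs: int = 15,
                      n_unrelated: int = 10, n_features: int = 12,
                      n_perm: int = 50) -> np.ndarray:
    """DAPC cross-validation permutation p-values on replicate cohorts with
    labels independent of the features (calibration check)."""
    from .classify import dapc_cv

    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = SimConfig(n_mz_pairs=n_mz_pairs, n_dz_pairs=n_dz_pairs,
                        n_unrelated=n_unrelated, n_otus=max(n_features, 10),
                        mean_depth=1500, n_background_snps=0,
                        secretor_unknown_fraction=0.0,
                        seed=_derive_seed(seed, 10, r))
        sim = simulate_cohort(cfg)
        coh = infer_phenotypes(sim.cohort, sim.genotypes)
        rng = np.random.default_rng(_derive_seed(seed, 12, r))
        x = rng.normal(size=(len(coh), n_features))
        y = coh["secretor"]
        plan = build_plan(coh, y, n_permutations=n_perm,
                          seed=_derive_seed(cfg.seed, 13))
        cv = dapc_cv(x, y, k_folds=5, plan=plan, n_perm=n_perm,
                     seed=_derive_seed(cfg.seed, 14),
                     families=coh["family_id"].values,
                     pcs_grid=[3, 6], a_score_reps=2)
        ps[r] = cv.p
    return ps
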