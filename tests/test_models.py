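"""Association model specs, scans, and the presence/absence test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinbiome.models import (alpha_models, bifido_lct_scan,
                              model_fixed_effects, model_subset,
                              presence_absence_scan, run_taxa_scan)
from twinbiome.permutation import build_plan


@pytest.fixture(scope="module")
def scan_inputs(small_cohort, small_phenotypes, small_rarefied):
    from twinbiome.taxa import (prevalence_filter, residualize,
                                technical_covariates)
    abo, sec = small_phenotypes
    coh = small_cohort.loc[small_rarefied.sample_ids]
    common = prevalence_filter(small_rarefied, 0.5)
    res = residualize(small_rarefied.counts[common],
                      technical_covariates(coh))
    return coh, abo.loc[coh.index], sec.loc[coh.index], res.values


class TestModelSpecs:
    def test_m1_design_columns(self, scan_inputs):
        coh, abo, sec, _ = scan_inputs
        fx = model_fixed_effects("m1", abo, sec)
        assert list(fx.columns) == ["A", "AB", "B"]
        # baseline O rows are all-zero
        o_rows = fx.loc[abo.loc[fx.index] == "O"]
        assert (o_rows.values == 0).all()

    def test_m6_restricted_to_secretors(self, scan_inputs):
        coh, abo, sec, _ = scan_inputs
        idx = model_subset("m6", abo, sec)
        assert (sec.loc[idx] == "S").all()

    def test_m8_interaction_columns(self, scan_inputs):
        coh, abo, sec, _ = scan_inputs
        fx = model_fixed_effects("m8", abo, sec)
        assert list(fx.columns) == ["A", "AB", "B", "S", "S_x_A", "S_x_AB",
                                    "S_x_B"]
        assert (fx["S_x_B"] == fx["S"] * fx["B"]).all()

    def test_m1_and_m2_have_different_df(self, scan_inputs):
        coh, abo, sec, res = scan_inputs
        one = res.iloc[:, [0]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_taxa_scan(one, coh, abo, sec, model_ids=("m1", "m2"))
        df = out.set_index("model")["df"]
        assert df["m1"] == 3
        assert df["m2"] == 1


class TestTaxaScan:
    def test_full_scan_shape_and_q_range(self, scan_inputs):
        coh, abo, sec, res = scan_inputs
        sub = res.iloc[:, :6]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_taxa_scan(sub, coh, abo, sec)
        assert set(out["model"]) == {f"m{i}" for i in range(1, 10)}
        assert len(out) == 9 * 6
        ok = out["p"].notna()
        assert out.loc[ok, "p"].between(0, 1).all()
        assert out.loc[ok, "q"].between(0, 1).all()
        assert out.loc[ok, "q_global"].between(0, 1).all()

    def test_single_taxon_q_equals_p_bounded(self, scan_inputs):
        coh, abo, sec, res = scan_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_taxa_scan(res.iloc[:, [0]], coh, abo, sec,
                                model_ids=("m5",))
        assert len(out) == 1
        assert out["q"].iloc[0] <= 1.0

    def test_empty_taxon_set_rejected(self, scan_inputs):
        coh, abo, sec, res = scan_inputs
        with pytest.raises(ValueError, match="empty"):
            run_taxa_scan(res.iloc[:, :0], coh, abo, sec)

    def test_ancestry_pcs_barely_change_p_without_structure(self):
        # needs a larger cohort than the shared fixture: at small n the
        # five extra covariates genuinely perturb the per-taxon fits
        from twinbiome.config import SimConfig
        from twinbiome.genotypes import (ancestry_pca, infer_phenotypes,
                                         resolve_abo)
        from twinbiome.simulate import simulate_cohort
        from twinbiome.taxa import (prevalence_filter, rarefy, residualize,
                                    technical_covariates)
        cfg = SimConfig(n_mz_pairs=150, n_dz_pairs=150, n_unrelated=100,
                        n_otus=50, n_background_snps=120, mean_depth=3000,
                        seed=17)
        sim = simulate_cohort(cfg)
        coh = infer_phenotypes(sim.cohort, sim.genotypes)
        rt = rarefy(sim.otu_table, 1500, seed=1)
        coh = coh.loc[rt.sample_ids]
        abo, sec = resolve_abo(coh), coh["secretor"]
        res = residualize(rt.counts[prevalence_filter(rt, 0.5)],
                          technical_covariates(coh))
        bg = sim.genotypes.snp_ids[sim.genotypes.background_mask()]
        pcs = ancestry_pca(sim.genotypes.dosage(list(bg)), k=5)
        sub = res.values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = run_taxa_scan(sub, coh, abo, sec, model_ids=("m1", "m5"))
            adj = run_taxa_scan(sub, coh, abo, sec, model_ids=("m1", "m5"),
                                ancestry_pcs=pcs.coords)
        for model in ("m1", "m5"):
            a = plain[plain["model"] == model].set_index("taxon")["p"]
            b = adj[adj["model"] == model].set_index("taxon")["p"]
            r2 = np.corrcoef(a, b.loc[a.index])[0, 1] ** 2
            assert r2 > 0.9


class TestLctScan:
    def test_adjusted_scan_absorbs_genotype_effect(self, small_sim,
                                                   scan_inputs):
        coh, abo, sec, res = scan_inputs
        lct = small_sim.genotypes.dosage(["rs1446585"])["rs1446585"]
        lct = lct.loc[coh.index].astype(float)
        rng = np.random.default_rng(0)
        # a synthetic bifido-like taxon driven only by the LCT genotype
        y = pd.DataFrame(
            {"bifido": 0.8 * lct.values + rng.normal(size=len(coh))},
            index=coh.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj = bifido_lct_scan(y, coh, abo, sec, lct, model_ids=("m5",))
            naive = run_taxa_scan(y, coh, abo, sec, model_ids=("m5",))
        assert adj["p"].iloc[0] > 0.001  # no secretor signal remains
        # adjusted and unadjusted agree when the genotype effect is absent
        y0 = pd.DataFrame({"null": rng.normal(size=len(coh))},
                          index=coh.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = bifido_lct_scan(y0, coh, abo, sec, lct, model_ids=("m5",))
            b = run_taxa_scan(y0, coh, abo, sec, model_ids=("m5",))
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0], abs=0.1)

    def test_empty_taxa_rejected(self, scan_inputs, small_sim):
        coh, abo, sec, res = scan_inputs
        lct = small_sim.genotypes.dosage(["rs1446585"])["rs1446585"]
        with pytest.raises(ValueError, match="empty"):
            bifido_lct_scan(res.iloc[:, :0], coh, abo, sec, lct)


class TestAlphaModels:
    def test_smoke_and_structure(self, scan_inputs, small_sim):
        from twinbiome.diversity import alpha_diversity_all
        from twinbiome.taxa import residualize_values, technical_covariates
        coh, abo, sec, _ = scan_inputs
        alpha = alpha_diversity_all(
            small_sim.otu_table, small_sim.tree, n_rarefactions=2,
            depth=1000, seed=1).loc[coh.index]
        ares = residualize_values(alpha, technical_covariates(coh))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = alpha_models(ares, coh, abo, sec)
        assert set(out["model"]) >= {"m1", "m5", "m6"}
        base = out[out["model"].isin(["m1", "m5", "m6"])]
        assert len(base) == 5 * 3
        assert base["p"].between(0, 1).all()
        within = out[out["model"] == "within_class_secretor"]
        assert set(within["abo_class"]) <= {"A", "AB", "B", "O"}
        assert within["p"].dropna().between(0, 1).all()


class TestPresenceAbsence:
    @staticmethod
    def _plan_and_binary(n=100, m=20, p=0.4, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        coh = pd.DataFrame({
            "family_id": [f"f{i}" for i in range(n)],
            "zygosity": "singleton"}, index=idx)
        pheno = pd.Series(rng.choice(["S", "NS"], n), index=idx)
        binary = pd.DataFrame(rng.binomial(1, p, size=(n, m)), index=idx,
                              columns=[f"t{j}" for j in range(m)])
        plan = build_plan(coh, pheno, seed=seed)
        return coh, pheno, binary, plan

    def test_equal_proportions_give_zero_chi2(self):
        idx = [f"s{i}" for i in range(100)]
        coh = pd.DataFrame({"family_id": [f"f{i}" for i in range(100)],
                            "zygosity": "singleton"}, index=idx)
        pheno = pd.Series(["g1"] * 50 + ["g2"] * 50, index=idx)
        col = [1] * 30 + [0] * 20 + [1] * 30 + [0] * 20
        binary = pd.DataFrame({"t0": col}, index=idx)
        plan = build_plan(coh, pheno, seed=1)
        out = presence_absence_scan(binary, pheno, plan, n_perm=100)
        assert out["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["perm_p"].iloc[0] == 1.0

    def test_hand_computed_chi2(self):
        # present 40/50 vs 20/50 -> Pearson chi2 = 16.667 uncorrected
        idx = [f"s{i}" for i in range(100)]
        coh = pd.DataFrame({"family_id": [f"f{i}" for i in range(100)],
                            "zygosity": "singleton"}, index=idx)
        pheno = pd.Series(["g1"] * 50 + ["g2"] * 50, index=idx)
        col = [1] * 40 + [0] * 10 + [1] * 20 + [0] * 30
        binary = pd.DataFrame({"t0": col}, index=idx)
        plan = build_plan(coh, pheno, seed=2)
        out = presence_absence_scan(binary, pheno, plan, n_perm=10)
        assert out["chi2"].iloc[0] == pytest.approx(16.6667, abs=1e-3)
        oracle = stats.chi2_contingency(
            np.array([[40, 10], [20, 30]]), correction=False)[0]
        assert out["chi2"].iloc[0] == pytest.approx(oracle, abs=1e-10)

    def test_permutation_matches_analytic_on_unrelated(self):
        coh, pheno, binary, plan = self._plan_and_binary(n=1000, m=50,
                                                         seed=3)
        out = presence_absence_scan(binary, pheno, plan, n_perm=1000)
        gap = (out["perm_p"] - out["analytic_p"]).abs()
        assert (gap < 0.05).mean() > 0.9
        assert gap.mean() < 0.03

    def test_constant_otu_excluded(self):
        coh, pheno, binary, plan = self._plan_and_binary(seed=4)
        binary["t0"] = 1
        with pytest.warns(UserWarning, match="constant"):
            out = presence_absence_scan(binary, pheno, plan, n_perm=10)
        assert "t0" not in set(out["taxon"])
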