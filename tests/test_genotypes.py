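"""ABO/secretor calling, QC filters, LD pruning, and ancestry PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinbiome.config import SimConfig
from twinbiome.genotypes import (abo_phenotype, ancestry_pca,
                                 call_abo_alleles, call_secretor,
                                 concordance, default_haplotype_table,
                                 filter_variants, hwe_exact_p,
                                 infer_phenotypes, ld_prune, resolve_abo)
from twinbiome.io import read_vcf, write_vcf
from twinbiome.simulate import simulate_cohort


class TestAboCalling:
    def test_table_lookup(self):
        table = default_haplotype_table()
        assert call_abo_alleles("000", table) == "O"
        assert call_abo_alleles("100", table) == "A1"
        assert call_abo_alleles("110", table) == "unresolved"

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            call_abo_alleles("00", default_haplotype_table())

    @pytest.mark.parametrize("a1,a2,expected", [
        ("A1", "O", "A"), ("A2", "O", "A"), ("A1", "A2", "A"),
        ("A2", "B", "AB"), ("A1", "B", "AB"), ("B", "O", "B"),
        ("B", "B", "B"), ("O", "O", "O"),
    ])
    def test_dominance(self, a1, a2, expected):
        assert abo_phenotype(a1, a2) == expected

    def test_symmetric_in_arguments(self):
        for a1, a2 in itertools.product(("A1", "A2", "B", "O"), repeat=2):
            assert abo_phenotype(a1, a2) == abo_phenotype(a2, a1)

    def test_unresolved_input_rejected(self):
        with pytest.raises(ValueError, match="unresolved"):
            abo_phenotype("unresolved", "O")


class TestSecretor:
    @pytest.mark.parametrize("gt,expected", [
        ("AA", "NS"), ("GA", "S"), ("AG", "S"), ("GG", "S"),
        (None, "unknown"),
    ])
    def test_calls(self, gt, expected):
        assert call_secretor(gt) == expected

    def test_bad_allele(self):
        with pytest.raises(ValueError, match="alleles"):
            call_secretor("GT")


class TestConcordance:
    def test_identical(self):
        v = pd.Series(["A", "B", "O"])
        assert concordance(v, v.copy()) == 1.0

    def test_partial(self):
        typed = pd.Series(["A", "B", "O", "O"])
        inferred = pd.Series(["A", "B", "O", "A"])
        assert concordance(typed, inferred) == 0.75

    def test_missing_excluded(self):
        typed = pd.Series(["A", "missing", "O"])
        inferred = pd.Series(["A", "B", "missing"])
        assert concordance(typed, inferred) == 1.0

    def test_no_overlap(self):
        with pytest.raises(ValueError, match="no samples"):
            concordance(pd.Series(["missing"]), pd.Series(["A"]))


class TestRoundTrip:
    def test_vcf_phenotype_round_trip(self, tmp_path):
        """Noise-free synthetic VCF -> ABO/secretor calls equal truth."""
        cfg = SimConfig(n_mz_pairs=25, n_dz_pairs=25, n_unrelated=20,
                        n_otus=10, n_background_snps=20, mean_depth=500,
                        typing_error_rate=0.0, seed=42)
        sim = simulate_cohort(cfg)
        path = tmp_path / "geno.vcf"
        write_vcf(sim.genotypes, path)
        geno = read_vcf(path)
        coh = infer_phenotypes(sim.cohort, geno)
        assert (coh["abo_inferred"].values
                == sim.truth["abo_true"].values).all()
        known = ~sim.cohort["secretor_unknown"]
        assert (coh.loc[known, "secretor"].values
                == sim.truth.loc[known.values, "secretor_true"].values).all()
        assert concordance(coh["abo_typed"], coh["abo_inferred"]) == 1.0

    def test_corrupted_haplotype_dropped(self, tmp_path):
        cfg = SimConfig(n_mz_pairs=0, n_dz_pairs=0, n_unrelated=10,
                        n_otus=10, n_background_snps=5, mean_depth=500,
                        seed=1)
        sim = simulate_cohort(cfg)
        geno = sim.genotypes
        # corrupt sample 0: impossible double-tag haplotype (A1 and B)
        i007 = geno.snp_index("rs651007")
        i746 = geno.snp_index("rs8176746")
        geno.haplotypes[0, i007, 0] = 1
        geno.haplotypes[0, i746, 0] = 1
        coh = infer_phenotypes(sim.cohort, geno)
        assert coh["abo_inferred"].iloc[0] == "missing"
        assert (coh["abo_inferred"].iloc[1:] != "missing").all()

    def test_resolve_abo_prefers_inferred(self):
        coh = pd.DataFrame({
            "abo_typed": ["A", "B", "missing"],
            "abo_inferred": ["O", "missing", "missing"],
        }, index=["s1", "s2", "s3"])
        resolved = resolve_abo(coh)
        assert list(resolved) == ["O", "B", "missing"]


class TestVariantFilters:
    def test_low_maf_removed(self):
        rng = np.random.default_rng(0)
        common = rng.binomial(2, 0.3, size=500)
        rare = rng.binomial(2, 0.02, size=500)
        d = pd.DataFrame({"common": common, "rare": rare})
        kept = filter_variants(d, maf_min=0.05, hwe_p_min=0.001)
        assert kept == ["common"]

    def test_monomorphic_removed_not_error(self):
        d = pd.DataFrame({"mono": np.zeros(100, dtype=int)})
        assert filter_variants(d) == []

    def test_all_heterozygote_fails_hwe(self):
        # n=1000 all heterozygotes: wildly out of HWE
        assert hwe_exact_p(0, 1000, 0) < 1e-10
        d = pd.DataFrame({"het": np.ones(1000, dtype=int)})
        assert filter_variants(d, maf_min=0.05, hwe_p_min=0.001) == []

    def test_hwe_exact_matches_enumeration(self):
        # brute-force conditional distribution for a small table
        from math import comb
        n_ref, n_het, n_alt_hom = 18, 14, 8
        n = n_ref + n_het + n_alt_hom
        na = 2 * n_alt_hom + n_het

        def prob(het):
            hom_a = (na - het) // 2
            hom_r = n - het - hom_a
            return (comb(n, hom_r) * comb(n - hom_r, het) * 2 ** het
                    / comb(2 * n, na))
        hets = range(na % 2, min(na, 2 * n - na) + 1, 2)
        probs = {h: prob(h) for h in hets}
        z = sum(probs.values())
        p_obs = probs[n_het] / z
        expected = sum(v / z for v in probs.values()
                       if v / z <= p_obs * (1 + 1e-12))
        assert hwe_exact_p(n_ref, n_het, n_alt_hom) == pytest.approx(
            expected, rel=1e-10)

    def test_snp_in_hwe_retained(self):
        rng = np.random.default_rng(1)
        retained = 0
        for rep in range(50):
            g = rng.binomial(1, 0.3, size=(5000, 2)).sum(axis=1)
            d = pd.DataFrame({"snp": g})
            retained += filter_variants(d, 0.05, 0.001) == ["snp"]
        assert retained >= 49


def _brute_force_ld_prune(g, positions, window_kb, step_snps, r2_max):
    """Independent re-implementation of the documented greedy rule."""
    m = g.shape[1]
    p = g.mean(axis=0) / 2
    maf = np.minimum(p, 1 - p)
    kept = set(range(m))
    start = 0
    while start < m:
        window = [i for i in range(start, m)
                  if positions[i] < positions[start] + window_kb * 1000]
        while True:
            pair = None
            present = sorted(i for i in window if i in kept)
            for ai in range(len(present)):
                for bi in range(ai + 1, len(present)):
                    i, j = present[ai], present[bi]
                    si, sj = g[:, i].std(), g[:, j].std()
                    if si == 0 or sj == 0:
                        continue
                    r2 = np.corrcoef(g[:, i], g[:, j])[0, 1] ** 2
                    if r2 > r2_max:
                        pair = (i, j)
                        break
                if pair:
                    break
            if pair is None:
                break
            i, j = pair
            kept.discard(i if maf[i] < maf[j] else j)
        start += step_snps
    return sorted(kept)


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.4, size=200)
        d = pd.DataFrame({"s1": a, "s2": a,
                          "s3": rng.binomial(2, 0.4, size=200)})
        kept = ld_prune(d, np.array([100, 200, 300]), r2_max=0.2)
        assert len([k for k in kept if k in ("s1", "s2")]) == 1
        assert "s3" in kept

    def test_independent_snps_retained(self):
        rng = np.random.default_rng(3)
        d = pd.DataFrame(rng.binomial(2, 0.4, size=(2000, 10)),
                         columns=[f"s{i}" for i in range(10)])
        kept = ld_prune(d, np.arange(10) * 1000.0, r2_max=0.2)
        assert kept == list(d.columns)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        n, m = 150, 200
        base = rng.binomial(1, 0.5, size=(n, m // 4))
        # correlated blocks of 4
        g = np.repeat(base, 4, axis=1)
        flip = rng.random(size=g.shape) < 0.25
        g = np.abs(g - flip).astype(int) + rng.binomial(1, 0.3, size=g.shape)
        g = np.clip(g, 0, 2)
        positions = np.sort(rng.integers(0, 3_000_000, size=m)).astype(float)
        d = pd.DataFrame(g, columns=[f"s{i}" for i in range(m)])
        kept = ld_prune(d, positions, window_kb=1000, step_snps=50,
                        r2_max=0.2)
        oracle = _brute_force_ld_prune(g, positions, 1000, 50, 0.2)
        assert kept == [f"s{i}" for i in oracle]

    def test_no_retained_pair_violates_threshold(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(1, 0.5, size=(120, 15))
        g = np.repeat(base, 2, axis=1)[:, :30] + rng.binomial(
            1, 0.2, size=(120, 30))
        g = np.clip(g, 0, 2)
        d = pd.DataFrame(g, columns=[f"s{i}" for i in range(30)])
        positions = np.arange(30) * 10.0  # all in one window
        kept = ld_prune(d, positions, window_kb=1000, r2_max=0.2)
        cols = [d.columns.get_loc(k) for k in kept]
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                r2 = np.corrcoef(g[:, cols[a]], g[:, cols[b]])[0, 1] ** 2
                assert r2 <= 0.2 + 1e-12

    def test_unsorted_positions_rejected(self):
        d = pd.DataFrame({"a": [0, 1, 2], "b": [1, 1, 0]})
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(d, np.array([200.0, 100.0]))


class TestAncestryPca:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(8)
        n, m = 400, 300
        labels = np.repeat([0, 1], n // 2)
        p0 = rng.uniform(0.1, 0.5, size=m)
        shift = rng.normal(0, 0.8, size=m)
        logit = np.log(p0 / (1 - p0))
        p1 = 1 / (1 + np.exp(-(logit + shift)))
        freqs = np.where(labels[:, None] == 0, p0, p1)
        g = rng.binomial(2, freqs)
        pcs = ancestry_pca(pd.DataFrame(g), k=5)
        r = stats.pearsonr(pcs.coords["PC1"], labels.astype(float))[0]
        assert abs(r) > 0.9

    def test_variance_fractions_valid(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(rng.binomial(2, 0.3, size=(100, 40)))
        pcs = ancestry_pca(d, k=5)
        assert np.all(np.diff(pcs.variance_fraction) <= 1e-12)
        assert np.all((pcs.variance_fraction >= 0)
                      & (pcs.variance_fraction <= 1))

    def test_rank_one_matrix(self):
        g = np.outer(np.arange(10) % 3, np.ones(5)).astype(int)
        pcs = ancestry_pca(pd.DataFrame(g), k=1)
        assert pcs.variance_fraction[0] == pytest.approx(1.0)

    def test_k_exceeding_rank_rejected(self):
        g = np.outer(np.arange(10) % 3, np.ones(5)).astype(int)
        with pytest.raises(ValueError, match="rank"):
            ancestry_pca(pd.DataFrame(g), k=3)
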