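"""Rarefaction, filtering, collapsing, Box-Cox, and residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinbiome.otu import OtuTable
from twinbiome.taxa import (boxcox_transform, collapse_taxonomy,
                            presence_absence, prevalence_filter, rarefy,
                            residualize, residualize_values)


def make_table(counts, taxonomy=None, **kw):
    df = pd.DataFrame(counts,
                      index=[f"s{i}" for i in range(len(counts))])
    df.columns = [f"t{j}" for j in range(df.shape[1])]
    tax = pd.Series(taxonomy, index=df.columns) if taxonomy else None
    return OtuTable(df, tax, **kw)


class TestRarefy:
    def test_depth_reached_and_low_samples_dropped(self):
        t = make_table([[50, 60], [10, 5], [200, 300]])
        r = rarefy(t, depth=100, seed=0)
        assert list(r.counts.index) == ["s0", "s2"]
        assert (r.counts.sum(axis=1) == 100).all()

    def test_sample_exactly_at_depth_unchanged(self):
        t = make_table([[60, 40]])
        r = rarefy(t, depth=100, seed=0)
        assert list(r.counts.iloc[0]) == [60, 40]

    def test_hypergeometric_moments(self):
        # repeated rarefaction of [600, 400] to 100: mean first-taxon count
        # within 3 SEs of the hypergeometric expectation 60
        t = make_table([[600, 400]])
        draws = np.array([rarefy(t, 100, seed=s).counts.iloc[0, 0]
                          for s in range(2000)])
        var = 100 * 0.6 * 0.4 * (1000 - 100) / (1000 - 1)
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - 60) < 3 * se

    def test_absent_taxon_stays_absent(self):
        t = make_table([[500, 0, 500]])
        r = rarefy(t, depth=200, seed=3)
        assert r.counts.iloc[0, 1] == 0

    def test_all_samples_too_shallow(self):
        t = make_table([[5, 5]])
        with pytest.raises(ValueError, match="below"):
            rarefy(t, depth=100)

    def test_deterministic(self):
        t = make_table([[300, 500, 200], [900, 50, 60]])
        a = rarefy(t, 100, seed=9).counts
        b = rarefy(t, 100, seed=9).counts
        pd.testing.assert_frame_equal(a, b)


class TestPrevalenceFilter:
    def test_threshold_is_ceiling(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:49, 0] = 1   # present in 49 of 100 -> below ceil(50)
        counts[:, 1] = 1
        t = make_table(counts)
        assert prevalence_filter(t, 0.5) == ["t1"]

    def test_everywhere_present_always_retained(self):
        t = make_table(np.ones((10, 3), dtype=int))
        assert prevalence_filter(t, 1.0) == ["t0", "t1", "t2"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        counts = rng.binomial(1, 0.2, size=(10, 30)) * rng.integers(
            1, 10, size=(10, 30))
        t = make_table(counts)
        got = prevalence_filter(t, 0.1)
        need = int(np.ceil(0.1 * 10))
        expected = [f"t{j}" for j in range(30)
                    if (counts[:, j] > 0).sum() >= need]
        assert got == expected

    def test_reference_sample_subset(self):
        counts = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        t = make_table(counts)
        assert prevalence_filter(t, 0.5, ["s0", "s1"]) == ["t0"]


class TestCollapse:
    def test_totals_conserved_at_every_rank(self, small_sim):
        from twinbiome.taxa import collapse_all_ranks
        totals = small_sim.otu_table.counts.sum(axis=1)
        for rank, collapsed in collapse_all_ranks(
                small_sim.otu_table).items():
            assert (collapsed.counts.sum(axis=1) == totals).all(), rank

    def test_matches_groupby_oracle(self):
        tax = ["k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1",
               "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G2",
               "k__Bacteria;p__P2;c__C2;o__O2;f__F2;g__G3"]
        counts = np.array([[5, 7, 11], [2, 3, 4]])
        t = make_table(counts, taxonomy=tax)
        got = collapse_taxonomy(t, "genus").counts
        assert got["g__G1"].tolist() == [5, 2]
        phylum = collapse_taxonomy(t, "phylum").counts
        assert phylum["p__P1"].tolist() == [12, 5]
        assert phylum["p__P2"].tolist() == [11, 4]

    def test_unassigned_grouped_under_parent(self):
        tax = ["k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__",
               "k__Bacteria;p__P1;c__C1;o__O1;f__F1;g__G1"]
        t = make_table([[3, 4]], taxonomy=tax)
        got = collapse_taxonomy(t, "genus").counts
        assert set(got.columns) == {"unclassified-f__F1", "g__G1"}

    def test_unknown_rank(self):
        t = make_table([[1]], taxonomy=["k__Bacteria;p__P1"])
        with pytest.raises(ValueError, match="rank"):
            collapse_taxonomy(t, "kingdom")


class TestBoxCox:
    def test_zero_maps_to_zero(self):
        lam, ty = boxcox_transform(np.array([0, 1, 2, 5, 9, 3, 7]))
        assert ty[0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_half(self):
        # (4^0.5 - 1) / 0.5 = 2 for y=3 with offset 1
        y = np.array([3.0])
        assert ((y + 1) ** 0.5 - 1) / 0.5 == pytest.approx(2.0)

    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(1)
        y = np.exp(rng.normal(2.0, 0.5, size=5000)) - 1
        lam, _ = boxcox_transform(y)
        assert abs(lam) < 0.1

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 3.0, size=400)
        lam, _ = boxcox_transform(y)
        grid = np.linspace(-2, 2, 4001)
        ll = [stats.boxcox_llf(g, y + 1.0) for g in grid]
        assert abs(lam - grid[int(np.argmax(ll))]) < 2e-3

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox_transform(np.full(10, 3.0))


class TestResidualize:
    @staticmethod
    def _covariates(n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "age": rng.normal(60, 10, n),
            "sex": rng.choice(["F", "M"], n),
            "depth": rng.integers(5000, 20000, n).astype(float),
        }, index=[f"s{i}" for i in range(n)])

    def test_residuals_orthogonal_to_covariates(self):
        n = 200
        cov = self._covariates(n)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(20, size=(n, 4)), index=cov.index,
            columns=list("abcd"))
        res = residualize(counts, cov)
        for col in res.values.columns:
            for cv in ("age", "depth"):
                r = np.corrcoef(res.values[col], cov[cv])[0, 1]
                assert abs(r) < 1e-8

    def test_projection_idempotent(self):
        n = 150
        cov = self._covariates(n, seed=3)
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(n, 3)), index=cov.index)
        once = residualize_values(mat, cov)
        twice = residualize_values(once, cov)
        assert np.abs(once.values - twice.values).max() < 1e-10

    def test_known_signal_removed(self):
        n = 1000
        cov = self._covariates(n, seed=4)
        rng = np.random.default_rng(104)
        noise = rng.normal(0, 1.0, n)
        y = pd.DataFrame({"y": 2.0 * cov["age"] + noise}, index=cov.index)
        res = residualize_values(y, cov)
        assert res["y"].var() == pytest.approx(noise.var(), rel=0.05)

    def test_collinear_design_names_columns(self):
        n = 50
        cov = self._covariates(n, seed=5)
        cov["age_copy"] = cov["age"]
        mat = pd.DataFrame(np.ones((n, 1)), index=cov.index)
        with pytest.raises(ValueError, match="age_copy"):
            residualize_values(mat, cov)


class TestPresenceAbsence:
    def test_binary_and_idempotent(self):
        t = make_table([[0, 3], [2, 0]])
        b = presence_absence(t)
        assert b.values.tolist() == [[0, 1], [1, 0]]
        t2 = OtuTable(b.astype(np.int64))
        assert (presence_absence(t2).values == b.values).all()

    def test_column_sums_equal_prevalence(self):
        rng = np.random.default_rng(6)
        counts = rng.binomial(1, 0.3, size=(20, 10)) * rng.integers(
            1, 5, size=(20, 10))
        t = make_table(counts)
        b = presence_absence(t)
        assert (b.sum(axis=0).values == (counts > 0).sum(axis=0)).all()
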