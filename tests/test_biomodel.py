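"""Bio-model: design structures, covariance rules, REML correctness."""

import math

import numpy as np
import pytest

import diallelkit as dk
from diallelkit._reml import REMLError, RandomTerm, reml_core
from diallelkit.biomodel import (BIOMODEL_TERMS, build_design,
                                 cross_covariance, lrt_component,
                                 mom_components, partition_summary)
from diallelkit.datatypes import VialRecord
from tests.conftest import make_tiny_dataset

VC = dk.VarianceComponents(sigma2_f=1.3, sigma2_m=0.7, sigma2_fm=0.41,
                           sigma2_n=0.29, sigma2_nn=0.17, sigma2_e=2.0)


def rec(f, m, rep=1):
    return VialRecord(f, m, rep, 0, 0)


class TestCrossCovariance:
    """The five relative-class covariances identify the components."""

    @pytest.mark.parametrize("a,b,expected", [
        # full sibs: replicate vials of the same ordered cross
        (rec("A", "B", 1), rec("A", "B", 2),
         VC.sigma2_f + VC.sigma2_m + VC.sigma2_fm + 2 * VC.sigma2_n
         + VC.sigma2_nn),
        # reciprocal full sibs
        (rec("A", "B"), rec("B", "A"), 2 * VC.sigma2_n + VC.sigma2_nn),
        # maternal half sibs
        (rec("A", "B"), rec("A", "C"), VC.sigma2_f + VC.sigma2_n),
        # paternal half sibs
        (rec("A", "B"), rec("C", "B"), VC.sigma2_m + VC.sigma2_n),
        # reciprocal half sibs
        (rec("A", "B"), rec("C", "A"), VC.sigma2_n),
        # unrelated
        (rec("A", "B"), rec("C", "D"), 0.0),
    ])
    def test_relative_classes(self, a, b, expected):
        assert cross_covariance(a, b, VC) == pytest.approx(expected)

    def test_same_vial_adds_residual(self):
        a = rec("A", "B", 1)
        full_sib = cross_covariance(a, rec("A", "B", 2), VC)
        assert cross_covariance(a, a, VC) == pytest.approx(
            full_sib + VC.sigma2_e)

    def test_self_cross_doubles_nuclear(self):
        # replicate vials of a self-cross share 4 sigma_n^2
        a, b = rec("A", "A", 1), rec("A", "A", 2)
        expected = (VC.sigma2_f + VC.sigma2_m + VC.sigma2_fm
                    + 4 * VC.sigma2_n + VC.sigma2_nn)
        assert cross_covariance(a, b, VC) == pytest.approx(expected)


class TestBuildDesign:
    def test_two_line_structures(self):
        _, _, ds = make_tiny_dataset(n_lines=2, n_reps=1, seed=0)
        design = build_design(ds)
        Zn = design.Z["n"].toarray()
        # rows follow the dataset; collect as a set of tuples
        assert sorted(map(tuple, Zn)) == [(0.0, 2.0), (1.0, 1.0),
                                          (1.0, 1.0), (2.0, 0.0)]
        assert design.Z["fm"].shape[1] == 4
        assert design.Z["nn"].shape[1] == 3

    def test_row_sums(self):
        _, _, ds = make_tiny_dataset(n_lines=4, n_reps=2, seed=1)
        design = build_design(ds)
        for name, mult in (("f", 1), ("m", 1), ("fm", 1), ("nn", 1), ("n", 2)):
            sums = np.asarray(design.Z[name].sum(axis=1)).ravel()
            np.testing.assert_array_equal(sums, mult)

    def test_fifty_line_fm_columns(self, paper_sim_seed1):
        _, _, _, ds = paper_sim_seed1
        design = build_design(ds)
        assert design.Z["fm"].shape[1] == 2500


class TestREML:
    def test_single_component_recovery(self):
        _, _, ds = make_tiny_dataset(n_lines=20, n_reps=2, seed=12,
                                     sigma2_f=100.0, sigma2_m=0.0,
                                     sigma2_fm=0.0, sigma2_n=0.0,
                                     sigma2_nn=0.0, sigma2_e=25.0)
        vc = dk.fit_biomodel(ds)
        mom = mom_components(ds)
        # REML and method-of-moments agree on the dominant component
        assert vc.sigma2_f == pytest.approx(mom["f"], rel=0.35, abs=10)
        assert abs(vc.sigma2_f - 100.0) < 60.0
        assert vc.sigma2_e == pytest.approx(25.0, rel=0.3)
        assert vc.sigma2_m < 15.0 and vc.sigma2_fm < 15.0

    def test_constant_phenotype(self):
        _, _, ds = make_tiny_dataset(n_lines=3, n_reps=2, seed=0)
        ds.df["n_female"] = 25
        ds.df["n_male"] = 25
        ds.df["total"] = 50
        vc = dk.fit_biomodel(dk.DiallelDataset(ds.df))
        assert vc.sigma2_g < 1e-6
        assert vc.beta[0] == pytest.approx(50.0, abs=1e-6)

    def test_one_way_closed_form(self):
        # balanced one-way ANOVA: REML equals the mean-square estimators
        rng = np.random.default_rng(5)
        k, r = 12, 4
        y = np.repeat(rng.normal(0, 3, k), r) + rng.normal(0, 1.5, k * r)
        df = {
            "female_line": np.repeat([f"L{i}" for i in range(k)], r),
            "male_line": np.repeat([f"L{i}" for i in range(k)], r),
            "replicate": np.tile(np.arange(1, r + 1), k),
            "n_female": np.maximum(np.round(y).astype(int), 0),
            "n_male": 0,
        }
        import pandas as pd
        ds = dk.DiallelDataset(pd.DataFrame(df))
        fit = dk.total_genetic_model(ds)
        yy = ds.df["total"].to_numpy(float)
        gm = yy.reshape(k, r).mean(axis=1)
        msb = r * np.var(gm, ddof=1)
        msw = float(np.sum((yy.reshape(k, r) - gm[:, None]) ** 2) / (k * (r - 1)))
        assert fit.sigma2_e == pytest.approx(msw, rel=1e-4)
        assert fit.sigma2_cross == pytest.approx(max((msb - msw) / r, 0.0),
                                                 rel=1e-4, abs=1e-6)

    def test_no_replicates_raises(self):
        _, _, ds = make_tiny_dataset(n_lines=3, n_reps=1, seed=2)
        with pytest.raises(REMLError, match="replicat"):
            dk.total_genetic_model(ds)

    def test_reduction_identity(self):
        # collapsed fast path and full-data path reach the same optimum
        _, _, ds = make_tiny_dataset(n_lines=5, n_reps=3, seed=7)
        design = build_design(ds)
        y = ds.phenotype()
        start = mom_components(ds)
        fast = reml_core(y, design.X, design.incidence(),
                         groups=design.groups, start=start)
        slow = reml_core(y, design.X, design.incidence(),
                         groups=None, start=start)
        assert fast.loglik == pytest.approx(slow.loglik, abs=1e-4)
        for name in ("f", "m", "fm", "n", "nn", "residual"):
            assert fast.variances[name] == pytest.approx(
                slow.variances[name], rel=0.02, abs=0.5)

    def test_permutation_invariance(self):
        _, _, ds = make_tiny_dataset(n_lines=5, n_reps=2, seed=3)
        vc1 = dk.fit_biomodel(ds)
        relabel = {l: f"Q{9 - i}" for i, l in enumerate(ds.lines)}
        df = ds.df.copy()
        df["female_line"] = df["female_line"].map(relabel)
        df["male_line"] = df["male_line"].map(relabel)
        vc2 = dk.fit_biomodel(dk.DiallelDataset(df))
        for name in ("sigma2_f", "sigma2_m", "sigma2_fm", "sigma2_n",
                     "sigma2_nn", "sigma2_e"):
            assert getattr(vc1, name) == pytest.approx(
                getattr(vc2, name), rel=1e-4, abs=1e-5)

    def test_likelihood_monotone_over_accepted_steps(self):
        _, _, ds = make_tiny_dataset(n_lines=6, n_reps=3, seed=8)
        vc = dk.fit_biomodel(ds)
        traj = vc.trajectory
        assert len(traj) >= 1
        assert all(b - a > -1e-5 for a, b in zip(traj, traj[1:]))

    def test_deterministic_fit(self):
        _, _, ds = make_tiny_dataset(n_lines=5, n_reps=2, seed=3)
        a = dk.fit_biomodel(ds)
        b = dk.fit_biomodel(ds)
        assert a.as_dict() == b.as_dict()


class TestPartition:
    def test_share_arithmetic(self):
        vc = dk.VarianceComponents(sigma2_f=85.0, sigma2_m=5.0, sigma2_fm=5.0,
                                   sigma2_n=1.0, sigma2_nn=3.0, sigma2_e=100.0)
        tab = partition_summary(vc).set_index("component")
        assert vc.sigma2_g == pytest.approx(100.0)
        assert tab.loc["female_extranuclear", "pct_genetic"] == pytest.approx(85.0)
        assert tab.loc["nuclear", "variance"] == pytest.approx(2.0)
        assert tab["pct_phenotypic"].sum() == pytest.approx(100.0)
        genetic = tab["pct_genetic"].dropna().sum()
        assert genetic == pytest.approx(100.0)

    def test_zero_variance_errors(self):
        vc = dk.VarianceComponents(0, 0, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            partition_summary(vc)


class TestLRT:
    def test_dominant_component_significant_and_nonneg(self):
        _, _, ds = make_tiny_dataset(n_lines=15, n_reps=2, seed=21,
                                     sigma2_f=200.0, sigma2_m=1.0,
                                     sigma2_fm=1.0, sigma2_n=0.5,
                                     sigma2_nn=0.5, sigma2_e=20.0)
        design = build_design(ds)
        y = ds.phenotype()
        full = dk.reml_fit(design, y, start=mom_components(ds))
        test_f = lrt_component(design, y, full, "f")
        assert test_f.lrt >= 0.0
        assert test_f.p_value < 1e-6
        test_nn = lrt_component(design, y, full, "nn")
        assert test_nn.lrt >= -1e-8
        assert test_nn.p_value > 0.01
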