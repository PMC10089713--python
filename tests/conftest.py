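import numpy as np
import pandas as pd
import pytest

import diallelkit as dk
from diallelkit import gwas
from diallelkit.datatypes import DiallelDataset, LinePanel, TrueParameters


def make_tiny_dataset(n_lines=3, n_reps=2, seed=0, **truth_kw):
    """Small complete diallel with mild variance structure."""
    truth = TrueParameters(
        mu=truth_kw.pop("mu", 100.0),
        sigma2_f=truth_kw.pop("sigma2_f", 50.0),
        sigma2_m=truth_kw.pop("sigma2_m", 10.0),
        sigma2_fm=truth_kw.pop("sigma2_fm", 5.0),
        sigma2_n=truth_kw.pop("sigma2_n", 2.0),
        sigma2_nn=truth_kw.pop("sigma2_nn", 3.0),
        sigma2_e=truth_kw.pop("sigma2_e", 25.0),
        **truth_kw,
    )
    panel = dk.make_panel(n_lines, 0.5, seed=seed)
    ds = dk.simulate_diallel(panel, None, truth, n_reps=n_reps, seed=seed)
    return panel, truth, ds


@pytest.fixture
def tiny():
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def paper_sim_seed1():
    """One paper-like replicate, shared across structural tests."""
    return dk.simulate_paper_like(seed=1)


@pytest.fixture(scope="session")
def recovery_study():
    """The 20-seed paper-like recovery study.

    Simulates seeds 1..20 of the preset, runs infection adjustment, the
    one-way genetic model, the bio-model REML fit, the causal-variant
    regression and the mediation analysis, and collects the estimates
    that the acceptance criteria check.  Expensive (several minutes);
    session-scoped so every criterion shares the same fits.
    """
    out = {k: [] for k in
           ("cv", "genetic_share", "female_share_g", "female_share_p",
            "eff_female", "eff_male01", "a_hat", "var_explained",
            "prop_mediated", "acme_identity")}
    for seed in range(1, 21):
        panel, geno, truth, ds = dk.simulate_paper_like(seed=seed)
        tot = ds.df["total"]
        out["cv"].append(100.0 * tot.std() / tot.mean())
        eff = dk.fit_infection_model(ds, panel)
        out["eff_female"].append(eff.cell_effects[(1, 0)])
        out["eff_male01"].append(eff.cell_effects[(0, 1)])
        adj = dk.adjust_productivity(ds, eff, panel)
        one = dk.total_genetic_model(adj)
        out["genetic_share"].append(100.0 * one.genetic_share)
        vc = dk.fit_biomodel(adj)
        out["female_share_g"].append(100.0 * vc.genetic_shares()["f"])
        out["female_share_p"].append(100.0 * vc.sigma2_f / vc.sigma2_p)
        lm = gwas.female_line_means(adj)
        row = gwas.variant_regression(lm, geno.calls[truth.causal.variant_id])
        out["a_hat"].append(row.effect)
        s2g = gwas.linemean_genetic_variance(vc, ds.n_lines)
        out["var_explained"].append(100.0 * gwas.variance_explained(row, s2g))
        med = dk.fit_mediation(geno.calls[truth.causal.variant_id],
                               panel.expression, lm.means, seed=seed)
        out["prop_mediated"].append(100.0 * med.prop_mediated)
        out["acme_identity"].append(med.acme + med.ade - med.total_effect)
    return out
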