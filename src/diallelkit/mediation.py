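"""Linear causal mediation of a variant effect through gene expression.

Two linear models are fitted to line-level data:

    mediator:  M_i = alpha0 + alpha1 * G_i + e_i
    outcome:   Y_i = beta0  + beta1 * G_i + beta2 * M_i + u_i

Without a treatment-mediator interaction the average causal mediation
effect (ACME) is the coefficient product ``alpha1 * beta2``, the average
direct effect (ADE) is ``beta1`` and the total effect is their sum, so
``ACME + ADE = total`` holds exactly at the point estimates.
Uncertainty comes from quasi-Bayesian resampling: coefficients are drawn
from the multivariate-normal sampling distributions of the two fits and
the effects recomputed per draw (a nonparametric bootstrap is available
as an alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MediationResult", "fit_mediation"]


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: Optional[float]
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    prop_ci: tuple
    acme_p: float
    ade_p: float
    total_p: float
    n: int
    n_resamples: int
    seed: int
    method: str = "quasi-bayesian"

    def to_json(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _resample_p(draws: np.ndarray) -> float:
    """Two-sided p-value from the resample distribution of an effect."""
    pos = float(np.mean(draws > 0.0))
    neg = float(np.mean(draws < 0.0))
    return min(1.0, 2.0 * min(pos, neg) + float(np.mean(draws == 0.0)))


def fit_mediation(genotype: pd.Series, mediator: pd.Series,
                  outcome: pd.Series, n_resamples: int = 1000,
                  seed: int = 0, ci_level: float = 0.95,
                  method: str = "quasi-bayesian") -> MediationResult:
    """Partition a variant's effect into mediated and direct parts.

    Parameters
    ----------
    genotype, mediator, outcome
        Per-line values aligned by index; rows with any missing value
        are dropped (complete-case).
    n_resamples, seed
        Resampling effort and RNG seed; the seed is required for
        reproducible intervals.
    method
        ``"quasi-bayesian"`` (coefficient resampling, default) or
        ``"bootstrap"`` (nonparametric case resampling).
    """
    df = pd.DataFrame({
        "g": pd.Series(genotype),
        "m": pd.Series(mediator).reindex(pd.Series(genotype).index),
        "y": pd.Series(outcome).reindex(pd.Series(genotype).index),
    }).dropna()
    n = len(df)
    if n < 10:
        raise ValueError("need at least 10 complete (G, M, Y) triples")
    if df["g"].nunique() < 2:
        raise ValueError("genotype is monomorphic")

    Xm = sm.add_constant(df["g"].to_numpy())
    med_fit = sm.OLS(df["m"].to_numpy(), Xm).fit()
    Xy = sm.add_constant(np.column_stack([df["g"], df["m"]]))
    out_fit = sm.OLS(df["y"].to_numpy(), Xy).fit()

    alpha1 = float(med_fit.params[1])
    beta1 = float(out_fit.params[1])
    beta2 = float(out_fit.params[2])
    acme = alpha1 * beta2
    ade = beta1
    total = acme + ade
    prop = acme / total if total != 0.0 else None

    rng = np.random.default_rng(seed)
    if method == "quasi-bayesian":
        med_draws = rng.multivariate_normal(med_fit.params,
                                            med_fit.cov_params(),
                                            size=n_resamples)
        out_draws = rng.multivariate_normal(out_fit.params,
                                            out_fit.cov_params(),
                                            size=n_resamples)
        acme_d = med_draws[:, 1] * out_draws[:, 2]
        ade_d = out_draws[:, 1]
    elif method == "bootstrap":
        acme_d = np.empty(n_resamples)
        ade_d = np.empty(n_resamples)
        g = df["g"].to_numpy()
        m_ = df["m"].to_numpy()
        y_ = df["y"].to_numpy()
        filled = 0
        while filled < n_resamples:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(g[idx])) < 2:
                continue
            a = sm.OLS(m_[idx], sm.add_constant(g[idx])).fit()
            b = sm.OLS(y_[idx], sm.add_constant(
                np.column_stack([g[idx], m_[idx]]))).fit()
            acme_d[filled] = a.params[1] * b.params[2]
            ade_d[filled] = b.params[1]
            filled += 1
    else:
        raise ValueError("method must be 'quasi-bayesian' or 'bootstrap'")

    total_d = acme_d + ade_d
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(total_d != 0.0, acme_d / total_d, np.nan)
    lo, hi = 50.0 * (1.0 - ci_level), 50.0 * (1.0 + ci_level)

    def ci(d):
        return (float(np.nanpercentile(d, lo)), float(np.nanpercentile(d, hi)))

    return MediationResult(
        acme=acme, ade=ade, total_effect=total, prop_mediated=prop,
        acme_ci=ci(acme_d), ade_ci=ci(ade_d), total_ci=ci(total_d),
        prop_ci=ci(prop_d),
        acme_p=_resample_p(acme_d), ade_p=_resample_p(ade_d),
        total_p=_resample_p(total_d),
        n=n, n_resamples=n_resamples, seed=seed, method=method,
    )
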