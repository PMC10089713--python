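"""Wolbachia adjustment, sex-ratio and inbreeding checks.

Wolbachia is a heritable intracellular symbiont; infection of either
parent can depress productivity.  Infection status is a property of the
line, so its effect is estimated with female and male parental status
(and their interaction) as fixed effects while line identities enter as
random effects nested in status — otherwise line-level genetic variance
would masquerade as an infection effect.  Phenotypes are then adjusted
by subtracting the estimated cell effects before any genetic analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binomtest, norm

from ._reml import REMLOptions, RandomTerm, reml_core
from .biomodel import fit_biomodel
from .datatypes import INFECTION_CELLS, DiallelDataset, LinePanel

__all__ = ["InfectionEffects", "SexRatioResult", "InbreedingContrast",
           "fit_infection_model", "adjust_productivity", "sex_ratio_test",
           "inbreeding_contrast"]


@dataclass
class InfectionEffects:
    """Estimated productivity deviations of the four infection cells.

    ``cell_effects`` maps (female_infected, male_infected) to the mean
    deviation in flies relative to the uninfected x uninfected cell,
    which is anchored at exactly zero.
    """

    cell_effects: dict
    cell_se: dict
    tests: dict                  # 'female' / 'male' / 'interaction' -> (est, se, p)
    method: str = "model"
    variances: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "cells": [
                {"female_infected": k[0], "male_infected": k[1],
                 "effect": self.cell_effects[k], "se": self.cell_se[k]}
                for k in INFECTION_CELLS
            ],
            "tests": {k: {"estimate": v[0], "se": v[1], "p_value": v[2]}
                      for k, v in self.tests.items()},
            "method": self.method,
            "variances": self.variances,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def fit_infection_model(dataset: DiallelDataset, panel: LinePanel,
                        method: str = "model",
                        options: Optional[REMLOptions] = None) -> InfectionEffects:
    """Estimate infection-cell effects on productivity.

    ``method="model"`` (default) fits, by REML, a mixed model with
    female status, male status and their interaction as fixed effects
    and female line and male line as random effects (lines are nested
    in status: each line has one status).  ``method="cellmeans"``
    returns raw cell-mean differences instead.
    """
    df = dataset.df
    status = panel.infection_status()
    unknown = (set(df["female_line"]) | set(df["male_line"])) - set(status.index)
    if unknown:
        raise ValueError(f"lines with unknown infection status: {sorted(unknown)[:5]}")
    if status.nunique() < 2:
        raise ValueError("all lines share one infection status; "
                         "infection effects are not estimable")
    wf = status.loc[df["female_line"]].to_numpy()
    wm = status.loc[df["male_line"]].to_numpy()
    y = dataset.phenotype()

    if method == "cellmeans":
        base = y[(wf == 0) & (wm == 0)]
        effects, ses = {}, {}
        for cell in INFECTION_CELLS:
            sel = y[(wf == cell[0]) & (wm == cell[1])]
            if cell == (0, 0):
                effects[cell], ses[cell] = 0.0, 0.0
                continue
            effects[cell] = float(sel.mean() - base.mean())
            ses[cell] = float(math.sqrt(sel.var(ddof=1) / len(sel)
                                        + base.var(ddof=1) / len(base)))
        return InfectionEffects(cell_effects=effects, cell_se=ses, tests={},
                                method="cellmeans")
    if method != "model":
        raise ValueError("method must be 'model' or 'cellmeans'")

    lines = dataset.lines
    idx = {l: i for i, l in enumerate(lines)}
    n_obs = len(df)
    rows = np.arange(n_obs)
    Z_f = sp.csr_matrix((np.ones(n_obs),
                         (rows, df["female_line"].map(idx).to_numpy())),
                        shape=(n_obs, len(lines)))
    Z_m = sp.csr_matrix((np.ones(n_obs),
                         (rows, df["male_line"].map(idx).to_numpy())),
                        shape=(n_obs, len(lines)))
    X = np.column_stack([np.ones(n_obs), wf, wm, wf * wm]).astype(float)
    groups = pd.factorize(df["female_line"] + "\x00" + df["male_line"])[0]
    res = reml_core(y, X, [RandomTerm("f", Z_f), RandomTerm("m", Z_m)],
                    groups=groups, options=options,
                    fixed_names=["intercept", "female_infected",
                                 "male_infected", "interaction"])
    beta, cov = res.beta, res.beta_cov

    def cell(fi, mi):
        c = np.array([0.0, fi, mi, fi * mi])
        return float(c @ beta), float(math.sqrt(c @ cov @ c))

    effects, ses = {}, {}
    for cl in INFECTION_CELLS:
        effects[cl], ses[cl] = cell(*cl)
    tests = {}
    for name, j in (("female", 1), ("male", 2), ("interaction", 3)):
        est, se = float(beta[j]), float(math.sqrt(cov[j, j]))
        p = 2.0 * float(norm.sf(abs(est) / se)) if se > 0 else math.nan
        tests[name] = (est, se, p)
    return InfectionEffects(cell_effects=effects, cell_se=ses, tests=tests,
                            method="model", variances=res.variances)


def adjust_productivity(dataset: DiallelDataset, effects: InfectionEffects,
                        panel: LinePanel) -> DiallelDataset:
    """Subtract estimated infection-cell effects from each vial total.

    Baseline-cell vials are unchanged; adjusted values are real-valued
    (no re-rounding) and stored in ``total_adjusted``.
    """
    status = panel.infection_status()
    df = dataset.df.copy()
    unknown = (set(df["female_line"]) | set(df["male_line"])) - set(status.index)
    if unknown:
        raise ValueError(f"records with unknown lines: {sorted(unknown)[:5]}")
    wf = status.loc[df["female_line"]].to_numpy()
    wm = status.loc[df["male_line"]].to_numpy()
    eff = np.array([[effects.cell_effects[(f, m)] for m in (0, 1)]
                    for f in (0, 1)])
    df["total_adjusted"] = df["total"].to_numpy(float) - eff[wf, wm]
    return DiallelDataset(df)


@dataclass
class SexRatioResult:
    female_proportion: float
    p_value: float
    n_offspring: int
    per_cross: pd.DataFrame

    @property
    def biased(self) -> bool:
        return self.p_value < 0.05


def sex_ratio_test(dataset: DiallelDataset) -> SexRatioResult:
    """Binomial test of the pooled female offspring proportion against 1/2.

    Descriptive companion table gives the per-cross proportions; no
    multiplicity correction is applied.
    """
    df = dataset.df
    nf = int(df["n_female"].sum())
    nm = int(df["n_male"].sum())
    total = nf + nm
    if total <= 0:
        raise ValueError("dataset contains no offspring")
    test = binomtest(nf, total, 0.5)
    per_cross = (df.groupby(["female_line", "male_line"])[["n_female", "n_male"]]
                 .sum().reset_index())
    tot = per_cross["n_female"] + per_cross["n_male"]
    per_cross["female_proportion"] = np.where(
        tot > 0, per_cross["n_female"] / tot.replace(0, 1), np.nan)
    return SexRatioResult(female_proportion=nf / total,
                          p_value=float(test.pvalue),
                          n_offspring=total, per_cross=per_cross)


@dataclass
class InbreedingContrast:
    estimate: float
    se: float
    p_value: float


def inbreeding_contrast(dataset: DiallelDataset,
                        options: Optional[REMLOptions] = None) -> InbreedingContrast:
    """Wald test of the self-cross (inbred progeny) fixed effect.

    Adds a self-cross indicator to the bio-model fixed design; the
    coefficient is the mean productivity deviation of inbred progeny.
    """
    df = dataset.df
    if not (df["female_line"] == df["male_line"]).any():
        raise ValueError("dataset contains no self-crosses")
    vc = fit_biomodel(dataset, self_cross_indicator=True, options=options)
    j = vc.fixed_names.index("self_cross")
    est = float(vc.beta[j])
    se = float(math.sqrt(vc.beta_cov[j, j]))
    p = 2.0 * float(norm.sf(abs(est) / se)) if se > 0 else math.nan
    return InbreedingContrast(estimate=est, se=se, p_value=p)
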