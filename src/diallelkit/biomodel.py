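"""The Cockerham–Weir "bio" model for full diallel crosses.

Productivity of replicate ``k`` of the cross female line ``i`` x male
line ``j`` is modelled as

    y_ijk = mu + f_i + m_j + fm_ij + n_i + n_j + nn_ij + eps_ijk

with independent zero-mean random effects: ``f`` and ``m`` are the
female and male *extranuclear* line effects (maternal cytoplasm,
parent-of-origin contributions), ``fm`` their ordered-pair interaction,
``n`` the additive *nuclear* effect a line transmits regardless of
parental role, and ``nn`` the unordered-pair nuclear interaction.  A
self-cross receives its line's nuclear effect twice (``2 n_i``).

The implied covariances among relative classes identify the
components:

    full sibs (same ordered cross)    sigma_f^2 + sigma_m^2 + sigma_fm^2 + 2 sigma_n^2 + sigma_nn^2
    reciprocal full sibs (i x j, j x i)                       2 sigma_n^2 + sigma_nn^2
    maternal half sibs (shared dam)   sigma_f^2 + sigma_n^2
    paternal half sibs (shared sire)  sigma_m^2 + sigma_n^2
    reciprocal half sibs (dam of one = sire of the other)     sigma_n^2

Total genetic variance is the variance among (non-self) cross means,
``sigma_g^2 = sigma_f^2 + sigma_m^2 + sigma_fm^2 + 2 sigma_n^2 +
sigma_nn^2``; phenotypic variance adds the residual.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2

from ._reml import (REMLError, REMLOptions, REMLResult, RandomTerm,
                    reml_core)
from .datatypes import DiallelDataset, VialRecord

__all__ = [
    "DesignMatrices", "VarianceComponents", "ComponentTest",
    "TotalGeneticFit", "build_design", "cross_covariance", "reml_fit",
    "fit_biomodel", "mom_components", "total_genetic_model",
    "partition_summary", "lrt_component", "BIOMODEL_TERMS",
]

BIOMODEL_TERMS = ("f", "m", "fm", "n", "nn")


@dataclass
class DesignMatrices:
    """Fixed design and random-term incidence structures for a diallel."""

    X: np.ndarray
    fixed_names: list
    Z: dict                      # term name -> csr incidence matrix
    levels: dict                 # term name -> level labels
    groups: np.ndarray           # ordered-cross code per vial row
    n_obs: int

    def incidence(self, order: Sequence[str] = BIOMODEL_TERMS):
        return [RandomTerm(name, self.Z[name]) for name in order
                if name in self.Z]


def build_design(dataset: DiallelDataset,
                 fixed_covariates: Optional[pd.DataFrame] = None,
                 self_cross_indicator: bool = False) -> DesignMatrices:
    """Build fixed and random design matrices for the bio-model.

    Level indexing is deterministic: line ids sorted, ordered pairs
    ``(i, j)`` in lexicographic order, unordered pairs ``{i, j}`` with
    ``i <= j``.  ``fixed_covariates`` (indexed like the dataset rows)
    are appended to the intercept; ``self_cross_indicator`` adds the
    inbred-progeny contrast column.
    """
    df = dataset.df
    n_obs = len(df)
    if n_obs == 0:
        raise ValueError("dataset is empty")
    lines = dataset.lines
    line_idx = {l: i for i, l in enumerate(lines)}
    fi = df["female_line"].map(line_idx).to_numpy()
    mi = df["male_line"].map(line_idx).to_numpy()

    rows = np.arange(n_obs)

    Z_f = sp.csr_matrix((np.ones(n_obs), (rows, fi)),
                        shape=(n_obs, len(lines)))
    Z_m = sp.csr_matrix((np.ones(n_obs), (rows, mi)),
                        shape=(n_obs, len(lines)))
    # nuclear: one unit for each parental line, so 2 units on self-crosses
    Z_n = sp.csr_matrix(
        (np.ones(2 * n_obs),
         (np.concatenate([rows, rows]), np.concatenate([fi, mi]))),
        shape=(n_obs, len(lines)))

    ordered = sorted({(f, m) for f, m in zip(fi, mi)})
    ord_idx = {p: i for i, p in enumerate(ordered)}
    fm_col = np.array([ord_idx[(f, m)] for f, m in zip(fi, mi)])
    Z_fm = sp.csr_matrix((np.ones(n_obs), (rows, fm_col)),
                         shape=(n_obs, len(ordered)))

    unordered = sorted({(min(f, m), max(f, m)) for f, m in zip(fi, mi)})
    un_idx = {p: i for i, p in enumerate(unordered)}
    nn_col = np.array([un_idx[(min(f, m), max(f, m))]
                       for f, m in zip(fi, mi)])
    Z_nn = sp.csr_matrix((np.ones(n_obs), (rows, nn_col)),
                         shape=(n_obs, len(unordered)))

    cols = [np.ones(n_obs)]
    names = ["intercept"]
    if self_cross_indicator:
        cols.append((fi == mi).astype(float))
        names.append("self_cross")
    if fixed_covariates is not None:
        for c in fixed_covariates.columns:
            vals = np.asarray(fixed_covariates[c], dtype=float)
            if vals.shape != (n_obs,):
                raise ValueError(f"covariate {c!r} has wrong length")
            cols.append(vals)
            names.append(str(c))
    X = np.column_stack(cols)

    return DesignMatrices(
        X=X,
        fixed_names=names,
        Z={"f": Z_f, "m": Z_m, "fm": Z_fm, "n": Z_n, "nn": Z_nn},
        levels={
            "f": lines, "m": lines, "n": lines,
            "fm": [(lines[a], lines[b]) for a, b in ordered],
            "nn": [(lines[a], lines[b]) for a, b in unordered],
        },
        groups=fm_col,
        n_obs=n_obs,
    )


@dataclass
class VarianceComponents:
    """Fitted bio-model variance components (flies^2) and diagnostics."""

    sigma2_f: float
    sigma2_m: float
    sigma2_fm: float
    sigma2_n: float
    sigma2_nn: float
    sigma2_e: float
    loglik: float = math.nan
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = math.nan
    trajectory: list = field(default_factory=list)
    beta: Optional[np.ndarray] = None
    beta_cov: Optional[np.ndarray] = None
    fixed_names: Optional[list] = None

    @property
    def sigma2_g(self) -> float:
        """Total genetic variance; the nuclear term enters as 2*sigma2_n
        (the non-self full-sib covariance, i.e. the variance among cross
        means)."""
        return (self.sigma2_f + self.sigma2_m + self.sigma2_fm
                + 2.0 * self.sigma2_n + self.sigma2_nn)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_g + self.sigma2_e

    def as_dict(self) -> dict:
        return {
            "sigma2_f": self.sigma2_f, "sigma2_m": self.sigma2_m,
            "sigma2_fm": self.sigma2_fm, "sigma2_n": self.sigma2_n,
            "sigma2_nn": self.sigma2_nn, "sigma2_e": self.sigma2_e,
        }

    def genetic_shares(self) -> dict:
        g = self.sigma2_g
        if g <= 0:
            raise ValueError("total genetic variance is zero")
        return {
            "f": self.sigma2_f / g, "m": self.sigma2_m / g,
            "fm": self.sigma2_fm / g, "n": 2.0 * self.sigma2_n / g,
            "nn": self.sigma2_nn / g,
        }

    def to_json(self, path) -> None:
        d = self.as_dict()
        d.update(loglik=self.loglik, converged=self.converged,
                 n_iter=self.n_iter, sigma2_g=self.sigma2_g,
                 sigma2_p=self.sigma2_p)
        if self.beta is not None:
            d["fixed_effects"] = dict(zip(self.fixed_names or [],
                                          np.asarray(self.beta).tolist()))
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class ComponentTest:
    component: str
    loglik_full: float
    loglik_reduced: float
    lrt: float
    p_value: float


@dataclass
class TotalGeneticFit:
    sigma2_cross: float
    sigma2_e: float
    loglik: float

    @property
    def genetic_share(self) -> float:
        return self.sigma2_cross / (self.sigma2_cross + self.sigma2_e)


def cross_covariance(record_a: VialRecord, record_b: VialRecord,
                     vc: VarianceComponents) -> float:
    """Model covariance between the productivity of two vials.

    Evaluates the bio-model covariance from parent-sharing indicators,
    which reproduces the five named relative classes (full sibs,
    reciprocal full sibs, maternal/paternal/reciprocal half sibs) and
    extends them consistently to self-cross pairs.  The same vial gets
    the full-sib covariance plus the residual.
    """
    fa, ma = record_a.female_line, record_a.male_line
    fb, mb = record_b.female_line, record_b.male_line
    cov = 0.0
    if fa == fb:
        cov += vc.sigma2_f
    if ma == mb:
        cov += vc.sigma2_m
    if (fa, ma) == (fb, mb):
        cov += vc.sigma2_fm
    cov += vc.sigma2_n * ((fa == fb) + (fa == mb) + (ma == fb) + (ma == mb))
    if tuple(sorted((fa, ma))) == tuple(sorted((fb, mb))):
        cov += vc.sigma2_nn
    if record_a == record_b:
        cov += vc.sigma2_e
    return float(cov)


def reml_fit(design: DesignMatrices, phenotype: np.ndarray,
             options: Optional[REMLOptions] = None,
             start: Optional[dict] = None) -> VarianceComponents:
    """REML fit of the bio-model given design matrices and a phenotype."""
    y = np.asarray(phenotype, dtype=float)
    res = reml_core(y, design.X, design.incidence(), groups=design.groups,
                    start=start, options=options,
                    fixed_names=design.fixed_names)
    return _to_components(res)


def _to_components(res: REMLResult) -> VarianceComponents:
    v = res.variances
    return VarianceComponents(
        sigma2_f=v["f"], sigma2_m=v["m"], sigma2_fm=v["fm"],
        sigma2_n=v["n"], sigma2_nn=v["nn"], sigma2_e=v["residual"],
        loglik=res.loglik, converged=res.converged, n_iter=res.n_iter,
        grad_norm=res.grad_norm, trajectory=res.trajectory,
        beta=res.beta, beta_cov=res.beta_cov, fixed_names=res.fixed_names,
    )


def mom_components(dataset: DiallelDataset) -> dict:
    """Method-of-moments component estimates from empirical covariances.

    Uses the empirical covariance of cross means within each relative
    class (reciprocal full sibs, maternal/paternal/reciprocal half sibs)
    and the pooled within-cross variance, solving the class equations
    directly.  Less efficient than REML but closed-form; used as an
    independent check and as the REML warm start.  Estimates are clipped
    at zero.
    """
    df = dataset.df
    pheno = dataset.phenotype_column
    lines = dataset.lines
    n = len(lines)
    idx = {l: i for i, l in enumerate(lines)}
    means = np.full((n, n), np.nan)
    grp = df.groupby(["female_line", "male_line"])[pheno]
    gm = grp.mean()
    counts = grp.size()
    for (f, m), val in gm.items():
        means[idx[f], idx[m]] = val
    N = len(df)
    C = counts.size
    ssw = float(((df[pheno] - df.groupby(["female_line", "male_line"])[pheno]
                  .transform("mean")) ** 2).sum())
    resid = ssw / max(N - C, 1)
    r_bar = N / C

    D = means - np.nanmean(means)
    D0 = np.nan_to_num(D)
    present = (~np.isnan(D)).astype(float)

    off = present.copy()
    np.fill_diagonal(off, 0.0)
    n_off = off.sum()
    v1 = float((D0 * D0 * off).sum() / max(n_off - 1, 1))

    both = off * off.T
    c_rec = float((D0 * D0.T * both).sum() / max(both.sum(), 1))

    row = (D0 * off).sum(axis=1)
    row_sq = (D0 * D0 * off).sum(axis=1)
    cnt_row = off.sum(axis=1)
    c_mat = float(np.sum(row ** 2 - row_sq)
                  / max(np.sum(cnt_row * (cnt_row - 1)), 1))
    col = (D0 * off).sum(axis=0)
    col_sq = (D0 * D0 * off).sum(axis=0)
    cnt_col = off.sum(axis=0)
    c_pat = float(np.sum(col ** 2 - col_sq)
                  / max(np.sum(cnt_col * (cnt_col - 1)), 1))

    recip = (D0 * D0.T * both).sum(axis=1)
    c_rechalf = float(np.sum(row * col - recip)
                      / max(np.sum(cnt_row * cnt_col - both.sum(axis=1)), 1))

    s_n = c_rechalf
    s_nn = c_rec - 2.0 * s_n
    s_f = c_mat - s_n
    s_m = c_pat - s_n
    s_fm = v1 - (s_f + s_m + 2.0 * s_n + s_nn) - resid / r_bar
    out = {"f": s_f, "m": s_m, "fm": s_fm, "n": s_n, "nn": s_nn,
           "residual": resid}
    return {k: max(v, 0.0) for k, v in out.items()}


def fit_biomodel(dataset: DiallelDataset,
                 fixed_covariates: Optional[pd.DataFrame] = None,
                 self_cross_indicator: bool = False,
                 options: Optional[REMLOptions] = None) -> VarianceComponents:
    """Convenience wrapper: design + method-of-moments warm start + REML."""
    design = build_design(dataset, fixed_covariates=fixed_covariates,
                          self_cross_indicator=self_cross_indicator)
    start = mom_components(dataset)
    return reml_fit(design, dataset.phenotype(), options=options, start=start)


def total_genetic_model(dataset: DiallelDataset,
                        options: Optional[REMLOptions] = None) -> TotalGeneticFit:
    """One-way random-effects model with ordered cross as the random term.

    Because parents differ only by genotype, the among-cross component
    is the total genetic variance; its share of the phenotypic variance
    is the broad-sense heritability of single-vial productivity.
    """
    df = dataset.df
    key = df["female_line"] + "\x00" + df["male_line"]
    codes, _ = pd.factorize(key, sort=True)
    counts = np.bincount(codes)
    if counts.max() < 2:
        raise REMLError("need >=2 replicates of at least one cross to "
                        "separate genetic and residual variance")
    n_obs = len(df)
    Z = sp.csr_matrix((np.ones(n_obs), (np.arange(n_obs), codes)),
                      shape=(n_obs, codes.max() + 1))
    y = dataset.phenotype()
    gmeans = np.bincount(codes, weights=y) / counts
    v_between = float(np.var(gmeans[counts > 0], ddof=1))
    ssw = float(np.sum((y - gmeans[codes]) ** 2))
    start = {"cross": max(v_between, 1e-3),
             "residual": max(ssw / max(n_obs - len(counts), 1), 1e-3)}
    res = reml_core(y, np.ones((n_obs, 1)), [RandomTerm("cross", Z)],
                    groups=codes, start=start, options=options,
                    fixed_names=["intercept"])
    return TotalGeneticFit(sigma2_cross=res.variances["cross"],
                           sigma2_e=res.variances["residual"],
                           loglik=res.loglik)


PARTITION_LABELS = {
    "f": "female_extranuclear", "m": "male_extranuclear",
    "fm": "extranuclear_interaction", "n": "nuclear",
    "nn": "nuclear_interaction", "residual": "residual",
}


def partition_summary(vc: VarianceComponents) -> pd.DataFrame:
    """Variance partition table: component, flies^2, % of genetic, % of
    phenotypic variance.  The nuclear row carries ``2*sigma2_n``."""
    if vc.sigma2_p <= 0:
        raise ValueError("phenotypic variance is zero; shares undefined")
    values = {
        "f": vc.sigma2_f, "m": vc.sigma2_m, "fm": vc.sigma2_fm,
        "n": 2.0 * vc.sigma2_n, "nn": vc.sigma2_nn, "residual": vc.sigma2_e,
    }
    g = vc.sigma2_g
    rows = []
    for key, val in values.items():
        rows.append({
            "component": PARTITION_LABELS[key],
            "variance": val,
            "pct_genetic": (100.0 * val / g
                            if key != "residual" and g > 0 else np.nan),
            "pct_phenotypic": 100.0 * val / vc.sigma2_p,
        })
    return pd.DataFrame(rows)


def lrt_component(design: DesignMatrices, phenotype: np.ndarray,
                  full: VarianceComponents, component: str,
                  options: Optional[REMLOptions] = None) -> ComponentTest:
    """Boundary likelihood-ratio test of one variance component.

    Refits with the component removed; because the null value lies on
    the boundary of the parameter space, the statistic is referred to
    the 50:50 mixture of a point mass at zero and chi-square(1).
    """
    if component not in design.Z:
        raise ValueError(f"unknown component {component!r}")
    terms = [RandomTerm(name, design.Z[name]) for name in BIOMODEL_TERMS
             if name != component]
    start = {k: v for k, v in full.as_dict().items()}
    start = {name.replace("sigma2_", ""): val for name, val in start.items()}
    start["residual"] = full.sigma2_e
    start.pop(component, None)
    res = reml_core(np.asarray(phenotype, dtype=float), design.X, terms,
                    groups=design.groups, start=start, options=options,
                    fixed_names=design.fixed_names)
    lrt = 2.0 * (full.loglik - res.loglik)
    lrt = max(lrt, 0.0)
    p = 1.0 if lrt == 0.0 else 0.5 * float(chi2.sf(lrt, 1))
    return ComponentTest(component=component, loglik_full=full.loglik,
                         loglik_reduced=res.loglik, lrt=lrt, p_value=p)
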