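"""Line-mean GWAS of the female component of productivity.

Because each inbred line is crossed to every other line, the mean of a
line's vials *as female parent* isolates its female (largely
extranuclear) contribution; regressing these means on homozygous line
genotypes (coded 0/1, not 0/1/2 — inbred lines carry two copies of one
allele) maps the female component.  The per-allele effect is then the
difference between the two homozygous line classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .biomodel import VarianceComponents
from .datatypes import DiallelDataset, GenotypeMatrix

__all__ = [
    "LineMeans", "GwasRow", "female_line_means", "filter_variants",
    "variant_regression", "run_gwas", "variance_explained",
    "linemean_genetic_variance", "replicate_variants", "pearson_correlation",
]


@dataclass
class LineMeans:
    """Per-line female-parent phenotype means with vial counts."""

    means: pd.Series
    n_vials: pd.Series
    covariates: Optional[pd.DataFrame] = None

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.means.index]


@dataclass
class GwasRow:
    variant_id: str
    maf: float
    n: int
    effect: float
    se: float
    p_value: float
    p_conditional: Optional[float] = None
    var_explained: Optional[float] = None


def female_line_means(dataset: DiallelDataset,
                      covariates: Optional[pd.DataFrame] = None) -> LineMeans:
    """Mean (adjusted) productivity over all vials with the line as dam.

    Self-crosses are included — the phenotype is the mean over *all*
    crosses of the respective female parent.  Lines never used as dams
    are dropped with a warning.
    """
    df = dataset.df
    grp = df.groupby("female_line")[dataset.phenotype_column]
    means = grp.mean()
    counts = grp.size()
    never = sorted(set(dataset.lines) - set(means.index))
    if never:
        warnings.warn(f"lines never used as female parent: {never}")
    return LineMeans(means=means.rename("female_mean"),
                     n_vials=counts.rename("n_vials"),
                     covariates=covariates)


def filter_variants(genotypes: GenotypeMatrix,
                    maf_min: float = 0.10) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` among non-missing lines.

    The boundary is inclusive (a variant at exactly the threshold is
    retained); all-missing variants are removed.  MAF metadata is
    recomputed on the filtered matrix.
    """
    maf = genotypes.maf()
    keep = maf.index[(maf >= maf_min) & maf.notna()]
    if len(keep) == 0:
        warnings.warn("no variants pass the MAF filter")
    return GenotypeMatrix(calls=genotypes.calls[list(keep)],
                          positions=(genotypes.positions.loc[list(keep)]
                                     if genotypes.positions is not None else None))


def variant_regression(phenotype: LineMeans, genotype: pd.Series,
                       covariate: Optional[pd.Series] = None) -> GwasRow:
    """OLS of line means on one 0/1 variant, minor-allele orientation.

    Missing genotypes drop lines pairwise.  The effect is reported per
    minor allele: if the allele coded 1 is the major allele among the
    analysed lines, the sign is flipped.  When a covariate is supplied
    the conditional p-value comes from the model including it (the
    reported effect stays the marginal one).
    """
    y = phenotype.means
    g = genotype.reindex(y.index)
    data = pd.DataFrame({"y": y, "g": g})
    if covariate is not None:
        data["cov"] = covariate.reindex(y.index)
    data = data.dropna(subset=["y", "g"])
    n = len(data)
    if n < 3:
        raise ValueError(f"variant {genotype.name!r}: fewer than 3 lines")
    freq1 = data["g"].mean()
    if freq1 in (0.0, 1.0):
        raise ValueError(f"variant {genotype.name!r} is monomorphic "
                         "after dropping missing lines")
    flip = freq1 > 0.5
    gvec = 1.0 - data["g"] if flip else data["g"]
    maf = min(freq1, 1.0 - freq1)

    X = sm.add_constant(gvec.to_numpy())
    fit = sm.OLS(data["y"].to_numpy(), X).fit()
    effect, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]

    p_cond = None
    if covariate is not None:
        sub = data.dropna(subset=["cov"])
        if len(sub) >= 4 and sub["g"].nunique() > 1:
            gv = (1.0 - sub["g"]) if flip else sub["g"]
            Xc = sm.add_constant(np.column_stack([gv, sub["cov"]]))
            p_cond = float(sm.OLS(sub["y"].to_numpy(), Xc).fit().pvalues[1])
    return GwasRow(variant_id=str(genotype.name), maf=float(maf), n=n,
                   effect=float(effect), se=float(se), p_value=float(p),
                   p_conditional=p_cond)


def run_gwas(phenotype: LineMeans, genotypes: GenotypeMatrix,
             covariate: Optional[pd.Series] = None,
             p_threshold: float = 1e-5,
             sigma2_g_linemeans: Optional[float] = None) -> pd.DataFrame:
    """Single-variant regressions across the genotype matrix.

    Returns one row per testable variant, sorted by p-value (ties broken
    by variant id) with a boolean ``significant`` column at
    ``p < p_threshold``.  Per-variant failures (monomorphic after
    missing-data removal, too few lines) are recorded and skipped.
    """
    rows, skipped = [], []
    for vid in genotypes.variant_ids:
        try:
            row = variant_regression(phenotype, genotypes.calls[vid], covariate)
        except ValueError as exc:
            skipped.append((vid, str(exc)))
            continue
        if sigma2_g_linemeans is not None:
            row.var_explained = variance_explained(row, sigma2_g_linemeans)
        rows.append(row)
    table = pd.DataFrame([r.__dict__ for r in rows])
    if len(table):
        table = (table.sort_values(["p_value", "variant_id"])
                 .reset_index(drop=True))
        table["significant"] = table["p_value"] < p_threshold
    table.attrs["skipped"] = skipped
    return table


def linemean_genetic_variance(vc: VarianceComponents, n_lines: int) -> float:
    """Genetic variance of female line means implied by a bio-model fit.

    Averaging a female's vials over all n mates keeps her own female
    extranuclear effect intact, keeps her nuclear effect with weight
    (n+1)/n (she mates with herself once), and attenuates the
    interaction terms by 1/n; male-side terms average to the same
    constant for every female and drop out:

        sigma2_g,lm = sigma2_f + ((n+1)/n)^2 sigma2_n
                      + sigma2_fm / n + sigma2_nn / n
    """
    n = n_lines
    return (vc.sigma2_f + ((n + 1.0) / n) ** 2 * vc.sigma2_n
            + vc.sigma2_fm / n + vc.sigma2_nn / n)


def variance_explained(row: GwasRow, sigma2_g_linemeans: float) -> float:
    """Proportion of line-mean genetic variance explained by a variant.

    ``p(1-p) a^2 / sigma2_g`` with p the MAF and a the per-allele effect
    between homozygous line classes; capped at 1 with a warning.
    """
    if sigma2_g_linemeans <= 0:
        raise ValueError("line-mean genetic variance must be positive")
    prop = row.maf * (1.0 - row.maf) * row.effect ** 2 / sigma2_g_linemeans
    if prop >= 1.0:
        warnings.warn(f"variant {row.variant_id}: variance explained "
                      f"{prop:.2f} capped at 1")
        prop = 1.0
    return float(prop)


def replicate_variants(top: pd.DataFrame, phenotype: LineMeans,
                       genotypes: GenotypeMatrix,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Re-test top variants against an independent phenotype.

    Variants absent from the new genotype panel are skipped with a note
    in ``attrs['skipped']``; ``replicated`` flags two-sided p < alpha.
    """
    rows, skipped = [], []
    for vid in top["variant_id"] if len(top) else []:
        if vid not in genotypes.calls.columns:
            skipped.append((vid, "absent from replication panel"))
            continue
        try:
            row = variant_regression(phenotype, genotypes.calls[vid])
        except ValueError as exc:
            skipped.append((vid, str(exc)))
            continue
        rows.append(row)
    out = pd.DataFrame([r.__dict__ for r in rows])
    if len(out):
        out["replicated"] = out["p_value"] < alpha
    out.attrs["skipped"] = skipped
    return out


def pearson_correlation(x: pd.Series, y: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation with pairwise-complete observations.

    Returns ``(r, two-sided p, n)``; the p-value uses the exact
    t-distribution reference.
    """
    x = pd.Series(x)
    y = pd.Series(y).reindex(x.index)
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 paired complete observations")
    xv, yv = x[ok].to_numpy(float), y[ok].to_numpy(float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p), n
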