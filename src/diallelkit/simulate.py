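"""Seeded synthetic diallel experiments.

The generator runs the analysis model forward: for each line it draws a
female extranuclear effect ``f``, a male extranuclear effect ``m`` and a
nuclear effect ``n``; for each ordered pair an extranuclear interaction
``fm``; for each unordered pair a nuclear interaction ``nn``.  The
latent vial value for replicate ``k`` of cross female ``i`` x male ``j``
is

    y_ijk = mu + f_i + m_j + fm_ij + n_i + n_j + nn_ij
            + infection_effect(cell_ij) + self_effect * 1[i == j]
            + a_direct * g_i + beta2 * expression_i + eps_ijk

where for a self-cross the nuclear term ``n_i + n_j`` collapses to
``2 n_i`` (the line contributes its genome twice), ``g_i`` is the female
parent's causal genotype and ``expression_i`` its mediator value.  The
latent value is rounded half-up, floored at zero and split into female
and male offspring counts by a Binomial(total, 0.5) draw.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    CausalVariant,
    DiallelDataset,
    GenotypeMatrix,
    LinePanel,
    MediationTruth,
    TrueParameters,
)

__all__ = [
    "make_panel",
    "make_genotypes",
    "simulate_expression",
    "simulate_diallel",
    "paper_like_truth",
    "simulate_paper_like",
    "PAPER_LIKE",
]


def make_panel(n_lines: int, infection_prob: float = 0.5, seed: int = 0,
               prefix: str = "L") -> LinePanel:
    """Create a panel of inbred lines with random infection status.

    Line ids are ``L001 ...`` (zero-padded so lexicographic order equals
    numeric order); infection is drawn independently per line with
    probability ``infection_prob``.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be at least 2")
    if not 0.0 <= infection_prob <= 1.0:
        raise ValueError("infection_prob must be a probability")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_lines)))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_lines)]
    infected = (rng.random(n_lines) < infection_prob).astype(int)
    return LinePanel(line_ids=ids, infected=infected)


def make_genotypes(panel: LinePanel, n_variants: int,
                   maf_range: tuple[float, float] = (0.05, 0.5),
                   causal: Optional[CausalVariant] = None,
                   missing_rate: float = 0.0, seed: int = 0) -> GenotypeMatrix:
    """Simulate independent homozygous variants for a line panel.

    Each variant's minor-allele count is ``round(maf * n_lines)`` with
    ``maf`` drawn uniformly from ``maf_range`` (at least one copy), the
    carriers a uniform random subset of lines.  The causal variant, if
    requested, is placed with exactly ``round(causal.maf * n_lines)``
    minor-allele lines and is never masked; missing calls are injected
    into the remaining variants at ``missing_rate``.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie inside (0, 0.5]")
    if not 0.0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be < 0.5")
    rng = np.random.default_rng(seed)
    n = panel.n_lines
    mat = np.zeros((n, n_variants))
    mafs = rng.uniform(lo, hi, size=n_variants)
    for v in range(n_variants):
        k = max(1, int(round(mafs[v] * n)))
        carriers = rng.choice(n, size=k, replace=False)
        mat[carriers, v] = 1.0
    width = max(4, len(str(n_variants)))
    names = [f"snp{v + 1:0{width}d}" for v in range(n_variants)]
    causal_col = None
    if causal is not None:
        causal_col = rng.integers(0, n_variants)
        k = int(round(causal.maf * n))
        if k < 1 or k > n - 1:
            raise ValueError("causal MAF gives a monomorphic variant")
        col = np.zeros(n)
        col[rng.choice(n, size=k, replace=False)] = 1.0
        mat[:, causal_col] = col
        names[causal_col] = causal.variant_id
    if missing_rate > 0.0:
        mask = rng.random(mat.shape) < missing_rate
        if causal_col is not None:
            mask[:, causal_col] = False
        mat[mask] = np.nan
    calls = pd.DataFrame(mat, index=panel.line_ids, columns=names)
    return GenotypeMatrix(calls=calls)


def simulate_expression(panel: LinePanel, genotypes: GenotypeMatrix,
                        truth: TrueParameters, seed: int = 0) -> pd.Series:
    """Draw per-line mediator expression and store it in the panel.

    expression_i = alpha0 + alpha1 * g_i + N(0, sigma_expr^2); a line
    with a missing causal genotype gets a missing expression value.
    """
    if truth.mediation is None:
        raise ValueError("truth.mediation is not set")
    if truth.causal is None:
        raise ValueError("truth.causal is not set")
    med = truth.mediation
    g = genotypes.calls[truth.causal.variant_id].reindex(panel.line_ids)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, med.sigma_expr, size=panel.n_lines)
    expr = med.alpha0 + med.alpha1 * g.to_numpy(dtype=float) + noise
    series = pd.Series(expr, index=panel.line_ids, name="expression")
    panel.expression = series
    return series


def simulate_diallel(panel: LinePanel, genotypes: Optional[GenotypeMatrix],
                     truth: TrueParameters, n_reps: int = 3, seed: int = 0,
                     round_counts: bool = True) -> DiallelDataset:
    """Generate a complete diallel dataset from ground-truth parameters.

    ``round_counts=False`` keeps the latent Gaussian values (stored in
    ``total`` as floats split evenly) so that moment checks are exact.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    n = panel.n_lines
    rng = np.random.default_rng(seed)

    f = rng.normal(0.0, np.sqrt(truth.sigma2_f), size=n)
    m = rng.normal(0.0, np.sqrt(truth.sigma2_m), size=n)
    nuc = rng.normal(0.0, np.sqrt(truth.sigma2_n), size=n)
    fm = rng.normal(0.0, np.sqrt(truth.sigma2_fm), size=(n, n))
    # nn is symmetric: draw an upper triangle (diagonal included) and mirror
    nn_upper = rng.normal(0.0, np.sqrt(truth.sigma2_nn), size=(n, n))
    nn = np.triu(nn_upper) + np.triu(nn_upper, 1).T

    # female-line additions: causal variant and mediated expression
    female_add = np.zeros(n)
    if truth.causal is not None:
        if genotypes is None:
            raise ValueError("a causal variant requires a genotype matrix")
        g = genotypes.calls[truth.causal.variant_id].reindex(panel.line_ids)
        if g.isna().any():
            raise ValueError("causal genotype missing for some lines")
        female_add += truth.causal.effect_direct * g.to_numpy(dtype=float)
    if truth.mediation is not None:
        if panel.expression is None:
            simulate_expression(panel, genotypes, truth, seed=seed)
        expr = panel.expression.reindex(panel.line_ids)
        if expr.isna().any():
            raise ValueError("mediator expression missing for some lines")
        # centre the mediator contribution so mu stays the grand mean
        med = truth.mediation
        expr_mean = med.alpha0 + med.alpha1 * truth.causal.maf
        female_add += med.beta2 * (expr.to_numpy(dtype=float) - expr_mean)

    infected = panel.infected
    cell_effect = np.array([
        [truth.infection_effects[(fi, mi)] for mi in (0, 1)] for fi in (0, 1)
    ])

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    latent_mean = (
        truth.mu
        + f[ii] + m[jj] + fm
        + np.where(ii == jj, 2.0 * nuc[ii], nuc[ii] + nuc[jj])
        + nn
        + cell_effect[infected[ii], infected[jj]]
        + np.where(ii == jj, truth.self_cross_effect, 0.0)
        + female_add[ii]
    )

    eps = rng.normal(0.0, np.sqrt(truth.sigma2_e), size=(n, n, n_reps))
    latent = latent_mean[:, :, None] + eps

    ids = np.array(panel.line_ids)
    rows = {
        "female_line": np.repeat(ids, n * n_reps),
        "male_line": np.tile(np.repeat(ids, n_reps), n),
        "replicate": np.tile(np.arange(1, n_reps + 1), n * n),
    }
    flat = latent.reshape(-1)
    if round_counts:
        totals = np.maximum(np.floor(flat + 0.5), 0.0).astype(int)
        n_fem = rng.binomial(totals, 0.5)
        rows["n_female"] = n_fem
        rows["n_male"] = totals - n_fem
        df = pd.DataFrame(rows)
    else:
        rows["n_female"] = np.zeros(flat.size, dtype=int)
        rows["n_male"] = np.zeros(flat.size, dtype=int)
        df = pd.DataFrame(rows)
        df["total"] = 0
        ds = DiallelDataset(df)
        ds.df["total"] = flat  # keep the latent Gaussian value
        ds.df["n_female"] = flat / 2.0
        ds.df["n_male"] = flat / 2.0
        return ds
    return DiallelDataset(df)


# ----------------------------------------------------------------------
# the "paper-like" preset
# ----------------------------------------------------------------------

#: Observed-scale anchors for the preset world: 737,868 adult flies over
#: 7,500 vials gives the grand mean; the coefficient of variation of
#: per-vial productivity is 37%; 39% of phenotypic variance is genetic;
#: the female extranuclear component is 85% of the genetic variance.
_MU = 737868 / 7500  # 98.3824 flies per vial
_SIGMA2_P = (0.37 * _MU) ** 2
_SIGMA2_G = 0.39 * _SIGMA2_P
_SIGMA2_E = _SIGMA2_P - _SIGMA2_G
# split of the genetic variance among components (shares of sigma2_g;
# the nuclear share is the full-sib contribution 2*sigma2_n)
_SHARE_F, _SHARE_M, _SHARE_FM, _SHARE_2N, _SHARE_NN = 0.85, 0.04, 0.08, 0.01, 0.02

_CAUSAL_MAF = 0.2
_CAUSAL_TOTAL = 13.92          # flies per minor allele, female parents
_PROP_MEDIATED = 0.19
_ALPHA1 = 0.5                  # log2 expression units per minor allele
_BETA2 = _PROP_MEDIATED * _CAUSAL_TOTAL / _ALPHA1
_SIGMA_EXPR = 1.0
_ALPHA0 = 5.0

PAPER_LIKE = {
    "n_lines": 50,
    "n_reps": 3,
    "infection_prob": 0.5,
    "n_variants": 1000,
    "maf_range": (0.1, 0.5),
    "missing_rate": 0.02,
}


def paper_like_truth(causal: bool = True, mediation: bool = True) -> TrueParameters:
    """Ground truth of the default 50-line preset.

    The causal variant (total per-allele effect 13.92 flies at MAF 0.2,
    19% of it mediated by expression) and the expression-noise pathway
    both act through the female parent, so their variance is carved out
    of the polygenic female component: the *total* female extranuclear
    variance stays at 85% of the genetic variance regardless of whether
    the causal pathway is enabled.
    """
    f_total = _SHARE_F * _SIGMA2_G
    causal_var = _CAUSAL_MAF * (1 - _CAUSAL_MAF) * _CAUSAL_TOTAL ** 2
    med_var = _BETA2 ** 2 * _SIGMA_EXPR ** 2
    cv = mv = 0.0
    causal_spec = med_spec = None
    if causal:
        cv = causal_var
        direct = _CAUSAL_TOTAL
        if mediation:
            mv = med_var
            direct = _CAUSAL_TOTAL * (1.0 - _PROP_MEDIATED)
            med_spec = MediationTruth(alpha0=_ALPHA0, alpha1=_ALPHA1,
                                      beta2=_BETA2, sigma_expr=_SIGMA_EXPR)
        causal_spec = CausalVariant(variant_id="snp_causal", maf=_CAUSAL_MAF,
                                    effect_direct=direct)
    return TrueParameters(
        mu=_MU,
        sigma2_f=f_total - cv - mv,
        sigma2_m=_SHARE_M * _SIGMA2_G,
        sigma2_fm=_SHARE_FM * _SIGMA2_G,
        sigma2_n=0.5 * _SHARE_2N * _SIGMA2_G,
        sigma2_nn=_SHARE_NN * _SIGMA2_G,
        sigma2_e=_SIGMA2_E,
        infection_effects={(0, 0): 0.0, (0, 1): -3.0, (1, 0): -6.0, (1, 1): -6.0},
        self_cross_effect=0.0,
        causal=causal_spec,
        mediation=med_spec,
    )


def simulate_paper_like(seed: int, causal: bool = True, mediation: bool = True,
                        n_variants: Optional[int] = None,
                        round_counts: bool = True):
    """Simulate one paper-like preset replicate.

    Returns ``(panel, genotypes, truth, dataset)``.  All randomness is
    derived from ``seed`` so the replicate is fully reproducible.
    """
    cfg = PAPER_LIKE
    truth = paper_like_truth(causal=causal, mediation=mediation)
    ss = np.random.SeedSequence(seed)
    s_panel, s_geno, s_expr, s_diallel = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)
    )
    panel = make_panel(cfg["n_lines"], cfg["infection_prob"], seed=s_panel)
    genotypes = None
    if causal:
        genotypes = make_genotypes(
            panel,
            n_variants=n_variants if n_variants is not None else cfg["n_variants"],
            maf_range=cfg["maf_range"],
            causal=truth.causal,
            missing_rate=cfg["missing_rate"],
            seed=s_geno,
        )
        if mediation:
            simulate_expression(panel, genotypes, truth, seed=s_expr)
    dataset = simulate_diallel(panel, genotypes, truth, n_reps=cfg["n_reps"],
                               seed=s_diallel, round_counts=round_counts)
    return panel, genotypes, truth, dataset
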