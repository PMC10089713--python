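"""Core containers for diallel-cross productivity experiments.

A full diallel of ``n`` inbred lines crosses every line to every line,
reciprocals and self-crosses included, giving ``n**2`` ordered crosses.
The phenotype is *productivity*: the number of adult offspring emerging
from a standardized parental vial, recorded separately for female and
male offspring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LinePanel",
    "GenotypeMatrix",
    "CausalVariant",
    "MediationTruth",
    "TrueParameters",
    "VialRecord",
    "DiallelDataset",
]

#: infection cells keyed by (female_infected, male_infected)
INFECTION_CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))


class VialRecord(NamedTuple):
    """One replicate vial of a single ordered cross."""

    female_line: str
    male_line: str
    replicate: int
    n_female: int
    n_male: int

    @property
    def total(self) -> int:
        return self.n_female + self.n_male


@dataclass
class LinePanel:
    """A panel of inbred lines with per-line covariates.

    Parameters
    ----------
    line_ids
        Unique, ordered line identifiers.
    infected
        Per-line Wolbachia infection status, 0/1, aligned with ``line_ids``.
    expression
        Optional per-line expression value of the candidate gene
        (log scale); NaN marks a missing value.
    """

    line_ids: list[str]
    infected: np.ndarray
    expression: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        self.infected = np.asarray(self.infected, dtype=int)
        if self.infected.shape != (len(self.line_ids),):
            raise ValueError("infected must align with line_ids")
        if not np.isin(self.infected, (0, 1)).all():
            raise ValueError("infected must be 0/1")
        if self.expression is not None:
            self.expression = pd.Series(
                np.asarray(self.expression, dtype=float), index=self.line_ids
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def infection_status(self) -> pd.Series:
        return pd.Series(self.infected, index=self.line_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinePanel):
            return NotImplemented
        if self.line_ids != other.line_ids:
            return False
        if not np.array_equal(self.infected, other.infected):
            return False
        a, b = self.expression, other.expression
        if (a is None) != (b is None):
            return False
        if a is not None:
            return bool(np.allclose(a.values, b.values, equal_nan=True))
        return True


@dataclass
class GenotypeMatrix:
    """Homozygous line genotypes, coded 0 (major) / 1 (minor) / NaN (missing).

    Inbred lines carry two copies of the same allele, so a single 0/1
    code per line suffices; residually segregating calls are treated as
    missing.
    """

    calls: pd.DataFrame
    positions: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(float)
        vals = self.calls.values
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1 or missing")

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.calls.index]

    @property
    def variant_ids(self) -> list[str]:
        return [str(c) for c in self.calls.columns]

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def maf(self) -> pd.Series:
        """Minor-allele frequency per variant among non-missing lines.

        The stored coding is checked rather than trusted: frequencies
        above 0.5 are folded so 0 <= MAF <= 0.5 always holds.
        """
        freq = self.calls.mean(axis=0, skipna=True)
        return np.minimum(freq, 1.0 - freq).rename("maf")

    def minor_freq(self) -> pd.Series:
        """Frequency of the allele coded 1 (unfolded)."""
        return self.calls.mean(axis=0, skipna=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        if self.calls.shape != other.calls.shape:
            return False
        if list(self.calls.index) != list(other.calls.index):
            return False
        if list(self.calls.columns) != list(other.calls.columns):
            return False
        return bool(
            np.allclose(self.calls.values, other.calls.values, equal_nan=True)
        )


@dataclass
class CausalVariant:
    """Ground-truth causal variant embedded by the generator.

    ``effect_direct`` is the per-minor-allele effect (flies) on the
    female parent's line effect that does not pass through the
    expression mediator.
    """

    variant_id: str
    maf: float
    effect_direct: float

    def total_effect(self, mediation: Optional["MediationTruth"]) -> float:
        """Total per-allele effect on the female line effect (flies)."""
        if mediation is None:
            return self.effect_direct
        return self.effect_direct + mediation.alpha1 * mediation.beta2


@dataclass
class MediationTruth:
    """Ground truth for the SNP -> expression -> productivity pathway.

    expression_i = alpha0 + alpha1 * g_i + e_i,  e_i ~ N(0, sigma_expr^2)
    and the phenotype receives beta2 * expression_i from the female
    parent's line.
    """

    alpha0: float
    alpha1: float
    beta2: float
    sigma_expr: float


@dataclass
class TrueParameters:
    """Generator ground truth for one synthetic diallel world.

    Variances are in flies^2, effects in flies. ``infection_effects``
    maps (female_infected, male_infected) cells to fixed deviations,
    anchored so the uninfected x uninfected cell is 0.
    """

    mu: float
    sigma2_f: float
    sigma2_m: float
    sigma2_fm: float
    sigma2_n: float
    sigma2_nn: float
    sigma2_e: float
    infection_effects: dict = field(
        default_factory=lambda: {c: 0.0 for c in INFECTION_CELLS}
    )
    self_cross_effect: float = 0.0
    causal: Optional[CausalVariant] = None
    mediation: Optional[MediationTruth] = None

    def __post_init__(self) -> None:
        for name in ("sigma2_f", "sigma2_m", "sigma2_fm", "sigma2_n",
                     "sigma2_nn", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.infection_effects = {
            tuple(int(v) for v in k): float(val)
            for k, val in self.infection_effects.items()
        }
        for cell in INFECTION_CELLS:
            self.infection_effects.setdefault(cell, 0.0)
        if self.infection_effects[(0, 0)] != 0.0:
            raise ValueError("infection effects must be anchored at the "
                             "uninfected x uninfected cell")

    # -- expected values on the scale the estimators see ---------------

    def causal_total_effect(self) -> float:
        if self.causal is None:
            return 0.0
        return self.causal.total_effect(self.mediation)

    def expected_components(self) -> dict:
        """Variance components an estimator should recover.

        The causal variant and the expression pathway both act through
        the female parent's line, so their variance folds into the
        female extranuclear component:

            sigma2_f_total = sigma2_f + p(1-p) * a_total^2 + beta2^2 * sigma_expr^2
        """
        f_total = self.sigma2_f
        if self.causal is not None:
            p = self.causal.maf
            f_total += p * (1.0 - p) * self.causal_total_effect() ** 2
        if self.mediation is not None:
            f_total += self.mediation.beta2 ** 2 * self.mediation.sigma_expr ** 2
        out = {
            "sigma2_f": f_total,
            "sigma2_m": self.sigma2_m,
            "sigma2_fm": self.sigma2_fm,
            "sigma2_n": self.sigma2_n,
            "sigma2_nn": self.sigma2_nn,
            "sigma2_e": self.sigma2_e,
        }
        out["sigma2_g"] = (out["sigma2_f"] + out["sigma2_m"] + out["sigma2_fm"]
                           + 2.0 * out["sigma2_n"] + out["sigma2_nn"])
        out["sigma2_p"] = out["sigma2_g"] + out["sigma2_e"]
        return out

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "mu": self.mu,
            "sigma2_f": self.sigma2_f,
            "sigma2_m": self.sigma2_m,
            "sigma2_fm": self.sigma2_fm,
            "sigma2_n": self.sigma2_n,
            "sigma2_nn": self.sigma2_nn,
            "sigma2_e": self.sigma2_e,
            "infection_effects": {
                f"{k[0]},{k[1]}": v for k, v in self.infection_effects.items()
            },
            "self_cross_effect": self.self_cross_effect,
            "causal": None,
            "mediation": None,
        }
        if self.causal is not None:
            d["causal"] = {
                "variant_id": self.causal.variant_id,
                "maf": self.causal.maf,
                "effect_direct": self.causal.effect_direct,
            }
        if self.mediation is not None:
            d["mediation"] = {
                "alpha0": self.mediation.alpha0,
                "alpha1": self.mediation.alpha1,
                "beta2": self.mediation.beta2,
                "sigma_expr": self.mediation.sigma_expr,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParameters":
        causal = d.get("causal")
        mediation = d.get("mediation")
        return cls(
            mu=d["mu"],
            sigma2_f=d["sigma2_f"],
            sigma2_m=d["sigma2_m"],
            sigma2_fm=d["sigma2_fm"],
            sigma2_n=d["sigma2_n"],
            sigma2_nn=d["sigma2_nn"],
            sigma2_e=d["sigma2_e"],
            infection_effects={
                tuple(int(x) for x in k.split(",")): v
                for k, v in d["infection_effects"].items()
            },
            self_cross_effect=d.get("self_cross_effect", 0.0),
            causal=CausalVariant(**causal) if causal else None,
            mediation=MediationTruth(**mediation) if mediation else None,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrueParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


DIALLEL_COLUMNS = ["female_line", "male_line", "replicate", "n_female", "n_male"]


@dataclass
class DiallelDataset:
    """Vial-level productivity records of a (possibly partial) diallel.

    ``df`` has one row per replicate vial with columns
    ``female_line, male_line, replicate, n_female, n_male, total`` and,
    after Wolbachia adjustment, ``total_adjusted``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DIALLEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        df = self.df.copy()
        df["female_line"] = df["female_line"].astype(str)
        df["male_line"] = df["male_line"].astype(str)
        for c in ("replicate", "n_female", "n_male"):
            df[c] = df[c].astype(int)
        if (df[["n_female", "n_male"]].values < 0).any():
            raise ValueError("offspring counts must be non-negative")
        if "total" not in df.columns:
            df["total"] = df["n_female"] + df["n_male"]
        elif not (df["total"] == df["n_female"] + df["n_male"]).all():
            raise ValueError("total must equal n_female + n_male")
        self.df = df.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.df["female_line"]) | set(self.df["male_line"]))

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_reps(self) -> int:
        return int(self.df.groupby(["female_line", "male_line"]).size().max())

    @property
    def is_complete(self) -> bool:
        """True when every (female, male, replicate) combination appears once."""
        n, r = self.n_lines, self.n_reps
        if self.n_records != n * n * r:
            return False
        counts = self.df.groupby(["female_line", "male_line"]).size()
        return len(counts) == n * n and (counts == r).all()

    @property
    def phenotype_column(self) -> str:
        return "total_adjusted" if "total_adjusted" in self.df.columns else "total"

    def phenotype(self) -> np.ndarray:
        return self.df[self.phenotype_column].to_numpy(dtype=float)

    def records(self) -> Iterator[VialRecord]:
        for row in self.df.itertuples(index=False):
            yield VialRecord(row.female_line, row.male_line, int(row.replicate),
                             int(row.n_female), int(row.n_male))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiallelDataset):
            return NotImplemented
        cols = list(self.df.columns)
        if cols != list(other.df.columns):
            return False
        a = self.df.sort_values(DIALLEL_COLUMNS[:3]).reset_index(drop=True)
        b = other.df.sort_values(DIALLEL_COLUMNS[:3]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True
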