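"""End-to-end orchestration: simulate -> adjust -> fit -> GWAS -> mediate.

One YAML configuration drives every stage; each enabled stage writes its
artifacts under the output directory and contributes one summary block
to the run report.  A fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import biomodel, gwas, io, mediation, preprocess, simulate
from .datatypes import DiallelDataset, GenotypeMatrix, LinePanel

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline",
           "load_config"]

log = logging.getLogger("diallelkit")

STAGES = ("simulate", "adjust", "fit", "gwas", "mediate")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: Optional[int] = None
    stages: tuple = STAGES
    preset: Optional[str] = None          # "paper_like" or None
    data: Optional[Path] = None           # diallel TSV when no generator
    panel: Optional[Path] = None
    genotypes: Optional[Path] = None
    maf_min: float = 0.10
    p_threshold: float = 1e-5
    resamples: int = 1000
    causal_variant: Optional[str] = None  # mediation target; default: top hit
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {"out_dir", "seed", "stages", "preset", "data", "panel",
                 "genotypes", "maf_min", "p_threshold", "resamples",
                 "causal_variant"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in d:
            raise ConfigError("config requires out_dir")
        preset = d.get("preset")
        if preset not in (None, "paper_like"):
            raise ConfigError(f"unknown preset {preset!r}")
        default_stages = STAGES if preset else tuple(
            s for s in STAGES if s != "simulate")
        stages = tuple(d.get("stages", default_stages))
        bad = [s for s in stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if preset is None and "simulate" in stages:
            raise ConfigError("stage 'simulate' requires preset: paper_like")
        if preset is None and "data" not in d:
            raise ConfigError("either a preset or a data path is required")
        if preset is not None and d.get("seed") is None:
            raise ConfigError("a seed is mandatory when simulating")
        for key in ("data", "panel", "genotypes"):
            if d.get(key) is not None and not Path(d[key]).exists():
                raise ConfigError(f"{key} path does not exist: {d[key]}")
        return cls(
            out_dir=Path(d["out_dir"]), seed=d.get("seed"), stages=stages,
            preset=preset,
            data=Path(d["data"]) if d.get("data") else None,
            panel=Path(d["panel"]) if d.get("panel") else None,
            genotypes=Path(d["genotypes"]) if d.get("genotypes") else None,
            maf_min=float(d.get("maf_min", 0.10)),
            p_threshold=float(d.get("p_threshold", 1e-5)),
            resamples=int(d.get("resamples", 1000)),
            causal_variant=d.get("causal_variant"),
            raw=dict(d),
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(d)


def _timed(stage):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.time()
            log.info("stage %s ...", stage)
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise StageError(stage, exc) from exc
            log.info("stage %s done in %.1fs", stage, time.time() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and write all artifacts.

    Returns the run report (also written as ``report.json``); a failure
    in any stage raises :class:`StageError` naming the stage.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: str(v) if isinstance(v, Path) else v
                               for k, v in config.raw.items()},
                    "stages": {}}

    panel: Optional[LinePanel] = None
    genotypes: Optional[GenotypeMatrix] = None
    dataset: Optional[DiallelDataset] = None
    truth = None

    if config.preset == "paper_like" and "simulate" in config.stages:
        @_timed("simulate")
        def _simulate():
            return simulate.simulate_paper_like(config.seed)
        panel, genotypes, truth, dataset = _simulate()
        io.write_dataset(dataset, out / "diallel.tsv")
        io.write_panel(panel, out / "panel.tsv")
        if genotypes is not None:
            io.write_genotypes(genotypes, out / "genotypes.tsv")
        truth.to_json(out / "truth.json")
        report["stages"]["simulate"] = {
            "n_lines": panel.n_lines, "n_records": dataset.n_records,
            "mean_total": float(dataset.df["total"].mean()),
        }
    else:
        if config.data is not None:
            dataset = io.read_dataset(config.data)
        if config.panel is not None:
            panel = io.read_panel(config.panel)
        if config.genotypes is not None:
            p = str(config.genotypes)
            genotypes = (io.read_genotypes_vcf(p) if p.endswith(".vcf")
                         else io.read_genotypes(p))

    if "adjust" in config.stages:
        @_timed("adjust")
        def _adjust():
            eff = preprocess.fit_infection_model(dataset, panel)
            adj = preprocess.adjust_productivity(dataset, eff, panel)
            sex = preprocess.sex_ratio_test(dataset)
            return eff, adj, sex
        effects, dataset, sex = _adjust()
        effects.to_json(out / "infection_effects.json")
        io.write_dataset(dataset, out / "diallel_adjusted.tsv")
        report["stages"]["adjust"] = {
            "cell_effects": {f"{k[0]},{k[1]}": v
                             for k, v in effects.cell_effects.items()},
            "sex_ratio": {"female_proportion": sex.female_proportion,
                          "p_value": sex.p_value},
        }

    vc = None
    if "fit" in config.stages:
        @_timed("fit")
        def _fit():
            total = biomodel.total_genetic_model(dataset)
            comps = biomodel.fit_biomodel(dataset)
            return total, comps
        total, vc = _fit()
        part = biomodel.partition_summary(vc)
        part.to_csv(out / "partition.tsv", sep="\t", index=False)
        vc.to_json(out / "biomodel_fit.json")
        report["stages"]["fit"] = {
            "genetic_share_of_phenotypic": total.genetic_share,
            "components": vc.as_dict(),
            "female_share_of_genetic": vc.genetic_shares()["f"],
        }

    gwas_table = None
    linemeans = None
    if "gwas" in config.stages:
        @_timed("gwas")
        def _gwas():
            lm = gwas.female_line_means(dataset)
            filt = gwas.filter_variants(genotypes, config.maf_min)
            s2g = (gwas.linemean_genetic_variance(vc, dataset.n_lines)
                   if vc is not None else None)
            table = gwas.run_gwas(lm, filt, p_threshold=config.p_threshold,
                                  sigma2_g_linemeans=s2g)
            return lm, table
        linemeans, gwas_table = _gwas()
        gwas_table.to_csv(out / "gwas.tsv", sep="\t", index=False)
        top = gwas_table.head(5)
        report["stages"]["gwas"] = {
            "n_tested": len(gwas_table),
            "n_significant": int(gwas_table["significant"].sum())
            if len(gwas_table) else 0,
            "top": top[["variant_id", "effect", "p_value"]]
            .to_dict("records"),
        }

    if "mediate" in config.stages:
        @_timed("mediate")
        def _mediate():
            if panel is None or panel.expression is None:
                raise ValueError("mediation requires panel expression values")
            target = config.causal_variant
            if target is None:
                if gwas_table is None or not len(gwas_table):
                    raise ValueError("no GWAS table to pick the top variant "
                                     "from; set causal_variant explicitly")
                target = gwas_table.iloc[0]["variant_id"]
            lm = linemeans or gwas.female_line_means(dataset)
            return target, mediation.fit_mediation(
                genotypes.calls[target], panel.expression, lm.means,
                n_resamples=config.resamples, seed=config.seed or 0)
        target, med = _mediate()
        med.to_json(out / "mediation.json")
        report["stages"]["mediate"] = {
            "variant": str(target), "acme": med.acme, "ade": med.ade,
            "total_effect": med.total_effect,
            "prop_mediated": med.prop_mediated,
        }

    tmp = out / "report.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    tmp.replace(out / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
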