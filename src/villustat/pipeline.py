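"""Pipeline orchestration: config, stage chaining, run report.

A run either simulates one or more conditions (WT-like / cKO-like sections,
repertoires, compositions) or loads user tables, then chains
SAP -> crypt regions -> scoring -> compositional statistics -> proximity
network, writing every stage artifact plus a JSON run report. Identical
config + inputs + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition as comp_mod
from . import io as vio
from . import proximity as prox_mod
from . import sap as sap_mod
from . import scoring as score_mod
from . import signatures as sigs
from . import simulate as sim_mod
from .types import PipelineError, RunReport, ValidationError

logger = logging.getLogger(__name__)

_TISSUE_PRESETS = {
    "wt_like": sim_mod.wt_like_tissue,
    "cko_like": sim_mod.cko_like_tissue,
    "generic": lambda seed=0, **kw: sim_mod.TissueConfig(seed=seed, **kw),
}
_REPERTOIRE_PRESETS = {
    "wt_like": sim_mod.wt_like_repertoire,
    "cko_like": sim_mod.cko_like_repertoire,
}


def _default_conditions() -> dict:
    return {
        "WT": {"tissue": {"preset": "wt_like"}, "repertoire": {"preset": "wt_like"}},
        "cKO": {"tissue": {"preset": "cko_like"}, "repertoire": {"preset": "cko_like"}},
    }


def _default_composition() -> dict:
    return {
        "n_per_sample": {"WT_1": 5000, "WT_2": 5000, "cKO_1": 5000, "cKO_2": 5000},
        "sample_groups": {"WT_1": "WT", "WT_2": "WT", "cKO_1": "cKO", "cKO_2": "cKO"},
        "subset_probs": {
            "WT": {"CD4_Tn": 0.30, "CD4_Tem": 0.15, "CD8_Tn": 0.25,
                   "CD8_Tem": 0.12, "CD8_Teff": 0.08, "Treg": 0.10},
            "cKO": {"CD4_Tn": 0.24, "CD4_Tem": 0.15, "CD8_Tn": 0.20,
                    "CD8_Tem": 0.12, "CD8_Teff": 0.19, "Treg": 0.10},
        },
    }


@dataclass
class PipelineConfig:
    """Everything one run needs; unknown keys in a config file are rejected."""

    outdir: str = "villustat_out"
    seed: int = 0
    conditions: dict = field(default_factory=_default_conditions)
    composition: dict | None = field(default_factory=_default_composition)
    inputs: dict | None = None          # alternative to simulated conditions
    normalization_scale: float = 1e4
    positive_rate_genes: list = field(
        default_factory=lambda: list(sigs.PROLIFERATION_GENES)
    )
    positive_rate_threshold: int = 0
    region_radius_factor: float = 3.0   # x spot pitch
    proximity_radius_factor: float = 3.0
    n_perm: int = 1000
    include_unclear: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _tissue_config(spec: dict, seed: int, condition: str) -> sim_mod.TissueConfig:
    spec = dict(spec or {})
    preset = spec.pop("preset", "generic")
    if preset not in _TISSUE_PRESETS:
        raise ValidationError(f"unknown tissue preset {preset!r}")
    cfg = _TISSUE_PRESETS[preset](seed=seed)
    spec.setdefault("condition", condition)
    return cfg.replace(**spec) if spec else cfg


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            # timings are logged, never written: the report must be a pure
            # function of inputs + config + seeds
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo = config.echo()
    report = RunReport(config_echo=echo)
    data: dict[str, dict] = {}   # per-condition spots/counts/pitch

    if config.inputs is not None:
        with _stage(report, "load"):
            spots = vio.read_spot_table(config.inputs["spots"])
            counts = vio.read_counts(config.inputs["counts"])
            data["input"] = {"spots": spots, "counts": counts}
            for key in ("spots", "clonotypes", "composition"):
                if key in config.inputs:
                    report.input_checksums[key] = vio.sha256_of(config.inputs[key])
    else:
        with _stage(report, "simulate"):
            for i, name in enumerate(sorted(config.conditions)):
                cond = config.conditions[name]
                tcfg = _tissue_config(cond.get("tissue"), config.seed + i, name)
                spots, counts, gt = sim_mod.simulate_section(tcfg)
                cdir = outdir / name
                vio.write_spot_table(spots, cdir / "spots.tsv", echo)
                vio.write_counts(counts, cdir / "counts")
                (cdir / "ground_truth.json").write_text(
                    json.dumps(gt, indent=2, sort_keys=True)
                )
                data[name] = {"spots": spots, "counts": counts,
                              "pitch": tcfg.spot_pitch_um, "ground_truth": gt}
            report.stage_summaries["simulate"] = {
                name: {"n_spots": len(d["spots"])} for name, d in data.items()
            }

    with _stage(report, "sap"):
        for name, d in data.items():
            sap_df = sap_mod.compute_sap(d["spots"])
            pitch = d.get("pitch") or sap_mod._grid_indices(d["spots"], None)[2]
            d["pitch"] = pitch
            regions = sap_mod.define_crypt_regions(d["spots"], pitch=pitch)
            region_map = sap_mod.assign_spots_to_regions(
                d["spots"], regions, radius_um=config.region_radius_factor * pitch
            )
            d["sap"], d["regions"], d["region_map"] = sap_df, regions, region_map
            cdir = outdir / name
            vio.write_table(sap_df, cdir / "sap.tsv", echo)
            membership = pd.DataFrame(
                [(r.region_id, s) for r in regions for s in r.spot_ids],
                columns=["region_id", "spot_id"],
            )
            vio.write_table(membership, cdir / "crypt_regions.tsv", echo)
            report.stage_summaries.setdefault("sap", {})[name] = {
                "n_regions": len(regions),
                "n_assigned": int(region_map.notna().sum()),
            }

    with _stage(report, "score"):
        for name, d in data.items():
            spots, counts = d["spots"], d["counts"]
            lognorm = score_mod.normalize_counts(counts, config.normalization_scale)
            s_m1 = score_mod.signature_score(lognorm, sigs.DEFAULT_M1)
            s_m2 = score_mod.signature_score(lognorm, sigs.DEFAULT_M2)
            delta = score_mod.polarization_delta(s_m1, s_m2)
            vio.write_table(delta, outdir / name / "polarization.tsv", echo)

            rate_rows = []
            t_spots = spots.loc[spots["cell_type"].isin(["CD4T", "CD8T"]), "spot_id"]
            crypt_spots = spots.loc[spots["compartment"] == "crypt", "spot_id"]
            for gene in config.positive_rate_genes:
                for pop, subset in (("T_cell", t_spots), ("crypt", crypt_spots)):
                    if len(subset) == 0 or gene not in counts.var_names:
                        continue
                    pr = score_mod.positive_rate(
                        counts, gene, subset, config.positive_rate_threshold
                    )
                    rate_rows.append((pop, gene, pr.rate, pr.n_positive, pr.n_total))
            rates = pd.DataFrame(
                rate_rows,
                columns=["population", "gene", "rate", "n_positive", "n_total"],
            )
            vio.write_table(rates, outdir / name / "positive_rates.tsv", echo)
            d["polarization"], d["positive_rates"] = delta, rates

            macro = spots["cell_type"].isin(["M1", "M2"]).to_numpy()
            crypt_zone = d["region_map"].notna()
            macro_ids = set(spots.loc[macro, "spot_id"]) & set(
                crypt_zone.index[crypt_zone]
            )
            sel = delta["spot_id"].isin(macro_ids)
            report.stage_summaries.setdefault("score", {})[name] = {
                "mean_crypt_macrophage_delta": (
                    float(delta.loc[sel, "delta"].mean()) if sel.any() else None
                ),
            }

    with _stage(report, "composition"):
        if config.inputs is not None and "composition" in (config.inputs or {}):
            comp = vio.read_composition(config.inputs["composition"])
        elif config.composition is not None:
            c = config.composition
            comp = sim_mod.simulate_composition(
                c["n_per_sample"], c["subset_probs"], c["sample_groups"],
                seed=config.seed,
            )
        else:
            comp = None
        if comp is not None:
            roe = comp_mod.roe_scores(comp)
            vio.write_roe(roe, outdir / "roe.tsv", outdir / "roe.json", echo)
            report.stage_summaries["composition"] = {
                "groups": list(roe.roe.index), "subsets": list(roe.roe.columns),
            }

    with _stage(report, "diversity"):
        if config.inputs is not None and "clonotypes" in (config.inputs or {}):
            clones = vio.read_clonotypes(config.inputs["clonotypes"])
        elif config.inputs is None:
            frames = []
            for i, name in enumerate(sorted(config.conditions)):
                spec = dict(config.conditions[name].get("repertoire") or {})
                preset = spec.pop("preset", "wt_like")
                rcfg = _REPERTOIRE_PRESETS[preset](
                    seed=config.seed + 100 + i, sample=f"{name}_1"
                )
                frames.append(sim_mod.simulate_repertoire(rcfg))
            clones = pd.concat(frames, ignore_index=True)
        else:
            clones = None
        if clones is not None:
            div = comp_mod.repertoire_diversity(clones, per_subset=True)
            classes = comp_mod.clonal_size_classes(clones)
            vio.write_table(div, outdir / "diversity.tsv", echo)
            vio.write_table(classes, outdir / "clonal_size_classes.tsv", echo)
            report.stage_summaries["diversity"] = {
                "samples": sorted(set(clones["sample"])),
            }

    with _stage(report, "proximity"):
        for name, d in data.items():
            radius = config.proximity_radius_factor * d["pitch"]
            edges = prox_mod.permutation_null(
                d["spots"], radius, d["region_map"],
                n_perm=config.n_perm, seed=config.seed + 1000,
                include_unclear=config.include_unclear,
            )
            vio.write_table(edges, outdir / name / "proximity_edges.tsv", echo)
            doc = {
                "radius_um": radius, "n_perm": config.n_perm,
                "edges": edges.drop(columns=[]).to_dict(orient="records"),
            }
            (outdir / name / "proximity.json").write_text(
                json.dumps(doc, indent=2, sort_keys=True, default=_json_default)
            )
            report.stage_summaries.setdefault("proximity", {})[name] = {
                "n_edges": len(edges),
            }
            d["proximity"] = edges

    (outdir / "report.json").write_text(
        json.dumps(
            {
                "config": report.config_echo,
                "input_checksums": report.input_checksums,
                "stages": report.stage_summaries,
                "warnings": report.warnings,
            },
            indent=2, sort_keys=True, default=_json_default,
        )
    )
    return report


def _json_default(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, float) and np.isnan(v):
        return None
    return str(v)


def demo_config(outdir, seed: int = 0) -> PipelineConfig:
    """The bundled end-to-end demo: two ~24k-spot sections with 1,000 genes."""
    cfg = PipelineConfig(outdir=str(outdir), seed=seed)
    for cond in cfg.conditions.values():
        cond["tissue"]["n_genes"] = 1000
    return cfg
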