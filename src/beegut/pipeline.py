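"""End-to-end orchestration of the analysis stages.

The pipeline runs: (optional) simulation -> qPCR quantification ->
taxonomy + contaminant filtering -> absolute-abundance table -> community
ecology (distances, PCoA, PERMANOVA/ANOSIM/PERMDISP) -> per-ASV
permutation ANOVA + Venn -> physiology statistics + UPGMA heatmap ->
survival and consumption. Every stage writes plain-text outputs into the
output directory and is recorded, with its derived seed, in a JSON
manifest; identical configurations reproduce all numeric outputs.
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

from . import (
    absolute_abundance,
    asv_filtering,
    community_ecology,
    differential_asv,
    physiology,
    qpcr,
    survival_consumption,
    synthetic_data,
)

log = logging.getLogger("beegut")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

ALL_STAGES = ("qpcr", "filter", "abundance", "ecology", "asvtest", "physiology",
              "survival", "cluster")


@dataclass
class PipelineConfig:
    output_dir: str = "beegut_out"
    seed: int = 0
    simulate: synthetic_data.SimulationConfig | None = None
    input_dir: str | None = None       # read a written dataset when simulate is None
    n_permutations: int = 999
    n_permutations_asv: int = 10_000
    alpha: float = 0.05
    contaminant_threshold: float = asv_filtering.DEFAULT_CONTAMINANT_THRESHOLD
    prevalence_floor: float = differential_asv.DEFAULT_PREVALENCE_FLOOR
    stages: tuple = ALL_STAGES

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either simulate or input_dir must be given")


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        ds = synthetic_data.simulate_experiment(config.simulate)
        return {
            "asv_counts": ds.asv_counts,
            "taxonomy": ds.taxonomy,
            "tree": ds.tree_newick,
            "metadata": ds.metadata,
            "cq": ds.cq_table,
            "dilutions": ds.dilution_series,
            "enzymes": ds.enzyme_table,
            "survival": ds.survival_log,
            "feeder": ds.feeder_log,
        }
    raw = synthetic_data.read_dataset(config.input_dir)
    raw["tree"] = raw["tree"]
    return raw


def validate_inputs(tables: dict) -> list[str]:
    """Schema and cross-reference checks; returns a report of problems."""
    report = []
    counts = tables.get("asv_counts")
    meta = tables.get("metadata")
    if counts is None or meta is None:
        return ["asv_counts and metadata are required"]
    for s in counts.index:
        if s not in meta.index:
            report.append(f"counts sample {s!r} absent from metadata")
    if (counts.to_numpy() < 0).any():
        report.append("negative entries in asv_counts")
    cq = tables.get("cq")
    if cq is not None:
        missing = {"sample", "gene", "cq"} - set(cq.columns)
        if missing:
            report.append(f"cq table missing columns {sorted(missing)}")
    tree = tables.get("tree")
    if tree:
        import dendropy

        try:
            t = dendropy.Tree.get(data=tree, schema="newick")
            leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
            for asv in counts.columns:
                if asv not in leaves:
                    report.append(f"tree missing ASV leaf {asv!r}")
        except Exception as exc:  # malformed newick
            report.append(f"tree failed to parse: {exc}")
    surv = tables.get("survival")
    if surv is not None:
        for cage, sub in surv.sort_values("day").groupby("cage"):
            alive = sub["alive"].to_numpy()
            if (np.diff(alive) > 0).any():
                report.append(f"cage {cage}: alive counts increase over time")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the output-file manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "files": {}}
    results_json = {}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    current_stage = "inputs"
    try:
        t0 = time.time()
        tables = _load_inputs(config)
        counts, meta = tables["asv_counts"], tables["metadata"]
        log.info("inputs loaded: %d samples x %d ASVs", *counts.shape)

        problems = validate_inputs(tables)
        if problems:
            raise RuntimeError(f"input validation failed: {problems[:5]}")

        def record(stage, files):
            manifest["stages"][stage] = {
                "seed": _stage_seed(config.seed, stage),
                "elapsed_s": round(time.time() - t0, 2),
            }
            manifest["files"].update(files)
            log.info("stage %s done (%.2fs elapsed, %d files)", stage,
                     time.time() - t0, len(files))

        # ---------------- qPCR
        loads = None
        current_stage = "qpcr"
        if "qpcr" in config.stages:
            loads, curves = qpcr.quantify(tables["cq"], tables["dilutions"])
            path = out / "loads.tsv"
            loads.to_csv(path, sep="\t")
            gut_meta = meta[~meta["is_blank"]]
            comp = qpcr.compare_loads(
                loads["cells_per_gut"], gut_meta.loc[loads.index, "colonization"]
            )
            results_json["load_comparison"] = {
                "statistic": comp.statistic,
                "p_value": comp.p_value,
                "median_ratio_CL_MD": comp.extra["median_ratio"],
            }
            record("qpcr", {"loads": str(path)})

        # ---------------- filtering
        current_stage = "filter"
        if "filter" in config.stages:
            filtered, removed = asv_filtering.taxonomy_filter(counts, tables["taxonomy"])
            load_series = (
                loads["normalized_16S"]
                if loads is not None
                else filtered[~meta["is_blank"]].sum(axis=1)
            )
            calls = asv_filtering.identify_contaminants(
                filtered,
                meta["is_blank"],
                load_series,
                strata=meta.loc[~meta["is_blank"], "colonization"],
                threshold=config.contaminant_threshold,
            )
            counts = asv_filtering.remove_contaminants(filtered, calls, meta["is_blank"])
            path = out / "contaminants.tsv"
            calls.to_csv(path, sep="\t")
            results_json["filtering"] = {
                "organellar_removed": removed,
                "contaminants_removed": sorted(calls.index[calls["is_contaminant"]]),
            }
            record("filter", {"contaminants": str(path)})

        # ---------------- absolute abundance
        abs_table = None
        current_stage = "abundance"
        if "abundance" in config.stages:
            if loads is None:
                raise RuntimeError("abundance stage requires the qpcr stage")
            abs_table = absolute_abundance.build_absolute_table(
                counts, loads["normalized_16S"]
            )
            path = out / "abs_abund.tsv"
            abs_table.to_csv(path, sep="\t")
            record("abundance", {"abs_abund": str(path)})

        # ---------------- community ecology
        current_stage = "ecology"
        if "ecology" in config.stages and abs_table is not None:
            seed = _stage_seed(config.seed, "ecology")
            gut_meta = meta.loc[abs_table.index]
            bc = community_ecology.bray_curtis(abs_table)
            wu = community_ecology.weighted_unifrac(abs_table, tables["tree"])
            uu = community_ecology.unweighted_unifrac(abs_table, tables["tree"])
            ord_res = community_ecology.pcoa(bc)
            files = {}
            for name, dm in (("braycurtis", bc), ("weighted_unifrac", wu),
                             ("unweighted_unifrac", uu)):
                p = out / f"dist_{name}.tsv"
                dm.to_frame().to_csv(p, sep="\t")
                files[f"dist_{name}"] = str(p)
            p = out / "pcoa_coordinates.tsv"
            ord_res.coordinates.to_csv(p, sep="\t")
            files["pcoa"] = str(p)
            grouping = gut_meta["colonization"]
            eco = {}
            eco["permanova_braycurtis_colonization"] = community_ecology.permanova(
                bc, grouping, config.n_permutations, seed
            )
            eco["anosim_weighted_unifrac_colonization"] = community_ecology.anosim(
                wu, grouping, config.n_permutations, seed + 1
            )
            eco["anosim_unweighted_unifrac_colonization"] = community_ecology.anosim(
                uu, grouping, config.n_permutations, seed + 2
            )
            for stratum in ("CL", "MD"):
                ids = gut_meta.index[gut_meta["colonization"] == stratum]
                sub = bc.filter(list(ids))
                eco[f"permanova_braycurtis_pesticide_{stratum}"] = (
                    community_ecology.permanova(
                        sub, gut_meta.loc[ids, "pesticide"], config.n_permutations, seed + 3
                    )
                )
                eco[f"permdisp_braycurtis_pesticide_{stratum}"] = (
                    community_ecology.permdisp(
                        sub, gut_meta.loc[ids, "pesticide"], config.n_permutations, seed + 4
                    )
                )
            results_json["ecology"] = {
                k: {
                    "statistic": v.statistic,
                    "p_value": v.p_value,
                    "effect_size": v.effect_size,
                    "n_permutations": v.n_permutations,
                }
                for k, v in eco.items()
            }
            record("ecology", files)

        # ---------------- per-ASV tests
        current_stage = "asvtest"
        if "asvtest" in config.stages and abs_table is not None:
            res = differential_asv.run_all_asvs(
                abs_table,
                meta.loc[abs_table.index],
                n_permutations=config.n_permutations_asv,
                master_seed=_stage_seed(config.seed, "asvtest"),
                prevalence_floor=config.prevalence_floor,
                alpha=config.alpha,
            )
            frame = differential_asv.records_to_frame(res)
            path = out / "asv_tests.tsv"
            frame.to_csv(path, sep="\t", index=False)
            sig = {
                s: {r.asv for r in recs if r.significant} for s, recs in res.items()
            }
            venn = differential_asv.venn_partition(sig.get("CL", set()), sig.get("MD", set()))
            vpath = out / "venn.json"
            vpath.write_text(json.dumps(
                {"CL": sorted(venn.set_a), "MD": sorted(venn.set_b), **venn.counts}, indent=1
            ))
            results_json["asv_tests"] = venn.counts
            record("asvtest", {"asv_tests": str(path), "venn": str(vpath)})

        # ---------------- physiology
        norm = None
        current_stage = "physiology"
        if "physiology" in config.stages:
            tests = physiology.marker_treatment_tests(tables["enzymes"], alpha=config.alpha)
            contrasts = physiology.colonization_contrast(tables["enzymes"], alpha=config.alpha)
            path = out / "physiology_tests.tsv"
            tests.drop(columns=["posthoc"]).to_csv(path, sep="\t", index=False)
            cpath = out / "colonization_contrasts.tsv"
            contrasts.to_csv(cpath, sep="\t", index=False)
            mat = physiology.marker_matrix(tables["enzymes"])
            norm = physiology.control_normalize(mat)
            npath = out / "normalized_matrix.tsv"
            norm.to_csv(npath, sep="\t")
            results_json["physiology"] = {
                "n_significant_treatment_tests": int((tests["p_value"] < config.alpha).sum()),
                "n_significant_colonization_contrasts": int(
                    (contrasts["p_value"] < config.alpha).sum()
                ),
            }
            record("physiology", {"physiology_tests": str(path),
                                  "colonization_contrasts": str(cpath),
                                  "normalized_matrix": str(npath)})

        # ---------------- survival / consumption
        current_stage = "survival"
        if "survival" in config.stages:
            surv, feeder = tables["survival"], tables["feeder"]
            cage_info = surv[["cage"]].drop_duplicates().set_index("cage")
            cage_treat = pd.Series(
                {c: ".".join(c.split(".")[:2]) for c in cage_info.index}, name="treatment"
            )
            groups = {}
            for cage, sub in surv.sort_values("day").groupby("cage"):
                deaths = dict(zip(sub["day"], sub["deaths"]))
                n0 = int(sub.iloc[0]["alive"] + sub.iloc[0]["deaths"])
                groups.setdefault(cage_treat[cage], []).append((deaths, n0))
            merged = {}
            for treat, cages_list in groups.items():
                deaths = {}
                n0 = 0
                for d, n in cages_list:
                    n0 += n
                    for day, c in d.items():
                        deaths[day] = deaths.get(day, 0) + c
                merged[treat] = (deaths, n0)
            omnibus, posthoc = survival_consumption.logrank(merged)
            evap = feeder[feeder["cage"] == "evaporation_control"].set_index("day")[
                "mass_consumed"
            ]
            feeding = feeder[feeder["cage"] != "evaporation_control"]
            series = survival_consumption.consumption_series(
                feeding.rename(columns={"mass_consumed": "mass_consumed"}),
                evap,
                surv,
            )
            cons = survival_consumption.compare_consumption(series, cage_treat)
            spath = out / "logrank.json"
            spath.write_text(json.dumps({"statistic": omnibus.statistic,
                                         "p_value": omnibus.p_value,
                                         "df": omnibus.df}, indent=1))
            cpath = out / "consumption.tsv"
            series.to_csv(cpath, sep="\t", index=False)
            results_json["survival"] = {"logrank_statistic": omnibus.statistic,
                                        "logrank_p": omnibus.p_value}
            results_json["consumption"] = {"kruskal_statistic": cons.statistic,
                                           "kruskal_p": cons.p_value}
            record("survival", {"logrank": str(spath), "consumption": str(cpath)})

        # ---------------- clustering / heatmap
        current_stage = "cluster"
        if "cluster" in config.stages and norm is not None:
            rows = physiology.upgma_cluster(norm, axis="rows")
            cols = physiology.upgma_cluster(norm, axis="columns")
            rpath = out / "dendrogram_rows.nwk"
            cpath = out / "dendrogram_columns.nwk"
            rpath.write_text(rows.to_newick() + "\n")
            cpath.write_text(cols.to_newick() + "\n")
            hpath = out / "heatmap.png"
            physiology.render_heatmap(norm, hpath, rows, cols)
            record("cluster", {"dendrogram_rows": str(rpath),
                               "dendrogram_columns": str(cpath),
                               "heatmap": str(hpath)})

    except Exception as exc:
        log.error("stage %s failed: %s", current_stage, exc)
        raise RuntimeError(
            f"pipeline stage {current_stage!r} failed: {exc}"
        ) from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    rpath = out / "results.json"
    rpath.write_text(json.dumps(results_json, indent=1, default=float))
    manifest["files"]["results"] = str(rpath)
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    manifest["files"]["manifest"] = str(mpath)
    return manifest


def config_from_dict(d: dict) -> PipelineConfig:
    sim = d.pop("simulate", None)
    if sim is not None:
        fields = {f.name for f in dataclasses.fields(synthetic_data.SimulationConfig)}
        sim = synthetic_data.SimulationConfig(**{k: v for k, v in sim.items() if k in fields})
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    return PipelineConfig(simulate=sim, **{k: v for k, v in d.items() if k in fields})
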