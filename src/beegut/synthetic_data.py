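"""In-silico replica of the factorial cage experiment.

The generator emulates the full study design: newly emerged bees either
colonized with a gut homogenate (CL) or left microbiota-depleted (MD),
exposed to five pesticide treatments (Control, Insecticide, Herbicide,
Fungicide, Mix) in four cages of 30 bees per treatment combination, with
four guts sequenced per cage (160 gut samples) plus 16 blank extractions.

Data-generating assumptions, all configurable:

* total gut loads are lognormal, with the CL mean a fixed fold (default 3)
  above the MD mean;
* within-stratum compositions are Dirichlet-multinomial around stratum base
  profiles — CL dominated by the core phylotype genera (Gilliamella,
  Snodgrassella, Bifidobacterium, Lactobacillus, Frischella), MD by
  hive-environment opportunists;
* treatment effects multiply the expected absolute abundance of target ASVs
  (default: low-abundance opportunists in MD only), leaving other ASVs'
  absolute abundances untouched;
* reagent contaminants enter at an absolute level independent of the
  sample's bacterial load, so their relative abundance falls as load rises;
  they dominate blank extractions. "Sporadic" contaminants additionally hit
  only a fraction of true-sample extractions, enriching them in blanks;
* host organellar ASVs (mitochondria / chloroplast lineage) appear at a
  small constant level in true samples;
* Cq values invert the qPCR standard-curve relation with Gaussian replicate
  noise; a shared per-sample extraction-efficiency factor multiplies both
  the 16S and actin signals (which the actin normalization cancels);
* enzyme activities are Gaussian around treatment-specific means; survival
  is daily-binomial with a per-treatment hazard (null by default); feeder
  mass changes combine per-bee intake, evaporation and weighing noise.

Identical seeds produce bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .physiology import VALID_COMBINATIONS
from .qpcr import StandardCurve, cq_from_copies, DEFAULT_ELUTION_VOLUME_UL, RRNA_LOCI_PER_CELL

__all__ = [
    "AsvEffect",
    "EnzymeEffect",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_experiment",
    "write_dataset",
    "read_dataset",
]

CORE_GENERA = ("Lactobacillus", "Gilliamella", "Snodgrassella", "Bifidobacterium", "Frischella")
OPPORTUNIST_GENERA = (
    "Fructobacillus", "Bombella", "Apilactobacillus", "Enterobacter", "Klebsiella",
    "Acinetobacter", "Pseudomonas", "Erwinia", "Pantoea", "Arsenophonus",
)
CONTAMINANT_GENERA = ("Ralstonia", "Sphingomonas", "Cutibacterium", "Bradyrhizobium", "Delftia")


@dataclass(frozen=True)
class AsvEffect:
    """Multiplicative treatment effect on one ASV's expected absolute abundance."""

    asv: str
    stratum: str
    treatment: str
    fold: float


@dataclass(frozen=True)
class EnzymeEffect:
    """Relative shift of one marker's mean activity under one treatment."""

    tissue: str
    marker: str
    stratum: str
    treatment: str
    shift: float  # +0.5 means a 50% increase over the stratum control mean


def _default_asv_effects() -> tuple:
    # low-abundance opportunists perturbed in the microbiota-depleted stratum
    # only; ten-fold shifts approximate five within-group standard deviations
    # on the log scale at the default load CV
    return (
        AsvEffect("Opp06", "MD", "Insecticide", 10.0),
        AsvEffect("Opp07", "MD", "Fungicide", 10.0),
        AsvEffect("Opp08", "MD", "Herbicide", 10.0),
        AsvEffect("Opp09", "MD", "Mix", 10.0),
        AsvEffect("Opp10", "MD", "Insecticide", 0.1),
    )


def _default_enzyme_effects() -> tuple:
    # mirrors the reported pattern: the fungicide raises head LDH in both
    # strata; herbicide and Mix raise head LDH and midgut GST in MD only
    return (
        EnzymeEffect("head", "LDH", "CL", "Fungicide", 0.5),
        EnzymeEffect("head", "LDH", "MD", "Fungicide", 0.6),
        EnzymeEffect("head", "LDH", "MD", "Herbicide", 0.4),
        EnzymeEffect("head", "LDH", "MD", "Mix", 0.6),
        EnzymeEffect("midgut", "GST", "CL", "Fungicide", -0.3),
        EnzymeEffect("midgut", "GST", "MD", "Herbicide", 0.3),
        EnzymeEffect("midgut", "GST", "MD", "Mix", 0.35),
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    colonization_levels: tuple = ("CL", "MD")
    pesticide_treatments: tuple = ("Control", "Insecticide", "Herbicide", "Fungicide", "Mix")
    cages_per_treatment: int = 4
    bees_per_cage: int = 30
    guts_per_treatment: int = 16   # 4 guts x 4 cages
    n_blanks: int = 16
    n_core_asvs: int = 10
    n_opportunist_asvs: int = 20
    n_contaminant_asvs: int = 5
    n_organelle_asvs: int = 2
    mean_load_MD: float = 5e6            # cells per gut
    load_ratio_CL_MD: float = 3.0
    load_cv: float = 0.5
    dirichlet_concentration: float = 50.0
    sequencing_depth_mean: float = 20_000.0
    blank_depth_fraction: float = 0.1
    contaminant_level: float = 2e4       # 16S copies-equivalent per extraction
    sporadic_sample_rate: float = 0.4    # sporadic contaminants hit this fraction of samples
    sporadic_blank_rate: float = 0.9
    organelle_level: float = 3e4
    effect_map: tuple = field(default_factory=_default_asv_effects)
    enzyme_effect_map: tuple = field(default_factory=_default_enzyme_effects)
    enzyme_cv: float = 0.10
    physiology_reps: int = 7
    exposure_days: int = 5
    daily_hazard: dict = field(default_factory=dict)   # treatment -> probability
    base_hazard: float = 0.02
    consumption_mean: float = 0.040      # g sucrose solution per bee per day
    consumption_sd: float = 0.006
    evaporation_mean: float = 0.10       # g per feeder per day
    evaporation_sd: float = 0.01
    weighing_sd: float = 0.05            # g, feeder balance noise
    cq_noise_sd: float = 0.15            # cycles, per technical replicate
    dilution_noise_sd: float = 0.05      # cycles, standard-curve points
    extraction_cv: float = 0.2
    elution_volume: float = DEFAULT_ELUTION_VOLUME_UL
    # midgut GST is higher in colonized bees at baseline
    colonization_baseline: tuple = (("midgut", "GST", "CL", 1.4),)

    def __post_init__(self):
        for name in ("cages_per_treatment", "bees_per_cage", "guts_per_treatment",
                     "n_blanks", "n_core_asvs", "n_opportunist_asvs", "physiology_reps",
                     "exposure_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.load_ratio_CL_MD <= 0:
            raise ValueError("load_ratio_CL_MD must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.sequencing_depth_mean <= 0:
            raise ValueError("sequencing depth must be positive")
        if len(set(self.pesticide_treatments)) != len(self.pesticide_treatments):
            raise ValueError("pesticide treatment labels must be unique")
        for t, h in self.daily_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"daily hazard for {t!r} outside [0, 1]")
        if not 0.0 <= self.base_hazard <= 1.0:
            raise ValueError("base_hazard outside [0, 1]")

    def hazard_for(self, treatment: str) -> float:
        return self.daily_hazard.get(treatment, self.base_hazard)


@dataclass
class GroundTruth:
    true_cells_per_gut: pd.Series
    true_proportions: pd.DataFrame     # gut-bacterial ASVs only; rows sum to 1
    true_contaminants: frozenset
    true_organelles: frozenset
    effect_map: tuple
    enzyme_effect_map: tuple
    enzyme_means: pd.DataFrame         # (tissue, marker, colonization, treatment) -> mean


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    asv_counts: pd.DataFrame           # samples (incl. blanks) x ASVs, integers
    taxonomy: pd.DataFrame             # ASV -> ranked lineage
    tree_newick: str
    metadata: pd.DataFrame             # sample -> colonization, pesticide, cage, is_blank
    cq_table: pd.DataFrame             # sample, gene, replicate, cq
    dilution_series: pd.DataFrame      # gene, copies, cq
    enzyme_table: pd.DataFrame         # tissue, marker, colonization, treatment, replicate, activity
    survival_log: pd.DataFrame         # cage, day, deaths, alive
    feeder_log: pd.DataFrame           # cage, day, mass_consumed (incl. evaporation_control rows)
    truth: GroundTruth

    @property
    def gut_samples(self) -> list:
        return list(self.metadata.index[~self.metadata["is_blank"]])

    @property
    def blank_samples(self) -> list:
        return list(self.metadata.index[self.metadata["is_blank"]])


# ------------------------------------------------------------------ helpers

def _random_binary_tree(labels, rng) -> str:
    """Coalescent-style random binary merge tree with unit-scale branch lengths."""
    nodes = {lab: (lab, 0.0) for lab in labels}   # newick fragment, height
    active = list(labels)
    height = 0.0
    while len(active) > 1:
        height += float(rng.exponential(1.0 / len(active)))
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]   # pop higher index first
        fa, ha = nodes.pop(a)
        fb, hb = nodes.pop(b)
        new = f"({fa}:{height - ha:.6f},{fb}:{height - hb:.6f})"
        key = f"__{len(nodes)}_{a}"
        nodes[key] = (new, height)
        active = [x for x in active if x not in (a, b)] + [key]
    return nodes[active[0]][0] + ";"


def _taxonomy_table(core, opportunists, contaminants, organelles) -> pd.DataFrame:
    rows = {}
    for i, asv in enumerate(core):
        genus = CORE_GENERA[i % len(CORE_GENERA)]
        rows[asv] = ("Bacteria", "Firmicutes" if genus == "Lactobacillus" else "Proteobacteria",
                     "c__", "o__", "f__", genus)
    for i, asv in enumerate(opportunists):
        genus = OPPORTUNIST_GENERA[i % len(OPPORTUNIST_GENERA)]
        rows[asv] = ("Bacteria", "Proteobacteria", "c__", "o__", "f__", genus)
    for i, asv in enumerate(contaminants):
        genus = CONTAMINANT_GENERA[i % len(CONTAMINANT_GENERA)]
        rows[asv] = ("Bacteria", "Proteobacteria", "c__", "o__", "f__", genus)
    for i, asv in enumerate(organelles):
        if i % 2 == 0:
            rows[asv] = ("Bacteria", "Cyanobacteria", "Oxyphotobacteria", "Chloroplast", "f__", "g__")
        else:
            rows[asv] = ("Eukaryota", "p__", "c__", "o__", "Mitochondria", "g__")
    tax = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["domain", "phylum", "class", "order", "family", "genus"],
    )
    tax.index.name = "asv"
    return tax


def _base_weights(config, core, opportunists):
    """Stratum base composition over gut bacterial ASVs (sums to 1).

    The profile is deterministic (individual variability enters through the
    per-sample Dirichlet draw): core phylotypes follow a geometric rank
    series and dominate CL; opportunists dominate MD, with a handful of
    common ones holding most of the mass and the rest — the default targets
    of planted treatment effects — at about one percent each so that
    perturbing them barely moves the total load.
    """
    n_core, n_opp = len(core), len(opportunists)
    core_w = 0.75 ** np.arange(n_core)
    core_w /= core_w.sum()
    n_common = min(5, n_opp)
    opp_w = np.empty(n_opp)
    common = 0.7 ** np.arange(n_common)
    opp_w[:n_common] = 0.85 * common / common.sum()
    if n_opp > n_common:
        opp_w[n_common:] = 0.15 / (n_opp - n_common)
    else:
        opp_w[:n_common] *= 1.0 / opp_w[:n_common].sum()
    cl = np.concatenate([0.92 * core_w, 0.08 * opp_w])
    md = np.concatenate([0.02 * core_w, 0.98 * opp_w])
    index = list(core) + list(opportunists)
    return pd.DataFrame({"CL": cl, "MD": md}, index=index)


def _standard_curves() -> dict:
    return {
        "16S": StandardCurve(slope=-3.3219, intercept=38.0, efficiency=2.0,
                             r_squared=1.0, gene="16S"),
        "actin": StandardCurve(slope=-3.45, intercept=36.0,
                               efficiency=10 ** (1 / 3.45), r_squared=1.0, gene="actin"),
    }


# ------------------------------------------------------------------ generator

def simulate_experiment(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the complete synthetic dataset for one experiment."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    core = [f"Core{i + 1:02d}" for i in range(config.n_core_asvs)]
    opportunists = [f"Opp{i + 1:02d}" for i in range(config.n_opportunist_asvs)]
    contaminants = [f"Cont{i + 1:02d}" for i in range(config.n_contaminant_asvs)]
    organelles = [f"Org{i + 1:02d}" for i in range(config.n_organelle_asvs)]
    gut_asvs = core + opportunists
    all_asvs = gut_asvs + contaminants + organelles

    taxonomy = _taxonomy_table(core, opportunists, contaminants, organelles)
    tree_newick = _random_binary_tree(all_asvs, rng)
    base = _base_weights(config, core, opportunists)

    # ---- design: cages and gut samples
    guts_per_cage = config.guts_per_treatment // config.cages_per_treatment
    cages, samples, meta_rows = [], [], []
    for col in config.colonization_levels:
        for pest in config.pesticide_treatments:
            for c in range(1, config.cages_per_treatment + 1):
                cage = f"{col}.{pest}.c{c}"
                cages.append((cage, col, pest))
                for g in range(1, guts_per_cage + 1):
                    sid = f"{cage}.g{g}"
                    samples.append(sid)
                    meta_rows.append((sid, col, pest, cage, False))
    blanks = [f"Blank{i + 1:02d}" for i in range(config.n_blanks)]
    for b in blanks:
        meta_rows.append((b, "", "", "", True))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample", "colonization", "pesticide", "cage", "is_blank"]
    ).set_index("sample")

    # ---- per-sample truth: load and composition
    sigma = np.sqrt(np.log(1.0 + config.load_cv**2))
    mean_load = {"MD": config.mean_load_MD}
    for col in config.colonization_levels:
        if col != "MD":
            mean_load[col] = config.mean_load_MD * config.load_ratio_CL_MD
    # per-contaminant regime: alternate constant-level and sporadic
    sporadic = {asv: (i % 2 == 1) for i, asv in enumerate(contaminants)}
    contam_level = {
        asv: config.contaminant_level * (0.5 if sporadic[asv] else 1.0)
        for asv in contaminants
    }

    true_cells = {}
    true_props = {}
    read_rows = {}
    for sid in samples:
        col = metadata.loc[sid, "colonization"]
        pest = metadata.loc[sid, "pesticide"]
        w = base[col].to_numpy().copy()
        for eff in config.effect_map:
            if eff.stratum == col and eff.treatment == pest and eff.asv in gut_asvs:
                w[gut_asvs.index(eff.asv)] *= eff.fold
        total_factor = w.sum()
        w_norm = w / total_factor
        load = float(
            rng.lognormal(np.log(mean_load[col] * total_factor) - sigma**2 / 2.0, sigma)
        )
        props = rng.dirichlet(config.dirichlet_concentration * w_norm)
        true_cells[sid] = load
        true_props[sid] = props

        # expected 16S copies by source: bacteria, contaminants, organelles
        copies_bact = load * RRNA_LOCI_PER_CELL * props
        copies_other = []
        for asv in contaminants:
            present = True
            if sporadic[asv]:
                present = rng.random() < config.sporadic_sample_rate
            copies_other.append(contam_level[asv] if present else 0.0)
        for _ in organelles:
            copies_other.append(config.organelle_level)
        expected = np.concatenate([copies_bact, np.array(copies_other)])
        fractions = expected / expected.sum()
        depth = rng.poisson(config.sequencing_depth_mean)
        read_rows[sid] = rng.multinomial(depth, fractions)

    for b in blanks:
        copies = np.zeros(len(all_asvs))
        for j, asv in enumerate(contaminants):
            rate = config.sporadic_blank_rate if sporadic[asv] else 1.0
            if rng.random() < rate:
                copies[len(gut_asvs) + j] = contam_level[asv] * float(
                    rng.lognormal(0.0, 0.3)
                )
        depth = rng.poisson(config.sequencing_depth_mean * config.blank_depth_fraction)
        if copies.sum() > 0 and depth > 0:
            read_rows[b] = rng.multinomial(depth, copies / copies.sum())
        else:
            read_rows[b] = np.zeros(len(all_asvs), dtype=int)

    asv_counts = pd.DataFrame.from_dict(read_rows, orient="index", columns=all_asvs)
    asv_counts.index.name = "sample"
    asv_counts = asv_counts.loc[samples + blanks]

    # ---- qPCR: dilution series and per-sample triplicate Cq values
    curves = _standard_curves()
    dil_rows = []
    for gene, curve in curves.items():
        for copies in 10.0 ** np.arange(1, 8):
            cq = cq_from_copies(curve, copies) + rng.normal(0.0, config.dilution_noise_sd)
            dil_rows.append((gene, copies, cq))
    dilution_series = pd.DataFrame(dil_rows, columns=["gene", "copies", "cq"])

    actin_base = 2e5  # actin copies per gut (host DNA, roughly constant)
    cq_rows = []
    for sid in samples:
        efficiency_factor = float(rng.lognormal(0.0, config.extraction_cv))
        per_ul_16s = true_cells[sid] * RRNA_LOCI_PER_CELL * efficiency_factor / config.elution_volume
        per_ul_actin = actin_base * efficiency_factor / config.elution_volume
        for gene, per_ul in (("16S", per_ul_16s), ("actin", per_ul_actin)):
            base_cq = cq_from_copies(curves[gene], per_ul)
            for rep in range(1, 4):
                cq_rows.append((sid, gene, rep, base_cq + rng.normal(0.0, config.cq_noise_sd)))
    cq_table = pd.DataFrame(cq_rows, columns=["sample", "gene", "replicate", "cq"])

    # ---- enzymes
    base_activity = {"GST": 20.0, "G6PDH": 15.0, "LDH": 30.0, "ALP": 10.0, "POx": 5.0}
    baseline_factor = {
        (t, m, s): f for (t, m, s, f) in config.colonization_baseline
    }
    shift_lut = {
        (e.tissue, e.marker, e.stratum, e.treatment): e.shift
        for e in config.enzyme_effect_map
    }
    enz_rows, mean_rows = [], []
    for tissue, marker in VALID_COMBINATIONS:
        for col in config.colonization_levels:
            for pest in config.pesticide_treatments:
                mean = base_activity[marker]
                mean *= baseline_factor.get((tissue, marker, col), 1.0)
                mean *= 1.0 + shift_lut.get((tissue, marker, col, pest), 0.0)
                mean_rows.append((tissue, marker, col, pest, mean))
                draws = rng.normal(mean, config.enzyme_cv * mean, size=config.physiology_reps)
                for rep, act in enumerate(draws, start=1):
                    enz_rows.append((tissue, marker, col, pest, rep, float(act)))
    enzyme_table = pd.DataFrame(
        enz_rows,
        columns=["tissue", "marker", "colonization", "treatment", "replicate", "activity"],
    )
    enzyme_means = pd.DataFrame(
        mean_rows, columns=["tissue", "marker", "colonization", "treatment", "mean"]
    )

    # ---- survival and feeders
    surv_rows, feeder_rows = [], []
    evap_series = {}
    for day in range(1, config.exposure_days + 1):
        evap_series[day] = float(rng.normal(config.evaporation_mean, config.evaporation_sd))
    for cage, col, pest in cages:
        alive = config.bees_per_cage
        hazard = config.hazard_for(pest)
        for day in range(1, config.exposure_days + 1):
            deaths = int(rng.binomial(alive, hazard))
            alive -= deaths
            surv_rows.append((cage, day, deaths, alive))
            per_bee = rng.normal(config.consumption_mean, config.consumption_sd)
            mass = alive * max(per_bee, 0.0) + evap_series[day] + rng.normal(
                0.0, config.weighing_sd
            )
            feeder_rows.append((cage, day, max(mass, 0.0)))
    for day in range(1, config.exposure_days + 1):
        feeder_rows.append(("evaporation_control", day, evap_series[day]))
    survival_log = pd.DataFrame(surv_rows, columns=["cage", "day", "deaths", "alive"])
    feeder_log = pd.DataFrame(feeder_rows, columns=["cage", "day", "mass_consumed"])

    truth = GroundTruth(
        true_cells_per_gut=pd.Series(true_cells, name="cells_per_gut"),
        true_proportions=pd.DataFrame.from_dict(true_props, orient="index", columns=gut_asvs),
        true_contaminants=frozenset(contaminants),
        true_organelles=frozenset(organelles),
        effect_map=tuple(config.effect_map),
        enzyme_effect_map=tuple(config.enzyme_effect_map),
        enzyme_means=enzyme_means,
    )
    return SyntheticDataset(
        config=config,
        asv_counts=asv_counts,
        taxonomy=taxonomy,
        tree_newick=tree_newick,
        metadata=metadata,
        cq_table=cq_table,
        dilution_series=dilution_series,
        enzyme_table=enzyme_table,
        survival_log=survival_log,
        feeder_log=feeder_log,
        truth=truth,
    )


# ------------------------------------------------------------------ round trip

_FILES = {
    "asv_counts": "asv_counts.tsv",
    "taxonomy": "taxonomy.tsv",
    "metadata": "metadata.tsv",
    "tree": "tree.nwk",
    "cq": "cq.csv",
    "dilutions": "dilutions.csv",
    "enzymes": "enzymes.tsv",
    "survival": "survival.csv",
    "feeder": "feeder.csv",
    "truth": "truth.json",
}


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write all tables as UTF-8 text; returns the file manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {k: str(directory / v) for k, v in _FILES.items()}
    try:
        ds.asv_counts.to_csv(manifest["asv_counts"], sep="\t")
        ds.taxonomy.to_csv(manifest["taxonomy"], sep="\t")
        ds.metadata.to_csv(manifest["metadata"], sep="\t")
        Path(manifest["tree"]).write_text(ds.tree_newick + "\n", encoding="utf-8")
        ds.cq_table.to_csv(manifest["cq"], index=False)
        ds.dilution_series.to_csv(manifest["dilutions"], index=False)
        ds.enzyme_table.to_csv(manifest["enzymes"], sep="\t", index=False)
        ds.survival_log.to_csv(manifest["survival"], index=False)
        ds.feeder_log.to_csv(manifest["feeder"], index=False)
        truth = {
            "true_cells_per_gut": ds.truth.true_cells_per_gut.to_dict(),
            "true_proportions": {
                s: ds.truth.true_proportions.loc[s].tolist()
                for s in ds.truth.true_proportions.index
            },
            "proportion_asvs": list(ds.truth.true_proportions.columns),
            "true_contaminants": sorted(ds.truth.true_contaminants),
            "true_organelles": sorted(ds.truth.true_organelles),
            "effect_map": [asdict(e) for e in ds.truth.effect_map],
            "enzyme_effect_map": [asdict(e) for e in ds.truth.enzyme_effect_map],
            "enzyme_means": ds.truth.enzyme_means.to_dict(orient="records"),
        }
        Path(manifest["truth"]).write_text(json.dumps(truth, indent=1), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return manifest


def read_dataset(directory) -> dict:
    """Read back the tables written by :func:`write_dataset` (as a dict)."""
    directory = Path(directory)
    out = {}
    out["asv_counts"] = pd.read_csv(directory / _FILES["asv_counts"], sep="\t",
                                    index_col=0)
    out["taxonomy"] = pd.read_csv(directory / _FILES["taxonomy"], sep="\t", index_col=0)
    out["metadata"] = pd.read_csv(directory / _FILES["metadata"], sep="\t", index_col=0,
                                  keep_default_na=False)
    out["metadata"]["is_blank"] = out["metadata"]["is_blank"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    out["tree"] = (directory / _FILES["tree"]).read_text(encoding="utf-8").strip()
    out["cq"] = pd.read_csv(directory / _FILES["cq"])
    out["dilutions"] = pd.read_csv(directory / _FILES["dilutions"])
    out["enzymes"] = pd.read_csv(directory / _FILES["enzymes"], sep="\t")
    out["survival"] = pd.read_csv(directory / _FILES["survival"])
    out["feeder"] = pd.read_csv(directory / _FILES["feeder"])
    out["truth"] = json.loads((directory / _FILES["truth"]).read_text(encoding="utf-8"))
    return out
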