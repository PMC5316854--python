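"""Synthetic cohorts with known ground truth.

Generates a discrete copy-number cohort, a pathway collection, an
interactome, and dose-sensitivity annotations from a single seeded
configuration, so every downstream module can be exercised offline.

Background genes receive i.i.d. alterations at a configurable per-gene
rate; conditional on alteration, the call mix defaults to 95% monoallelic
(+/-1) and 5% multi-copy (+/-2), reflecting the dominance of monoallelic
events in real tumour SCNA landscapes. Planted pathways carry alterations
in one direction at a configurable penetrance, optionally with a
high-degree, high-penetrance, mouse-annotated hub gene. Genes are
independent; no chromosome/arm linkage is simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    ConfigurationError,
    CopyNumberMatrix,
    DoseSensitivityMap,
    InteractionSet,
    MutationFrequencyMap,
    PathwayCollection,
    write_copy_number,
    write_dose_sensitivity,
    write_gene_sets,
    write_interactions,
    write_mutation_frequencies,
)

__all__ = [
    "HubSpec",
    "PlantedPathway",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "null_cohort",
    "write_cohort",
]

#: Conditional call mix given an alteration: ~95% monoallelic.
DEFAULT_MIX = {-2: 0.025, -1: 0.475, 1: 0.475, 2: 0.025}


@dataclass
class HubSpec:
    """A planted driver: elevated degree, penetrance, and GDS weight."""

    degree: int = 4
    penetrance: float = 0.7
    gds: int = 3

    def validate(self) -> None:
        if self.degree < 1:
            raise ConfigurationError("hub degree must be >= 1")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ConfigurationError("hub penetrance must be in [0, 1]")
        if self.gds not in (1, 2, 3):
            raise ConfigurationError("hub gds must be in {1, 2, 3}")


@dataclass
class PlantedPathway:
    """One pathway with a planted cohort-wide alteration signal."""

    name: str
    n_genes: int = 20
    edge_density: float = 0.3
    penetrance: float = 0.6
    direction: str = "deletion"     # or "gain"
    gds_fraction: float = 0.5       # fraction of genes dose-annotated
    mouse_fraction: float = 0.5     # of the annotated genes
    hub: HubSpec | None = None

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError(f"pathway {self.name!r}: need >= 2 genes")
        if self.direction not in ("deletion", "gain"):
            raise ConfigurationError(f"pathway {self.name!r}: bad direction {self.direction!r}")
        for label, v in (("edge_density", self.edge_density),
                         ("penetrance", self.penetrance),
                         ("gds_fraction", self.gds_fraction),
                         ("mouse_fraction", self.mouse_fraction)):
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"pathway {self.name!r}: {label}={v} outside [0, 1]")
        if self.hub is not None:
            self.hub.validate()
            if self.hub.degree > self.n_genes - 1:
                raise ConfigurationError(f"pathway {self.name!r}: hub degree exceeds pathway size")


@dataclass
class SimulationConfig:
    n_samples: int = 100
    n_background_genes: int = 500
    background_rate: float = 0.1
    background_mix: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    planted: list[PlantedPathway] = field(default_factory=list)
    n_random_pathways: int = 0       # null pathways drawn from background genes
    random_pathway_size: int = 10
    random_pathway_density: float = 0.3
    n_background_edges: int = 0      # sparse random interactome noise
    background_gds_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_samples < 1 or self.n_background_genes < 0:
            raise ConfigurationError("n_samples >= 1 and n_background_genes >= 0 required")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ConfigurationError(f"background_rate={self.background_rate} outside [0, 1]")
        if not (0.0 <= self.background_gds_fraction <= 1.0):
            raise ConfigurationError("background_gds_fraction outside [0, 1]")
        if set(self.background_mix) - {-2, -1, 1, 2}:
            raise ConfigurationError("background_mix keys must be in {-2, -1, 1, 2}")
        if abs(sum(self.background_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("background_mix must sum to 1")
        if self.n_random_pathways and \
                self.n_random_pathways * self.random_pathway_size > self.n_background_genes:
            raise ConfigurationError("not enough background genes for the random pathways")
        for pw in self.planted:
            pw.validate()
        names = [pw.name for pw in self.planted]
        if len(names) != len(set(names)):
            raise ConfigurationError("planted pathway names must be unique")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        planted = []
        for p in raw.pop("planted", []) or []:
            hub = p.pop("hub", None)
            planted.append(PlantedPathway(**p, hub=HubSpec(**hub) if hub else None))
        mix = raw.pop("background_mix", None)
        cfg = SimulationConfig(**raw, planted=planted)
        if mix:
            cfg.background_mix = {int(k): float(v) for k, v in mix.items()}
        return cfg


@dataclass
class GroundTruth:
    """Generating parameters of a simulated cohort."""

    planted: dict[str, str]                  # pathway -> direction
    hubs: dict[str, str]                     # pathway -> hub gene
    alteration_probability: dict[str, float]  # gene -> per-sample P(altered)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    matrix: CopyNumberMatrix
    pathways: PathwayCollection
    interactions: InteractionSet
    gds: DoseSensitivityMap
    truth: GroundTruth
    config: SimulationConfig | None = None

    def __iter__(self):
        return iter((self.matrix, self.pathways, self.interactions, self.gds, self.truth))


def _er_edges(genes: list[str], density: float, rng: np.random.Generator) -> set[tuple[str, str]]:
    edges = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < density:
                edges.add((min(genes[i], genes[j]), max(genes[i], genes[j])))
    return edges


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort; bitwise-reproducible from ``config`` (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_s = config.n_samples

    bg_genes = [f"BG{i:05d}" for i in range(config.n_background_genes)]
    mix_calls = np.array(sorted(config.background_mix), dtype=np.int8)
    mix_probs = np.array([config.background_mix[int(c)] for c in mix_calls])

    columns: dict[str, np.ndarray] = {}
    alt_prob: dict[str, float] = {}
    if bg_genes:
        altered = rng.random((len(bg_genes), n_s)) < config.background_rate
        calls = rng.choice(mix_calls, size=(len(bg_genes), n_s), p=mix_probs)
        bg_matrix = np.where(altered, calls, 0).astype(np.int8)
        for i, g in enumerate(bg_genes):
            columns[g] = bg_matrix[i]
            alt_prob[g] = config.background_rate

    pathways: dict[str, tuple[str, ...]] = {}
    edges: set[tuple[str, str]] = set()
    gds_yeast: set[str] = set()
    gds_mouse: set[str] = set()
    hubs: dict[str, str] = {}
    planted_dirs: dict[str, str] = {}

    for pw in config.planted:
        genes = [f"{pw.name}_G{i:03d}" for i in range(pw.n_genes)]
        pathways[pw.name] = tuple(genes)
        planted_dirs[pw.name] = pw.direction
        call = np.int8(-1) if pw.direction == "deletion" else np.int8(1)
        for g in genes:
            hit = rng.random(n_s) < pw.penetrance
            columns[g] = np.where(hit, call, 0).astype(np.int8)
            alt_prob[g] = pw.penetrance
        edges |= _er_edges(genes, pw.edge_density, rng)
        n_annot = int(round(pw.gds_fraction * pw.n_genes))
        annotated = list(rng.choice(genes, size=n_annot, replace=False)) if n_annot else []
        n_mouse = int(round(pw.mouse_fraction * len(annotated)))
        gds_mouse |= set(annotated[:n_mouse])
        gds_yeast |= set(annotated[n_mouse:])
        if pw.hub is not None:
            hub_gene = genes[0]
            hubs[pw.name] = hub_gene
            hit = rng.random(n_s) < pw.hub.penetrance
            columns[hub_gene] = np.where(hit, call, 0).astype(np.int8)
            alt_prob[hub_gene] = pw.hub.penetrance
            partners = rng.choice(genes[1:], size=pw.hub.degree, replace=False)
            for p in partners:
                edges.add((min(hub_gene, p), max(hub_gene, p)))
            if pw.hub.gds == 3:
                gds_mouse.add(hub_gene)
                gds_yeast.discard(hub_gene)
            elif pw.hub.gds == 2 and hub_gene not in gds_mouse:
                gds_yeast.add(hub_gene)

    if config.n_random_pathways:
        pool = list(rng.choice(bg_genes,
                               size=config.n_random_pathways * config.random_pathway_size,
                               replace=False))
        for k in range(config.n_random_pathways):
            genes = pool[k * config.random_pathway_size:(k + 1) * config.random_pathway_size]
            pathways[f"RANDOM{k:02d}"] = tuple(genes)
            edges |= _er_edges(genes, config.random_pathway_density, rng)

    if config.n_background_edges and len(columns) > 1:
        all_genes = list(columns)
        for _ in range(config.n_background_edges):
            a, b = rng.choice(all_genes, size=2, replace=False)
            edges.add((min(a, b), max(a, b)))

    if config.background_gds_fraction and bg_genes:
        n_annot = int(round(config.background_gds_fraction * len(bg_genes)))
        annotated = list(rng.choice(bg_genes, size=n_annot, replace=False))
        half = len(annotated) // 2
        gds_mouse |= set(annotated[:half])
        gds_yeast |= set(annotated[half:]) - gds_mouse

    df = pd.DataFrame(columns, index=[f"S{j:04d}" for j in range(n_s)]).T
    matrix = CopyNumberMatrix(df, mode="discrete")
    collection = PathwayCollection(pathways)
    interactions = InteractionSet(frozenset(edges))
    gds = DoseSensitivityMap.from_sources(sorted(gds_yeast), sorted(gds_mouse))
    truth = GroundTruth(planted=planted_dirs, hubs=hubs, alteration_probability=alt_prob)
    return SimulatedCohort(matrix, collection, interactions, gds, truth, config)


def null_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Same generator with the planted list emptied (for calibration runs)."""
    import copy

    cfg = copy.deepcopy(config)
    cfg.planted = []
    return simulate_cohort(cfg)


def write_cohort(cohort: SimulatedCohort, outdir,
                 mutation_frequencies: MutationFrequencyMap | None = None) -> dict[str, str]:
    """Write every component in the dialect its reader expects.

    Returns a name -> path map of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_sets": outdir / "pathways.gmt",
        "interactions": outdir / "interactions.tsv",
        "yeast_gds": outdir / "gds_yeast.tsv",
        "mouse_gds": outdir / "gds_mouse.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_gene_sets(cohort.pathways, paths["gene_sets"])
    write_interactions(cohort.interactions, paths["interactions"])
    write_dose_sensitivity(cohort.gds, paths["yeast_gds"], paths["mouse_gds"])
    write_copy_number(cohort.matrix, paths["copy_number"])
    cohort.truth.to_json(paths["ground_truth"])
    if cohort.config is not None:
        paths["config"] = outdir / "config.yaml"
        cohort.config.to_yaml(paths["config"])
    if mutation_frequencies is not None:
        paths["mutation_frequencies"] = outdir / "mutation_frequencies.tsv"
        write_mutation_frequencies(mutation_frequencies, paths["mutation_frequencies"])
    return {k: str(v) for k, v in paths.items()}
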