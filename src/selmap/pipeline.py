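"""Run configuration and end-to-end report assembly.

A run executes: (optional) orthology -> presence matrix -> trait
classification -> island scan -> candidate nomination -> trait
co-occurrence, writing TSV/JSON reports plus a run log that records the
package version, the seed and every threshold, so a log alone reproduces
a run.  Reports are deterministic given config + seed (no timestamps in
report bodies).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .compendium import (Compendium, attach_metadata, build_presence_matrix,
                         dedup_species, read_gene_table, write_gene_table,
                         write_metadata)
from .context import (DEFAULT_MAX_GAP, DEFAULT_MIN_RECURRENCE, DEFAULT_RADIUS,
                      candidates_to_frame, find_islands, nominate_candidates,
                      write_islands_bed)
from .orthology import (DEFAULT_EVALUE_MAX, assign_families, bbh_orthologs,
                        filter_hits, read_hit_table)
from .phylostats import cooccurrence_test
from .traits import (TraitDefinition, classify_traits, default_traits,
                     habitat_summary, partial_traits, taxon_distribution,
                     venn_counts)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Bad run configuration (names the offending key)."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, source: str, original: Exception):
        super().__init__(f"stage {stage!r} failed on {source}: {original}")
        self.stage = stage
        self.original = original


@dataclass
class InputPaths:
    gene_table: str | None = None
    format: str = "tsv"
    metadata: str | None = None
    hits_forward: str | None = None
    hits_reverse: str | None = None
    query_families: dict[str, str] = field(default_factory=dict)


@dataclass
class Thresholds:
    evalue_max: float = DEFAULT_EVALUE_MAX
    radius: int = DEFAULT_RADIUS
    max_gap: int = DEFAULT_MAX_GAP
    min_recurrence: int = DEFAULT_MIN_RECURRENCE
    min_phyla: int = 2
    min_freq: float = 0.9
    yates: bool = True

    def validate(self) -> None:
        if self.evalue_max <= 0:
            raise ConfigError("thresholds.evalue_max must be positive")
        if self.radius < 1:
            raise ConfigError("thresholds.radius must be >= 1")
        if self.max_gap < 0:
            raise ConfigError("thresholds.max_gap must be >= 0")
        if self.min_recurrence < 2:
            raise ConfigError("thresholds.min_recurrence must be >= 2")
        if not (0.0 < self.min_freq <= 1.0):
            raise ConfigError("thresholds.min_freq must be in (0, 1]")


@dataclass
class RunConfig:
    inputs: InputPaths = field(default_factory=InputPaths)
    thresholds: Thresholds = field(default_factory=Thresholds)
    traits: dict[str, list[str]] | None = None  # None -> the three defaults
    markers: list[str] | None = None            # known-Se families; None -> catalogue roles
    dedup: bool = False
    seed: int = 0
    outdir: str = "selmap_out"

    def trait_definitions(self) -> tuple[TraitDefinition, ...]:
        if self.traits is None:
            return default_traits()
        return tuple(TraitDefinition(name, frozenset(fams))
                     for name, fams in self.traits.items())

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        def build(dc_type, section: Mapping[str, Any], prefix: str):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = sorted(set(section) - names)
            if unknown:
                raise ConfigError(f"unknown config key '{prefix}{unknown[0]}'")
            return dc_type(**section)

        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - names)
        if unknown:
            raise ConfigError(f"unknown config key '{unknown[0]}'")
        kwargs: dict[str, Any] = dict(data)
        if "inputs" in kwargs:
            kwargs["inputs"] = build(InputPaths, kwargs["inputs"] or {}, "inputs.")
        if "thresholds" in kwargs:
            kwargs["thresholds"] = build(Thresholds, kwargs["thresholds"] or {}, "thresholds.")
        config = cls(**kwargs)
        config.thresholds.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _stage(name: str, source: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage provenance
            raise PipelineStageError(name, source, exc) from exc
    return wrap


def load_compendium(config: RunConfig) -> Compendium:
    inputs = config.inputs
    if not inputs.gene_table:
        raise ConfigError("inputs.gene_table is required")
    genomes = read_gene_table(inputs.gene_table, format=inputs.format)
    if inputs.metadata:
        genomes = attach_metadata(genomes, inputs.metadata)
    comp = Compendium.from_genomes(genomes)
    if config.markers:
        from .compendium import FamilyInfo
        for fam in config.markers:
            info = comp.family_catalog.setdefault(fam, FamilyInfo())
            info.role = "known-Se-marker"
    if config.dedup:
        comp = dedup_species(comp)
    return comp


def run_pipeline(config: RunConfig, compendium: Compendium | None = None) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle to
    ``config.outdir``.  Returns the in-memory artifacts keyed by name."""
    th = config.thresholds
    th.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}

    if compendium is None:
        compendium = _stage("load", config.inputs.gene_table or "<memory>")(
            load_compendium, config)
    artifacts["compendium"] = compendium

    if config.inputs.hits_forward and config.inputs.hits_reverse:
        def ortho():
            fwd = filter_hits(read_hit_table(config.inputs.hits_forward), th.evalue_max)
            rev = filter_hits(read_hit_table(config.inputs.hits_reverse), th.evalue_max)
            pairs = bbh_orthologs(fwd, rev)
            return assign_families(compendium, pairs, config.inputs.query_families)
        artifacts["ortholog_pairs"] = _stage("orthology", config.inputs.hits_forward)(ortho)

    defs = config.trait_definitions()
    markers = config.markers or compendium.families_with_role("known-Se-marker")
    if not markers:
        from .traits import KNOWN_SE_FAMILIES
        observed = set().union(*(g.families_present()
                                 for g in compendium.genomes.values()))
        markers = [f for f in KNOWN_SE_FAMILIES if f in observed] or \
            sorted(set().union(*(d.required_families for d in defs)))
    fam_order = sorted(compendium.family_catalog)
    matrix = _stage("presence_matrix", "compendium")(
        build_presence_matrix, compendium, fam_order)
    artifacts["presence_matrix"] = matrix
    matrix.to_tsv(outdir / "presence_matrix.tsv")

    profile = _stage("traits", "presence_matrix")(classify_traits, matrix, defs)
    artifacts["trait_profile"] = profile
    profile.to_tsv(outdir / "traits.tsv")
    summary = venn_counts(profile)
    artifacts["venn"] = summary
    (outdir / "venn.json").write_text(json.dumps(summary.to_dict(), indent=1))
    partial = partial_traits(matrix, defs)
    partial.to_csv(outdir / "partial_traits.tsv", sep="\t", index=False)

    taxon = taxon_distribution(profile, compendium, level=0)
    artifacts["taxon_table"] = taxon
    taxon.to_csv(outdir / "taxon_distribution.tsv", sep="\t", index=False)
    if any(g.habitat != "unknown" for g in compendium.genomes.values()):
        habitat = _stage("habitat", "metadata")(habitat_summary, profile, compendium)
        artifacts["habitat_table"] = habitat
        habitat.to_csv(outdir / "habitat_summary.tsv", sep="\t", index=False)

    islands = []
    for g in compendium.genomes.values():
        islands.extend(find_islands(g, markers, max_gap=th.max_gap))
    artifacts["islands"] = islands
    write_islands_bed(islands, outdir / "islands.bed")

    candidates = _stage("nominate", "compendium")(
        nominate_candidates, compendium, markers, radius=th.radius,
        max_gap=th.max_gap, min_recurrence=th.min_recurrence,
        min_phyla=th.min_phyla, yates=th.yates)
    artifacts["candidates"] = candidates
    candidates_to_frame(candidates).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    # Pairwise trait-level co-occurrence (the Venn-overlap statistics).
    rows = []
    names = profile.trait_names
    vectors = {t: [t in profile.traits[g] for g in profile.genome_ids] for t in names}
    for i, t1 in enumerate(names):
        for t2 in names[i + 1:]:
            table, res = cooccurrence_test(vectors[t1], vectors[t2], yates=th.yates)
            rows.append({"trait_1": t1, "trait_2": t2, "a": table.a, "b": table.b,
                         "c": table.c, "d": table.d, "chi2": res.statistic,
                         "p": res.p, "direction": res.direction})
    import pandas as pd
    cooc = pd.DataFrame(rows)
    artifacts["trait_cooccurrence"] = cooc
    cooc.to_csv(outdir / "trait_cooccurrence.tsv", sep="\t", index=False)

    run_log = {
        "selmap_version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(th),
        "traits": {d.name: sorted(d.required_families) for d in defs},
        "markers": list(markers),
        "n_genomes": len(compendium),
        "n_islands": len(islands),
        "n_candidates": len(candidates),
        "dedup": config.dedup,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))
    artifacts["run_log"] = run_log
    return artifacts


def simulate_inputs(outdir: str | Path, seed: int = 0, n_taxa: int = 50,
                    **sim_kwargs) -> dict[str, str]:
    """Emit a synthetic compendium as on-disk pipeline inputs (gene table,
    metadata, hit tables, tree, truth JSON) and return their paths."""
    from .simulate import SimConfig, generate_score_tables, simulate_compendium
    from .orthology import write_hit_table
    from .phylostats import write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=seed, n_taxa=n_taxa, **sim_kwargs)
    comp, truth = simulate_compendium(config)
    fwd, rev = generate_score_tables(comp, truth, config)
    paths = {
        "gene_table": str(outdir / "genes.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "hits_forward": str(outdir / "hits_forward.tsv"),
        "hits_reverse": str(outdir / "hits_reverse.tsv"),
        "tree": str(outdir / "species_tree.nwk"),
        "truth": str(outdir / "truth.json"),
    }
    write_gene_table(comp.genomes.values(), paths["gene_table"])
    write_metadata(comp.genomes.values(), paths["metadata"])
    write_hit_table(fwd, paths["hits_forward"])
    write_hit_table(rev, paths["hits_reverse"])
    write_newick(truth.tree, paths["tree"])
    truth.to_json(paths["truth"])
    return paths
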