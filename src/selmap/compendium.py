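"""Genome compendium: gene tables, metadata, and presence/absence profiles.

The compendium is the collection of genomes the whole analysis runs over:
per-genome ordered gene records with protein-family labels, plus species,
lineage and habitat metadata.  All downstream stages (trait classification,
gene-neighbourhood scans, co-occurrence statistics) consume either the
compendium itself or the genomes x families boolean *presence matrix* built
from it — the classical phylogenetic profile.

Conventions
-----------
* Coordinates are 1-based inclusive at every file boundary (the GFF
  convention).  ``start <= end`` always; strand is recorded but ignored for
  neighbourhood logic.
* Gene order within a replicon is summarised by ``rank``, the 0-based
  position in ascending-start order (ties broken by end, then gene id).
  Neighbourhoods downstream are counted in genes (ranks), not base pairs.
* Replicons are treated as linear: windows never wrap around.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")
HABITATS = ("aquatic", "nonaquatic", "unknown")
DOMAINS = ("bacteria", "archaea")

#: Roles a family can play in the catalogue.
FAMILY_ROLES = ("known-Se-marker", "candidate", "background")


class GeneTableError(ValueError):
    """Malformed gene table input (carries file and line context)."""


@dataclass
class GeneRecord:
    """One gene on one replicon of one genome.

    ``families`` holds the protein-family labels assigned to the gene
    (possibly empty, possibly several for multi-domain proteins).
    """

    genome_id: str
    replicon_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    families: set[str] = field(default_factory=set)
    rank: int = -1

    def validate(self) -> None:
        if self.start > self.end:
            raise GeneTableError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise GeneTableError(
                f"gene {self.gene_id!r}: start {self.start} < 1 (coordinates are 1-based)"
            )
        if self.strand not in STRANDS:
            raise GeneTableError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class Genome:
    """A genome: ordered gene lists per replicon plus metadata."""

    genome_id: str
    species: str = ""
    domain: str = "bacteria"
    lineage: tuple[str, ...] = ()
    habitat: str = "unknown"
    replicons: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def genes(self) -> Iterator[GeneRecord]:
        for records in self.replicons.values():
            yield from records

    def n_genes(self) -> int:
        return sum(len(r) for r in self.replicons.values())

    def gene_index(self) -> dict[str, GeneRecord]:
        """gene_id -> record map (built on demand; genomes are small)."""
        return {g.gene_id: g for g in self.genes()}

    def families_present(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes():
            out |= g.families
        return out

    def sort_and_rank(self) -> None:
        """Sort each replicon by (start, end, gene_id) and assign 0-based ranks."""
        for records in self.replicons.values():
            records.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for i, g in enumerate(records):
                g.rank = i


@dataclass
class FamilyInfo:
    description: str = ""
    role: str = "background"


@dataclass
class Compendium:
    """The genome collection plus a catalogue describing each family's role."""

    genomes: dict[str, Genome] = field(default_factory=dict)
    family_catalog: dict[str, FamilyInfo] = field(default_factory=dict)

    @classmethod
    def from_genomes(
        cls,
        genomes: Iterable[Genome],
        family_catalog: Mapping[str, FamilyInfo] | None = None,
    ) -> "Compendium":
        gmap: dict[str, Genome] = {}
        for g in genomes:
            if g.genome_id in gmap:
                raise GeneTableError(f"duplicate genome_id {g.genome_id!r}")
            gmap[g.genome_id] = g
        comp = cls(genomes=gmap, family_catalog=dict(family_catalog or {}))
        comp.register_observed_families()
        return comp

    def register_observed_families(self) -> None:
        """Ensure every family seen on a gene has a catalogue entry."""
        for g in self.genomes.values():
            for fam in g.families_present():
                self.family_catalog.setdefault(fam, FamilyInfo())

    def families_with_role(self, role: str) -> list[str]:
        return sorted(f for f, info in self.family_catalog.items() if info.role == role)

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class PresenceMatrix:
    """Genomes x families boolean matrix (present = genome encodes >= 1 gene
    assigned to the family).  Thin wrapper over a pandas DataFrame so the
    statistics modules can work on aligned vectors."""

    df: pd.DataFrame  # index = genome ids, columns = family ids, dtype bool

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.df.columns)

    def vector(self, family_id: str) -> pd.Series:
        if family_id not in self.df.columns:
            raise KeyError(f"family {family_id!r} is not a matrix column")
        return self.df[family_id]

    def to_tsv(self, path: str | Path) -> None:
        self.df.astype(int).to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genome_id")
        df.index.name = None
        return cls(df=df.astype(bool))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("genome_id", "replicon_id", "gene_id", "start", "end", "strand", "families")


def _finish_genomes(rows: list[GeneRecord], source: str) -> list[Genome]:
    genomes: dict[str, Genome] = {}
    seen_ids: dict[str, set[str]] = {}
    for rec in rows:
        g = genomes.setdefault(rec.genome_id, Genome(genome_id=rec.genome_id,
                                                     species=rec.genome_id))
        if rec.gene_id in seen_ids.setdefault(rec.genome_id, set()):
            raise GeneTableError(
                f"{source}: duplicate gene_id {rec.gene_id!r} within genome {rec.genome_id!r}"
            )
        seen_ids[rec.genome_id].add(rec.gene_id)
        g.replicons.setdefault(rec.replicon_id, []).append(rec)
    for g in genomes.values():
        g.sort_and_rank()
    return list(genomes.values())


def _parse_families_field(text: str) -> set[str]:
    text = text.strip()
    if not text or text == ".":
        return set()
    return {f.strip() for f in text.split(";") if f.strip()}


def read_gene_table(path: str | Path, format: str = "tsv",
                    genome_id: str | None = None) -> list[Genome]:
    """Read a gene-coordinate table into :class:`Genome` objects.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"tsv"`` — columns genome_id, replicon_id, gene_id, start, end,
        strand, families (semicolon-separated; empty or ``.`` for none);
        an optional header line is detected and skipped.
        ``"gff3"`` — genes as type ``gene`` or ``CDS``; the gene id is the
        ``ID`` attribute and families come from the ``family`` attribute
        (comma-separated).  One genome per GFF3 file; its id is
        ``genome_id`` or the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "gff3":
        return _read_gff3(path, genome_id=genome_id or path.stem)
    raise ValueError(f"unknown gene-table format {format!r}")


def _read_tsv(path: Path) -> list[Genome]:
    rows: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "genome_id":
                continue
            if len(parts) < 6:
                raise GeneTableError(f"{path}:{lineno}: expected >= 6 tab-separated fields, got {len(parts)}")
            fams = _parse_families_field(parts[6]) if len(parts) > 6 else set()
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GeneTableError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
            rec = GeneRecord(genome_id=parts[0], replicon_id=parts[1], gene_id=parts[2],
                             start=start, end=end, strand=parts[5], families=fams)
            try:
                rec.validate()
            except GeneTableError as exc:
                raise GeneTableError(f"{path}:{lineno}: {exc}") from None
            rows.append(rec)
    return _finish_genomes(rows, str(path))


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GeneTableError(f"attribute chunk {chunk!r} lacks '='")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path, genome_id: str) -> list[Genome]:
    rows: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneTableError(f"{path}:{lineno}: GFF3 line has {len(parts)} fields, expected 9")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GeneTableError(f"{path}:{lineno}: non-integer coordinate") from None
            try:
                attrs = _parse_gff_attributes(attrs_s)
            except GeneTableError as exc:
                raise GeneTableError(f"{path}:{lineno}: {exc}") from None
            gid = attrs.get("ID")
            if gid is None:
                raise GeneTableError(f"{path}:{lineno}: feature lacks an ID attribute")
            fams = {f.strip() for f in attrs.get("family", "").split(",") if f.strip()}
            rec = GeneRecord(genome_id=genome_id, replicon_id=seqid, gene_id=gid,
                             start=start, end=end, strand=strand, families=fams)
            try:
                rec.validate()
            except GeneTableError as exc:
                raise GeneTableError(f"{path}:{lineno}: {exc}") from None
            rows.append(rec)
    return _finish_genomes(rows, str(path))


def write_gene_table(genomes: Iterable[Genome], path: str | Path) -> None:
    """Write genomes back to the TSV dialect (round-trips read_gene_table)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for g in genomes:
            for rec in g.genes():
                fams = ";".join(sorted(rec.families))
                fh.write("\t".join([rec.genome_id, rec.replicon_id, rec.gene_id,
                                    str(rec.start), str(rec.end), rec.strand, fams]) + "\n")


METADATA_COLUMNS = ("genome_id", "species", "domain", "lineage", "habitat")


def attach_metadata(genomes: Iterable[Genome], path: str | Path) -> list[Genome]:
    """Attach species / domain / lineage / habitat from a metadata TSV.

    Columns: genome_id, species, domain, lineage (semicolon-separated,
    phylum first), habitat.  Genomes absent from the table keep defaults.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise GeneTableError(f"metadata file {path} lacks columns: {missing}")
    bymeta = {r.genome_id: r for r in meta.itertuples(index=False)}
    out = []
    for g in genomes:
        row = bymeta.get(g.genome_id)
        if row is not None:
            habitat = row.habitat or "unknown"
            if habitat not in HABITATS:
                raise GeneTableError(f"genome {g.genome_id!r}: bad habitat {habitat!r}")
            domain = row.domain or "bacteria"
            if domain not in DOMAINS:
                raise GeneTableError(f"genome {g.genome_id!r}: bad domain {domain!r}")
            g.species = row.species or g.species
            g.domain = domain
            g.lineage = tuple(t for t in row.lineage.split(";") if t)
            g.habitat = habitat
        out.append(g)
    return out


def write_metadata(genomes: Iterable[Genome], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for g in genomes:
            fh.write("\t".join([g.genome_id, g.species, g.domain,
                                ";".join(g.lineage), g.habitat]) + "\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def dedup_species(compendium: Compendium,
                  representative: Mapping[str, str] | None = None) -> Compendium:
    """Keep exactly one genome per species.

    Databases carry many strains of well-studied species; occurrence counts
    would otherwise be dominated by them.  The retained strain is the one
    the ``representative`` map names for that species, else the genome with
    the lexicographically smallest id.  Selections are logged at INFO.
    """
    representative = dict(representative or {})
    known_ids = set(compendium.genomes)
    for sp, gid in representative.items():
        if gid not in known_ids:
            raise KeyError(f"representative for species {sp!r} names absent genome {gid!r}")
    by_species: dict[str, list[str]] = {}
    for gid, g in compendium.genomes.items():
        by_species.setdefault(g.species or gid, []).append(gid)
    keep: list[str] = []
    for sp, gids in by_species.items():
        if sp in representative:
            chosen = representative[sp]
            if chosen not in gids:
                raise KeyError(
                    f"representative {chosen!r} for species {sp!r} is not a strain of it")
        else:
            chosen = min(gids)
        if len(gids) > 1:
            logger.info("dedup_species: %s -> kept %s of %s", sp, chosen, sorted(gids))
        keep.append(chosen)
    keep_set = set(keep)
    return Compendium(
        genomes={gid: g for gid, g in compendium.genomes.items() if gid in keep_set},
        family_catalog=dict(compendium.family_catalog),
    )


def build_presence_matrix(compendium: Compendium,
                          families: Sequence[str]) -> PresenceMatrix:
    """Build the genomes x families phylogenetic profile.

    A cell is True iff the genome carries >= 1 gene assigned to the family;
    multi-copy families collapse to a single True.
    """
    unknown = [f for f in families if f not in compendium.family_catalog]
    if unknown:
        raise KeyError(f"families not in catalogue: {unknown}")
    genome_ids = list(compendium.genomes)
    fam_index = {f: j for j, f in enumerate(families)}
    cells = np.zeros((len(genome_ids), len(families)), dtype=bool)
    for i, gid in enumerate(genome_ids):
        for gene in compendium.genomes[gid].genes():
            for fam in gene.families:
                j = fam_index.get(fam)
                if j is not None:
                    cells[i, j] = True
    df = pd.DataFrame(cells, index=genome_ids, columns=list(families))
    return PresenceMatrix(df=df)
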