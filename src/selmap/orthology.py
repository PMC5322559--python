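"""Homology filtering and bidirectional-best-hit (BBH) orthology.

Query proteins (one per marker family, e.g. the E. coli SelA/SelB/SelD
sequences) are searched against every genome; the resulting hit tables
(query, genome, subject gene, E-value, bit score) are the input here.
Orthology is called when a query's best hit in a genome and that gene's
best hit back against the query proteome point at each other — the
standard reciprocal-best-hit proxy — optionally reinforced by conserved
domain annotations (COG/Pfam/CDD style).

All selection rules are deterministic: best hit = minimal E-value, ties
broken by maximal bit score, then lexicographic subject id.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .compendium import Compendium

logger = logging.getLogger(__name__)

#: Default E-value cutoff for retaining homology hits (boundary inclusive).
DEFAULT_EVALUE_MAX = 0.1


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    genome_id: str
    subject_gene_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError(f"non-finite bitscore for {self.query_id}")


@dataclass(frozen=True)
class OrthologPair:
    query_id: str
    genome_id: str
    subject_gene_id: str
    evidence: str = "bbh"  # bbh | bbh+domain | domain-only


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a TSV hit table (query_id, genome_id, subject_gene_id, evalue,
    bitscore); an optional header line is detected and skipped."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "query_id":
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            hits.append(HomologyHit(parts[0], parts[1], parts[2],
                                    float(parts[3]), float(parts[4])))
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tgenome_id\tsubject_gene_id\tevalue\tbitscore\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.genome_id}\t{h.subject_gene_id}\t{h.evalue:.6g}\t{h.bitscore:.6g}\n")


def import_blast_tabular(path: str | Path, genome_id: str,
                         column_map: Mapping[str, int] | None = None) -> list[HomologyHit]:
    """Import BLAST outfmt-6 rows for one genome.

    ``column_map`` gives 0-based column indices for query_id, subject_gene_id,
    evalue, bitscore; the default matches the standard 12-column layout
    (qseqid=0, sseqid=1, evalue=10, bitscore=11).
    """
    cmap = {"query_id": 0, "subject_gene_id": 1, "evalue": 10, "bitscore": 11}
    cmap.update(column_map or {})
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            hits.append(HomologyHit(parts[cmap["query_id"]], genome_id,
                                    parts[cmap["subject_gene_id"]],
                                    float(parts[cmap["evalue"]]),
                                    float(parts[cmap["bitscore"]])))
    return hits


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def filter_hits(hits: Sequence[HomologyHit],
                evalue_max: float = DEFAULT_EVALUE_MAX) -> list[HomologyHit]:
    """Retain hits with E-value <= ``evalue_max`` (boundary inclusive),
    preserving input order."""
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    return [h for h in hits if h.evalue <= evalue_max]


def _hit_sort_key(h: HomologyHit):
    # minimal evalue wins; ties -> maximal bitscore -> lexicographic subject id
    return (h.evalue, -h.bitscore, h.subject_gene_id)


def best_hit(hits: Sequence[HomologyHit]) -> str | None:
    """Best subject for one query within one genome, or None on empty input."""
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    genomes = {h.genome_id for h in hits}
    if len(queries) > 1 or len(genomes) > 1:
        raise ValueError(
            f"best_hit expects one (query, genome) group, got queries={sorted(queries)} "
            f"genomes={sorted(genomes)}")
    return min(hits, key=_hit_sort_key).subject_gene_id


def _best_by_group(hits: Iterable[HomologyHit]) -> dict[tuple[str, str], str]:
    """(query_id, genome_id) -> best subject, applying the full tie rule."""
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.query_id, h.genome_id)
        cur = best.get(key)
        if cur is None or _hit_sort_key(h) < _hit_sort_key(cur):
            best[key] = h
    return {k: v.subject_gene_id for k, v in best.items()}


def bbh_orthologs(forward: Sequence[HomologyHit],
                  reverse: Sequence[HomologyHit]) -> list[OrthologPair]:
    """Bidirectional best hits.

    ``forward`` holds query-protein hits against genome genes; ``reverse``
    holds genome-gene hits back against the query proteome, encoded with
    ``query_id`` = gene id, ``genome_id`` = the genome the gene lives in
    and ``subject_gene_id`` = the query protein hit.  A pair (q, g, gene)
    is emitted iff q's best hit in g is ``gene`` and ``gene``'s best hit is
    q.  Both tables are expected pre-filtered by :func:`filter_hits`.
    Output is sorted by (query_id, genome_id) and independent of input
    row order.
    """
    fwd_best = _best_by_group(forward)
    rev_best = _best_by_group(reverse)
    pairs = []
    for (q, g), gene in fwd_best.items():
        if rev_best.get((gene, g)) == q:
            pairs.append(OrthologPair(query_id=q, genome_id=g,
                                      subject_gene_id=gene, evidence="bbh"))
    pairs.sort(key=lambda p: (p.query_id, p.genome_id))
    return pairs


def assign_families(compendium: Compendium,
                    pairs: Sequence[OrthologPair],
                    query_family: Mapping[str, str],
                    domain_annotations: Mapping[str, set[str]] | None = None,
                    require_domain: bool = False) -> list[OrthologPair]:
    """Attach marker families to genes from BBH evidence plus domains.

    ``query_family`` maps each query protein to the marker family it
    represents.  For every BBH pair the target gene receives the family
    unless ``require_domain`` is set, the gene has domain annotations, and
    the expected family is not among them (annotated-but-wrong-domain genes
    are rejected; unannotated genes pass on BBH alone).  Returns the pairs
    actually applied, with evidence upgraded to ``bbh+domain`` where the
    domain agreed.  A second gene acquiring an already-present marker family
    within a genome is kept (paralogs) with a warning.
    """
    domain_annotations = domain_annotations or {}
    applied: list[OrthologPair] = []
    for p in pairs:
        fam = query_family.get(p.query_id)
        if fam is None:
            continue
        genome = compendium.genomes.get(p.genome_id)
        if genome is None:
            raise KeyError(f"pair references absent genome {p.genome_id!r}")
        idx = genome.gene_index()
        gene = idx.get(p.subject_gene_id)
        if gene is None:
            raise KeyError(f"pair references absent gene {p.subject_gene_id!r} "
                           f"in genome {p.genome_id!r}")
        doms = domain_annotations.get(p.subject_gene_id)
        if doms:
            if fam in doms:
                evidence = "bbh+domain"
            elif require_domain:
                continue  # annotations exist but expected domain absent
            else:
                evidence = "bbh"
        else:
            evidence = "bbh"
        prior = [g for g in genome.genes() if fam in g.families and g.gene_id != gene.gene_id]
        if prior:
            logger.warning("genome %s: family %s already on %s; keeping both (paralogs)",
                           p.genome_id, fam, [g.gene_id for g in prior])
        gene.families.add(fam)
        applied.append(OrthologPair(p.query_id, p.genome_id, p.subject_gene_id, evidence))
    return applied
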