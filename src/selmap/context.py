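"""Gene-neighbourhood scanning, Se-island detection, candidate nomination.

Known Se-utilization genes cluster into compact genomic regions ("Se
islands", operon-like runs).  New candidate genes are nominated by scanning
a +/- 10-gene window around every island gene, counting in how many
distinct genomes a family recurs inside such windows, and attaching its
presence/absence co-occurrence statistics against SelD.  Adjacency is
counted in genes (ranks along the replicon), not base pairs, and replicons
are linear (no wrap-around).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import Compendium, Genome
from .phylostats import ChiSquareResult, Contingency2x2, chisq_2x2, cooccurrence_test

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 10
DEFAULT_MAX_GAP = 3
DEFAULT_MIN_RECURRENCE = 3


@dataclass(frozen=True)
class Window:
    """Genes within +/- ``radius`` ranks of an anchor gene on one replicon,
    truncated at replicon ends."""

    genome_id: str
    replicon_id: str
    anchor_gene_id: str
    radius: int
    members: tuple[tuple[int, str], ...]  # (signed offset, gene_id), 0 = anchor

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for _off, g in self.members)


def window(genome: Genome, anchor_gene_id: str, radius: int = DEFAULT_RADIUS) -> Window:
    """The +/- ``radius``-gene neighbourhood of an anchor gene."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    anchor = genome.gene_index().get(anchor_gene_id)
    if anchor is None:
        raise KeyError(f"anchor gene {anchor_gene_id!r} absent from genome {genome.genome_id!r}")
    records = genome.replicons[anchor.replicon_id]
    lo = max(0, anchor.rank - radius)
    hi = min(len(records) - 1, anchor.rank + radius)
    members = tuple((rec.rank - anchor.rank, rec.gene_id) for rec in records[lo:hi + 1])
    return Window(genome_id=genome.genome_id, replicon_id=anchor.replicon_id,
                  anchor_gene_id=anchor_gene_id, radius=radius, members=members)


@dataclass(frozen=True)
class SeIsland:
    """A maximal run of known-Se-family genes with small internal gaps.

    The span runs from the first to the last Se gene (ranks, inclusive);
    at most ``max_gap`` non-Se genes separate consecutive Se genes.
    """

    genome_id: str
    replicon_id: str
    start_rank: int
    end_rank: int
    gene_ids: tuple[str, ...]       # the Se genes, in rank order
    families: frozenset[str]
    max_gap: int
    start_bp: int = 0
    end_bp: int = 0

    def __len__(self) -> int:
        return len(self.gene_ids)


def find_islands(genome: Genome, known_families: Iterable[str],
                 max_gap: int = DEFAULT_MAX_GAP) -> list[SeIsland]:
    """Detect Se islands on every replicon, left to right.

    A new island starts whenever the gap to the previous Se gene exceeds
    ``max_gap``; islands therefore never overlap and the construction is
    deterministic.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    known = set(known_families)
    islands: list[SeIsland] = []
    for rep_id, records in genome.replicons.items():
        se_genes = [rec for rec in records if rec.families & known]
        run: list = []
        for rec in se_genes:
            if run and rec.rank - run[-1].rank - 1 > max_gap:
                islands.append(_make_island(genome.genome_id, rep_id, run, known, max_gap))
                run = []
            run.append(rec)
        if run:
            islands.append(_make_island(genome.genome_id, rep_id, run, known, max_gap))
    return islands


def _make_island(genome_id, rep_id, run, known, max_gap) -> SeIsland:
    fams = frozenset().union(*(rec.families & known for rec in run))
    return SeIsland(genome_id=genome_id, replicon_id=rep_id,
                    start_rank=run[0].rank, end_rank=run[-1].rank,
                    gene_ids=tuple(rec.gene_id for rec in run),
                    families=fams, max_gap=max_gap,
                    start_bp=run[0].start, end_bp=run[-1].end)


def write_islands_bed(islands: Sequence[SeIsland], path: str | Path) -> None:
    """Islands as BED (0-based half-open, converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        for isl in islands:
            name = f"{isl.genome_id}|{'+'.join(sorted(isl.families))}"
            fh.write(f"{isl.replicon_id}\t{isl.start_bp - 1}\t{isl.end_bp}\t{name}\n")


@dataclass
class CandidateScore:
    """Genomic-linkage recurrence of a family plus its SelD co-occurrence."""

    family_id: str
    n_linked_genomes: int
    linked: dict[str, int]  # genome_id -> signed offset to the nearest island gene
    table: Contingency2x2 | None = None
    chi2: ChiSquareResult | None = None
    n_phyla: int = 0
    rank: int = 0


def _linked_families(genome: Genome, islands: Sequence[SeIsland],
                     radius: int) -> dict[str, int]:
    """family -> signed offset (minimal |offset|) of its nearest occurrence
    inside the union of windows around island genes."""
    out: dict[str, int] = {}
    idx = genome.gene_index()
    for isl in islands:
        island_ranks = [idx[g].rank for g in isl.gene_ids]
        records = genome.replicons[isl.replicon_id]
        lo = max(0, min(island_ranks) - radius)
        hi = min(len(records) - 1, max(island_ranks) + radius)
        for rec in records[lo:hi + 1]:
            if not rec.families:
                continue
            offset = min((rec.rank - r for r in island_ranks), key=abs)
            if abs(offset) > radius:
                continue
            for fam in rec.families:
                if fam not in out or abs(offset) < abs(out[fam]):
                    out[fam] = offset
    return out


def nominate_candidates(compendium: Compendium,
                        known_families: Iterable[str] | None = None,
                        radius: int = DEFAULT_RADIUS,
                        max_gap: int = DEFAULT_MAX_GAP,
                        min_recurrence: int = DEFAULT_MIN_RECURRENCE,
                        min_phyla: int = 2,
                        exclusions: Iterable[str] | None = None,
                        seld_family: str = "SelD",
                        yates: bool = True) -> list[CandidateScore]:
    """Nominate candidate Se-related families from island neighbourhoods.

    For every genome, windows of ``radius`` genes are taken around each
    island gene and unioned; every non-excluded family found inside counts
    that genome once (paralogs collapse).  Families recurring in at least
    ``min_recurrence`` distinct genomes — spanning at least ``min_phyla``
    distinct phyla when lineages are available, guarding against a single
    clade's operon — are kept, given their chi-square co-occurrence with
    SelD across the whole compendium, and ranked by linked-genome count,
    then chi-square statistic, then family id.
    """
    if min_recurrence < 2:
        raise ValueError(f"min_recurrence must be >= 2, got {min_recurrence}")
    known = set(known_families) if known_families is not None else set(
        compendium.families_with_role("known-Se-marker"))
    if not known:
        raise ValueError("no known Se marker families given or catalogued")
    excluded = set(exclusions) if exclusions is not None else set(known)

    linked: dict[str, dict[str, int]] = {}
    any_island = False
    for gid, genome in compendium.genomes.items():
        islands = find_islands(genome, known, max_gap=max_gap)
        if not islands:
            continue
        any_island = True
        for fam, offset in _linked_families(genome, islands, radius).items():
            if fam in excluded:
                continue
            linked.setdefault(fam, {})[gid] = offset
    if not any_island:
        logger.warning("nominate_candidates: no Se islands found in any genome")
        return []

    # SelD presence vector over the whole compendium, genome order fixed.
    genome_ids = list(compendium.genomes)
    seld = np.array([any(seld_family in g.families for g in compendium.genomes[gid].genes())
                     for gid in genome_ids])

    scores: list[CandidateScore] = []
    for fam, genomes in linked.items():
        if len(genomes) < min_recurrence:
            continue
        phyla = {compendium.genomes[gid].lineage[0]
                 for gid in genomes if compendium.genomes[gid].lineage}
        if phyla and len(phyla) < min_phyla:
            continue
        fam_presence = np.array([any(fam in g.families for g in compendium.genomes[gid].genes())
                                 for gid in genome_ids])
        table, chi2 = cooccurrence_test(fam_presence, seld, yates=yates)
        scores.append(CandidateScore(family_id=fam, n_linked_genomes=len(genomes),
                                     linked=dict(sorted(genomes.items())),
                                     table=table, chi2=chi2, n_phyla=len(phyla)))
    scores.sort(key=lambda s: (-s.n_linked_genomes, -s.chi2.statistic, s.family_id))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def candidates_to_frame(scores: Sequence[CandidateScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        rows.append({
            "rank": s.rank,
            "family_id": s.family_id,
            "n_linked_genomes": s.n_linked_genomes,
            "n_phyla": s.n_phyla,
            "chi2": s.chi2.statistic if s.chi2 else float("nan"),
            "p": s.chi2.p if s.chi2 else float("nan"),
            "direction": s.chi2.direction if s.chi2 else 0,
            "genomes": ";".join(s.linked),
            "offsets": ";".join(str(v) for v in s.linked.values()),
        })
    return pd.DataFrame(rows, columns=["rank", "family_id", "n_linked_genomes", "n_phyla",
                                       "chi2", "p", "direction", "genomes", "offsets"])
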