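"""Protein distances, neighbor joining, and clade-enrichment scanning.

Distances are Poisson-corrected p-distances (expected substitutions per
site under a uniform-rate model), the classical quick alternative to full
empirical-matrix distances; externally computed PHYLIP square matrices are
accepted as input when model fidelity matters.  Trees are unrooted
neighbor-joining (Saitou & Nei) trees held as :mod:`dendropy` objects.

The clade-enrichment scan formalises the visual identification of a
trait-linked subfamily on a gene tree: every internal edge splits the
leaves in two; each side is tested for enrichment of trait-positive
organisms with a one-sided Fisher exact test, and clades are ranked by
p-value.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO

from .contingency import Contingency2x2, fisher_exact_2x2

logger = logging.getLogger(__name__)

GAP_CHARS = set("-.")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate taxon ids")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-9:
            raise ValueError("matrix is asymmetric beyond tolerance 1e-9")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, t1: str, t2: str) -> float:
        i, j = self.ids.index(t1), self.ids.index(t2)
        return float(self.values[i, j])


def read_phylip_distances(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix (one taxon per line, no
    line-wrapping)."""
    with open(path) as fh:
        tokens = fh.readline().split()
        if not tokens:
            raise ValueError(f"{path}: empty matrix file")
        n = int(tokens[0])
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            if len(parts) != n + 1:
                raise ValueError(f"{path}: row for taxon {len(ids)} has {len(parts) - 1} "
                                 f"values, expected {n}")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(ids=tuple(ids), values=np.array(rows))


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"    {len(dm)}\n")
        for i, name in enumerate(dm.ids):
            vals = " ".join(f"{v:.6f}" for v in dm.values[i])
            fh.write(f"{name:<10s} {vals}\n")


# ---------------------------------------------------------------------------
# Alignments and distances
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str = "fasta") -> list[tuple[str, str]]:
    """Read an aligned FASTA or Clustal file into (id, sequence) pairs."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    aln = AlignIO.read(str(path), format)
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def as_records(msa) -> list[tuple[str, str]]:
    """Normalise an alignment argument to (id, sequence) pairs.

    Accepts Biopython alignments / SeqRecord lists or plain (id, seq)
    pairs.  Sequences are upper-cased; equal lengths enforced.
    """
    records: list[tuple[str, str]] = []
    for item in msa:
        if isinstance(item, tuple):
            records.append((item[0], str(item[1]).upper()))
        else:  # SeqRecord-like
            records.append((item.id, str(item.seq).upper()))
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0][1])
    for rid, seq in records:
        if len(seq) != length:
            raise ValueError(f"sequence {rid!r} has length {len(seq)}, expected {length}")
    return records


def protein_distances(msa, model: str = "poisson",
                      max_distance: float = 10.0) -> DistanceMatrix:
    """Pairwise protein distances from an alignment.

    p-distance uses pairwise-complete columns (neither sequence gapped);
    the Poisson correction d = -ln(1 - p) estimates substitutions per site.
    Saturated pairs (p = 1) are capped at ``max_distance`` and logged.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    records = as_records(msa)
    if len(records) < 2:
        raise ValueError("need >= 2 sequences")
    ids = tuple(r[0] for r in records)
    seqs = [r[1] for r in records]
    arr = np.array([list(s) for s in seqs])
    gaps = np.isin(arr, list(GAP_CHARS))
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            p = float((arr[i, ok] != arr[j, ok]).sum()) / ncomp
            if model == "p":
                d = p
            elif p >= 1.0:
                logger.warning("pair (%s, %s) saturated (p = 1); capping at %g",
                               ids[i], ids[j], max_distance)
                d = max_distance
            else:
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=ids, values=D)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _new_leaf(tns: dendropy.TaxonNamespace, label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = tns.require_taxon(label=label)
    return node


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on the Q criterion.

    Deterministic: ties in Q are broken by the smallest (row, column) index
    pair in cluster-creation order.  Negative branch-length estimates are
    clamped to 0 with the deficit logged.  The returned tree is unrooted
    (held with a degree-3 seed node; degree-2 for fewer than 4 taxa).
    """
    n0 = len(dm)
    if n0 < 2:
        raise ValueError("need >= 2 taxa")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    if n0 == 2:
        d = float(dm.values[0, 1])
        for label, elen in zip(dm.ids, (d / 2.0, d / 2.0)):
            child = _new_leaf(tns, label)
            child.edge.length = elen
            tree.seed_node.add_child(child)
        return tree

    nodes = [_new_leaf(tns, label) for label in dm.ids]
    D = dm.values.copy()

    def clamp(x: float, what: str) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("neighbor_joining: clamped negative %s %.3g to 0", what, x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(D)
        r = D.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li, "branch length")
        nodes[j].edge.length = clamp(lj, "branch length")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        keep = [k for k in range(m) if k not in (i, j)]
        dnew = np.array([clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]), "distance")
                         for k in keep])
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = dnew
        D[:-1, -1] = dnew
        nodes = [nodes[k] for k in keep] + [parent]

    # Final three clusters: unique star with closed-form branch lengths.
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = ((d01 + d02 - d12) / 2.0, (d01 + d12 - d02) / 2.0, (d02 + d12 - d01) / 2.0)
    for node, elen in zip(nodes, lengths):
        node.edge.length = clamp(elen, "branch length")
        tree.seed_node.add_child(node)
    return tree


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[leaves[i]], taxa[leaves[j]])
    return DistanceMatrix(ids=tuple(leaves), values=D)


def read_newick(source: str | Path) -> dendropy.Tree:
    src = str(source)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Newick string with branch lengths at 6 decimals; optionally written
    to ``path``."""
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          real_value_format_specifier=".6f")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Clade enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeEnrichment:
    """Enrichment of trait-positive leaves inside one side of an internal
    edge's bipartition."""

    edge_id: str  # sorted leaf labels of the tested side, '|'-joined
    inside_pos: int
    inside_neg: int
    outside_pos: int
    outside_neg: int
    p: float

    @property
    def score(self) -> float:
        return -math.log10(max(self.p, 5e-324))

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.edge_id.split("|"))


@dataclass
class CladeScanResult:
    best: CladeEnrichment
    ranking: list[CladeEnrichment]
    uninformative: bool = False


def clade_enrichment_scan(tree: dendropy.Tree,
                          labels: Mapping[str, bool]) -> CladeScanResult:
    """Scan every internal edge for trait enrichment.

    Each internal edge's bipartition yields up to two candidate clades (the
    sides with >= 2 leaves); each is scored with a one-sided Fisher exact
    test of trait+ leaves inside versus outside.  Ranking: p ascending,
    ties by larger inside trait+ count, then edge id.  If every leaf has
    the same label the scan is flagged uninformative (p = 1 everywhere).
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaf_labels) < 4:
        raise ValueError("need >= 4 leaves")
    unlabeled = [l for l in leaf_labels if l not in labels]
    if unlabeled:
        raise KeyError(f"unlabeled leaves: {sorted(unlabeled)}")
    total_pos = sum(bool(labels[l]) for l in leaf_labels)
    total_neg = len(leaf_labels) - total_pos
    uninformative = total_pos == 0 or total_neg == 0
    all_leaves = frozenset(leaf_labels)

    sides: dict[frozenset, None] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) == len(all_leaves):  # degree-2 seed artefact
            continue
        for side in (below, all_leaves - below):
            if len(side) >= 2:
                sides.setdefault(side)

    entries: list[CladeEnrichment] = []
    for side in sides:
        ip = sum(bool(labels[l]) for l in side)
        inn = len(side) - ip
        op, on = total_pos - ip, total_neg - inn
        if uninformative:
            p = 1.0
        else:
            p = fisher_exact_2x2(Contingency2x2(a=ip, b=inn, c=op, d=on), side="greater")
        entries.append(CladeEnrichment(edge_id="|".join(sorted(side)),
                                       inside_pos=ip, inside_neg=inn,
                                       outside_pos=op, outside_neg=on, p=p))
    if not entries:
        raise ValueError("tree has no internal edges to scan")
    entries.sort(key=lambda e: (e.p, -e.inside_pos, e.edge_id))
    return CladeScanResult(best=entries[0], ranking=entries, uninformative=uninformative)
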