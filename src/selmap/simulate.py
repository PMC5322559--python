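"""Synthetic genome compendia with known ground truth.

Real occurrence data for the Se-utilization analysis is a database
snapshot of thousands of genomes; this module generates desk-scale
compendia that reproduce its statistical structure so every pipeline stage
can be exercised against a known answer:

* a Yule species tree;
* per-family presence/absence evolved as a two-state Markov gain/loss
  process along the tree (the source of the mosaic phylogenetic profile);
* Se islands: present marker families laid out as a contiguous gene block,
  with planted candidate families placed inside the +/- 10-gene window
  with a configurable linkage probability;
* a multi-paralog superfamily with one trait-linked subfamily member;
* habitat labels with a planted trait association;
* noisy forward/reverse homology score tables for the BBH stage.

Everything is deterministic given the seed in :class:`SimConfig`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .compendium import Compendium, FamilyInfo, GeneRecord, Genome
from .orthology import HomologyHit
from .phylostats.contingency import chisq_statistic_2x2, chisq_sf_df1
from .phylostats.trees import write_newick
from .traits import TraitDefinition, default_traits

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GainLoss:
    """Gain/loss rates per unit branch length for one family."""

    gain: float
    loss: float
    root_present: bool = True

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise ValueError("rates must be nonnegative")


def default_rates() -> dict[str, GainLoss]:
    """Gain/loss rates for the known marker families.

    Root states are 'present' (Se utilization as an ancient, widely lost
    trait).  Stationary frequencies (gain / (gain + loss)) are set so that
    the simulated occurrence levels sit near the observed ones in sequenced
    bacteria — SelD in roughly 40% of genomes, the Sec-decoding machinery
    in roughly a quarter, the Se-cofactor pair rarest — with total rates
    low enough that phylogenetic correlation along the shared tree
    survives to the tips (the mosaic pattern).
    """
    return {
        "SelD": GainLoss(0.22, 0.18),
        "SelA": GainLoss(0.22, 0.18),
        "SelB": GainLoss(0.22, 0.18),
        "YbbB": GainLoss(0.20, 0.20),
        "YqeB": GainLoss(0.12, 0.28),
        "YqeC": GainLoss(0.12, 0.28),
        "sec_lyase": GainLoss(0.18, 0.22),
        "sirA_like": GainLoss(0.18, 0.22),
    }


@dataclass
class IslandLayout:
    """Order of marker families inside a synthetic Se island and the
    candidate families planted next to it with their linkage probability."""

    markers: tuple[str, ...] = ("SelD", "SelA", "SelB", "sec_lyase", "sirA_like",
                                "YbbB", "YqeB", "YqeC")
    candidates: dict[str, float] = field(default_factory=lambda: {"yedE": 0.9})


@dataclass
class SuperfamilyConfig:
    family_id: str = "lysR"
    subfamily_id: str = "lysR_Se"
    n_members_per_genome: int = 2
    subfamily_linked: bool = True


@dataclass
class HabitatModel:
    """Habitat labels drawn conditionally on trait status, planting an
    aquatic-vs-nonaquatic association recoverable by the habitat summary."""

    p_unknown: float = 0.05
    p_aquatic_if_trait: float = 0.45
    p_aquatic_if_no_trait: float = 0.30


@dataclass
class ScoreNoise:
    """Spurious-hit model for synthetic homology tables: per (query,
    genome) a spurious hit is injected with probability ``rate``, its
    E-value log-uniform over [10^log10_min, 10^log10_max] — straddling the
    0.1 retention cutoff; true orthologs draw log-uniform below 1e-6."""

    rate: float = 0.02
    log10_min: float = -8.0
    log10_max: float = 1.0
    true_log10_min: float = -30.0
    true_log10_max: float = -6.0


@dataclass
class SimConfig:
    n_taxa: int = 50
    seed: int = 0
    rates: dict[str, GainLoss] = field(default_factory=default_rates)
    island: IslandLayout = field(default_factory=IslandLayout)
    n_background_families: int = 200
    background_presence: float = 0.3
    genes_per_genome: int = 300
    superfamily: SuperfamilyConfig = field(default_factory=SuperfamilyConfig)
    habitat: HabitatModel = field(default_factory=HabitatModel)
    noise: ScoreNoise = field(default_factory=ScoreNoise)
    radius: int = 10

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4 for a meaningful compendium")
        for fam, p in self.island.candidates.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_link for {fam!r} must be in [0, 1], got {p}")


@dataclass
class SimTruth:
    """Ground truth of one simulated compendium."""

    tree: dendropy.Tree
    states: pd.DataFrame                   # bool; index = family, columns = genome ids
    candidates: dict[str, float]           # planted family -> p_link
    trait_positive: frozenset[str]         # genomes with >= 1 complete trait
    habitat: dict[str, str]
    linked_genomes: dict[str, frozenset[str]] = field(default_factory=dict)
    subfamily_genes: dict[str, str] = field(default_factory=dict)  # genome -> gene id
    ortholog_map: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_newick": write_newick(self.tree).strip(),
            "states": {fam: {g: bool(v) for g, v in row.items()}
                       for fam, row in self.states.T.to_dict().items()},
            "candidates": self.candidates,
            "trait_positive": sorted(self.trait_positive),
            "habitat": self.habitat,
            "linked_genomes": {f: sorted(g) for f, g in self.linked_genomes.items()},
            "subfamily_genes": self.subfamily_genes,
            "ortholog_map": {f"{q}\t{g}": gene
                             for (q, g), gene in self.ortholog_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_tree(n_taxa: int, seed) -> dendropy.Tree:
    """Yule (pure-birth) species tree.

    Each of the k extant lineages splits at unit rate, so the k-lineage
    epoch lasts Exp(k); a uniformly chosen lineage splits at the end of
    each epoch until ``n_taxa`` lineages exist, and one final Exp(n) epoch
    extends the tips.  Expected root-to-tip depth is therefore the
    harmonic sum over k = 2..n of 1/k.  Leaves are labelled G001..Gn.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    rng = _as_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    active = [dendropy.Node(), dendropy.Node()]
    for node in active:
        tree.seed_node.add_child(node)
    pending = {id(node): 0.0 for node in active}
    k = 2
    while True:
        t = rng.exponential(1.0 / k)
        for node in active:
            pending[id(node)] += t
        if k == n_taxa:
            break
        idx = int(rng.integers(k))
        node = active.pop(idx)
        node.edge.length = pending.pop(id(node))
        children = [dendropy.Node(), dendropy.Node()]
        for c in children:
            node.add_child(c)
            pending[id(c)] = 0.0
        active.extend(children)
        k += 1
    width = max(3, len(str(n_taxa)))
    for i, node in enumerate(active, start=1):
        node.edge.length = pending[id(node)]
        node.taxon = tns.require_taxon(label=f"G{i:0{width}d}")
    return tree


def evolve_binary_trait(tree: dendropy.Tree, gain: float, loss: float,
                        root_present: bool, seed) -> dict[str, bool]:
    """Two-state Markov gain/loss along every branch.

    Transition probabilities over a branch of length t are the closed
    forms P(absent -> present) = (a/(a+b)) (1 - e^{-(a+b) t}) and
    P(present -> absent) = (b/(a+b)) (1 - e^{-(a+b) t}) with a = gain,
    b = loss.  Returns the leaf states.
    """
    if gain < 0 or loss < 0:
        raise ValueError("rates must be nonnegative")
    total = gain + loss
    if total <= 0:
        raise ValueError("gain + loss must be positive")
    rng = _as_rng(seed)
    states: dict[int, bool] = {id(tree.seed_node): bool(root_present)}
    leaf_states: dict[str, bool] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            flip = (1.0 - np.exp(-total * t))
            parent_state = states[id(node.parent_node)]
            p_change = (loss / total if parent_state else gain / total) * flip
            states[id(node)] = bool(parent_state ^ (rng.random() < p_change))
        if node.is_leaf():
            leaf_states[node.taxon.label] = states[id(node)]
    return leaf_states


def simulate_states(config: SimConfig, tree: dendropy.Tree,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Evolve every marker family independently on the shared tree.

    Cross-family correlation arises only through shared tree structure
    (and, at the trait level, shared SelD membership in the definitions)."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    rows = {}
    for fam in sorted(config.rates):
        gl = config.rates[fam]
        states = evolve_binary_trait(tree, gl.gain, gl.loss, gl.root_present, rng)
        rows[fam] = [states[g] for g in leaves]
    return pd.DataFrame.from_dict(rows, orient="index", columns=leaves)


def _trait_positive(states: pd.DataFrame,
                    defs: Iterable[TraitDefinition]) -> frozenset[str]:
    out = set()
    for gid in states.columns:
        present = {f for f in states.index if states.at[f, gid]}
        if any(d.required_families <= present for d in defs):
            out.add(gid)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Compendium synthesis
# ---------------------------------------------------------------------------

def simulate_truth(config: SimConfig) -> SimTruth:
    """Draw the tree, marker states, trait status and habitat labels."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, rng)
    states = simulate_states(config, tree, rng)
    trait_pos = _trait_positive(states, default_traits())
    habitat: dict[str, str] = {}
    hm = config.habitat
    for gid in states.columns:
        u = rng.random()
        if u < hm.p_unknown:
            habitat[gid] = "unknown"
        else:
            p_aq = hm.p_aquatic_if_trait if gid in trait_pos else hm.p_aquatic_if_no_trait
            habitat[gid] = "aquatic" if rng.random() < p_aq else "nonaquatic"
    return SimTruth(tree=tree, states=states, candidates=dict(config.island.candidates),
                    trait_positive=trait_pos, habitat=habitat)


def _lineages_from_tree(tree: dendropy.Tree) -> dict[str, tuple[str, str]]:
    """(phylum, class) labels per leaf, cut from the first two tree levels."""
    out: dict[str, tuple[str, str]] = {}
    for i, child in enumerate(tree.seed_node.child_nodes(), start=1):
        phylum = f"P{i}"
        if child.is_leaf():
            out[child.taxon.label] = (phylum, f"{phylum}.C1")
            continue
        for j, grand in enumerate(child.child_nodes(), start=1):
            cls = f"{phylum}.C{j}"
            for lf in ([grand] if grand.is_leaf() else grand.leaf_iter()):
                out[lf.taxon.label] = (phylum, cls)
    return out


def synthesize_compendium(truth: SimTruth, config: SimConfig) -> Compendium:
    """Lay genes on one replicon per genome from the simulated truth.

    Trait-positive genomes (and any genome with >= 1 marker present) get
    their present marker families as a contiguous island; each planted
    candidate lands inside the island's +/- radius window with probability
    p_link, else uniformly elsewhere; superfamily and background families
    fill free slots uniformly.  Fills ``truth.linked_genomes`` and
    ``truth.subfamily_genes`` in place.  Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.genes_per_genome
    required = (len(config.island.markers) + 2 * (config.radius + 2)
                + len(config.island.candidates) + config.superfamily.n_members_per_genome + 2)
    if n < required:
        raise ValueError(f"genes_per_genome={n} too small to host island, candidates "
                         f"and superfamily (need >= {required})")
    lineages = _lineages_from_tree(truth.tree)
    genome_ids = sorted(truth.states.columns)
    genomes: list[Genome] = []
    linked: dict[str, set[str]] = {fam: set() for fam in config.island.candidates}

    for gid in genome_ids:
        records = []
        for k in range(n):
            start = 1 + 1000 * k
            records.append(GeneRecord(
                genome_id=gid, replicon_id=f"{gid}_chr", gene_id=f"{gid}_g{k:04d}",
                start=start, end=start + 899,
                strand="+" if rng.random() < 0.5 else "-"))
        free = set(range(n))

        present_markers = [m for m in config.island.markers
                           if m in truth.states.index and truth.states.at[m, gid]]
        window_ranks: set[int] = set()
        if present_markers:
            L = len(present_markers)
            margin = config.radius + 2
            start_rank = int(rng.integers(margin, n - L - margin))
            for off, fam in enumerate(present_markers):
                records[start_rank + off].families.add(fam)
                free.discard(start_rank + off)
            window_ranks = set(range(max(0, start_rank - config.radius),
                                     min(n, start_rank + L + config.radius)))

        def place(fams: set[str], ranks: Iterable[int]) -> int:
            pool = sorted(set(ranks) & free)
            if not pool:
                raise ValueError(f"genome {gid}: no free gene slot left")
            r = pool[int(rng.integers(len(pool)))]
            records[r].families |= fams
            free.discard(r)
            return r

        is_pos = gid in truth.trait_positive
        for fam in sorted(config.island.candidates):
            p_link = config.island.candidates[fam]
            if not is_pos:
                continue
            if window_ranks and rng.random() < p_link:
                place({fam}, window_ranks)
                linked[fam].add(gid)
            else:
                # uniform over the whole replicon: under p_link = 0 the
                # window hit rate follows the uniform-placement null
                place({fam}, range(n))

        # Generic superfamily paralogs everywhere; the trait-linked
        # subfamily member is annotated at subfamily resolution only.
        sf = config.superfamily
        for _ in range(sf.n_members_per_genome):
            place({sf.family_id}, range(n))
        if sf.subfamily_linked and is_pos and window_ranks:
            r = place({sf.subfamily_id}, window_ranks)
            truth.subfamily_genes[gid] = records[r].gene_id

        for b in range(config.n_background_families):
            if rng.random() < config.background_presence:
                place({f"bg{b:03d}"}, range(n))

        phylum, cls = lineages.get(gid, ("P0", "P0.C0"))
        genomes.append(Genome(genome_id=gid, species=f"species_{gid}", domain="bacteria",
                              lineage=(phylum, cls), habitat=truth.habitat[gid],
                              replicons={f"{gid}_chr": records}))
    for g in genomes:
        g.sort_and_rank()

    catalog = {m: FamilyInfo(role="known-Se-marker") for m in config.island.markers}
    for fam in config.island.candidates:
        catalog[fam] = FamilyInfo(role="candidate")
    catalog[config.superfamily.subfamily_id] = FamilyInfo(role="candidate")
    catalog[config.superfamily.family_id] = FamilyInfo(role="background")
    for b in range(config.n_background_families):
        catalog[f"bg{b:03d}"] = FamilyInfo(role="background")
    truth.linked_genomes = {f: frozenset(g) for f, g in linked.items()}
    return Compendium.from_genomes(genomes, family_catalog=catalog)


def simulate_compendium(config: SimConfig) -> tuple[Compendium, SimTruth]:
    """Convenience wrapper: truth + compendium in one call."""
    truth = simulate_truth(config)
    comp = synthesize_compendium(truth, config)
    return comp, truth


# ---------------------------------------------------------------------------
# Homology score tables
# ---------------------------------------------------------------------------

def generate_score_tables(compendium: Compendium, truth: SimTruth,
                          config: SimConfig,
                          ) -> tuple[list[HomologyHit], list[HomologyHit]]:
    """Forward (query -> genome) and reverse (gene -> query proteome) hit
    tables consistent with the planted marker placements.

    True orthologs draw E-values log-uniform below the retention cutoff;
    spurious hits are injected per (query, genome) at ``noise.rate`` with
    E-values straddling the cutoff.  Fills ``truth.ortholog_map``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    noise = config.noise
    queries = [(f"Q_{fam}", fam) for fam in config.island.markers]
    forward: list[HomologyHit] = []
    reverse: list[HomologyHit] = []
    truth.ortholog_map.clear()

    def true_e() -> float:
        return float(10.0 ** rng.uniform(noise.true_log10_min, noise.true_log10_max))

    def noise_e() -> float:
        return float(10.0 ** rng.uniform(noise.log10_min, noise.log10_max))

    for gid in sorted(compendium.genomes):
        genome = compendium.genomes[gid]
        genes = [g.gene_id for g in genome.genes()]
        carrier = {}
        for g in genome.genes():
            for fam in g.families:
                carrier.setdefault(fam, g.gene_id)
        for qid, fam in queries:
            target = carrier.get(fam)
            if target is not None:
                truth.ortholog_map[(qid, gid)] = target
                forward.append(HomologyHit(qid, gid, target, true_e(),
                                           float(rng.uniform(100, 500))))
                reverse.append(HomologyHit(target, gid, qid, true_e(),
                                           float(rng.uniform(100, 500))))
            if noise.rate > 0 and rng.random() < noise.rate:
                decoy = genes[int(rng.integers(len(genes)))]
                forward.append(HomologyHit(qid, gid, decoy, noise_e(),
                                           float(rng.uniform(20, 60))))
            if noise.rate > 0 and rng.random() < noise.rate:
                decoy = genes[int(rng.integers(len(genes)))]
                qd = queries[int(rng.integers(len(queries)))][0]
                reverse.append(HomologyHit(decoy, gid, qd, noise_e(),
                                           float(rng.uniform(20, 60))))
    return forward, reverse


# ---------------------------------------------------------------------------
# Alignments and calibration
# ---------------------------------------------------------------------------

def generate_msa(n_seqs: int, length: int,
                 conserved_columns: Mapping[int, str] | Iterable[tuple[int, str]] | None,
                 seed, ids: list[str] | None = None) -> list[tuple[str, str]]:
    """Random protein alignment with specified columns fixed to a residue.

    ``conserved_columns`` maps 0-based columns to residues (pairs with
    conflicting residues for one column are rejected); all other cells are
    uniform over the 20 amino acids.
    """
    rng = _as_rng(seed)
    fixed: dict[int, str] = {}
    if conserved_columns:
        items = (conserved_columns.items() if isinstance(conserved_columns, Mapping)
                 else conserved_columns)
        for col, res in items:
            if not (0 <= col < length):
                raise ValueError(f"conserved column {col} outside alignment of length {length}")
            res = res.upper()
            if res not in AA20:
                raise ValueError(f"residue {res!r} is not an amino acid")
            if fixed.get(col, res) != res:
                raise ValueError(f"conflicting residues for column {col}")
            fixed[col] = res
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(n_seqs)]
    if len(ids) != n_seqs:
        raise ValueError("ids length must equal n_seqs")
    aa = np.array(list(AA20))
    out = []
    for rid in ids:
        chars = aa[rng.integers(0, len(AA20), size=length)]
        for col, res in fixed.items():
            chars[col] = res
        out.append((rid, "".join(chars)))
    return out


def independent_traits_rejection_rate(n_genomes: int = 200, n_replicates: int = 1000,
                                      p1: float = 0.5, p2: float = 0.5,
                                      alpha: float = 0.05, seed=0,
                                      yates: bool = False) -> float:
    """Type-I error of the 2x2 chi-square on two independent traits.

    Genomes are iid — the star-tree case, where independent gain/loss
    processes really are independent across tips.  Returns the fraction of
    replicates rejecting at level ``alpha``; calibrated code should land
    near ``alpha`` for the uncorrected Pearson statistic (the Yates
    variant is conservative by construction).
    """
    rng = _as_rng(seed)
    x = rng.random((n_replicates, n_genomes)) < p1
    y = rng.random((n_replicates, n_genomes)) < p2
    a = (x & y).sum(axis=1)
    b = (x & ~y).sum(axis=1)
    c = (~x & y).sum(axis=1)
    d = (~x & ~y).sum(axis=1)
    stat = chisq_statistic_2x2(a, b, c, d, yates=yates)
    p = chisq_sf_df1(stat)
    return float(np.mean(p < alpha))
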