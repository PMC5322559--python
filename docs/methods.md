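# Methods

This note documents the models, conventions, defaults and numerical
choices behind `selmap`, and what the synthetic-data tests do and do not
demonstrate about real genome collections.

## Domain model and conventions

Gene coordinates are 1-based inclusive at every file boundary (the GFF
convention); validation rejects `start > end`, `start < 1`, and duplicate
gene ids within a genome, naming the offending line. Internally a gene's
position along its replicon is its **rank** — the 0-based index in
ascending-start order, ties broken by end then gene id. All neighbourhood
logic (windows, islands, offsets) is counted in genes, not base pairs,
because functional clustering in prokaryotes is an operon/ordering
phenomenon, not a distance one. Replicons are treated as linear; windows
truncate at replicon ends and never wrap, which is conservative for
circular chromosomes (a future `circular` flag is reserved). Strand is
recorded and reported but ignored for adjacency.

One genome per species is enforced by `dedup_species` (explicit
representative map, else lexicographically smallest genome id, logged), so
heavily resequenced species do not dominate occurrence counts.

Habitat vocabulary is fixed to `{aquatic, nonaquatic, unknown}`; unknown
genomes are excluded from habitat denominators, and a habitat class with no
genomes is reported as absent rather than 0%.

## Orthology

Hits are retained at E-value ≤ 0.1, boundary inclusive, applied to both
search directions (a flag can relax the reverse direction). Best hit =
minimal E-value, ties by maximal bit score, then lexicographic subject id —
fully deterministic, so a reciprocal tie cannot survive the final
lexicographic fallback. BBH output is independent of row order and genome
iteration order. Domain evidence is combined as: an annotated gene whose
annotations contain the expected family upgrades the pair to `bbh+domain`;
with `require_domain` set, an annotated gene lacking the expected family is
rejected, while unannotated genes pass on BBH alone (many genes simply have
no domain call). Genomic-location confirmation is available as a
diagnostic — whether an assigned gene lies inside a Se island — but never
overrides BBH.

## Trait rules

Traits are pure conjunctions over the presence matrix: Sec =
SelA∧SelB∧SelD, SeU = SelD∧YbbB, SeCofactor = SelD∧YqeB∧YqeC, evaluated
independently per genome. Partial machineries are listed in a diagnostic
table but never counted. The orphan-SelD exclusion list is derived from
the trait definitions (union of required families minus SelD), so
user-defined traits extend it automatically. Classification is on
machinery only; no selenoprotein inventory is required for a genome to
count as Sec-decoding. Venn regions are exact trait-combination counts and
partition the trait-positive genomes by construction (asserted
internally).

## Genomic context and candidate nomination

Se islands are maximal left-to-right runs of genes carrying known-Se
families in which consecutive Se genes are separated by at most `max_gap`
(default 3) other genes. Windows of `radius` genes (default 10) are taken
around **every island gene** and unioned, matching the practice of scanning
the neighbourhood of whole Se gene regions rather than isolated genes.
Candidate counting is per-genome — multiple linked paralogs count once —
and a family is nominated when it recurs in ≥ `min_recurrence` distinct
genomes (default 3) spanning ≥ 2 distinct phyla when lineages are
available; the phylum-spread guard prevents a single clade's operon from
masquerading as convergent evidence. Ranking: linked-genome count, then
SelD co-occurrence χ², then family id. Known-Se families are excluded from
nomination by default. Automated island selection replaces the hand-picked
representative regions of manual practice; the `offsets` column in the
candidate table preserves the evidence for review.

The default known-Se seed set for island detection is the six trait
markers plus Sec lyase and the SirA-like family, two further families with
established Se associations that co-cluster in Se islands.

## Statistics

The 2×2 χ² statistic is computed from the closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); Yates' correction subtracts n/2 from
|ad−bc| (floored at 0) before squaring. Yates is **on by default** for
reported co-occurrence tests, matching common statistical-environment
defaults; a flag disables it, and reported p-values are exact (no flooring
at machine-readable limits). The df = 1 survival function is evaluated as
erfc(√(χ²/2)); tests verify it against an independent incomplete-gamma
evaluation to 1e−10. A zero marginal makes the statistic undefined: such
tables return statistic 0, p = 1, flagged `degenerate`. Fisher's exact
test sums exact hypergeometric point probabilities on the
margin-conditioned lattice (`greater` = upper tail on the a-cell;
`two-sided` = probabilities ≤ observed), and is the default for clade
enrichment because clades are small.

Type-I calibration: with two independent traits on a star tree (iid
genomes) the **uncorrected** Pearson test is the calibrated quantity — it
rejects at ≈ α; the Yates variant is conservative by construction and is
reported, not asserted. The correlated-on-tree case (shared phylogeny
inflates co-occurrence) is likewise reported, not asserted: the test's
null is genome exchangeability, which a tree violates by design.

## Distances, neighbor joining, enrichment

Protein distances are pairwise-complete p-distances (columns where neither
sequence is gapped) with Poisson correction d = −ln(1−p); a saturated pair
(p = 1) is capped at 10 substitutions/site and logged, and a pair with no
comparable columns is an error naming the pair. Full empirical-matrix
models (Dayhoff/JTT) are out of scope; externally computed PHYLIP square
matrices are accepted as input when model fidelity matters, and distance
model choice rarely changes NJ topology at subfamily scale.

Neighbor joining is the Saitou–Nei Q-criterion agglomeration; ties in Q
break to the smallest cluster-index pair (creation order), making output
deterministic. Negative branch-length estimates are clamped to 0 with the
deficit logged. The 3-taxon star and 2-taxon edge use their closed forms;
the 2-leaf tree is serialised with the single edge split evenly across the
degree-2 root, preserving the leaf-to-leaf path length. On additive
matrices NJ provably reproduces the generating tree; tests assert path
recovery to 1e−9 (1e−6 in the whole-method checks).

The clade-enrichment scan tests each side (≥ 2 leaves) of every internal
edge's bipartition for excess trait-positive leaves with one-sided Fisher;
ranking is p, then larger inside-positive count, then edge id. A scan in
which all leaves share one label is flagged `uninformative` with p = 1
everywhere. Formalising subfamily identification as the minimal-p clade is
this package's definition of what is otherwise a visual call on a tree,
and reports label it as such.

Conservation scanning computes per-column consensus frequency over non-gap
rows, skips columns with > 50% gaps, and flags columns at ≥ `min_freq`
(default 0.9), optionally restricted to one residue (e.g. the invariant
Cys). Motif scanning matches patterns over the amino-acid alphabet with
`X` as wildcard on ungapped sequences, reporting both the 1-based ungapped
position and the alignment column.

## Synthetic compendium

The generator produces the statistical structure of a genome-collection
survey with known truth, at desk scale (defaults: 50 taxa, 300 genes per
genome, 200 background families).

* **Species tree**: Yule process — each of k extant lineages splits at
  unit rate (epoch durations Exp(k)), a uniform lineage splits per epoch,
  one final Exp(n) epoch extends the tips; expected root-to-tip depth is
  the harmonic sum Σ_{k=2..n} 1/k, which the tests verify by Monte Carlo.
* **Marker presence**: each family evolves independently as a two-state
  Markov chain along the shared tree using the closed-form transition
  probabilities P(absent→present over t) = (α/(α+β))(1−e^{−(α+β)t}) and
  complement. Root states are 'present'; gain/loss defaults put stationary
  presence at 0.55 for SelA/SelB/SelD, 0.5 for YbbB, 0.3 for YqeB/YqeC,
  0.45 for Sec lyase/SirA-like, chosen so simulated occurrence sits near
  observed survey levels (SelD in roughly 40% of bacteria, Sec-decoding in
  roughly a quarter, the cofactor trait rarest) while total rates are low
  enough that phylogenetic signal survives to the tips. Cross-trait
  correlation arises **only** through the shared tree and shared SelD
  membership — no explicit rate coupling.
* **Gene layout**: one replicon per genome (windows never span replicons);
  present markers form a contiguous island at a uniform position; each
  planted candidate (default `yedE`, p_link 0.9) is present in every
  trait-positive genome and placed inside the island's ±10-gene window
  with probability p_link, else uniformly anywhere — so at p_link = 0 its
  window-hit rate follows the uniform null. A LysR-like superfamily
  contributes 2 generic paralogs per genome (matching the ≈ 1 LysR per
  150 genes density of real genomes at this genome size) plus, in
  trait-positive genomes, one island-linked member annotated at subfamily
  resolution (`lysR_Se`). Background families are present per genome with
  probability 0.3, placed uniformly.
* **Habitat**: labels drawn conditionally on trait status (aquatic with
  probability 0.45 given a trait, 0.30 otherwise, 5% unknown), planting a
  recoverable aquatic association of the magnitude seen in survey data.
* **Score tables**: true orthologs draw E-values log-uniform in
  [1e−30, 1e−6]; spurious hits are injected per (query, genome) at rate
  0.02 with E log-uniform in [1e−8, 10] — straddling the 0.1 cutoff so
  filtering is exercised on both sides. The E-value distribution is a
  modelling convenience, not a claim about BLAST statistics; tests state
  this assumption.
* **Alignments**: `generate_msa` fixes specified columns to given residues
  and draws the rest uniformly over the 20 amino acids.

Everything is deterministic given the config seed (sub-streams are derived
with `SeedSequence` so stages are independently reproducible).

**What passing tests show — and don't.** Recovery of planted candidates,
subfamilies, ortholog maps and habitat fractions shows the pipeline's
logic is correct and well-calibrated under its own generative assumptions:
independent family evolution, single-replicon genomes, uniform background
placement, clean family labels. Real collections violate all of these —
horizontal transfer couples families beyond tree structure, annotation is
noisy and incomplete, paralogy confuses BBH, and habitat metadata is
patchy — so simulated performance bounds, but does not guarantee, field
performance.

## Problem sizes

Default test and acceptance runs use 50-taxon compendia (300 genes each),
100 random BBH matrices (≤ 10×10), 500/200 random contingency tables, 50
additive matrices of 5–10 taxa, 1,000 calibration replicates of 200
genomes, and enrichment trees of 6–15 leaves — sizes at which every
brute-force oracle is exact and the full suite plus acceptance script
completes in well under a minute.

## Known limitations

* Occurrence numbers from real survey snapshots depend on the genome
  inventory of their date; this package reports explicit numerators and
  denominators rather than assuming any particular collection total.
* PROTDIST-style empirical substitution models, parsimony and
  likelihood/Bayesian tree inference are out of scope (import trees or
  PHYLIP matrices instead).
* Operon prediction from intergenic distance/strand runs is not attempted;
  islands are rank-gap runs only.
* The chi-square co-occurrence test treats genomes as exchangeable;
  phylogenetic pseudo-replication inflates significance on real trees, so
  candidate p-values are ranking devices, not calibrated error rates.
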