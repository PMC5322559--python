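# selmap

Comparative-genomics toolkit for mapping **selenium (Se) utilization
traits** across prokaryotic genomes and nominating new Se-related candidate
genes from genomic context, phylogenetic-profile co-occurrence, and
tree-based subfamily enrichment.

Intended for microbial comparative genomicists: you bring per-genome gene
coordinate tables (GFF3 or TSV) with protein-family labels, homology hit
tables, and optional habitat/lineage metadata; `selmap` classifies each
genome's Se machinery, finds the operon-like "Se islands" where those genes
cluster, and ranks the unknown families that keep turning up next to them.

## The biology and the method

Three selenophosphate-dependent traits are known in prokaryotes, each
recognisable from its complete marker machinery:

| trait | markers (all required) | chemistry |
|---|---|---|
| Sec | SelA + SelB + SelD | selenocysteine decoding at UGA |
| SeU | SelD + YbbB | 2-selenouridine tRNA wobble modification |
| SeCofactor | SelD + YqeB + YqeC | Se-containing cofactor of Mo-hydroxylases |

SelD (selenophosphate synthetase) supplies the Se donor to all three and is
the universal signature of Se utilization; a genome with SelD but none of
the trait-specific markers is an **orphan SelD**. The analysis pipeline:

1. **Orthology** — homology hits are kept at E ≤ 0.1 and orthologs called
   by bidirectional best hits (minimal E-value, ties by bit score then id),
   optionally reinforced by conserved-domain annotations.
2. **Phylogenetic profile** — a genomes × families boolean presence matrix.
3. **Traits** — pure AND rules over the matrix; Venn-region overlaps,
   per-taxon occurrence and aquatic/nonaquatic habitat summaries.
4. **Genomic context** — Se islands are maximal runs of known-Se genes with
   ≤ `max_gap` interruptions; a ±10-gene window around every island gene is
   scanned, and every unknown family recurring in ≥ 3 genomes (spanning
   ≥ 2 phyla) is scored by its 2×2 co-occurrence with SelD:
   χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, optional Yates
   correction, p = erfc(√(χ²/2)).
5. **Subfamily trees** — Poisson-corrected protein distances
   (d = −ln(1−p)), Saitou–Nei neighbor joining, and a clade-enrichment scan
   that scores every internal edge's bipartition with a one-sided Fisher
   exact test — the formal version of spotting a trait-linked subfamily
   (e.g. a Se-associated LysR regulator) on a gene tree. Conserved-residue
   and motif scans (`CPXP`, `CGXC`, invariant Cys) check the diagnostic
   residues of candidates.
6. **Simulator** — Yule species trees, binary gain/loss trait evolution,
   planted Se islands/candidates/subfamilies and noisy score tables with
   full ground truth, so every stage is testable at desk scale.

## Worked example

Simulate a 50-genome compendium with a planted linked candidate (`yedE`,
p_link = 0.9) and a planted trait-linked subfamily (`lysR_Se`), then
classify and nominate:

```bash
selmap simulate --out sim --seed 7 --n-taxa 50
selmap classify --genes sim/genes.tsv --metadata sim/metadata.tsv --out cls
selmap nominate --genes sim/genes.tsv --metadata sim/metadata.tsv --out candidates.tsv
```

`cls/venn.json` (trait-overlap regions; 38 of 50 genomes carry ≥ 1 trait):

```json
{"regions": {"Sec": 4, "SeU": 13, "SeCofactor": 0, "Sec&SeU": 20,
             "Sec&SeCofactor": 0, "SeU&SeCofactor": 0, "Sec&SeU&SeCofactor": 1},
 "orphan_selD": 0, "n_trait_positive": 38}
```

`cls/habitat_summary.tsv` shows the planted habitat bias (85.7% of aquatic
vs 66.7% of nonaquatic genomes carry a trait), and the top of
`candidates.tsv`:

```text
rank  family_id  n_linked_genomes  n_phyla  chi2     p          direction
1     lysR_Se    38                2        29.86    4.64e-08   1
2     yedE       35                2        29.86    4.64e-08   1
3     bg068      4                 2        0.32     0.57       1
```

Both planted families lead the ranking by a wide margin — recurrently
island-linked in dozens of genomes and strongly co-occurring with SelD —
while the best of 200 background families sits at χ² ≈ 0.3.

`selmap tree`, `selmap enrich`, `selmap cooccur`, `selmap scan` and
`selmap report` (full YAML-configured pipeline) cover the remaining stages;
every subcommand is a thin wrapper over the `selmap.*` library modules.

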