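"""Gene-table I/O, species dedup, and the presence matrix."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selmap.compendium import (Compendium, FamilyInfo, GeneTableError,
                               attach_metadata, build_presence_matrix,
                               dedup_species, read_gene_table, write_gene_table,
                               write_metadata)

from conftest import make_genome


def write_tsv(path, rows, header=True):
    lines = []
    if header:
        lines.append("genome_id\treplicon_id\tgene_id\tstart\tend\tstrand\tfamilies")
    lines += ["\t".join(str(x) for x in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadGeneTable:
    def test_ranks_follow_ascending_start(self, tmp_path):
        p = write_tsv(tmp_path / "g.tsv", [
            ("G1", "chr", "a", 100, 199, "+", ""),
            ("G1", "chr", "b", 900, 999, "-", "SelD"),
            ("G1", "chr", "c", 500, 599, "+", "SelA;SelB"),
        ])
        (genome,) = read_gene_table(p)
        ranks = {g.gene_id: g.rank for g in genome.genes()}
        assert ranks == {"a": 0, "c": 1, "b": 2}
        assert genome.gene_index()["c"].families == {"SelA", "SelB"}

    def test_start_after_end_rejected_with_line_number(self, tmp_path):
        p = write_tsv(tmp_path / "g.tsv", [("G1", "chr", "a", 50, 40, "+", "")])
        with pytest.raises(GeneTableError, match=r":2:.*start 50 > end 40"):
            read_gene_table(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "g.tsv", [
            ("G1", "chr", "a", 1, 9, "+", ""),
            ("G1", "chr2", "a", 11, 19, "+", ""),
        ])
        with pytest.raises(GeneTableError, match="duplicate gene_id 'a'"):
            read_gene_table(p)

    def test_shuffled_rows_give_identical_genome(self, tmp_path, rng):
        # oracle: sort-then-rank is order-independent
        rows = []
        starts = rng.choice(np.arange(1, 10_000), size=20, replace=False)
        for i, s in enumerate(starts):
            rows.append(("G1", "chr", f"g{i}", int(s), int(s) + 100, "+", f"fam{i % 3}"))
        p1 = write_tsv(tmp_path / "sorted.tsv", sorted(rows, key=lambda r: r[3]))
        shuffled = list(rows)
        rng.shuffle(shuffled)
        p2 = write_tsv(tmp_path / "shuffled.tsv", shuffled)
        (g1,), (g2,) = read_gene_table(p1), read_gene_table(p2)
        assert [(g.gene_id, g.rank, g.start) for g in g1.genes()] == \
               [(g.gene_id, g.rank, g.start) for g in g2.genes()]

    def test_gff3_parsing_and_coordinate_error(self, tmp_path):
        good = tmp_path / "G7.gff3"
        good.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t100\t400\t.\t+\t.\tID=a;family=SelD\n"
            "chr\tsrc\tCDS\t600\t900\t.\t-\t.\tID=b;family=SelA,SelB\n"
            "chr\tsrc\tregion\t1\t99999\t.\t+\t.\tID=skipme\n")
        (genome,) = read_gene_table(good, format="gff3")
        assert genome.genome_id == "G7"
        assert genome.n_genes() == 2
        assert genome.gene_index()["b"].families == {"SelA", "SelB"}
        bad = tmp_path / "bad.gff3"
        bad.write_text("chr\tsrc\tgene\t10\t5\t.\t+\t.\tID=x\n")
        with pytest.raises(GeneTableError, match=r":1:.*start 10 > end 5"):
            read_gene_table(bad, format="gff3")

    def test_round_trip_preserves_everything(self, tmp_path, rng):
        genomes = []
        for gi in range(3):
            genes = []
            for k in range(15):
                s = 1 + int(rng.integers(0, 100_000))
                genes.append((f"G{gi}_g{k}", s, s + int(rng.integers(1, 500)),
                              "+" if rng.random() < 0.5 else "-",
                              {f"f{int(rng.integers(5))}"} if rng.random() < 0.5 else set()))
            genomes.append(make_genome(f"G{gi}", genes))
        out = tmp_path / "rt.tsv"
        write_gene_table(genomes, out)
        back = {g.genome_id: g for g in read_gene_table(out)}
        for g in genomes:
            got = back[g.genome_id]
            assert [(x.gene_id, x.start, x.end, x.strand, frozenset(x.families))
                    for x in g.genes()] == \
                   [(x.gene_id, x.start, x.end, x.strand, frozenset(x.families))
                    for x in got.genes()]

    def test_metadata_round_trip(self, tmp_path):
        g = make_genome("G1", [("a", 1, 9, "+", set())], lineage=("P1", "C2"),
                        habitat="aquatic", species="sp one")
        g.domain = "archaea"
        p = tmp_path / "meta.tsv"
        write_metadata([g], p)
        g2 = make_genome("G1", [("a", 1, 9, "+", set())])
        (g2,) = attach_metadata([g2], p)
        assert (g2.species, g2.domain, g2.lineage, g2.habitat) == \
               ("sp one", "archaea", ("P1", "C2"), "aquatic")


class TestDedupSpecies:
    def two_strains(self):
        a = make_genome("G_b", [("x1", 1, 9, "+", set())], species="Escherichia coli")
        b = make_genome("G_a", [("x2", 1, 9, "+", set())], species="Escherichia coli")
        c = make_genome("G_c", [("x3", 1, 9, "+", set())], species="Bacillus subtilis")
        return Compendium.from_genomes([a, b, c])

    def test_lexicographically_smallest_kept(self):
        out = dedup_species(self.two_strains())
        assert set(out.genomes) == {"G_a", "G_c"}

    def test_representative_map_overrides(self):
        out = dedup_species(self.two_strains(), {"Escherichia coli": "G_b"})
        assert set(out.genomes) == {"G_b", "G_c"}

    def test_absent_representative_rejected(self):
        with pytest.raises(KeyError, match="absent genome"):
            dedup_species(self.two_strains(), {"Escherichia coli": "nope"})

    def test_one_genome_per_species_and_idempotent(self, rng):
        genomes = []
        for s in range(10):
            for strain in range(int(rng.integers(1, 4))):
                gid = f"sp{s}_st{strain}"
                genomes.append(make_genome(gid, [(f"{gid}_g", 1, 9, "+", set())],
                                           species=f"species {s}"))
        comp = Compendium.from_genomes(genomes)
        once = dedup_species(comp)
        assert len(once) == 10
        twice = dedup_species(once)
        assert set(twice.genomes) == set(once.genomes)


class TestPresenceMatrix:
    def test_presence_is_existential(self):
        g = make_genome("G1", [("a", 1, 9, "+", {"SelD"}), ("b", 11, 19, "+", {"SelD"})])
        empty = make_genome("G2", [("c", 1, 9, "+", set())])
        comp = Compendium.from_genomes([g, empty])
        comp.family_catalog.setdefault("SelD", FamilyInfo())
        m = build_presence_matrix(comp, ["SelD"])
        assert bool(m.df.at["G1", "SelD"]) is True
        assert bool(m.df.at["G2", "SelD"]) is False

    def test_unknown_family_rejected(self):
        comp = Compendium.from_genomes([make_genome("G1", [("a", 1, 9, "+", set())])])
        with pytest.raises(KeyError, match="nosuch"):
            build_presence_matrix(comp, ["nosuch"])

    def test_matches_brute_force_and_gene_order_invariant(self, rng):
        fams = [f"f{i}" for i in range(5)]
        genomes = []
        for gi in range(8):
            genes = []
            for k in range(12):
                s = 1 + int(rng.integers(0, 100_000))
                fs = {f for f in fams if rng.random() < 0.25}
                genes.append((f"G{gi}_g{k}", s, s + 10, "+", fs))
            genomes.append(make_genome(f"G{gi}", genes))
        comp = Compendium.from_genomes(genomes)
        m = build_presence_matrix(comp, fams)
        for gid, genome in comp.genomes.items():
            for fam in fams:  # brute-force double loop
                expect = any(fam in gene.families for gene in genome.genes())
                assert bool(m.df.at[gid, fam]) == expect
        # permuting gene order within genomes changes nothing
        for genome in comp.genomes.values():
            for rec_list in genome.replicons.values():
                rec_list.reverse()
        m2 = build_presence_matrix(comp, fams)
        pd.testing.assert_frame_equal(m.df, m2.df)

    def test_tsv_round_trip(self, tmp_path, sim_default):
        _config, comp, _truth = sim_default
        m = build_presence_matrix(comp, sorted(comp.family_catalog))
        m.to_tsv(tmp_path / "pm.tsv")
        from selmap.compendium import PresenceMatrix
        back = PresenceMatrix.from_tsv(tmp_path / "pm.tsv")
        pd.testing.assert_frame_equal(m.df, back.df)
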