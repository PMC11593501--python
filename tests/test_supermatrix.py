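"""Locus alignment, concatenation bookkeeping, writers, gene-tree merging."""

import dendropy
import pytest

from orthoprep.og_model import SpeciesRoster
from orthoprep.simmerge import MergedOrthogroup
from orthoprep.supermatrix import (
    GeneTreeSet,
    LocusAlignment,
    Supermatrix,
    aggregate_gene_trees,
    align_locus,
    concatenate,
    read_phylip,
    write_partitions,
    write_phylip,
)
from orthoprep.synthgen import SynthScenario, generate_dataset, mutate

from conftest import random_protein


def mog(og_id, seqs):
    return MergedOrthogroup(og_id, seqs)


class TestAlignLocus:
    def test_identical_sequences_no_gaps(self):
        la = align_locus(mog("og", {"A": "MKVLD", "B": "MKVLD"}))
        assert la.length == 5
        assert "-" not in la.rows["A"] + la.rows["B"]

    def test_single_deletion_gives_single_gap(self):
        la = align_locus(
            mog("og", {"A": "MKVLDPE", "B": "MKVLDPE", "C": "MKVLPE"})
        )
        assert la.rows["C"].count("-") == 1
        assert la.rows["A"] == "MKVLDPE"

    def test_degapping_recovers_inputs(self, rng):
        for _ in range(10):
            base = random_protein(rng, 50)
            seqs = {
                sp: mutate(base, 0.05, rng) for sp in ("A", "B", "C", "D")
            }
            la = align_locus(mog("og", seqs))
            for sp, row in la.rows.items():
                assert row.replace("-", "") == seqs[sp]

    def test_fewer_than_two_species_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            align_locus(mog("og", {"A": "MKV"}))

    def test_external_mafft_matches_invariants(self):
        la = align_locus(
            mog("og", {"A": "MKVLDPE", "B": "MKVLDPE", "C": "MKVLPE"}),
            aligner="external_mafft",
        )
        assert len({len(r) for r in la.rows.values()}) == 1
        for sp, seq in (("A", "MKVLDPE"), ("C", "MKVLPE")):
            assert la.rows[sp].replace("-", "") == seq

    def test_missing_mafft_names_the_fallback(self):
        with pytest.raises(FileNotFoundError, match="builtin_star"):
            align_locus(
                mog("og", {"A": "MKV", "B": "MKV"}),
                aligner="external_mafft",
                mafft_path="definitely-not-mafft",
            )


ROSTER = SpeciesRoster(("A", "B", "C"))


def two_loci():
    l1 = LocusAlignment("og1", {"A": "MKVLDPEMKV", "B": "MKVLDPEMKV",
                                "C": "MKVLDPEMKV"})
    l2 = LocusAlignment("og2", {"A": "MKVLDPE", "B": "MKVLDPE"})
    return [l1, l2]


class TestConcatenate:
    def test_partition_arithmetic(self):
        sm = concatenate(two_loci(), ROSTER)
        assert sm.n_sites == 17
        assert sm.partitions == [("og1", 1, 10), ("og2", 11, 17)]

    def test_missing_species_padded(self):
        sm = concatenate(two_loci(), ROSTER)
        assert sm.matrix["C"] == "MKVLDPEMKV" + "-" * 7

    def test_single_locus_identity(self):
        [l1, _] = two_loci()
        sm = concatenate([l1], ROSTER)
        for sp, row in l1.rows.items():
            assert sm.matrix[sp] == row

    def test_extraction_reproduces_locus(self):
        sm = concatenate(two_loci(), ROSTER)
        part = sm.extract("og2")
        assert part["A"] == "MKVLDPE"
        assert part["C"] == "-" * 7

    def test_associativity(self):
        l1, l2 = two_loci()
        l3 = LocusAlignment("og3", {"B": "MMKK", "C": "MMKK"})
        once = concatenate([l1, l2, l3], ROSTER)
        l12 = concatenate([l1, l2], ROSTER)
        as_locus = [
            LocusAlignment("og1+og2", l12.matrix), l3
        ]
        twice = concatenate(as_locus, ROSTER)
        assert twice.matrix == once.matrix

    def test_unknown_species_is_error(self):
        bad = LocusAlignment("og", {"A": "MKV", "Z": "MKV"})
        with pytest.raises(ValueError, match="Z"):
            concatenate([bad], ROSTER)

    def test_conservation_of_residues(self):
        sm = concatenate(two_loci(), ROSTER)
        for sp in ROSTER:
            expect = sum(
                len(l.rows[sp].replace("-", ""))
                for l in two_loci()
                if sp in l.rows
            )
            assert len(sm.matrix[sp].replace("-", "")) == expect


class TestPhylip:
    def test_header_and_rows(self, tmp_path):
        sm = concatenate(two_loci(), ROSTER)
        write_phylip(sm, tmp_path / "sm.phy")
        lines = (tmp_path / "sm.phy").read_text().splitlines()
        assert lines[0] == "3 17"
        assert lines[1].startswith("A ")

    def test_write_read_write_byte_identical(self, tmp_path):
        sm = concatenate(two_loci(), ROSTER)
        p1, p2 = tmp_path / "a.phy", tmp_path / "b.phy"
        write_phylip(sm, p1)
        write_phylip(read_phylip(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_matrix_no_file(self, tmp_path):
        target = tmp_path / "x.phy"
        with pytest.raises(ValueError):
            write_phylip(Supermatrix(ROSTER, {}, []), target)
        assert not target.exists()

    def test_whitespace_name_rejected(self, tmp_path):
        sm = Supermatrix(
            SpeciesRoster(("A sp", "B")),
            {"A sp": "MKV", "B": "MKV"},
            [("og", 1, 3)],
        )
        with pytest.raises(ValueError, match="whitespace"):
            write_phylip(sm, tmp_path / "x.phy")


class TestPartitions:
    def test_lines_and_coordinates(self, tmp_path):
        sm = concatenate(two_loci(), ROSTER)
        write_partitions(sm, tmp_path / "p.txt")
        lines = (tmp_path / "p.txt").read_text().splitlines()
        assert lines == ["PROT, og1 = 1-10", "PROT, og2 = 11-17"]

    def test_round_trip_against_partition_list(self, tmp_path):
        sm = concatenate(two_loci(), ROSTER)
        write_partitions(sm, tmp_path / "p.txt")
        parsed = []
        for ln in (tmp_path / "p.txt").read_text().splitlines():
            name = ln.split(",")[1].split("=")[0].strip()
            rng_part = ln.split("=")[1].strip()
            start, end = map(int, rng_part.split("-"))
            parsed.append((name, start, end))
        assert parsed == sm.partitions


class TestGeneTrees:
    NWK = [
        "((A:1,B:1):1,C:2);",
        "((A:1,C:1):1,B:2);",
        "((B:1,C:1):1,A:2);",
    ]

    def _write_trees(self, tmp_path):
        paths = []
        for i, nwk in enumerate(self.NWK):
            p = tmp_path / f"t{i}.nwk"
            p.write_text(nwk + "\n")
            paths.append(p)
        return paths

    def test_three_files_three_lines(self, tmp_path):
        paths = self._write_trees(tmp_path)
        out = tmp_path / "all.trees"
        gts = aggregate_gene_trees(paths, ROSTER, out)
        assert len(gts.trees) == 3
        text = out.read_text()
        assert text.endswith("\n") and len(text.splitlines()) == 3

    def test_windows_line_endings_normalised(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_bytes(b"((A:1,B:1):1,C:2);\r\n")
        gts = aggregate_gene_trees([p], ROSTER)
        assert "\r" not in gts.trees[0]

    def test_topology_preserved(self, tmp_path):
        paths = self._write_trees(tmp_path)
        out = tmp_path / "all.trees"
        aggregate_gene_trees(paths, ROSTER, out)
        tns = dendropy.TaxonNamespace()
        for line, original in zip(out.read_text().splitlines(), self.NWK):
            t_out = dendropy.Tree.get(data=line, schema="newick",
                                      taxon_namespace=tns,
                                      preserve_underscores=True)
            t_in = dendropy.Tree.get(data=original, schema="newick",
                                     taxon_namespace=tns,
                                     preserve_underscores=True)
            t_out.encode_bipartitions()
            t_in.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(
                t_in, t_out
            ) == 0

    def test_unparseable_newick_names_file(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:1;")
        with pytest.raises(ValueError, match="bad.nwk"):
            aggregate_gene_trees([p], ROSTER)

    def test_unknown_leaf_warns_but_keeps(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,Zz:2);\n")
        with caplog.at_level("WARNING"):
            gts = aggregate_gene_trees([p], ROSTER)
        assert len(gts.trees) == 1
        assert any("Zz" in rec.getMessage() for rec in caplog.records)
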