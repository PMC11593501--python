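"""Alignment, identity and consensus merging against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoprep.filters import FilterParams, Outcome
from orthoprep.og_model import GeneSequence
from orthoprep.simmerge import (
    AlignmentParams,
    alignment_score,
    copies_mergeable,
    global_align,
    merge_copies,
    pairwise_identity,
    process_orthogroup,
)
from orthoprep.synthgen import mutate

from conftest import AA20, make_og, random_protein
from helpers_align import (
    brute_force_best_score,
    identity_excl_terminal_gaps,
    score_alignment,
    vote_consensus,
)

protein = st.text(alphabet=AA20, min_size=1, max_size=30)


def G(gid, seq, sp="A"):
    return GeneSequence(gid, sp, seq)


class TestGlobalAlign:
    def test_identity_alignment(self):
        assert global_align("MKV", "MKV") == ("MKV", "MKV")
        assert alignment_score("MKV", "MKV") == 3.0

    def test_single_deletion(self):
        assert global_align("MKV", "MV") == ("MKV", "M-V")

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            global_align("", "MKV")

    def test_degapped_rows_recover_inputs(self, rng):
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(1, 40)))
            b = random_protein(rng, int(rng.integers(1, 40)))
            aa, ab = global_align(a, b)
            assert len(aa) == len(ab)
            assert aa.replace("-", "") == a
            assert ab.replace("-", "") == b

    def test_score_matches_brute_force_small(self, rng):
        """DP optimum equals the exhaustive maximum over all alignments
        (small sample here; the full 50-pair check is in acceptance)."""
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            assert alignment_score(a, b) == brute_force_best_score(a, b)
            aa, ab = global_align(a, b)
            assert score_alignment(aa, ab) == alignment_score(a, b)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFG", "ACDEFG") == 1.0

    def test_one_substitution(self):
        assert pairwise_identity("ACDEFG", "ACDEYG") == pytest.approx(5 / 6)

    def test_terminal_overhang_excluded_by_default(self):
        # fragment vs full length: overhang does not dilute identity
        assert pairwise_identity("MKVLDPE", "MKVLD") == 1.0

    def test_shorter_sequence_denominator(self):
        params = AlignmentParams(identity_denominator="shorter_sequence_length")
        assert pairwise_identity("MKVLDPE", "MKVLD", params) == 1.0
        assert pairwise_identity("ACDEFG", "ACDEYG", params) == pytest.approx(5 / 6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(protein, protein)
    def test_symmetry_and_range(self, a, b):
        ab, ba = pairwise_identity(a, b), pairwise_identity(b, a)
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(ba)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(protein)
    def test_self_identity_is_one(self, a):
        assert pairwise_identity(a, a) == 1.0


class TestCopiesMergeable:
    def test_identical_copies(self):
        ok, ident = copies_mergeable([G("g1", "MKVLD"), G("g2", "MKVLD")], 0.97)
        assert ok and ident == 1.0

    def test_divergent_pair_fails(self):
        ok, ident = copies_mergeable(
            [G("g1", "ACDEFG"), G("g2", "ACDEYG")], 0.97
        )
        assert not ok
        assert ident == pytest.approx(5 / 6)

    def test_complete_linkage(self):
        # two near-identical copies plus one outlier: any failing pair sinks it
        ok, _ = copies_mergeable(
            [G("g1", "MKVLDPE"), G("g2", "MKVLDPE"), G("g3", "WWWLDPE")], 0.97
        )
        assert not ok

    def test_single_copy_is_callers_error(self):
        with pytest.raises(ValueError):
            copies_mergeable([G("g1", "MKV")], 0.97)

    def test_mixed_species_rejected(self):
        with pytest.raises(ValueError):
            copies_mergeable([G("g1", "MKV", "A"), G("g2", "MKV", "B")], 0.97)


class TestMergeCopies:
    def test_identical_copies_fixed_point(self):
        rec = merge_copies([G("g1", "MKVLD"), G("g2", "MKVLD")])
        assert rec.consensus == "MKVLD"
        assert rec.n_sites_unanimous == 5
        assert rec.n_sites_majority == rec.n_sites_trimmed == 0

    def test_majority_site_merged(self):
        rec = merge_copies(
            [G("g1", "MKVLD"), G("g2", "MKVLD"), G("g3", "MKALD")]
        )
        assert rec.consensus == "MKVLD"
        assert (rec.n_sites_unanimous, rec.n_sites_majority,
                rec.n_sites_trimmed) == (4, 1, 0)

    def test_split_site_trimmed(self):
        rec = merge_copies([G("g1", "MKVLD"), G("g2", "MKALD")])
        assert rec.consensus == "MKLD"
        assert (rec.n_sites_unanimous, rec.n_sites_trimmed) == (4, 1)

    def test_counts_tile_reference(self):
        rec = merge_copies([G("g1", "MKVLD"), G("g2", "MKALD")])
        assert rec.n_sites_unanimous + rec.n_sites_majority == len(rec.consensus)
        assert len(rec.consensus) + rec.n_sites_trimmed == 5

    def test_matches_vote_oracle_on_random_copies(self, rng):
        """Indel-free random copies: the star alignment is gapless, so the
        consensus must equal a direct per-column vote."""
        for _ in range(25):
            base = random_protein(rng, 40)
            n = int(rng.integers(2, 5))
            seqs = [mutate(base, 0.05, rng) for _ in range(n)]
            copies = [G(f"g{i}", s) for i, s in enumerate(seqs)]
            rec = merge_copies(copies)
            cons, n_u, n_m, n_t = vote_consensus(seqs)
            assert rec.consensus == cons
            assert (rec.n_sites_unanimous, rec.n_sites_majority,
                    rec.n_sites_trimmed) == (n_u, n_m, n_t)

    def test_order_invariance(self, rng):
        base = random_protein(rng, 30)
        seqs = [mutate(base, 0.05, rng) for _ in range(4)]
        copies = [G(f"g{i}", s) for i, s in enumerate(seqs)]
        rec_fwd = merge_copies(copies)
        rec_rev = merge_copies(list(reversed(copies)))
        assert rec_fwd.consensus == rec_rev.consensus

    def test_reference_tie_break_by_gene_id(self):
        # equal lengths: reference is the lexicographically smallest gene_id
        rec = merge_copies([G("zz", "MKALD"), G("aa", "MKVLD")])
        # with 1-1 split the site is trimmed either way; the provenance
        # ordering still reflects the input
        assert rec.input_gene_ids == ["zz", "aa"]
        assert rec.consensus == "MKLD"

    def test_insertion_in_non_reference_copy_dropped(self):
        # copy has one extra residue: reference coordinates are kept
        rec = merge_copies([G("g1", "MKVLDPE"), G("g2", "MKVLDE")])
        assert len(rec.consensus) <= 7


class TestProcessOrthogroup:
    def test_single_copy_pass_through(self, roster3, tiny_set):
        mog = process_orthogroup(tiny_set.orthogroups[0], roster3)
        assert mog.rejected is None
        assert mog.sequences == {"A": "MKVLD", "B": "MKVLD", "C": "MKVLE"}
        assert mog.merge_records == []

    def test_allele_pair_merged_to_ancestral_consensus(self, roster3, rng):
        base = random_protein(rng, 200)
        allele = mutate(base, 0.01, rng)
        og = make_og("og", roster3,
                     {"A": [base, allele], "B": [base], "C": [base]})
        mog = process_orthogroup(og, roster3)
        assert mog.rejected is None
        assert len(mog.merge_records) == 1
        rec = mog.merge_records[0]
        # unanimous sites are exactly the unmutated ones -> ancestral residue
        kept = [c for x, c in zip(allele, base) if x == c]
        assert rec.consensus == "".join(kept)
        assert rec.min_pairwise_identity >= 0.97 or rec is None

    def test_deep_paralog_rejects_orthogroup(self, roster3, rng):
        base = random_protein(rng, 100)
        paralog = mutate(base, 0.40, rng)
        og = make_og("og", roster3,
                     {"A": [base, paralog], "B": [base], "C": [base]})
        mog = process_orthogroup(og, roster3)
        assert mog.rejected == Outcome.FAIL_SIMILARITY.value
        assert mog.sequences == {}

    def test_drop_species_policy_prunes_only_offender(self, roster3, rng):
        base = random_protein(rng, 100)
        paralog = mutate(base, 0.40, rng)
        og = make_og("og", roster3,
                     {"A": [base, paralog], "B": [base], "C": [base]})
        mog = process_orthogroup(
            og, roster3, FilterParams(reject_policy="drop_species")
        )
        assert mog.rejected is None
        assert mog.dropped_species == ["A"]
        assert set(mog.sequences) == {"B", "C"}
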