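"""Pairwise identity among same-species copies and consensus merging.

This is the heart of the pipeline.  In de novo transcriptome assemblies of
heterozygous genomes, both alleles of a gene (and very recent duplicates)
assemble as separate "genes", inflating copy numbers and starving the
single-copy ortholog set.  Rather than discarding such orthogroups, copies
of one species are collapsed into a consensus when every pair of them is at
least ``min_similarity`` identical (complete linkage): sites where the
copies agree are kept, sites with a strict-majority residue are merged to
that residue, and divergent sites with no majority are trimmed.

Identity is computed from a Needleman–Wunsch global alignment with affine
gap penalties (delegated to Biopython's C implementation); the default
denominator excludes terminal gap overhangs so that fragmentary transcripts
are not penalised for length differences alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from Bio import Align

from .filters import FilterParams, Outcome, normalize_similarity
from .og_model import GeneSequence, Orthogroup, SpeciesRoster

__all__ = [
    "AlignmentParams",
    "MergeRecord",
    "MergedOrthogroup",
    "global_align",
    "pairwise_identity",
    "copies_mergeable",
    "merge_copies",
    "process_orthogroup",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scores for global alignment and the identity convention.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``; terminal
    gaps are penalised like internal ones (true global alignment).

    identity_denominator
        ``"aligned_columns_excl_terminal_gaps"`` (default): identical
        columns over the aligned span from the first to the last column in
        which both sequences carry a residue.  ``"shorter_sequence_length"``:
        identical columns over min(len(a), len(b)) (CD-HIT convention).
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    identity_denominator: str = "aligned_columns_excl_terminal_gaps"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.identity_denominator not in (
            "aligned_columns_excl_terminal_gaps",
            "shorter_sequence_length",
        ):
            raise ValueError(
                f"unknown identity_denominator {self.identity_denominator!r}"
            )

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class MergeRecord:
    """Provenance of one species' consensus."""

    species: str
    input_gene_ids: list[str]
    consensus: str
    n_sites_unanimous: int
    n_sites_majority: int
    n_sites_trimmed: int
    min_pairwise_identity: float


@dataclass
class MergedOrthogroup:
    """One orthogroup after merging: at most one sequence per species."""

    og_id: str
    sequences: dict[str, str]
    merge_records: list[MergeRecord] = field(default_factory=list)
    dropped_species: list[str] = field(default_factory=list)
    rejected: Optional[str] = None

    @property
    def n_species(self) -> int:
        return len(self.sequences)


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[str, str]:
    """Optimal global alignment of two residue strings.

    Returns gapped strings of equal length whose de-gapped forms recover the
    inputs.  Among co-optimal alignments the engine's first alignment is
    returned, which is deterministic for fixed inputs and scores.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if params is None:
        params = AlignmentParams()
    aln = params.make_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def alignment_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score (cheaper than a full traceback)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if params is None:
        params = AlignmentParams()
    return params.make_aligner().score(a, b)


def identity_from_alignment(
    aligned_a: str, aligned_b: str, params: AlignmentParams
) -> float:
    matches = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    if params.identity_denominator == "shorter_sequence_length":
        denom = min(
            len(aligned_a.replace("-", "")), len(aligned_b.replace("-", ""))
        )
    else:
        both = [
            i
            for i, (x, y) in enumerate(zip(aligned_a, aligned_b))
            if x != "-" and y != "-"
        ]
        if not both:
            return 0.0
        lo, hi = both[0], both[-1]
        denom = hi - lo + 1
        matches = sum(
            1
            for x, y in zip(aligned_a[lo : hi + 1], aligned_b[lo : hi + 1])
            if x == y and x != "-"
        )
    return matches / denom if denom else 0.0


def pairwise_identity(
    a: str, b: str, params: AlignmentParams | None = None
) -> float:
    """Fraction of identical aligned positions between two sequences.

    Symmetric up to co-optimal-alignment choice, 1.0 for identical inputs.
    """
    if params is None:
        params = AlignmentParams()
    aligned_a, aligned_b = global_align(a, b, params)
    return identity_from_alignment(aligned_a, aligned_b, params)


def copies_mergeable(
    copies: Sequence[GeneSequence],
    min_similarity: float,
    params: AlignmentParams | None = None,
) -> tuple[bool, float]:
    """Complete-linkage mergeability test for one species' copies.

    True iff *every* pair of copies reaches ``min_similarity`` identity —
    a consensus is only meaningful when no copy is an outlier.  Also returns
    the minimum observed identity, for reporting.
    """
    if len(copies) < 2:
        raise ValueError("copies_mergeable requires at least two copies")
    species = {c.species for c in copies}
    if len(species) != 1:
        raise ValueError(f"copies span multiple species: {sorted(species)}")
    threshold = normalize_similarity(min_similarity)
    if params is None:
        params = AlignmentParams()
    min_ident = 1.0
    ok = True
    for x, y in combinations(copies, 2):
        ident = pairwise_identity(x.residues, y.residues, params)
        if ident < min_ident:
            min_ident = ident
        if ident < threshold:
            ok = False
    return ok, min_ident


def _reference_index(copies: Sequence[GeneSequence]) -> int:
    """Longest copy; ties broken by lexicographically smallest gene_id."""
    return min(
        range(len(copies)),
        key=lambda i: (-len(copies[i].residues), copies[i].gene_id),
    )


def merge_copies(
    copies: Sequence[GeneSequence],
    params: AlignmentParams | None = None,
    min_pairwise_identity: float | None = None,
) -> MergeRecord:
    """Collapse near-identical same-species copies into a consensus.

    The copies are star-aligned against the longest copy (reference).  Each
    reference column then takes a vote among the residues aligned to it;
    gaps do not vote and insertions relative to the reference are dropped:

    * all votes identical            → residue kept (unanimous site)
    * a residue with > half of votes → that residue kept (merged site)
    * otherwise                      → column trimmed (divergent site)

    Voting is order-free and the reference choice is deterministic, so the
    input order of the copies never changes the consensus; merging a copy
    with itself is the identity.
    """
    if len(copies) < 2:
        raise ValueError("merge_copies requires at least two copies")
    if params is None:
        params = AlignmentParams()
    ref_i = _reference_index(copies)
    ref = copies[ref_i].residues

    # votes[j] = residues aligned to reference position j (reference included)
    votes: list[list[str]] = [[c] for c in ref]
    min_ident = 1.0
    for i, copy in enumerate(copies):
        if i == ref_i:
            continue
        aref, acpy = global_align(ref, copy.residues, params)
        if min_pairwise_identity is None:
            ident = identity_from_alignment(aref, acpy, params)
            if ident < min_ident:
                min_ident = ident
        j = 0
        for rc, cc in zip(aref, acpy):
            if rc == "-":
                continue  # insertion in the copy: dropped
            if cc != "-":
                votes[j].append(cc)
            j += 1
    if min_pairwise_identity is not None:
        min_ident = min_pairwise_identity

    consensus_chars: list[str] = []
    n_unanimous = n_majority = n_trimmed = 0
    for column in votes:
        counts = Counter(column)
        residue, top = counts.most_common(1)[0]
        if top == len(column):
            consensus_chars.append(residue)
            n_unanimous += 1
        elif top * 2 > len(column):
            consensus_chars.append(residue)
            n_majority += 1
        else:
            n_trimmed += 1

    return MergeRecord(
        species=copies[0].species,
        input_gene_ids=[c.gene_id for c in copies],
        consensus="".join(consensus_chars),
        n_sites_unanimous=n_unanimous,
        n_sites_majority=n_majority,
        n_sites_trimmed=n_trimmed,
        min_pairwise_identity=min_ident,
    )


def process_orthogroup(
    og: Orthogroup,
    roster: SpeciesRoster,
    filter_params: FilterParams | None = None,
    align_params: AlignmentParams | None = None,
) -> MergedOrthogroup:
    """Merge one structurally retained orthogroup down to <= 1 sequence per
    species.

    Single-copy species pass through unchanged.  A multi-copy species whose
    copies fail the complete-linkage similarity gate either rejects the
    whole orthogroup (``reject_policy="drop_orthogroup"``, the default) or
    is silently pruned (``"drop_species"``).
    """
    if filter_params is None:
        filter_params = FilterParams()
    if align_params is None:
        align_params = AlignmentParams()

    sequences: dict[str, str] = {}
    records: list[MergeRecord] = []
    dropped: list[str] = []
    for sp in roster:
        genes = og.members.get(sp, [])
        if not genes:
            continue
        if len(genes) == 1:
            sequences[sp] = genes[0].residues
            continue
        ok, min_ident = copies_mergeable(
            genes, filter_params.min_similarity, align_params
        )
        if not ok:
            if filter_params.reject_policy == "drop_orthogroup":
                return MergedOrthogroup(
                    og.og_id, {}, rejected=Outcome.FAIL_SIMILARITY.value
                )
            dropped.append(sp)
            continue
        record = merge_copies(
            genes, align_params, min_pairwise_identity=min_ident
        )
        records.append(record)
        sequences[sp] = record.consensus
    return MergedOrthogroup(og.og_id, sequences, records, dropped)


def write_merge_provenance(merged_ogs, path) -> None:
    """TSV of merge provenance: one row per consensus."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "og_id\tspecies\tinput_gene_ids\tmin_identity\t"
            "n_unanimous\tn_majority\tn_trimmed\n"
        )
        for mog in merged_ogs:
            for rec in mog.merge_records:
                fh.write(
                    f"{mog.og_id}\t{rec.species}\t"
                    f"{','.join(rec.input_gene_ids)}\t"
                    f"{rec.min_pairwise_identity:.6f}\t"
                    f"{rec.n_sites_unanimous}\t{rec.n_sites_majority}\t"
                    f"{rec.n_sites_trimmed}\n"
                )
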