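"""Domain types and I/O for orthogroup tables and protein sequence sets.

The orthogroup table dialect is the one produced by OrthoFinder's
``Orthogroups.tsv``: a header row ``Orthogroup<TAB>speciesA<TAB>speciesB...``
followed by one row per orthogroup whose cells hold ``", "``-separated gene
IDs (empty cell = species absent).  A simplified two-column long format
(``og_id<TAB>gene_id`` plus a separate gene→species map) is auto-detected by
header.  Species attribution always comes from the table (column position or
the map), never from parsing gene IDs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSequence",
    "SpeciesRoster",
    "Orthogroup",
    "OrthogroupSet",
    "read_fasta",
    "write_fasta",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
]

#: amino-acid alphabet accepted for residues (20 AA + ambiguity X; '*' is
#: stripped on read, gaps are not allowed in unaligned sequences)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_INNER_SEP = ", "


@dataclass(frozen=True)
class GeneSequence:
    """One protein sequence attributed to one species."""

    gene_id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"gene {self.gene_id!r}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non amino-acid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesRoster:
    """Ordered, unique species labels; order fixes supermatrix row order."""

    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("roster must not be empty")
        if len(set(self.species)) != len(self.species):
            raise ValueError("roster labels must be unique")
        object.__setattr__(self, "species", tuple(self.species))

    def __iter__(self):
        return iter(self.species)

    def __len__(self) -> int:
        return len(self.species)

    def __contains__(self, label: object) -> bool:
        return label in self.species


@dataclass
class Orthogroup:
    """One orthogroup: gene sequences grouped by species.

    ``members`` maps every roster species to a (possibly empty) list of
    :class:`GeneSequence`; absence is data, not an error.
    """

    og_id: str
    members: dict[str, list[GeneSequence]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        n = 0
        for sp, genes in self.members.items():
            for g in genes:
                if g.species != sp:
                    raise ValueError(
                        f"orthogroup {self.og_id}: gene {g.gene_id} filed under "
                        f"{sp!r} but attributed to {g.species!r}"
                    )
                if g.gene_id in seen:
                    raise ValueError(
                        f"orthogroup {self.og_id}: duplicate gene id {g.gene_id!r}"
                    )
                seen.add(g.gene_id)
                n += 1
        if n == 0:
            raise ValueError(f"orthogroup {self.og_id}: no genes")

    def copy_counts(self) -> dict[str, int]:
        return {sp: len(genes) for sp, genes in self.members.items()}

    def genes(self) -> list[GeneSequence]:
        return [g for genes in self.members.values() for g in genes]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())

    def species_present(self) -> list[str]:
        return [sp for sp, genes in self.members.items() if genes]


@dataclass
class OrthogroupSet:
    """A roster plus an ordered list of orthogroups (input order preserved)."""

    roster: SpeciesRoster
    orthogroups: list[Orthogroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [og.og_id for og in self.orthogroups]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate orthogroup ids: {dup}")
        for og in self.orthogroups:
            for sp in og.members:
                if sp not in self.roster:
                    raise ValueError(
                        f"orthogroup {og.og_id}: species {sp!r} not in roster"
                    )

    def __iter__(self):
        return iter(self.orthogroups)

    def __len__(self) -> int:
        return len(self.orthogroups)


# ---------------------------------------------------------------------------
# FASTA I/O (thin wrappers over Bio.SeqIO with the package's normalisation)
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a protein FASTA into ``[(id, residues), ...]``.

    IDs are the first whitespace-delimited token.  Residues are upper-cased
    and a single trailing stop ``*`` is stripped (TransDecoder emits them;
    they must not count toward alignment identity).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        if not residues:
            raise ValueError(f"{path}: empty sequence for {rid!r}")
        records.append((rid, residues))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                width: int = 60) -> None:
    """Write ``(id, residues)`` pairs as wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(residues), id=rid, description="")
        for rid, residues in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _collect_sequences(sequence_source: str | os.PathLike) -> dict[str, str]:
    """Build a gene_id → residues map from a FASTA file or a directory of
    FASTA files (per-species or per-orthogroup layout; both reduce to a flat
    id→sequence map because species attribution comes from the table)."""
    src = Path(sequence_source)
    if src.is_dir():
        paths = sorted(
            p for p in src.iterdir()
            if p.suffix.lower() in {".fa", ".faa", ".fasta", ".pep"}
        )
        if not paths:
            raise FileNotFoundError(f"no FASTA files found in {src}")
    elif src.is_file():
        paths = [src]
    else:
        raise FileNotFoundError(f"sequence source not found: {src}")
    seqs: dict[str, str] = {}
    for p in paths:
        for rid, residues in read_fasta(p):
            if rid in seqs and seqs[rid] != residues:
                raise ValueError(
                    f"gene id {rid!r} appears with conflicting sequences "
                    f"across files under {src}"
                )
            seqs[rid] = residues
    return seqs


# ---------------------------------------------------------------------------
# Orthogroup table I/O
# ---------------------------------------------------------------------------

def read_orthogroups_tsv(
    table_path: str | os.PathLike,
    sequence_source: str | os.PathLike,
    species_map: str | os.PathLike | Mapping[str, str] | None = None,
) -> OrthogroupSet:
    """Read an orthogroup membership table plus sequences.

    Two dialects, auto-detected by header:

    * wide (OrthoFinder ``Orthogroups.tsv``): header ``Orthogroup`` + one
      column per species; cells are ``", "``-separated gene IDs.
    * long: two columns ``og_id<TAB>gene_id``; requires ``species_map``
      (a mapping or a two-column TSV ``gene_id<TAB>species``).

    Every listed gene ID must resolve to a sequence in ``sequence_source``
    (one FASTA file, or a directory of per-species / per-orthogroup FASTAs).
    """
    with open(table_path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{table_path}: empty orthogroup table")
    header = lines[0].split("\t")
    seqs = _collect_sequences(sequence_source)

    if header[0] == "Orthogroup" and len(header) >= 2:
        return _read_wide(table_path, lines, header, seqs)
    if len(header) == 2:
        return _read_long(table_path, lines, seqs, species_map)
    raise ValueError(
        f"{table_path}: unrecognised header {header!r}; expected "
        "'Orthogroup<TAB>species...' or a two-column long format"
    )


def _lookup(seqs: Mapping[str, str], gene_id: str, og_id: str,
            species: str) -> str:
    try:
        return seqs[gene_id]
    except KeyError:
        raise KeyError(
            f"no sequence for gene {gene_id!r} (orthogroup {og_id}, "
            f"species {species})"
        ) from None


def _read_wide(table_path, lines, header, seqs) -> OrthogroupSet:
    roster = SpeciesRoster(tuple(header[1:]))
    orthogroups: list[Orthogroup] = []
    seen_ids: set[str] = set()
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ValueError(
                f"{table_path}: row {cells[0]!r} has {len(cells)} cells, "
                f"header has {len(header)}"
            )
        og_id = cells[0]
        if og_id in seen_ids:
            raise ValueError(f"{table_path}: duplicate orthogroup id {og_id!r}")
        seen_ids.add(og_id)
        members: dict[str, list[GeneSequence]] = {}
        for sp, cell in zip(roster, cells[1:]):
            genes: list[GeneSequence] = []
            cell = cell.strip()
            if cell:
                for gid in cell.split(_INNER_SEP):
                    gid = gid.strip()
                    if not gid:
                        raise ValueError(
                            f"{table_path}: orthogroup {og_id}, species {sp}: "
                            "empty gene id token (gene ids containing "
                            f"{_INNER_SEP!r} are unsupported)"
                        )
                    genes.append(
                        GeneSequence(gid, sp, _lookup(seqs, gid, og_id, sp))
                    )
            members[sp] = genes
        orthogroups.append(Orthogroup(og_id, members))
    return OrthogroupSet(roster, orthogroups)


def _read_long(table_path, lines, seqs, species_map) -> OrthogroupSet:
    if species_map is None:
        raise ValueError(
            f"{table_path}: long-format table requires a gene→species map"
        )
    if isinstance(species_map, (str, os.PathLike)):
        mapping: dict[str, str] = {}
        with open(species_map) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln:
                    continue
                gid, sp = ln.split("\t")
                mapping[gid] = sp
    else:
        mapping = dict(species_map)

    # roster order: first appearance in the map (stable, declared order)
    roster = SpeciesRoster(tuple(dict.fromkeys(mapping.values())))
    rows = [ln.split("\t") for ln in lines[1:]]
    grouped: dict[str, dict[str, list[GeneSequence]]] = {}
    for row in rows:
        if len(row) != 2:
            raise ValueError(f"{table_path}: malformed long-format row {row!r}")
        og_id, gid = row[0].strip(), row[1].strip()
        if gid not in mapping:
            raise KeyError(f"gene {gid!r} (orthogroup {og_id}) not in species map")
        sp = mapping[gid]
        og = grouped.setdefault(
            og_id, {s: [] for s in roster}
        )
        og[sp].append(GeneSequence(gid, sp, _lookup(seqs, gid, og_id, sp)))
    return OrthogroupSet(
        roster, [Orthogroup(og_id, members) for og_id, members in grouped.items()]
    )


def write_orthogroups_tsv(ogset: OrthogroupSet, path: str | os.PathLike) -> None:
    """Write the wide (OrthoFinder) dialect; inverse of :func:`read_orthogroups_tsv`."""
    with open(path, "w", newline="\n") as fh:
        fh.write("Orthogroup\t" + "\t".join(ogset.roster) + "\n")
        for og in ogset:
            cells = [
                _INNER_SEP.join(g.gene_id for g in og.members.get(sp, []))
                for sp in ogset.roster
            ]
            fh.write(og.og_id + "\t" + "\t".join(cells) + "\n")
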