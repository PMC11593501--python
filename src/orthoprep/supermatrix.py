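"""Per-locus alignment, supermatrix concatenation, and gene-tree aggregation.

Outputs feed two downstream tree-building routes: the concatenation route
(one relaxed-PHYLIP supermatrix ``final_OrthologsAlign_GDL.phy`` plus a
RAxML-style partition table) and the coalescent route (per-locus FASTAs for
per-gene ML trees, and a multi-newick ``all.trees`` file for ASTRAL-style
summary methods).  Tree inference itself is external; documented command
templates live in the package docs.
"""

from __future__ import annotations

import logging
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy

from .og_model import SpeciesRoster, read_fasta, write_fasta
from .simmerge import AlignmentParams, MergedOrthogroup, global_align

__all__ = [
    "LocusAlignment",
    "Supermatrix",
    "GeneTreeSet",
    "align_locus",
    "concatenate",
    "write_phylip",
    "read_phylip",
    "write_partitions",
    "write_locus_fastas",
    "aggregate_gene_trees",
]

logger = logging.getLogger(__name__)

GAP = "-"

#: command templates for the external tree-building stages (not executed here)
TREE_COMMAND_TEMPLATES = {
    "raxml_concat": (
        "raxmlHPC -f a -x {seed} -p {seed} -# 1000 -m GTRGAMMA "
        "-s final_OrthologsAlign_GDL.phy -q partitions.txt -n concat"
    ),
    "iqtree_per_locus": "iqtree2 -s {locus_fasta} -m MFP -B 1000",
    "astral_pro": "astral-pro -i all.trees -o species_tree.nwk",
}


@dataclass
class LocusAlignment:
    """One aligned locus: equal-length gapped rows keyed by species."""

    og_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(
                f"locus {self.og_id}: alignments need >= 2 species"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.og_id}: ragged rows {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class Supermatrix:
    """Concatenated alignment with a partition table.

    ``partitions`` holds ``(og_id, start, end)`` with 1-based inclusive
    coordinates in concatenation order; species absent from a locus carry
    gaps across that partition.
    """

    roster: SpeciesRoster
    matrix: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.matrix.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged supermatrix rows: {lengths}")
        total = lengths.pop() if lengths else 0
        expected = sum(end - start + 1 for _, start, end in self.partitions)
        if total != expected:
            raise ValueError(
                f"partition lengths sum to {expected}, matrix width is {total}"
            )
        pos = 1
        for og_id, start, end in self.partitions:
            if start != pos or end < start:
                raise ValueError(
                    f"partition {og_id}: [{start}, {end}] does not tile "
                    f"(expected start {pos})"
                )
            pos = end + 1

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    def extract(self, og_id: str) -> dict[str, str]:
        """Rows of one partition (all roster species, gap-padded)."""
        for name, start, end in self.partitions:
            if name == og_id:
                return {
                    sp: row[start - 1 : end] for sp, row in self.matrix.items()
                }
        raise KeyError(f"no partition {og_id!r}")


@dataclass
class GeneTreeSet:
    """Ordered newick strings, one per retained orthogroup."""

    trees: list[str]

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="\n") as fh:
            for nwk in self.trees:
                fh.write(nwk.rstrip("\n") + "\n")


# ---------------------------------------------------------------------------
# Locus alignment
# ---------------------------------------------------------------------------

def _center_star(sequences: dict[str, str], params: AlignmentParams) -> dict[str, str]:
    """Center-star multiple alignment: pairwise NW to the longest sequence,
    merged by gap propagation.  For near-identical inputs (the merged-copy
    regime) this is effectively exact and fully deterministic."""
    center_sp = min(sequences, key=lambda sp: (-len(sequences[sp]), sp))
    center = sequences[center_sp]
    L = len(center)

    # per sequence: residues mapped to center coordinates + insertion blocks
    # ins[k] = chars inserted after k center residues consumed (k in 0..L)
    parsed: dict[str, tuple[list[str], list[str]]] = {}
    max_ins = [0] * (L + 1)
    for sp, seq in sequences.items():
        if sp == center_sp:
            continue
        ac, asp = global_align(center, seq, params)
        cols = [""] * L  # residue (or "") at each center position
        ins = [""] * (L + 1)
        k = 0
        for cc, sc in zip(ac, asp):
            if cc == GAP:
                ins[k] += sc
            else:
                cols[k] = sc if sc != GAP else ""
                k += 1
        parsed[sp] = (cols, ins)
        for k in range(L + 1):
            if len(ins[k]) > max_ins[k]:
                max_ins[k] = len(ins[k])

    def build(cols: list[str], ins: list[str]) -> str:
        out = [ins[0].ljust(max_ins[0], GAP)]
        for k in range(L):
            out.append(cols[k] or GAP)
            out.append(ins[k + 1].ljust(max_ins[k + 1], GAP))
        return "".join(out)

    rows = {center_sp: build(list(center), [""] * (L + 1))}
    for sp, (cols, ins) in parsed.items():
        rows[sp] = build(cols, ins)
    return rows


def _mafft_align(
    sequences: dict[str, str], mafft_path: str
) -> dict[str, str]:
    if shutil.which(mafft_path) is None:
        raise FileNotFoundError(
            f"MAFFT executable {mafft_path!r} not found; pass "
            "aligner='builtin_star' to use the built-in aligner"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.faa"
        write_fasta(sorted(sequences.items()), infile)
        proc = subprocess.run(
            [mafft_path, "--auto", "--amino", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        outfile = Path(tmp) / "out.faa"
        outfile.write_text(proc.stdout)
        # read raw with SeqIO: aligned FASTA contains gap characters
        from Bio import SeqIO

        rows = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(outfile), "fasta")
        }
    return rows


def align_locus(
    merged: MergedOrthogroup,
    aligner: str = "builtin_star",
    align_params: AlignmentParams | None = None,
    mafft_path: str = "mafft",
) -> LocusAlignment:
    """Align one merged orthogroup's per-species sequences.

    ``builtin_star`` is a deterministic center-star alignment adequate for
    the near-identical regime this pipeline produces; ``external_mafft``
    shells out to a MAFFT binary for production alignments.
    """
    if len(merged.sequences) < 2:
        raise ValueError(
            f"locus {merged.og_id}: fewer than 2 species, cannot align"
        )
    if align_params is None:
        align_params = AlignmentParams()
    if aligner == "builtin_star":
        rows = _center_star(merged.sequences, align_params)
    elif aligner in ("external_mafft", "mafft"):
        rows = _mafft_align(merged.sequences, mafft_path)
    else:
        raise ValueError(f"unknown aligner {aligner!r}")
    return LocusAlignment(merged.og_id, rows)


# ---------------------------------------------------------------------------
# Concatenation and writers
# ---------------------------------------------------------------------------

def concatenate(
    loci: Sequence[LocusAlignment],
    roster: SpeciesRoster,
    fill_char: str = GAP,
) -> Supermatrix:
    """Concatenate loci in input order into a supermatrix.

    Species missing from a locus are padded with ``fill_char`` across that
    partition; every roster species gets a row.
    """
    if not loci:
        raise ValueError("cannot concatenate zero loci")
    for locus in loci:
        unknown = set(locus.rows) - set(roster.species)
        if unknown:
            raise ValueError(
                f"locus {locus.og_id}: species not in roster: {sorted(unknown)}"
            )
    parts: dict[str, list[str]] = {sp: [] for sp in roster}
    partitions: list[tuple[str, int, int]] = []
    pos = 1
    for locus in loci:
        width = locus.length
        for sp in roster:
            parts[sp].append(locus.rows.get(sp, fill_char * width))
        partitions.append((locus.og_id, pos, pos + width - 1))
        pos += width
    matrix = {sp: "".join(chunks) for sp, chunks in parts.items()}
    return Supermatrix(roster, matrix, partitions)


def write_phylip(sm: Supermatrix, path: str | os.PathLike) -> None:
    """Write relaxed PHYLIP: ``<ntaxa> <nsites>`` header, then one
    ``<name> <sequence>`` line per species in roster order.

    Relaxed (not strict 10-character) because binomial species labels
    routinely exceed ten characters; RAxML accepts the relaxed form.
    """
    if not sm.matrix or sm.n_sites == 0:
        raise ValueError("refusing to write an empty supermatrix")
    for sp in sm.roster:
        if any(ch.isspace() for ch in sp):
            raise ValueError(
                f"species name {sp!r} contains whitespace; invalid in "
                "relaxed PHYLIP"
            )
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{len(sm.roster)} {sm.n_sites}\n")
        for sp in sm.roster:
            fh.write(f"{sp} {sm.matrix[sp]}\n")


def read_phylip(path: str | os.PathLike) -> Supermatrix:
    """Read relaxed PHYLIP back into a (partition-less) supermatrix."""
    with open(path) as fh:
        header = fh.readline().split()
        ntaxa, nsites = int(header[0]), int(header[1])
        names: list[str] = []
        matrix: dict[str, str] = {}
        for _ in range(ntaxa):
            name, seq = fh.readline().split(maxsplit=1)
            seq = seq.strip()
            if len(seq) != nsites:
                raise ValueError(
                    f"{path}: row {name!r} has {len(seq)} sites, "
                    f"header says {nsites}"
                )
            names.append(name)
            matrix[name] = seq
    return Supermatrix(
        SpeciesRoster(tuple(names)), matrix, [("all", 1, nsites)]
    )


def write_partitions(sm: Supermatrix, path: str | os.PathLike) -> None:
    """RAxML-style partition lines ``PROT, <og_id> = <start>-<end>``."""
    pos = 1
    for og_id, start, end in sm.partitions:
        if start < pos:
            raise ValueError(f"overlapping partition {og_id}")
        pos = end + 1
    with open(path, "w", newline="\n") as fh:
        for og_id, start, end in sm.partitions:
            fh.write(f"PROT, {og_id} = {start}-{end}\n")


def write_locus_fastas(
    loci: Sequence[LocusAlignment], out_dir: str | os.PathLike
) -> list[Path]:
    """Per-locus aligned FASTAs (coalescent route inputs), ``<og_id>.faa``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for locus in loci:
        path = out / f"{locus.og_id}.faa"
        with open(path, "w", newline="\n") as fh:
            for sp in sorted(locus.rows):
                fh.write(f">{sp}\n{locus.rows[sp]}\n")
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Gene-tree aggregation
# ---------------------------------------------------------------------------

def aggregate_gene_trees(
    tree_paths: Sequence[str | os.PathLike],
    roster: SpeciesRoster | None = None,
    out_path: str | os.PathLike | None = None,
) -> GeneTreeSet:
    """Collect per-locus gene trees into one multi-newick set (``all.trees``).

    Each input file may hold one or more newick trees; output order follows
    the input path order.  Leaf labels outside the roster are warned about
    but kept (summary methods tolerate them); an unparseable file is a hard
    error naming the file.
    """
    trees: list[str] = []
    for path in tree_paths:
        try:
            tl = dendropy.TreeList.get(
                path=os.fspath(path),
                schema="newick",
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"cannot parse newick file {path}: {exc}") from exc
        if len(tl) == 0:
            raise ValueError(f"no trees found in {path}")
        for tree in tl:
            if roster is not None:
                unknown = {
                    leaf.taxon.label
                    for leaf in tree.leaf_node_iter()
                    if leaf.taxon is not None
                } - set(roster.species)
                if unknown:
                    logger.warning(
                        "%s: leaf labels not in roster: %s",
                        path,
                        sorted(unknown),
                    )
            trees.append(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    unquoted_underscores=True,
                ).strip()
            )
    result = GeneTreeSet(trees)
    if out_path is not None:
        result.write(out_path)
    return result
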