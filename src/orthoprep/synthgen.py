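"""Synthetic orthogroup datasets with the copy-number pathologies the
pipeline exists to handle, plus analytic ground-truth labels.

The generator emulates what de novo transcriptome assembly of a heterozygous
plant genome hands to an orthology pipeline: per species, a gene may be
represented by

* one sequence (the usual case),
* two alleles at ~99% identity (heterozygosity assembled as two "genes"),
* a burst of recent duplicates, also near-identical,
* a deep paralog at ~60% identity (ancient whole-genome-duplication
  remnant contaminating the orthogroup), or
* nothing at all (loss / tissue-specific non-expression).

Ground-truth filter labels are computed analytically from the realized
random draws — absences counted, copies counted, pairwise Hamming
identities measured — never by running the pipeline itself, so they are an
independent oracle for it.  Hamming identity equals alignment identity here
because the generator emits no indels by default (an optional ``indel_prob``
exercises gap handling, but then ground-truth labels are refused rather
than approximated).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .filters import FilterParams, Outcome
from .og_model import (
    GeneSequence,
    Orthogroup,
    OrthogroupSet,
    SpeciesRoster,
    write_fasta,
    write_orthogroups_tsv,
)

__all__ = ["SynthScenario", "GroundTruth", "generate_dataset", "mutate"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(AA20.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SynthScenario:
    """Generative parameters for one synthetic dataset.

    The defaults describe a heterozygous, duplication-prone transcriptome
    roster of 24 species: alleles diverge ~1% per site (≈99% identity,
    the heterozygosity regime), deep paralogs diverge 40% per site (the
    ancient-duplication regime, far below any sane similarity threshold),
    species diverge 5% per site, and each species is absent from a given
    orthogroup 5% of the time.
    """

    n_species: int = 24
    n_orthogroups: int = 100
    seq_length: int = 300
    het_prob: float = 0.3
    het_divergence: float = 0.01
    dup_prob: float = 0.1
    max_extra_dups: int = 8
    paralog_prob: float = 0.05
    paralog_divergence: float = 0.40
    loss_prob: float = 0.05
    species_divergence: float = 0.05
    indel_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_orthogroups < 1:
            raise ValueError("need at least one species and one orthogroup")
        for name in (
            "het_prob",
            "het_divergence",
            "dup_prob",
            "paralog_prob",
            "paralog_divergence",
            "loss_prob",
            "species_divergence",
            "indel_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SynthScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def species_labels(self) -> tuple[str, ...]:
        width = max(2, len(str(self.n_species)))
        return tuple(f"sp{i + 1:0{width}d}" for i in range(self.n_species))


@dataclass
class GroundTruth:
    """Analytic per-orthogroup facts sufficient to label any filter setting.

    ``min_identity`` holds, per orthogroup, the minimum realized pairwise
    identity over every multi-copy species' copy pairs (None when no species
    is multi-copy).  ``ancestral`` holds each species' pre-mutation base
    sequence — the target the consensus merge should recover.
    """

    n_species: int
    n_absent: dict[str, int]
    copy_counts: dict[str, dict[str, int]]
    min_identity: dict[str, Optional[float]]
    species_min_identity: dict[str, dict[str, float]]
    ancestral: dict[str, dict[str, str]]

    def label(self, og_id: str, params: FilterParams) -> Outcome:
        """Expected filter outcome, mirroring the documented test order:
        missing rate, then duplication, then similarity."""
        rate = self.n_absent[og_id] / self.n_species
        max_copy = max(self.copy_counts[og_id].values(), default=0)
        if params.strict:
            if not rate < params.max_missing_rate:
                return Outcome.FAIL_MISSING
            if not max_copy < params.max_duplication_num:
                return Outcome.FAIL_DUPLICATION
        else:
            if rate > params.max_missing_rate:
                return Outcome.FAIL_MISSING
            if max_copy > params.max_duplication_num:
                return Outcome.FAIL_DUPLICATION
        if params.reject_policy == "drop_orthogroup":
            ident = self.min_identity[og_id]
            if ident is not None and ident < params.min_similarity:
                return Outcome.FAIL_SIMILARITY
        return Outcome.PASS

    def labels(self, params: FilterParams) -> dict[str, Outcome]:
        return {og: self.label(og, params) for og in self.n_absent}

    def write_tsv(self, path: str | os.PathLike,
                  params: FilterParams | None = None) -> None:
        if params is None:
            params = FilterParams()
        with open(path, "w", newline="\n") as fh:
            fh.write(
                "og_id\tlabel\tn_absent\tmax_copy\tmin_identity\n"
            )
            for og_id in self.n_absent:
                ident = self.min_identity[og_id]
                fh.write(
                    f"{og_id}\t{self.label(og_id, params).value}\t"
                    f"{self.n_absent[og_id]}\t"
                    f"{max(self.copy_counts[og_id].values(), default=0)}\t"
                    f"{'' if ident is None else f'{ident:.6f}'}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA_ARR[rng.integers(0, len(_AA_ARR), size=length)]


def _mutate_arr(
    seq: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each site independently with probability ``p`` to a
    uniformly chosen *different* residue."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < p)[0]
    if hit.size:
        # draw an offset 1..19 into the alphabet, skipping the original
        idx = np.searchsorted(_AA_ARR, out[hit])
        offs = rng.integers(1, len(_AA_ARR), size=hit.size)
        out[hit] = _AA_ARR[(idx + offs) % len(_AA_ARR)]
    return out


def mutate(seq: str, per_site_prob: float, rng: np.random.Generator) -> str:
    """Per-site substitution of a residue string; p=0 is the identity,
    p=1 changes every site."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _mutate_arr(arr, per_site_prob, rng).tobytes().decode()


def _hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    return int(np.count_nonzero(a == b)) / a.size


def generate_dataset(
    scenario: SynthScenario,
    out_dir: str | os.PathLike | None = None,
) -> tuple[OrthogroupSet, GroundTruth]:
    """Simulate one dataset; optionally write it in the OrthoFinder dialect.

    When ``out_dir`` is given, writes ``Orthogroups.tsv``, one
    ``<species>.faa`` per species, and ``ground_truth.tsv``.  The same seed
    always yields byte-identical files.
    """
    rng = np.random.default_rng(scenario.seed)
    roster = SpeciesRoster(scenario.species_labels())
    og_width = max(4, len(str(scenario.n_orthogroups)))

    orthogroups: list[Orthogroup] = []
    n_absent: dict[str, int] = {}
    copy_counts: dict[str, dict[str, int]] = {}
    min_identity: dict[str, Optional[float]] = {}
    species_min_identity: dict[str, dict[str, float]] = {}
    ancestral: dict[str, dict[str, str]] = {}

    for i in range(scenario.n_orthogroups):
        og_id = f"OG{i:0{og_width}d}"
        root = _random_seq(rng, scenario.seq_length)
        members: dict[str, list[GeneSequence]] = {}
        absent = 0
        counts: dict[str, int] = {}
        og_min: Optional[float] = None
        sp_min: dict[str, float] = {}
        anc: dict[str, str] = {}

        for sp in roster:
            lost = rng.random() < scenario.loss_prob
            base = _mutate_arr(root, scenario.species_divergence, rng)
            if lost:
                members[sp] = []
                absent += 1
                continue
            anc[sp] = base.tobytes().decode()
            copies = [base]
            if rng.random() < scenario.het_prob:
                copies.append(
                    _mutate_arr(base, scenario.het_divergence, rng)
                )
            if rng.random() < scenario.dup_prob:
                n_extra = int(rng.integers(1, scenario.max_extra_dups + 1))
                for _ in range(n_extra):
                    copies.append(
                        _mutate_arr(base, scenario.het_divergence, rng)
                    )
            if rng.random() < scenario.paralog_prob:
                copies.append(
                    _mutate_arr(base, scenario.paralog_divergence, rng)
                )
            if scenario.indel_prob > 0:
                copies = [
                    _apply_indels(c, scenario.indel_prob, rng) for c in copies
                ]
            members[sp] = [
                GeneSequence(
                    f"{sp}_{og_id}_c{k + 1}", sp, c.tobytes().decode()
                )
                for k, c in enumerate(copies)
            ]
            counts[sp] = len(copies)
            if len(copies) >= 2 and scenario.indel_prob == 0:
                idents = [
                    _hamming_identity(copies[x], copies[y])
                    for x in range(len(copies))
                    for y in range(x + 1, len(copies))
                ]
                sp_min[sp] = min(idents)
                if og_min is None or sp_min[sp] < og_min:
                    og_min = sp_min[sp]

        if absent == scenario.n_species:
            # degenerate draw (everything lost): keep the first species so
            # the orthogroup is well-formed; counted as n_species - 1 absent
            sp0 = roster.species[0]
            anc[sp0] = _mutate_arr(
                root, scenario.species_divergence, rng
            ).tobytes().decode()
            members[sp0] = [GeneSequence(f"{sp0}_{og_id}_c1", sp0, anc[sp0])]
            counts[sp0] = 1
            absent -= 1

        orthogroups.append(Orthogroup(og_id, members))
        n_absent[og_id] = absent
        copy_counts[og_id] = counts
        min_identity[og_id] = og_min
        species_min_identity[og_id] = sp_min
        ancestral[og_id] = anc

    ogset = OrthogroupSet(roster, orthogroups)
    truth = GroundTruth(
        scenario.n_species,
        n_absent,
        copy_counts,
        min_identity,
        species_min_identity,
        ancestral,
    )
    if scenario.indel_prob > 0:
        truth.min_identity = {k: None for k in truth.min_identity}
        truth.species_min_identity = {k: {} for k in truth.species_min_identity}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_orthogroups_tsv(ogset, out / "Orthogroups.tsv")
        for sp in roster:
            records = [
                (g.gene_id, g.residues)
                for og in ogset
                for g in og.members.get(sp, [])
            ]
            write_fasta(records, out / f"{sp}.faa")
        truth.write_tsv(out / "ground_truth.tsv")
    return ogset, truth


def _apply_indels(
    seq: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Optional gap exercise: delete each site with probability p/2 and
    duplicate it in place with probability p/2 (crude but indel-shaped)."""
    r = rng.random(seq.size)
    keep = r >= p / 2
    dup = r > 1 - p / 2
    pieces = []
    for i in range(seq.size):
        if keep[i]:
            pieces.append(seq[i : i + 1])
        if dup[i]:
            pieces.append(seq[i : i + 1])
    out = np.concatenate(pieces) if pieces else seq[:1].copy()
    return out
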