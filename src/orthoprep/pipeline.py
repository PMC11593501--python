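"""End-to-end orchestration: read → filter → merge → align → emit.

`run` is the library equivalent of a command-line driver: it takes a
:class:`RunConfig`, executes the whole filter-and-merge pipeline, writes the
requested outputs into ``out_dir`` and returns a summary of the stage
counts.  The configuration is serialized verbatim into
``run_manifest.json`` so a run can be reproduced from its output directory
alone; reruns with identical config produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import supermatrix as sm
from .filters import FilterParams, Outcome, filter_orthogroups
from .og_model import OrthogroupSet, read_orthogroups_tsv
from .simmerge import (
    AlignmentParams,
    MergedOrthogroup,
    process_orthogroup,
    write_merge_provenance,
)

__all__ = ["RunConfig", "RunSummary", "run"]

logger = logging.getLogger(__name__)

SUPERMATRIX_FILENAME = "final_OrthologsAlign_GDL.phy"
TREES_FILENAME = "all.trees"


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    table_path: str
    sequence_source: str
    out_dir: str
    species_map: Optional[str] = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    align_params: AlignmentParams = field(default_factory=AlignmentParams)
    method: str = "both"  # concat | coalescent | both
    aligner: str = "builtin_star"  # builtin_star | external_mafft
    mafft_path: str = "mafft"
    gene_tree_paths: Optional[list[str]] = None
    fill_char: str = "-"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in ("concat", "coalescent", "both"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter_params" in raw and isinstance(raw["filter_params"], dict):
            raw["filter_params"] = FilterParams(**raw["filter_params"])
        if "align_params" in raw and isinstance(raw["align_params"], dict):
            raw["align_params"] = AlignmentParams(**raw["align_params"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunSummary:
    """Stage counts: input → structural pass → similarity pass → emitted."""

    n_input: int
    n_structural_pass: int
    n_similarity_pass: int
    n_loci_emitted: int
    outcome_counts: dict[str, int]
    outputs: list[str]


def _write_manifest(config: RunConfig, summary: RunSummary, path: Path) -> None:
    payload = {
        "config": config.to_dict(),
        "stage_counts": {
            "input_orthogroups": summary.n_input,
            "structural_pass": summary.n_structural_pass,
            "similarity_pass": summary.n_similarity_pass,
            "loci_emitted": summary.n_loci_emitted,
        },
        "outcome_counts": summary.outcome_counts,
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run(config: RunConfig) -> RunSummary:
    """Execute the pipeline.

    Writes, depending on ``method``:

    * ``concat``: ``final_OrthologsAlign_GDL.phy`` + ``partitions.txt``
    * ``coalescent``: per-locus aligned FASTAs under ``loci/`` and, when
      ``gene_tree_paths`` is supplied, ``all.trees``
    * ``both``: all of the above

    plus ``filter_report.tsv``, ``filter_summary.json``,
    ``merge_provenance.tsv`` and ``run_manifest.json`` in every mode.
    Any hard error removes the files written by this run before re-raising.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        ogset = read_orthogroups_tsv(
            config.table_path, config.sequence_source, config.species_map
        )
        logger.info("read %d orthogroups, %d species",
                    len(ogset), len(ogset.roster))

        kept, report = filter_orthogroups(
            ogset, config.filter_params, config.align_params
        )
        counts = report.counts
        n_structural = len(ogset) - counts[Outcome.FAIL_MISSING.value] \
            - counts[Outcome.FAIL_DUPLICATION.value]
        report.write_tsv(track(out / "filter_report.tsv"))
        report.write_json_summary(track(out / "filter_summary.json"))

        merged: list[MergedOrthogroup] = []
        for og in kept:
            mog = process_orthogroup(
                og, ogset.roster, config.filter_params, config.align_params
            )
            if mog.rejected is not None:
                # only reachable under drop_orthogroup, where the filter
                # stage already rejected it; defensive double-check
                continue
            merged.append(mog)
        write_merge_provenance(merged, track(out / "merge_provenance.tsv"))

        loci: list[sm.LocusAlignment] = []
        for mog in merged:
            if len(mog.sequences) < 2:
                logger.warning(
                    "locus %s: fewer than 2 species after merging; skipped",
                    mog.og_id,
                )
                continue
            loci.append(
                sm.align_locus(
                    mog,
                    aligner=config.aligner,
                    align_params=config.align_params,
                    mafft_path=config.mafft_path,
                )
            )
        logger.info(
            "stages: %d input -> %d structural pass -> %d similarity pass "
            "-> %d loci emitted",
            len(ogset), n_structural, len(merged), len(loci),
        )

        outputs: list[str] = []
        if config.method in ("concat", "both"):
            if not loci:
                raise ValueError("no loci passed filtering; nothing to concatenate")
            matrix = sm.concatenate(loci, ogset.roster, config.fill_char)
            sm.write_phylip(matrix, track(out / SUPERMATRIX_FILENAME))
            sm.write_partitions(matrix, track(out / "partitions.txt"))
            outputs += [SUPERMATRIX_FILENAME, "partitions.txt"]
        if config.method in ("coalescent", "both"):
            locus_dir = out / "loci"
            for p in sm.write_locus_fastas(loci, locus_dir):
                track(p)
            outputs.append("loci/")
            if config.gene_tree_paths:
                sm.aggregate_gene_trees(
                    config.gene_tree_paths,
                    roster=ogset.roster,
                    out_path=track(out / TREES_FILENAME),
                )
                outputs.append(TREES_FILENAME)

        summary = RunSummary(
            n_input=len(ogset),
            n_structural_pass=n_structural,
            n_similarity_pass=len(merged),
            n_loci_emitted=len(loci),
            outcome_counts=counts,
            outputs=["filter_report.tsv", "filter_summary.json",
                     "merge_provenance.tsv"] + outputs,
        )
        _write_manifest(config, summary, track(out / "run_manifest.json"))
        return summary
    except Exception:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise
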