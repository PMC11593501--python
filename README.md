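# orthoprep

Orthogroup filtering and heterozygosity-aware consensus merging for
phylogenomics from de novo transcriptomes.

## The problem

Species without reference genomes are usually placed on a phylogeny by
assembling transcriptomes de novo, clustering the predicted proteins into
orthogroups (e.g. with OrthoFinder), and building trees from single-copy
orthologs. In highly heterozygous, duplication-prone genomes this breaks
down: both alleles of a gene — and recent tandem duplicates — assemble as
separate "genes", so almost no orthogroup looks single-copy, and the strict
1:1 ortholog set collapses to a handful of loci. Meanwhile ancient
whole-genome-duplication paralogs lurk in the same orthogroups and must
*not* be merged, because they carry a different evolutionary history.

`orthoprep` addresses this by filtering and repairing orthogroups instead
of discarding them:

1. **Structural filter.** Keep an orthogroup when its *species missing
   rate* — the fraction of the roster with zero copies — is ≤
   `max_missing_rate` (default 0.05) and its maximum per-species copy
   number is ≤ `max_duplication_num` (default 6).
2. **Similarity gate.** Within each species, compute pairwise global
   alignment identity between all copies. All pairs must reach
   `min_similarity` (default 0.97, complete linkage); a failing species
   rejects the orthogroup (or, optionally, only that species is dropped).
   This is what separates alleles/recent duplicates (~99% identical) from
   deep paralogs (~60%).
3. **Consensus merge.** Mergeable copies are star-aligned to the longest
   copy and voted per site: unanimous sites are kept, strict-majority sites
   are merged to the majority residue, and divergent sites with no majority
   are trimmed. Each retained species ends up with exactly one sequence.
4. **Outputs.** Per-locus alignments are concatenated into a relaxed-PHYLIP
   supermatrix (`final_OrthologsAlign_GDL.phy`) with a RAxML-style
   partition table for concatenation tree building, and/or emitted as
   per-locus FASTAs plus an aggregated multi-newick `all.trees` file for
   coalescent summary methods (ASTRAL and relatives). Tree inference itself
   (RAxML/IQ-TREE/ASTRAL, MAFFT for production alignments) stays external;
   command templates are in `orthoprep.supermatrix.TREE_COMMAND_TEMPLATES`.

A fully seeded synthetic-data generator (`orthoprep.synthgen`) emulates the
pathologies above — heterozygous allele pairs, duplicate bursts, deep
paralogs, losses — in the OrthoFinder file dialect, with analytic
ground-truth labels, so the whole pipeline is testable without any
downloads.

## Worked example

```python
from orthoprep import (FilterParams, RunConfig, SynthScenario,
                       generate_dataset, run)

generate_dataset(SynthScenario(n_orthogroups=200, seed=3), "data")
summary = run(RunConfig(
    table_path="data/Orthogroups.tsv",
    sequence_source="data",
    out_dir="out",
    method="concat",
    filter_params=FilterParams(max_missing_rate=0.10),
))
```

This prints (via logging) and returns the stage counts:

```
stage counts: 200 input -> 69 structural pass -> 15 similarity pass -> 15 loci
supermatrix header : 24 4500  (taxa, concatenated sites)
first partitions   : ['PROT, OG0012 = 1-300', 'PROT, OG0022 = 301-600']
```

Read: of 200 simulated orthogroups, 69 survive the missing-rate and
duplication filters, 15 also pass the within-species similarity gate, and
those 15 merged loci concatenate into a 24-taxon × 4500-site supermatrix;
each partition line delimits one locus inside it. The `examples/` directory
holds one short runnable script per capability (filtering, merging,
supermatrix, simulation, gene-tree aggregation) producing exactly this kind
of output.

## Acceptance script

`scripts/acceptance.py` regenerates a seeded synthetic dataset, runs the
complete filter → merge → align → concatenate pipeline on it end to end,
and writes a JSON results file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
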