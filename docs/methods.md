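# Methods

## Model and procedure

`orthoprep` treats an orthogroup as a mapping from a fixed species roster to
lists of protein sequences. Three statistics drive selection:

* **missing rate** `m = (#roster species with zero copies) / |roster|`,
  computed on the *original* membership, before any similarity-based
  rejection, so outcomes never depend on processing order;
* **maximum duplication number**: the largest per-species copy count (not
  the orthogroup's total gene count);
* **within-species pairwise identity** from a Needleman–Wunsch global
  alignment with affine gap penalties.

Selection order is missing rate → duplication → similarity, all inclusive
(`≤` / `≥`) comparisons by default; a `strict` flag switches to strict
inequalities. Thresholds default to `max_missing_rate = 0.05`,
`max_duplication_num = 6`, `min_similarity = 0.97`; a widely used lenient
setting is `(0.10, 10, 0.95)`. Relaxing any threshold can only grow the
pass set (monotonicity; property-tested).

### Similarity gate

Copies of one species are mergeable only when **every** pair reaches
`min_similarity` (complete linkage). Single linkage would let a deep
paralog chain into a consensus through an intermediate copy; a consensus is
only meaningful when no copy is an outlier. The policy for a failing
species is configurable: reject the whole orthogroup (default,
`drop_orthogroup`) or prune just that species (`drop_species`). The choice
is genuinely underdetermined by the procedure's description; the default is
the conservative one, and under `drop_species` the missing rate is *not*
re-tested (it was already evaluated on original membership).

### Consensus merge

Mergeable copies are star-aligned against the longest copy (ties broken by
lexicographically smallest gene id), which for copies ≥ 95–97% identical is
effectively exact and fully deterministic — a full MSA would add
nondeterminism without changing the votes. Per reference column:

* gaps do not vote; insertions relative to the reference are dropped;
* unanimous residue → kept (unanimous site);
* residue with a strict majority (> half of non-gap votes) → kept
  (merged site);
* no strict majority → the column is removed (divergent site trimmed).

Consequences worth knowing: with exactly two copies every disagreement is a
1–1 split and is trimmed, so the consensus is precisely the agreement
subsequence; merging is idempotent and order-free; consensus length +
trimmed sites = reference length.

### Alignment

Global alignment uses match +1, mismatch −1, gap open −5, gap extend −1
(a gap of length k costs `open + (k−1)·extend`; terminal gaps are
penalised). The scheme is deliberately simple — the gate is a ~97% identity
threshold, far from any regime where a substitution matrix would flip a
decision — and every score is configurable. The engine is Biopython's
C-implemented `PairwiseAligner`; among co-optimal alignments the engine's
first traceback is used, which is deterministic for fixed inputs. Scores
are verified in the test suite against an exhaustive enumeration of all
alignments for short pairs.

Identity's default denominator is the aligned span excluding terminal gap
overhangs: de novo transcripts are fragmentary, and penalising pure length
difference would reject true alleles. The shorter-sequence denominator
(CD-HIT's convention) is available as an option. Sequences are amino acids
throughout; residues are upper-cased on read and one trailing stop `*` is
stripped.

### Outputs

The built-in center-star locus aligner exists so the pipeline is
self-contained and deterministic at test time; for publication-grade
alignments point `aligner="external_mafft"` at a MAFFT binary. The
supermatrix is written as relaxed PHYLIP (binomial species names exceed
strict PHYLIP's 10 characters) with `-` as the missing-taxon fill, plus
`PROT, <og_id> = <start>-<end>` partition lines, 1-based inclusive. The
supermatrix holds amino acids; if a nucleotide model (e.g. GTRGAMMA) is
used downstream the user should back-translate or switch to a protein
model — the package does not hide this mismatch. Gene-tree aggregation
writes one newick per line in input order (`all.trees`); leaf labels
outside the roster warn but are kept.

## Synthetic data generator

`SynthScenario` states the world the tests run in: 24 species, 300-residue
proteins, per-site substitution probabilities of 0.05 between species, 0.01
between alleles/recent duplicates (the heterozygosity regime, ≈ 99%
identity), and 0.40 for deep paralogs (the ancient-WGD regime, ≈ 60%
identity — far below any sane threshold). Event probabilities per species
and orthogroup — heterozygosity 0.3, duplication burst 0.1 (adding 1–8
extra copies; the burst size cap exists so the duplication filter is
actually exercised), deep paralog 0.05, loss 0.05 — were chosen once as
plausible for a high-heterozygosity perennial plant transcriptome set and
are not tuned against test outcomes. Substitutions are uniform over the 19
alternative residues: identity thresholds, not phylogenetic realism, are
what is under test, so no empirical amino-acid rate matrix is used. No
indels are generated by default (an `indel_prob` option exercises gap
handling separately), which isolates the voting logic from alignment noise.

Ground-truth labels are computed analytically from the realized draws —
absences counted, copies counted, pairwise Hamming identities measured —
never by running the pipeline. Hamming identity equals alignment identity
here because sequences are equal-length and indel-free, and a gapless
alignment is strictly optimal under the default scores; with `indel_prob >
0` the generator therefore refuses to emit similarity labels rather than
approximate them.

What a green test does **not** establish: realism of the substitution
process, behaviour under allopolyploidy (homoeologous copies at
intermediate divergence are out of scope by design), fragmentary/partial
transcripts, or the quality of downstream tree inference — tree building
is external.

## Numerical and degenerate-input choices

* Threshold comparisons are inclusive; identical formulas are used in the
  pipeline and in the ground-truth oracle, so boundary cases (identity
  exactly at threshold) cannot diverge through floating-point rounding.
* A merged orthogroup left with fewer than two species is skipped as a
  locus, with a logged warning.
* A simulated orthogroup in which every species drew a loss (probability
  ≈ 0.05²⁴) keeps its first species so the orthogroup stays well-formed.
* Hard errors: missing sequences for listed gene IDs (named gene and
  orthogroup), duplicate orthogroup or FASTA IDs, empty tables or
  sequences, species names with whitespace at PHYLIP write time,
  unparseable newick (named file). A failed pipeline run removes the files
  it had written.
* Determinism: a scenario seed fixes dataset bytes; a fixed config fixes
  all output bytes (no timestamps anywhere).

## Known limitations

* Star alignment assumes near-identical copies; it is not a general MSA.
* Identity between co-optimal alignments is engine-tie-break dependent
  (deterministic, but not specified beyond "an optimal alignment").
* Amino-acid only; no codon-aware merging or haplotype phasing.
* The `drop_species` policy can silently thin taxa from individual loci;
  inspect `merge_provenance.tsv` and the filter report when using it.
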