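"""Collect per-locus gene trees into one multi-newick file (all.trees).

Coalescent species-tree methods (ASTRAL and relatives) take one file with
one gene tree per line; this example writes three toy gene trees and
aggregates them, validating leaf labels against the species roster.
"""

import tempfile
from pathlib import Path

from orthoprep import SpeciesRoster, aggregate_gene_trees

roster = SpeciesRoster(("sp01", "sp02", "sp03", "sp04"))
newicks = [
    "((sp01:1,sp02:1):1,(sp03:1,sp04:1):1);",
    "((sp01:1,sp03:1):1,(sp02:1,sp04:1):1);",
    "((sp01:1,sp04:1):1,(sp02:1,sp03:1):1);",
]

with tempfile.TemporaryDirectory() as tmp:
    paths = []
    for i, nwk in enumerate(newicks):
        p = Path(tmp) / f"locus{i}.treefile"
        p.write_text(nwk + "\n")
        paths.append(p)
    out = Path(tmp) / "all.trees"
    trees = aggregate_gene_trees(paths, roster, out)
    print(f"aggregated {len(trees.trees)} gene trees into {out.name}:")
    print(out.read_text(), end="")
# The three topologies disagree deliberately — exactly the gene-tree
# discordance a coalescent summary method is designed to average over.
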