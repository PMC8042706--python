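#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emits the species tree, gene trees, replicate TPM expression panel,
promoter/TE/bound-TFBS tables, tissue atlas, annotations and the planted
ground truth under results/run/cohort/.
"""

import pandas as pd

from _common import run_through

d = run_through("simulate")
trees = pd.read_csv(d / "cohort" / "truth_trees.tsv", sep="\t")
genes = pd.read_csv(d / "cohort" / "truth_genes.tsv", sep="\t")
print(f"cohort written to {d / 'cohort'}")
print(trees.groupby(["kind", "complete"]).size().rename("n_trees"))
print(f"{len(genes)} genes across {genes['species'].nunique()} species")
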