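#!/usr/bin/env python
"""Apply the gene-tree topology/expression filters and the two-stage TMM
normalization (within species, then between species anchored on
singleton orthogroups), ending on the log2(TPM + 0.01) scale.
"""

import pandas as pd

from _common import run_through

d = run_through("normalize")
classes = pd.read_csv(d / "tree_classes.tsv", sep="\t")
print("gene-tree filter funnel:")
print(classes.groupby(["status", "reason"], dropna=False).size().rename("n"))
fac = pd.read_csv(d / "norm_factors.tsv", sep="\t")
between = fac[fac["stage"] == "between"].drop_duplicates("species")
print("\nbetween-species TMM factors:")
print(between[["species", "factor"]].to_string(index=False))
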