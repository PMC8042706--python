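#!/usr/bin/env python
"""Association tests tying regulatory divergence to genomic context:
paired Wilcoxon on TE load, pathway enrichment per shift category,
protein-complex label permutation, and the per-block gene-loss
(fractionation-bias) binomial test.  Also writes the final report table.
"""

import pandas as pd

from _common import run_through

d = run_through("report")
assoc = pd.read_csv(d / "assoc_tests.tsv", sep="\t")
print(assoc.to_string(index=False))
enr = d / "pathway_enrichment.tsv"
if enr.exists():
    e = pd.read_csv(enr, sep="\t")
    top = e.sort_values("p").groupby("category").head(2)
    print("\ntop enriched pathways per shift category:")
    print(top[["category", "term", "k", "K", "p"]].to_string(index=False))
print(f"\nfull report: {d / 'report.tsv'}")
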