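#!/usr/bin/env python
"""Combine per-copy shift calls into ohnolog pair categories and compute
pair asymmetry and tissue concordance against the tissue atlas.
"""

import pandas as pd

from _common import run_through

d = run_through("classify")
pairs = pd.read_csv(d / "pairs.tsv", sep="\t")
ok = pairs[pairs["excluded"].isna() | (pairs["excluded"] == "")]
print(f"{len(ok)} classified pairs ({len(pairs) - len(ok)} excluded)")
summary = ok.groupby("category").agg(n=("orthogroup", "size"),
                                     median_asym=("asymmetry", "median"))
print(summary)
dc = ok[(ok["category"] == "down+cons") & (ok["n_tissues_lower"] >= 0)]
if len(dc):
    frac = (dc["n_tissues_lower"] > dc["n_tissues_higher"]).mean()
    print(f"down-shifted copy lower in most other tissues: {frac:.0%} of {len(dc)} pairs")
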