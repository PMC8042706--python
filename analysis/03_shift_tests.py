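#!/usr/bin/env python
"""Run the two-optima OU shift test per duplicate clade.

For each accepted gene tree, each salmonid-role clade is tested
separately (the other duplicate clade removed) against the shared
outgroup expression; the LRT is referred to chi-squared with 1 df.
Prints the fraction of trees with a significant shift per tree class —
the synthetic analogue of the study's singleton-vs-ohnolog comparison.
"""

import pandas as pd

from _common import run_through

d = run_through("shift_test")
calls = pd.read_csv(d / "shift_calls.tsv", sep="\t")
tested = calls[calls["status"] == "tested"]
print(f"{len(tested)} clade tests on {tested['orthogroup'].nunique()} trees")
for status, sub in tested.groupby("tree_status"):
    by_tree = sub.groupby("orthogroup")["significant"].any()
    up = (sub["direction"] == "up").sum()
    down = (sub["direction"] == "down").sum()
    print(f"{status}: {by_tree.mean():.2%} of {by_tree.size} trees shifted "
          f"({up} clades up, {down} down)")
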