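#!/usr/bin/env python
"""Promoter TE load, bound-TFBS counting, and the liver-specific TF
network over up+cons pairs with a tissue-specific up-shifted copy.
"""

import pandas as pd

from _common import run_through

d = run_through("context")
te = pd.read_csv(d / "te_paired.tsv", sep="\t")
if len(te):
    frac = (te["te_down"] > te["te_cons"]).mean()
    print(f"TE promoter load higher in the down-shifted copy for "
          f"{frac:.0%} of {len(te)} down+cons pairs")
if (d / "network_nodes.tsv").exists():
    nodes = pd.read_csv(d / "network_nodes.tsv", sep="\t")
    edges = pd.read_csv(d / "network_edges.tsv", sep="\t")
    print(f"liver network: {len(nodes)} TFs, {len(edges)} TF->gene edges")
    print(nodes[["tf", "n_up_targets", "n_cons_targets", "up_bias"]]
          .head(9).to_string(index=False))
else:
    print("liver network empty (no tissue-specific up+cons pairs at this scale)")
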