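# Study configuration for the numbered analysis scripts.  The simulation
# block mirrors the study design: 4 WGD-descendant (salmonid-role)
# species + 3 outgroups, 4 replicates each, ~65% of orthogroups carrying
# a retained duplicate pair, shifts planted with a strong down bias.
sim:
  seed: 1
  n_species_ingroup: 4
  n_outgroups: 3
  replicates_per_species: 4
  n_singleton_trees: 120
  n_ohnolog_trees: 220
  frac_partial: 0.25
chi2_quantile: 0.95
enrichment_alpha: 0.05
tau_min: 0.6
liver_fraction: 0.9
n_perm: 10000
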