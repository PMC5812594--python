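# Default sahscan configuration.
#
# Matrix paths are resolved relative to this file; leave them unset to use the
# matrices bundled with the package.
matrix_i3: scoring_matrix_i_3.csv
matrix_i4: scoring_matrix_i_4.csv

# Sliding-window sizes (in residues) used for per-residue SAH-scores.  Each
# window also sets the minimum length of an SAH-domain it can detect.
window_sizes: [14, 21, 28, 49]

# Minimum normalized SAH-score for a residue to be part of an SAH-domain.
residue_cutoff: 0.25

# Minimum SAH-domain-score per detection window.
domain_score_cutoffs:
  14: 0.35
  21: 0.32
  28: 0.29
  49: 0.25

# Sub-window (residues) over which the SAH-domain-score (max of sub-window
# mean SAH-scores) is computed.
domain_subwindow: 14

# Fraction of residues inside a domain allowed to score at or below
# residue_cutoff (keeps long domains from being split by single dips).
below_cutoff_tolerance: 0.20

# Network scores: per matching residue triple in i,i+3,i+6 / i,i+3,i+7 /
# i,i+4,i+7 / i,i+4,i+8 spacing.  Alternating oppositely charged triples
# stabilize; hydrophobic triples (potential coiled-coil seams) destabilize.
network_score_charged: 0.25
network_score_hydrophobic: -0.25

# Minimum terminal overlap (residues) for two unique SAH-domains of the same
# gene to be flagged as overlapping.
min_overlap_aa: 5
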