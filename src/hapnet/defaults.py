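"""Published default parameters, collected in one place.

Every constant here is surfaced in CLI defaults and asserted by the
configuration test suite; change with care.
"""

#: Valid discrete copy-number calls (double deletion .. multi-copy gain).
GISTIC_DOMAIN = (-2, -1, 0, 1, 2)

#: Gene dose-sensitivity weights: no evidence, yeast-orthologue evidence,
#: mouse-orthologue evidence.
GDS_WEIGHTS = (1, 2, 3)
GDS_NONE = 1
GDS_YEAST = 2
GDS_MOUSE = 3

#: Number of shuffled control cohorts per run.
N_REPLICATES = 1000

#: Significance level for the direction call.
ALPHA = 0.05

#: Bonferroni comparison-count presets: the full human pathway universe
#: and the focal six-pathway x 21-cohort grid.
PAN_PATHWAY_COMPARISONS = 187
FOCAL_GRID_COMPARISONS = 126

#: Cohort-summary visualization cuts: SCNA prevalence required to draw a
#: styled PPI edge, and the mutation frequency that turns styling green.
SCNA_EDGE_CUT = 1.0 / 3.0
MUTATION_CUT = 0.10

#: Top-table sizes: per-pathway gene summary and the QC benchmarking table.
TOP_SUMMARY_K = 5
TOP_QC_K = 10

#: Default log2-ratio discretization cuts (t_del2, t_del1, t_amp1, t_amp2);
#: a value exactly at a cut is called altered (boundaries assigned outward).
LOG2_CUTS = (-1.3, -0.3, 0.3, 1.3)
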