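# Default workflow configuration. Every field is optional; values shown are
# the built-in defaults. The `microarray` block takes PlantedDesign fields,
# `counts` takes CountDesign fields.
#
# Dispersion convention for counts: Var = mu + dispersion * mu^2
# (dispersion -> 0 approaches Poisson; 0 itself is rejected).
seed: 42
out_dir: out
network_edges: null        # packaged curated TP53-miRNA network when null
clamp:
  TP53: down
overrides:
  - [miR-125b, down, "AKT1 represses miR-125b when TP53 is lost"]
novel_genes: [MEIS1, LDOC1, AGTR1, BAK1, TYMS, DTL]
microarray: {}             # e.g. {noise_sd: 1.0, effect_log2: 2.0}
counts: {}                 # e.g. {n_cases: 22, n_controls: 4, dispersion: 0.05}
qpcr_true_rq: {}           # gene -> relative quantity; derived from design if empty
qpcr_ct_noise_sd: 0.25
meta_weighted: false
meta_prescreen: false
kmeans_k: 2
min_cluster_frac: 0.1
stability_enabled: true
n_repeats: 100
n_features: 20
train_frac: 0.3333333333333333
cv_threshold: 0.001
pseudocount: 1.0
q_threshold: 0.05
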