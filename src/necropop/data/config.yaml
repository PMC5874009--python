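# Default analysis configuration reproducing the reference thresholds.
local_range_bounds: null        # derive from bone baseline + faunal interval
faunal_range: [0.7088, 0.7090]  # published pig-enamel baseline interval
baseline_round_decimals: 4
mobility_delta: 0.0001          # local baseline 2-sigma
correlation_r_threshold: 0.5
min_trait_observations: 5
vif_threshold: 5.0
n_permutations: 9999
rf_n_trees: 500
rf_max_features: sqrt
rf_importance_cutoff: 0.1
seed: 0
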