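"""Detect percept-related evoked-potential differences site by site.

Generates a synthetic block in which 2 of 8 sites carry an additive AEP
difference 60-130 ms after tone-B onset, preprocesses it into labeled
600 ms triplet-locked trials, and runs the cluster-level-mass permutation
test with BH-FDR across sites.
"""

import bistream as bs

cfg = bs.SyntheticConfig(
    n_sites=8, seed=42, effect_sites=(0, 3), effect_amp=25.0,
    percept_mean_dur=(15.0, 18.0),
)
synth = bs.simulate_block(cfg, bs.TripletStimulus(n_triplets=200))  # 2 min
epochs = bs.preprocess_block(synth.block, rt=0.6, n_discard=5)
print(f"{epochs.n_trials} trials; labeled 1-stream/2-stream: "
      f"{(epochs.labels == 1).sum()}/{(epochs.labels == 2).sum()}")

site_map = bs.aep_cluster_test(epochs, n_perm=2000, q=0.01, seed=7)
cols = ["site_id", "area", "p_site", "q_reject",
        "best_cluster_start_ms", "best_cluster_end_ms"]
print(site_map.table[cols].to_string(index=False))
print(f"ground-truth effect sites (0-based): {synth.effect_sites}")
print("q_reject marks sites surviving FDR; the best-cluster window should "
      "bracket 210-280 ms (60-130 ms after the tone-B onset at 150 ms).")
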