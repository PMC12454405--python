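"""Vegetation indices and random-forest feature selection.

Computes the 15-index library for every observation, ranks the indices by
random-forest importance for LAI, and keeps the top six.  NIR-bearing
indices dominate because canopy density expresses itself most strongly in
the red/NIR contrast.
"""

import ricelai

obs = ricelai.generate_dataset(ricelai.SimulationConfig(seed=1))
table = ricelai.build_feature_table(obs)
print(f"feature table: {len(table)} rows x {len(ricelai.VI_NAMES)} indices")

ranking = ricelai.rank_importance(table, seed=1)
print("\nimportance ranking (top 8):")
for name, score in ranking.entries[:8]:
    print(f"  {name:6s} {score:.3f}")

selected = ricelai.select_top_k(ranking, 6)
print(f"\nselected for the sequence models: {selected}")
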