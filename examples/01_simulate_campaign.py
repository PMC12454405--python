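"""Simulate a season-long multispectral campaign over a rice variety trial.

Generates the default design -- 30 plots observed at 9 acquisition stages --
and prints the LAI trajectory and band reflectance of one plot.  LAI rises
to a mid-season peak and declines toward maturity; NIR reflectance tracks
canopy density upward while red reflectance darkens as leaves cover soil.
"""

import ricelai

obs = ricelai.generate_dataset(ricelai.SimulationConfig(seed=1))
print(f"campaign: {obs['plot_id'].nunique()} plots x "
      f"{obs['stage_index'].nunique()} stages = {len(obs)} observations\n")

plot = obs[obs.plot_id == "P01"]
print("plot P01 trajectory:")
print(plot[["date_label", "lai", "b668", "b842"]].round(3).to_string(index=False))
print("\nlai peaks mid-season; red (b668) falls and NIR (b842) rises with canopy density.")
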