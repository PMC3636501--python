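"""Simulate exploration of the torus and the dentate-gyrus input it evokes.

Generates a persistent random walk (2.5 cm per 125 ms theta step), samples a
sparse multi-field DG population, and prints summary statistics of the
trajectory coverage and of the DG rate map.
"""

import numpy as np

import ca3metric as cm

env = cm.TorusEnvironment()  # 1 m x 1 m, 8 x 8 analysis grid
traj = cm.generate_trajectory(env, n_steps=10_000, seed=1)
occupancy = np.bincount(traj.bins(), minlength=env.n_bins)

print(f"trajectory: {len(traj)} steps of {traj.step_length*100:.1f} cm")
print(f"bins visited: {np.count_nonzero(occupancy)}/{env.n_bins}, "
      f"occupancy min/median/max = {occupancy.min()}/{int(np.median(occupancy))}/{occupancy.max()}")
# 10,000 steps (~20 virtual minutes) suffice to cover all 64 bins many times

pop = cm.sample_dg_population(n_dg=4_500, q=1.7, p_dg=0.033, seed=2, env=env)
Q = np.array([c.Q for c in pop.cells if c.active])
rates = cm.dg_rates(pop, traj.positions[:1000], env)
print(f"DG: {pop.n_cells} granule cells, {len(pop.active_ids)} active "
      f"({100*len(pop.active_ids)/pop.n_cells:.1f}%), "
      f"mean fields per active cell {Q.mean():.2f} (Poisson mean 1.7)")
print(f"population rate vector: mean {rates.mean():.4f}, "
      f"max {rates.max():.2f} (units of the field peak rate)")
# most cells are silent everywhere; active cells fire only near their fields,
# so the position is encoded by which few granule cells are active
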