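"""Self-organise the CA3 map: Hebbian learning on the recurrent collaterals.

Builds a small CA3 network, runs the learning session along an exploratory
trajectory, and shows what the trace-based rule did to the recurrent weights:
units with overlapping place fields end up coupled.
"""

import numpy as np

import ca3metric as cm

env = cm.TorusEnvironment()
pop = cm.sample_dg_population(1_000, seed=2, env=env)
net = cm.default_network(n_dg=1_000, n_ca3=100, c_mf=50, c_rc=60, seed=3)

traj = cm.generate_trajectory(env, n_steps=5_000, seed=4)
learned = cm.run_learning_phase(
    net, pop, traj, cm.LearningConfig(gamma=0.01, n_steps=5_000, tau=14), seed=5
)

print(f"RC weights: {np.count_nonzero(learned.j_rc)} synapses, "
      f"row sums normalised to {learned.j_rc.sum(axis=1).mean():.6f}")

# activity at one position: sparsity and mean rate are controlled exactly
beta = cm.dg_rates(pop, np.array([0.5, 0.5]), env)
state = cm.ca3_activity(learned, beta, seed=6)
print(f"activity at (0.5, 0.5): sparsity {state.sparsity:.3f} (target 0.1), "
      f"mean rate {state.mean_rate:.3f} (target 0.1), "
      f"{np.count_nonzero(state.rates)} of {learned.n_ca3} units firing")

# learned weights are symmetric in tendency: if i drives j, j tends to drive i
both = net.conn_rc.matrix.astype(bool) & net.conn_rc.matrix.T.astype(bool)
iu = np.triu_indices(learned.n_ca3, k=1)
sel = both[iu]
r = np.corrcoef(learned.j_rc[iu][sel], learned.j_rc.T[iu][sel])[0, 1]
print(f"corr(J_ij, J_ji) over reciprocal synapse pairs: {r:.2f} "
      "(positive: co-tuned units wire together in both directions)")
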