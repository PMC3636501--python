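"""Recover the global topology of the map: Sammon embedding of the templates.

Embeds the 64 full-population spatial templates in 3-D from their pairwise
correlation distances and reports the Sammon stress and a torus-adjacency
check: neighbouring bins of the environment should stay close in the
embedding if the map preserves the global metric.
"""

import numpy as np

import ca3metric as cm
from ca3metric import correlation_distance_matrix, sammon_map

env = cm.TorusEnvironment()
pop = cm.sample_dg_population(1_000, seed=2, env=env)
net = cm.default_network(1_000, 100, c_mf=50, c_rc=60, seed=3)
traj = cm.generate_trajectory(env, 5_000, seed=4)
net = cm.run_learning_phase(net, pop, traj, cm.LearningConfig(n_steps=5_000), seed=5)
ttraj = cm.generate_trajectory(env, 20_000, seed=6)
templates = cm.build_templates(net, pop, ttraj, np.arange(net.n_ca3), env, seed=7)

D = correlation_distance_matrix(templates)
emb = sammon_map(D, dim=3, n_iter=500, seed=8)
print(f"Sammon stress: {emb.stress:.4f} (0 = distances perfectly reproduced)")

L = env.L
adj, far = [], []
for s in range(env.n_bins):
    i, j = divmod(s, L)
    adj.append(np.linalg.norm(emb.coords[s] - emb.coords[i * L + (j + 1) % L]))
    adj.append(np.linalg.norm(emb.coords[s] - emb.coords[((i + 1) % L) * L + j]))
    opp = ((i + L // 2) % L) * L + (j + L // 2) % L
    far.append(np.linalg.norm(emb.coords[s] - emb.coords[opp]))
print(f"mean embedded distance: adjacent bins {np.mean(adj):.3f}, "
      f"maximally separated bins {np.mean(far):.3f}")
# adjacent << separated: the embedding is a (crumpled) torus, i.e. the map
# preserves the global structure of the environment
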