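"""Decode position from CA3 activity and build the confusion matrices.

Runs a template-building phase and a test phase on a reduced network, decodes
with unit samples of two sizes, and prints percent correct, the mutual
information of the full confusion matrix, and of its translation-averaged
reduced form.
"""

import numpy as np

import ca3metric as cm
from ca3metric import (
    build_templates,
    mutual_information,
    percent_correct,
    reduce_confusion,
    reduced_information,
    run_test_phase,
)

env = cm.TorusEnvironment()
pop = cm.sample_dg_population(1_000, seed=2, env=env)
net = cm.default_network(1_000, 100, c_mf=50, c_rc=60, seed=3)
traj = cm.generate_trajectory(env, 5_000, seed=4)
net = cm.run_learning_phase(net, pop, traj, cm.LearningConfig(n_steps=5_000), seed=5)

ttraj = cm.generate_trajectory(env, 20_000, seed=6)
templates = build_templates(net, pop, ttraj, np.arange(net.n_ca3), env, seed=7)

test_traj = cm.generate_trajectory(env, 20_000, seed=8)
samples = [np.arange(8), np.arange(64)]
confusions = run_test_phase(
    net, pop, test_traj, templates, samples, dg_mode="on", env=env, seed=9
)

for sample, C in zip(samples, confusions):
    R = reduce_confusion(C, env)
    print(f"sample of {len(sample):3d} units: "
          f"percent correct {percent_correct(C):.3f} (chance {1/env.n_bins:.3f}), "
          f"I_full {mutual_information(C):.2f} bits, "
          f"I_reduced {reduced_information(R):.2f} bits, "
          f"central mass {R.correct_mass:.3f}")
# the reduced (translation-averaged) matrix always carries less information
# than the full one: the difference measures location-specific error structure
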