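"""Templates, nearest-template decoding, confusion and reduced matrices."""

import numpy as np
import pytest

import ca3metric as cm
from ca3metric.decoding import (
    ConfusionMatrix,
    TemplateSet,
    decode_step,
    percent_correct,
    reduce_confusion,
    templates_from_rates,
)


def make_templates(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return TemplateSet(
        templates=matrix,
        sample=np.arange(matrix.shape[1]),
        occupancy=np.ones(matrix.shape[0], dtype=int),
    )


class TestTemplates:
    def test_constant_rates_give_identical_rows(self, env):
        rates = np.tile([0.3, 0.1, 0.5], (env.n_bins, 1))
        bins = np.arange(env.n_bins)
        ts = templates_from_rates(rates, bins, np.arange(3), env.n_bins)
        assert np.allclose(ts.templates, [0.3, 0.1, 0.5])

    def test_single_visit_bins_keep_raw_vectors(self, env):
        rng = np.random.default_rng(0)
        rates = rng.random((env.n_bins, 5))
        bins = rng.permutation(env.n_bins)
        ts = templates_from_rates(rates, bins, np.arange(5), env.n_bins)
        np.testing.assert_allclose(ts.templates[bins], rates)

    def test_two_visits_average(self, env):
        v1, v2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        rates = np.vstack([v1, v2] + [np.ones(2)] * (env.n_bins - 1))
        bins = np.concatenate([[0, 0], np.arange(1, env.n_bins)])
        ts = templates_from_rates(rates, bins, np.arange(2), env.n_bins)
        np.testing.assert_allclose(ts.templates[0], (v1 + v2) / 2)

    def test_unvisited_bin_raises_listing_bins(self, env):
        rates = np.ones((10, 2))
        bins = np.zeros(10, dtype=int)  # only bin 0 visited
        with pytest.raises(ValueError, match="1"):
            templates_from_rates(rates, bins, np.arange(2), env.n_bins)

    def test_subset_slices_columns(self, env):
        rng = np.random.default_rng(1)
        full = TemplateSet(
            templates=rng.random((env.n_bins, 10)),
            sample=np.arange(10),
            occupancy=np.ones(env.n_bins, dtype=int),
        )
        sub = full.subset(np.array([2, 7]))
        np.testing.assert_allclose(sub.templates, full.templates[:, [2, 7]])


class TestDecodeStep:
    def test_exact_template_decodes_to_its_bin(self):
        rng = np.random.default_rng(2)
        ts = make_templates(rng.random((64, 4)))
        assert decode_step(ts.templates[17], ts) == 17

    def test_tie_broken_to_lowest_bin(self):
        t = np.zeros((10, 1))
        t[3], t[7] = 1.0, -1.0  # query 0 is equidistant from rows 3 and 7
        ts = make_templates(t)
        # rows other than 3 and 7 are at distance 0 -> they win; use distinct rows
        t = np.full((10, 1), 5.0)
        t[3], t[7] = 1.0, -1.0
        ts = make_templates(t)
        assert decode_step(np.array([0.0]), ts) == 3

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        ts = make_templates(rng.random((64, 8)))
        for _ in range(20):
            v = rng.random(8)
            brute = min(
                range(64), key=lambda b: np.sum((ts.templates[b] - v) ** 2)
            )
            assert decode_step(v, ts) == brute


class TestConfusionReduction:
    def test_identity_confusion_reduces_to_origin_delta(self, env):
        C = ConfusionMatrix(counts=np.eye(env.n_bins, dtype=np.int64) * 5)
        R = reduce_confusion(C, env)
        assert R.correct_mass == pytest.approx(1.0)
        assert R.probs.sum() == pytest.approx(1.0)

    def test_translation_invariant_confusion_reproduces_kernel(self, env):
        # build a confusion matrix whose every row is the same displacement
        # kernel; the reduced matrix must equal that kernel
        L = env.L
        rng = np.random.default_rng(4)
        kernel = rng.integers(1, 20, size=(L, L))
        counts = np.zeros((L * L, L * L), dtype=np.int64)
        for s in range(L * L):
            si, sj = divmod(s, L)
            for di in range(L):
                for dj in range(L):
                    r = ((si + di) % L) * L + (sj + dj) % L
                    counts[s, r] = kernel[di, dj]
        R = reduce_confusion(ConfusionMatrix(counts=counts), env)
        expected = np.roll(kernel / kernel.sum(), (L // 2, L // 2), axis=(0, 1))
        np.testing.assert_allclose(R.probs, expected, atol=1e-12)

    def test_matches_brute_force_displacement_histogram(self, env):
        L = env.L
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(L * L, L * L)).astype(np.int64)
        R = reduce_confusion(ConfusionMatrix(counts=counts), env)
        brute = np.zeros((L, L))
        for s in range(L * L):
            for r in range(L * L):
                di = ((r // L) - (s // L)) % L
                dj = ((r % L) - (s % L)) % L
                brute[(di + L // 2) % L, (dj + L // 2) % L] += counts[s, r]
        brute /= brute.sum()
        np.testing.assert_allclose(R.probs, brute, atol=1e-12)


class TestPercentCorrect:
    def test_identity_is_one(self):
        C = ConfusionMatrix(counts=np.eye(8, dtype=np.int64) * 3)
        assert percent_correct(C) == pytest.approx(1.0)

    def test_uniform_rows_give_chance(self):
        C = ConfusionMatrix(counts=np.ones((16, 16), dtype=np.int64))
        assert percent_correct(C) == pytest.approx(1 / 16)

    def test_two_bin_hand_value(self):
        counts = np.array([[8, 2], [4, 6]], dtype=np.int64)
        assert percent_correct(ConfusionMatrix(counts=counts)) == pytest.approx(0.7)


class TestTestPhase:
    def test_injective_bin_code_yields_identity_confusion(self, env, small_system):
        # when rates are a deterministic injective function of the bin and
        # templates are exact, decoding is perfect
        pop, net = small_system
        quiet = cm.CA3Network(
            net.conn_mf, net.conn_rc, net.j_mf, net.j_rc, noise_sd=0.0
        )
        L = env.L
        centers = np.array(
            [((i + 0.5) / L, (j + 0.5) / L) for i in range(L) for j in range(L)]
        )
        bins = cm.bin_index(centers, env)
        traj = cm.Trajectory(
            positions=centers, headings=np.zeros(len(centers)), env=env
        )
        rates = cm.simulate_rates(quiet, pop, traj, dg_mode="on")
        ts = templates_from_rates(rates, bins, np.arange(quiet.n_ca3), env.n_bins)
        # rates at bin centres must be pairwise distinct for injectivity
        assert len(np.unique(rates.round(12), axis=0)) == env.n_bins
        confs = cm.run_test_phase(
            quiet, pop, traj, ts, [np.arange(quiet.n_ca3)], dg_mode="on", env=env
        )
        assert np.array_equal(
            confs[0].counts, np.eye(env.n_bins, dtype=np.int64)
        )

    def test_counts_conserve_test_steps(self, env, small_system):
        pop, net = small_system
        traj_train = cm.generate_trajectory(env, 3000, seed=10)
        ts = cm.build_templates(
            net, pop, traj_train, np.arange(net.n_ca3), env, seed=11
        )
        traj_test = cm.generate_trajectory(env, 500, seed=12)
        confs = cm.run_test_phase(
            net, pop, traj_test, ts, [np.arange(4), np.arange(16)],
            dg_mode="on", env=env, seed=13,
        )
        for c in confs:
            assert c.counts.sum() == 500

    def test_reproducible_given_seed(self, env, small_system):
        pop, net = small_system
        traj_train = cm.generate_trajectory(env, 3000, seed=10)
        ts = cm.build_templates(
            net, pop, traj_train, np.arange(net.n_ca3), env, seed=11
        )
        traj_test = cm.generate_trajectory(env, 300, seed=14)
        args = (net, pop, traj_test, ts, [np.arange(8)])
        a = cm.run_test_phase(*args, dg_mode="on", env=env, seed=15)[0].counts
        b = cm.run_test_phase(*args, dg_mode="on", env=env, seed=15)[0].counts
        assert np.array_equal(a, b)

    def test_unstructured_network_decodes_at_chance_when_dg_off(self, env):
        # uniform RC weights, no learning: reverberated activity carries no
        # positional information, so DG-off decoding sits near chance
        pop = cm.sample_dg_population(500, seed=20, env=env)
        net = cm.default_network(500, 80, c_mf=50, c_rc=48, seed=21)
        traj_train = cm.generate_trajectory(env, 4000, seed=22)
        ts = cm.build_templates(
            net, pop, traj_train, np.arange(net.n_ca3), env, dg_mode="off", seed=23
        )
        traj_test = cm.generate_trajectory(env, 2000, seed=24)
        confs = cm.run_test_phase(
            net, pop, traj_test, ts, [np.arange(net.n_ca3)],
            dg_mode="off", env=env, seed=25,
        )
        f = percent_correct(confs[0])
        chance = 1 / env.n_bins
        assert f < 5 * chance
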