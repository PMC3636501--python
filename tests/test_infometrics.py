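"""Mutual information, bounds, sigmoid/bump fits, reference curves, chi."""

import numpy as np
import pytest

import ca3metric as cm
from ca3metric.decoding import ConfusionMatrix, ReducedMatrix
from ca3metric.infometrics import (
    InfoCurve,
    _centered_r2,
    _plugin_mi,
    fit_gaussian_bump,
    fit_sigmoid,
    info_max_bias,
    info_max_unbiased,
    info_min,
    metric_content,
    mutual_information,
    reduced_information,
    reference_information,
    solve_metric_resolution,
)


def conf_from_rows(rows, prior=None):
    rows = np.asarray(rows, dtype=float)
    S = rows.shape[0]
    prior = np.full(S, 1 / S) if prior is None else np.asarray(prior)
    counts = np.round(rows * prior[:, None] * 1_000_000).astype(np.int64)
    return ConfusionMatrix(counts=counts)


class TestMutualInformation:
    def test_identity_matrix_gives_log2_s(self):
        C = ConfusionMatrix(counts=np.eye(64, dtype=np.int64) * 100)
        assert mutual_information(C) == pytest.approx(6.0)

    def test_identical_rows_give_zero(self):
        C = ConfusionMatrix(counts=np.full((16, 16), 7, dtype=np.int64))
        assert mutual_information(C) == pytest.approx(0.0, abs=1e-12)

    def test_binary_symmetric_channel_hand_value(self):
        # 2x2 rows ((3/4, 1/4), (1/4, 3/4)), uniform prior: I = 1 - H2(3/4)
        C = conf_from_rows([[0.75, 0.25], [0.25, 0.75]])
        expected = 1 + 0.75 * np.log2(0.75) + 0.25 * np.log2(0.25)
        assert expected == pytest.approx(0.18872, abs=1e-5)
        assert mutual_information(C) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_log2_s(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(0, 50, size=(16, 16)).astype(np.int64)
            mi = mutual_information(ConfusionMatrix(counts=counts))
            assert 0.0 <= mi <= 4.0

    def test_reduced_information_of_uniform_is_zero(self):
        R = ReducedMatrix(probs=np.full((8, 8), 1 / 64))
        assert reduced_information(R) == pytest.approx(0.0, abs=1e-12)

    def test_reduced_information_of_delta_is_log2_s(self):
        probs = np.zeros((8, 8))
        probs[4, 4] = 1.0
        assert reduced_information(ReducedMatrix(probs=probs)) == pytest.approx(6.0)


class TestBounds:
    def test_perfect_decoding_limits(self):
        assert info_min(64, 1.0) == pytest.approx(6.0)
        assert info_max_bias(64, 1.0) == pytest.approx(6.0)
        assert info_max_unbiased(64, 1.0) == pytest.approx(6.0)

    def test_chance_level_floor_is_zero(self):
        assert info_min(64, 1 / 64) == pytest.approx(0.0, abs=1e-12)
        assert info_max_unbiased(64, 1 / 64) == pytest.approx(0.0, abs=1e-12)

    def test_hand_values(self):
        # S=4, f=0.5: 2 + 0.5 log2(0.5) + 0.5 log2(0.5) - 0.5 log2(3)
        assert info_min(4, 0.5) == pytest.approx(2 - 1 - 0.5 * np.log2(3))
        assert info_min(4, 0.5) == pytest.approx(0.20752, abs=1e-5)
        assert info_max_unbiased(64, 0.5) == pytest.approx(5.0)

    def test_ordering_of_bounds(self):
        for f in np.linspace(0.02, 1.0, 40):
            assert info_min(64, f) <= info_max_bias(64, f) + 1e-12
            # the unbiased construction (1/f stimuli chosen equally often)
            # only exists for f <= 1/2; above that its closed form exceeds
            # the biased ceiling and the comparison is meaningless
            if 1 / 64 <= f <= 0.5:
                assert info_max_unbiased(64, f) <= info_max_bias(64, f) + 1e-12

    def test_metric_content_endpoints_and_midpoint(self):
        assert metric_content(1.0, 1.0, 3.0) == pytest.approx(0.0)
        assert metric_content(3.0, 1.0, 3.0) == pytest.approx(1.0)
        assert metric_content(2.0, 1.0, 3.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            metric_content(1.0, 2.0, 2.0)


class TestSigmoidFit:
    def test_recovers_exact_parameters(self):
        sizes = np.array([1, 2, 4, 8, 16, 32, 64, 128, 256], dtype=float)
        truth = (8.0, 10.0, 1.5)
        vals = truth[0] / (1 + (truth[1] / sizes) ** truth[2])
        fit = fit_sigmoid(sizes, vals, form="info")
        assert np.allclose(fit.params, truth, rtol=1e-6)
        assert fit.predict(truth[1]) == pytest.approx(truth[0] / 2, rel=1e-6)

    def test_pcor_form_recovers_parameters(self):
        sizes = np.array([1, 2, 4, 8, 16, 32, 64, 128], dtype=float)
        lo, hi, n0, b = 0.02, 0.8, 12.0, 1.2
        vals = lo + (hi - lo) / (1 + (n0 / sizes) ** b)
        fit = fit_sigmoid(sizes, vals, form="pcor")
        assert np.allclose(fit.params, (lo, hi, n0, b), rtol=1e-5)

    def test_constant_data_flagged_degenerate(self):
        fit = fit_sigmoid([1, 2, 4, 8], [0.5, 0.5, 0.5, 0.5], form="info")
        assert fit.degenerate
        assert fit.params[-1] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid([1, 2, 4], [0.1, 0.2, 0.3])


class TestBumpFit:
    def make_reduced(self, a, w, L=8):
        r2 = _centered_r2(L)
        bump = np.exp(-r2 / (2 * w * w))
        bump = a * bump / bump.sum() * bump.sum()  # volume handled below
        A = a / np.exp(-r2 / (2 * w * w)).sum()
        probs = A * np.exp(-r2 / (2 * w * w)) + (1 - a) / (L * L)
        return ReducedMatrix(probs=probs / probs.sum())

    @pytest.mark.parametrize("a,w", [(0.8, 1.2), (0.5, 0.8), (0.3, 1.8)])
    def test_parameter_recovery_within_5_percent(self, a, w):
        fit = fit_gaussian_bump(self.make_reduced(a, w))
        assert fit.w == pytest.approx(w, rel=0.05)
        assert fit.a == pytest.approx(a, rel=0.05)
        assert fit.baseline == pytest.approx((1 - a) / 64, rel=0.05)

    def test_delta_flags_sub_resolution(self):
        probs = np.zeros((8, 8))
        probs[4, 4] = 1.0
        fit = fit_gaussian_bump(ReducedMatrix(probs=probs))
        assert fit.sub_resolution
        assert fit.a == pytest.approx(fit.pc, rel=0.05)

    def test_uniform_matrix_has_no_bump(self):
        fit = fit_gaussian_bump(ReducedMatrix(probs=np.full((8, 8), 1 / 64)))
        assert fit.a == pytest.approx(0.0, abs=1e-4)
        assert fit.baseline == pytest.approx(1 / 64, rel=1e-3)


class TestReferenceInformation:
    def test_exact_single_bump_is_identity_channel(self):
        mi = reference_information(64, a=1.0, sigma=0.0, mode="max", seed=0)
        assert mi == pytest.approx(6.0)

    def test_min_mode_uniform_limit(self):
        # a = 1/S with sigma -> 0 leaves essentially a uniform channel
        mi = reference_information(64, a=1 / 64, sigma=0.0, mode="min", seed=0)
        assert mi < 0.05

    def test_max_mode_matches_small_s_construction(self):
        # S = 16, a = 0.5, sigma = 0: two point masses of 1/2, one correct
        # and one at a random wrong bin
        S, L = 16, 4
        rng = np.random.default_rng(1)
        mis = []
        for _ in range(200):
            rows = np.zeros((S, S))
            for s in range(S):
                other = (s + rng.integers(1, S)) % S
                rows[s, s] = 0.5
                rows[s, other] += 0.5
            mis.append(_plugin_mi(rows / S))
        expected = np.mean(mis)
        got = reference_information(S, a=0.5, sigma=0.0, mode="max",
                                    n_draws=200, seed=2)
        assert got == pytest.approx(expected, abs=0.05)

    def test_monotone_nonincreasing_in_sigma(self):
        from ca3metric.infometrics import draw_reference_placements, _kernel_translates
        rng = np.random.default_rng(3)
        placements = draw_reference_placements(64, 3, 30, rng)
        vals = [
            reference_information(
                64, a=1 / 3, sigma=s, n_bumps=3, mode="max",
                placements=placements, K=_kernel_translates(8, s),
            )
            for s in [0.0, 0.3, 0.6, 0.9, 1.2, 1.5]
        ]
        assert all(x >= y - 1e-9 for x, y in zip(vals, vals[1:]))

    def test_drift_splits_lower_information(self):
        a, sigma = 0.5, 0.4
        base = reference_information(64, a, sigma, mode="max", n_draws=30, seed=4)
        drifted = reference_information(64, a, sigma, mode="max", drift=True,
                                        n_draws=30, seed=4)
        assert drifted < base

    def test_too_many_bumps_rejected(self):
        with pytest.raises(ValueError):
            reference_information(16, a=0.01, sigma=0.5, mode="max", seed=0)


class TestMetricResolutionClosedLoop:
    def synthesize(self, chi_true, a, w, sizes, S=64, seed=0):
        """Confusion matrices drawn from the max-mode model at sigma = (1-chi) w."""
        from ca3metric.infometrics import (
            _kernel_translates,
            _reference_matrix,
            bump_volumes,
            draw_reference_placements,
        )
        sigma = (1 - chi_true) * w
        rng = np.random.default_rng(seed)
        K = _kernel_translates(8, sigma)
        volumes = bump_volumes(a)
        infos = []
        for _ in sizes:
            placements = draw_reference_placements(S, len(volumes), 40, rng)
            mis = [
                _plugin_mi(
                    _reference_matrix(K, 8, volumes, placements[0][d], None) / S
                )
                for d in range(40)
            ]
            infos.append(np.mean(mis))
        return np.array(infos)

    # planted sigma = (1-chi) w must stay above the ~1/3-bin grid resolution,
    # below which all bump widths degenerate to a point mass and chi is not
    # identifiable from an 8x8 displacement grid
    @pytest.mark.parametrize("chi_true", [0.1, 0.4, 0.7])
    def test_recovers_planted_chi(self, chi_true):
        a, w = 0.4, 1.5
        sizes = np.array([4, 8, 16, 32], dtype=float)
        infos = self.synthesize(chi_true, a, w, sizes, seed=5)
        curve = InfoCurve(sizes=sizes, values=infos, fit=None)
        bumps = [cm.BumpFit(pc=0.3, w=w, a=a, baseline=0.001) for _ in sizes]
        res = solve_metric_resolution(
            curve, bumps, 64, drift=False, n_draws=50, seed=6, use_fit=False
        )
        assert res.chi_mean == pytest.approx(chi_true, abs=0.03)
        assert np.all(np.abs(res.chi - chi_true) < 0.06)

    def test_exact_code_and_floor_limits(self):
        a, w = 0.5, 1.0
        sizes = np.array([8, 16], dtype=float)
        hi = self.synthesize(1.0, a, w, sizes, seed=7)
        curve = InfoCurve(sizes=sizes, values=hi, fit=None)
        bumps = [cm.BumpFit(pc=0.5, w=w, a=a, baseline=0.0) for _ in sizes]
        res = solve_metric_resolution(curve, bumps, 64, seed=8, use_fit=False,
                                      out_of_range="clamp")
        assert res.chi_mean > 0.9
        lo = self.synthesize(0.0, a, w, sizes, seed=9)
        curve = InfoCurve(sizes=sizes, values=lo, fit=None)
        res = solve_metric_resolution(curve, bumps, 64, seed=10, use_fit=False,
                                      out_of_range="clamp")
        assert res.chi_mean < 0.1

    def test_out_of_range_raises_by_default(self):
        sizes = np.array([8], dtype=float)
        curve = InfoCurve(sizes=sizes, values=np.array([6.5]), fit=None)
        bumps = [cm.BumpFit(pc=0.5, w=1.0, a=0.5, baseline=0.0)]
        with pytest.raises(cm.MetricRangeError):
            solve_metric_resolution(curve, bumps, 64, seed=0, use_fit=False)
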