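"""Coupling angles, circular statistics, pattern classes, variability, deltas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordgait import (
    NormalizedCycle,
    PatternClass,
    circular_mean,
    classify_pattern,
    coordination_variability,
    coupling_angles,
    ensemble_mean_cycle,
    pre_post_delta,
    subphase_coordination,
)
from coordgait.coordination import CouplingSeries
from coordgait.preprocess import SUBPHASE_WINDOWS, subphase_step_indices


def _series(theta):
    theta = np.asarray(theta, dtype=float)
    return CouplingSeries(theta, ~np.isfinite(theta))


def _cycle(values_by_joint, sid=0):
    return NormalizedCycle({j: np.asarray(v, dtype=float) for j, v in values_by_joint.items()}, sid)


class TestEnsembleMean:
    def test_single_cycle_is_identity(self, rng):
        y = rng.standard_normal(101)
        assert np.array_equal(ensemble_mean_cycle([_cycle({"hip": y})], "hip"), y)

    def test_constant_offset_pair_averages(self):
        x = np.linspace(0, 50, 101)
        cycles = [_cycle({"hip": x}), _cycle({"hip": x + 2.0}, 1)]
        assert np.allclose(ensemble_mean_cycle(cycles, "hip"), x + 1.0)

    def test_noisy_sine_mean_within_standard_error(self, rng):
        truth = 20.0 * np.sin(np.linspace(0, 2 * np.pi, 101))
        n = 20
        cycles = [_cycle({"hip": truth + rng.normal(0, 1.0, 101)}, i) for i in range(n)]
        mean = ensemble_mean_cycle(cycles, "hip")
        assert np.max(np.abs(mean - truth)) < 3.0 / np.sqrt(n) * 3.5  # ~3 sigma + slack

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_mean_cycle([], "hip")


class TestCouplingAngles:
    @pytest.mark.parametrize(
        "dprox,ddist,expected",
        [
            (1.0, 0.0, 90.0),   # only the proximal joint moves
            (-1.0, 0.0, 270.0),
            (1.0, 1.0, 45.0),
            (-1.0, -1.0, 225.0),
            (0.0, 1.0, 0.0),
            (0.0, -1.0, 180.0),
        ],
    )
    def test_step_directions(self, dprox, ddist, expected):
        prox = np.concatenate([[0.0], np.cumsum(np.full(100, dprox))])
        dist = np.concatenate([[0.0], np.cumsum(np.full(100, ddist))])
        theta = coupling_angles(prox, dist).theta_deg
        assert np.allclose(theta, expected)

    def test_zero_motion_step_is_missing(self):
        prox = np.linspace(0, 10, 101)
        dist = np.linspace(0, 10, 101)
        prox[51:] = prox[50]
        dist[51:] = dist[50]
        cs = coupling_angles(prox, dist)
        assert cs.missing[50:].all()
        assert not cs.missing[:50].any()
        assert np.isnan(cs.theta_deg[50])

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="101"):
            coupling_angles(np.zeros(100), np.zeros(100))

    def test_dominance_semantics_match_sectors(self, rng):
        """Angles in [45,135] u [225,315] are exactly the steps where the proximal
        joint moves at least as much as the distal joint (tan geometry)."""
        alpha = rng.uniform(0, 360, 2000)
        dp, dd = np.sin(np.deg2rad(alpha)), np.cos(np.deg2rad(alpha))
        theta = np.degrees(np.arctan2(dp, dd)) % 360.0
        in_prox_dominant_sectors = ((theta >= 45) & (theta <= 135)) | (
            (theta >= 225) & (theta <= 315)
        )
        assert np.array_equal(in_prox_dominant_sectors, np.abs(dp) >= np.abs(dd) - 1e-12)


class TestCircularMean:
    def test_concentrated_angles(self):
        s = circular_mean(np.array([45.0, 45.0, 45.0]))
        assert s.mean_deg == pytest.approx(45.0)
        assert s.R == pytest.approx(1.0)
        assert s.sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_pair_printed_formula(self):
        """{0, 90}: R = sqrt(2)/2, circular SD = sqrt(-2 ln R) * 180/pi ~ 47.71 deg."""
        s = circular_mean(np.array([0.0, 90.0]))
        assert s.mean_deg == pytest.approx(45.0, abs=1e-9)
        assert s.R == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert s.sd_deg == pytest.approx(
            np.sqrt(-2 * np.log(np.sqrt(2) / 2)) * 180 / np.pi, abs=1e-9
        )
        assert s.sd_deg == pytest.approx(47.71, abs=0.01)

    def test_antipodal_pair_undefined(self):
        s = circular_mean(np.array([0.0, 180.0]))
        assert s.R == 0.0
        assert np.isinf(s.sd_deg)
        assert np.isnan(s.mean_deg)
        assert s.undefined

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            circular_mean(np.array([np.nan, np.nan]))

    def test_matches_brute_force_complex_sum(self, rng):
        """Implementation vs an independent complex-accumulator oracle."""
        for _ in range(200):
            n = rng.integers(2, 51)
            a = rng.uniform(0, 360, n)
            acc = 0 + 0j
            for x in a:  # deliberate scalar-loop oracle
                acc += complex(np.cos(np.deg2rad(x)), np.sin(np.deg2rad(x)))
            acc /= n
            r_oracle = abs(acc)
            mean_oracle = np.degrees(np.arctan2(acc.imag, acc.real)) % 360.0
            s = circular_mean(a)
            assert s.R == pytest.approx(r_oracle, abs=1e-9)
            assert abs((s.mean_deg - mean_oracle + 180) % 360 - 180) < 1e-7

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 359.99), min_size=2, max_size=30),
        st.floats(-720, 720),
    )
    def test_rotation_equivariance(self, angles, phi):
        base = circular_mean(np.array(angles))
        rot = circular_mean((np.array(angles) + phi) % 360.0)
        assert rot.R == pytest.approx(base.R, abs=1e-9)
        if base.R > 1e-6:
            assert abs((rot.mean_deg - base.mean_deg - phi + 180) % 360 - 180) < 1e-6
        assert rot.sd_deg == pytest.approx(base.sd_deg, abs=1e-6) or (
            np.isinf(rot.sd_deg) and np.isinf(base.sd_deg)
        )


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (212.7, PatternClass.IN_PHASE_PROXIMAL),
            (235.5, PatternClass.IN_PHASE_DISTAL),
            (97.0, PatternClass.ANTI_PHASE_DISTAL),
            (85.5, PatternClass.IN_PHASE_DISTAL),
            (0.0, PatternClass.IN_PHASE_PROXIMAL),
            (45.0, PatternClass.IN_PHASE_DISTAL),  # left-closed boundary
            (135.0, PatternClass.ANTI_PHASE_PROXIMAL),
            (359.9, PatternClass.ANTI_PHASE_PROXIMAL),
        ],
    )
    def test_sector_mapping(self, angle, expected):
        assert classify_pattern(angle) is expected

    def test_sweep_covers_circle_exactly_once(self):
        angles = np.arange(0, 360, 0.1)
        classes = [classify_pattern(a) for a in angles]
        assert all(isinstance(c, PatternClass) for c in classes)
        counts = {c: classes.count(c) for c in PatternClass}
        assert all(v == 900 for v in counts.values())  # 2 sectors x 450 steps each


class TestSubphaseCoordination:
    def test_constant_series(self):
        out = subphase_coordination(_series(np.full(100, 45.0)))
        assert set(out) == set(SUBPHASE_WINDOWS)
        for s in out.values():
            assert s.mean_deg == pytest.approx(45.0)
            assert s.sd_deg == pytest.approx(0.0, abs=1e-6)

    def test_piecewise_constant_respects_windows(self):
        theta = np.full(100, np.nan)
        theta[subphase_step_indices("first_half_stance")] = 10.0
        theta[subphase_step_indices("second_half_stance")] = 300.0
        theta[41:] = 180.0
        out = subphase_coordination(_series(theta))
        assert out["first_half_stance"].mean_deg == pytest.approx(10.0)
        assert out["second_half_stance"].mean_deg == pytest.approx(300.0)

    def test_von_mises_noise_mean_recovered(self, rng):
        theta = np.degrees(rng.vonmises(np.deg2rad(200.0), 50.0, 100)) % 360.0
        out = subphase_coordination(_series(theta))
        for s in out.values():
            assert abs((s.mean_deg - 200.0 + 180) % 360 - 180) < 3.0

    def test_all_missing_subphase_named_in_error(self):
        theta = np.full(100, 45.0)
        theta[subphase_step_indices("first_half_swing")] = np.nan
        with pytest.raises(ValueError, match="first_half_swing"):
            subphase_coordination(_series(theta))


class TestCoordinationVariability:
    def test_identical_strides_zero_everywhere(self):
        strides = [_series(np.full(100, 123.0))] * 10
        var = coordination_variability(strides)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in var.values())

    def test_two_orthogonal_strides_give_47_71(self):
        strides = [_series(np.full(100, 0.0)), _series(np.full(100, 90.0))]
        var = coordination_variability(strides)
        expected = np.sqrt(-2 * np.log(np.sqrt(2) / 2)) * 180 / np.pi
        assert all(v == pytest.approx(expected, abs=1e-9) for v in var.values())

    def test_stride_means_method_differs_from_pointwise(self, rng):
        strides = [
            _series(np.degrees(rng.vonmises(np.deg2rad(100.0), 8.0, 100)) % 360.0)
            for _ in range(12)
        ]
        pw = coordination_variability(strides, method="pointwise")
        sm = coordination_variability(strides, method="stride_means")
        # per-stride means are far tighter than pointwise spread
        assert all(sm[k] < pw[k] for k in pw)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            coordination_variability([_series(np.zeros(100))], method="bogus")


class TestPrePostDelta:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (188.6, 184.2, -4.4),
            (100.0, 100.0, 0.0),
            (350.0, 10.0, 20.0),
            (10.0, 350.0, -20.0),
            (0.0, 180.0, 180.0),
        ],
    )
    def test_minimal_signed_difference(self, pre, post, expected):
        assert pre_post_delta(pre, post) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_wrap_search(self, rng):
        for _ in range(500):
            pre, post = rng.uniform(0, 360, 2)
            d = post - pre
            candidates = [d, d + 360.0, d - 360.0]
            oracle = min(candidates, key=abs)
            got = pre_post_delta(pre, post)
            # both conventions agree except exactly at |d| = 180 (measure zero)
            assert got == pytest.approx(oracle, abs=1e-9)
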