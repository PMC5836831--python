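"""Window scoring, region estimates, unit conversion, and calibration."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbpscan.affinity import (
    ModelParameters,
    calibrate,
    estimate_affinity,
    kd_nanomolar,
    minus_ln_kd_from_nanomolar,
    score_window,
)
from tbpscan.errors import AlphabetError, CalibrationRankError, WindowLengthError

from conftest import random_sequence

FLAT_SCALE = {a + b: 0.0 for a in "ACGT" for b in "ACGT"}


@pytest.fixture
def toy_params():
    """Hand-sized 3-position PWM with slide/bend switched off."""
    pwm = np.array([
        [1.0, -0.5, 0.25, 0.0],   # A C G T
        [0.0, 2.0, -1.0, 0.5],
        [-2.0, 0.0, 1.5, 3.0],
    ])
    return ModelParameters(pwm=pwm, k0=20.0, k_pwm=1.0, k_slide=0.0,
                           k_bend=0.0, slide_scale=FLAT_SCALE,
                           bend_scale=FLAT_SCALE, residual_sd=0.5,
                           window_length=3)


class TestScoreWindow:
    def test_matches_hand_computed_dot_product(self, toy_params):
        # ACG: 1.0 + 2.0 + 1.5 = 4.5 plus intercept
        result = score_window("ACG", toy_params)
        assert result.pwm == pytest.approx(4.5)
        assert result.minus_ln_kd == pytest.approx(20.0 + 4.5)

    def test_consensus_attains_window_maximum(self, toy_params):
        # per-position argmax consensus is ACT
        consensus = "ACT"
        best = score_window(consensus, toy_params).pwm
        rng = np.random.default_rng(0)
        for _ in range(50):
            other = random_sequence(rng, 3)
            assert score_window(other, toy_params).pwm <= best

    def test_wrong_length_rejected(self, toy_params):
        with pytest.raises(WindowLengthError):
            score_window("ACGT", toy_params)

    def test_non_acgt_rejected(self, toy_params):
        with pytest.raises(AlphabetError):
            score_window("ANG", toy_params)

    def test_dinucleotide_terms(self, toy_params):
        scale = dict(FLAT_SCALE)
        scale["AC"] = 2.0
        scale["CG"] = 4.0
        params = replace(toy_params, slide_scale=scale, k_slide=1.0)
        result = score_window("ACG", params)
        assert result.slide == pytest.approx(3.0)  # mean of AC, CG
        assert result.minus_ln_kd == pytest.approx(20.0 + 4.5 + 3.0)


def brute_force_best(sequence: str, params: ModelParameters) -> tuple[int, float]:
    """Independent exhaustive enumeration of every window (plain Python)."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    best_score, best_start = -math.inf, -1
    L = params.window_length
    for start in range(len(sequence) - L + 1):
        window = sequence[start:start + L]
        if any(b not in base_index for b in window):
            continue
        s_pwm = sum(params.pwm[i][base_index[b]] for i, b in enumerate(window))
        s_slide = sum(params.slide_scale[window[i:i + 2]]
                      for i in range(L - 1)) / (L - 1)
        s_bend = sum(params.bend_scale[window[i:i + 2]]
                     for i in range(L - 1)) / (L - 1)
        score = (params.k0 + params.k_pwm * s_pwm
                 + params.k_slide * s_slide + params.k_bend * s_bend)
        if score > best_score:
            best_score, best_start = score, start
    return best_start, best_score


class TestEstimateAffinity:
    def test_equals_brute_force_enumeration(self, calibrated):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = random_sequence(rng, 51)
            est = estimate_affinity(seq, calibrated)
            start, score = brute_force_best(seq, calibrated)
            assert est.minus_ln_kd == pytest.approx(score, abs=1e-9)
            assert est.best_window_start == start

    def test_tie_breaks_to_leftmost_window(self, toy_params):
        flat = replace(toy_params, pwm=np.zeros((3, 4)))
        est = estimate_affinity("ACGTACGT", flat)
        assert est.best_window_start == 0

    def test_too_short_sequence(self, toy_params):
        with pytest.raises(WindowLengthError):
            estimate_affinity("AC", toy_params)

    def test_kd_consistent_with_score(self, toy_params):
        est = estimate_affinity("ACGTACG", toy_params)
        assert est.kd_nM == pytest.approx(1e9 * math.exp(-est.minus_ln_kd))

    def test_masked_windows_skipped(self, toy_params):
        est = estimate_affinity("ACGNNNACT", toy_params)
        assert est.best_window_start in (0, 6)
        with pytest.raises(AlphabetError):
            estimate_affinity("NNNNN", toy_params)

    def test_epsilon_override(self, toy_params):
        est = estimate_affinity("ACGTACG", toy_params, epsilon=0.123)
        assert est.epsilon == 0.123

    def test_single_base_improvement_never_decreases_score(self, toy_params):
        """With only the PWM term active, improving the best window's match
        at any position can only raise the affinity estimate."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = list(random_sequence(rng, 12))
            est = estimate_affinity("".join(seq), toy_params)
            start = est.best_window_start
            for offset in range(3):
                best_base = "ACGT"[int(np.argmax(toy_params.pwm[offset]))]
                improved = seq.copy()
                improved[start + offset] = best_base
                est2 = estimate_affinity("".join(improved), toy_params)
                assert est2.minus_ln_kd >= est.minus_ln_kd - 1e-12


class TestKdConversion:
    def test_one_nanomolar_definition(self):
        assert kd_nanomolar(-math.log(1e-9)) == pytest.approx(1.0)

    def test_ln2_halving(self):
        assert kd_nanomolar(-math.log(1e-9) - math.log(2)) == pytest.approx(2.0)

    @pytest.mark.parametrize("kd", [0.5, 1.0, 10.0, 100.0])
    def test_round_trip(self, kd):
        assert kd_nanomolar(minus_ln_kd_from_nanomolar(kd)) == pytest.approx(kd)

    @settings(max_examples=50, derandomize=True)
    @given(x=st.floats(10, 30), y=st.floats(10, 30))
    def test_strictly_decreasing(self, x, y):
        if x < y:
            assert kd_nanomolar(x) > kd_nanomolar(y)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            minus_ln_kd_from_nanomolar(0.0)


class TestCalibrate:
    def _observations(self, truth, n, noise_sd, seed):
        rng = np.random.default_rng(seed)
        obs = []
        for _ in range(n):
            seq = random_sequence(rng, 51)
            y = estimate_affinity(seq, truth).minus_ln_kd + rng.normal(0, noise_sd)
            obs.append((seq, kd_nanomolar(y)))
        return obs

    def test_noiseless_recovery_is_exact(self, template):
        truth = replace(template, k0=21.0, k_pwm=0.8, k_slide=0.05, k_bend=-0.04)
        fit = calibrate(template, self._observations(truth, 50, 0.0, seed=0))
        assert fit.k0 == pytest.approx(21.0, abs=1e-6)
        assert fit.k_pwm == pytest.approx(0.8, abs=1e-8)
        assert fit.k_slide == pytest.approx(0.05, abs=1e-8)
        assert fit.k_bend == pytest.approx(-0.04, abs=1e-8)

    def test_noisy_recovery_within_simulation_bound(self, template):
        """At 0.5 ln-units of observation noise and n=100, coefficient RMSE
        stays below the bound established by the recovery simulation."""
        truth = replace(template, k0=21.0, k_pwm=0.8, k_slide=0.05, k_bend=-0.04)
        fit = calibrate(template, self._observations(truth, 100, 0.5, seed=0))
        fitted = np.array([fit.k0, fit.k_pwm, fit.k_slide, fit.k_bend])
        true_vec = np.array([21.0, 0.8, 0.05, -0.04])
        rmse = float(np.sqrt(np.mean((fitted - true_vec) ** 2)))
        assert rmse < 2.0
        assert 0.3 < fit.residual_sd < 0.8

    def test_underdetermined_system_rejected(self, template):
        obs = self._observations(template, 3, 0.0, seed=1)
        with pytest.raises(CalibrationRankError):
            calibrate(template, obs)

    def test_residual_sd_positive(self, template):
        truth = replace(template, k0=21.0)
        fit = calibrate(template, self._observations(truth, 30, 0.0, seed=2))
        assert fit.residual_sd > 0


class TestModelParameters:
    def test_yaml_round_trip(self, template, tmp_path):
        path = tmp_path / "params.yaml"
        template.to_yaml(path)
        loaded = ModelParameters.from_yaml(path)
        assert np.allclose(loaded.pwm, template.pwm)
        assert loaded.k0 == template.k0
        assert loaded.slide_scale == dict(template.slide_scale)

    def test_pwm_shape_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(pwm=np.zeros((3, 4)), k0=0, k_pwm=1, k_slide=0,
                            k_bend=0, slide_scale=FLAT_SCALE,
                            bend_scale=FLAT_SCALE, residual_sd=0.5,
                            window_length=15)

    def test_residual_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParameters(pwm=np.zeros((3, 4)), k0=0, k_pwm=1, k_slide=0,
                            k_bend=0, slide_scale=FLAT_SCALE,
                            bend_scale=FLAT_SCALE, residual_sd=0.0,
                            window_length=3)
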