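"""Observer model: choice probabilities, learning dynamics, group generator."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtr

from tidlearn.observers import (
    AUD,
    VIS,
    DEFAULT_DESIGNS,
    ObserverParams,
    default_observer,
    evolve_observer,
    p_comparison_longer,
    p_correct_fd,
    sample_group_improvements,
    simulate_cd_response,
    simulate_fd_choice,
    simulate_tid_choice,
)
from tidlearn.psychometrics import dprime_same_different
from tidlearn.engines import run_cd_block


def observer(**kw):
    return ObserverParams(**kw)


class TestTidChoice:
    def test_matches_closed_form_by_monte_carlo(self, rng):
        """P(comparison longer) at dt = sigma equals Phi(1/sqrt(2)) ~ 0.760."""
        obs = observer(sigma_central=6.0, sigma_aud=8.0, lapse=0.0)  # eff = 10
        n = 200_000
        hits = sum(
            simulate_tid_choice(obs, AUD, 10.0, rng) == "comparison_longer"
            for _ in range(n)
        )
        expected = ndtr(10.0 / (10.0 * math.sqrt(2)))
        assert hits / n == pytest.approx(expected, abs=0.004)
        assert expected == pytest.approx(0.760, abs=0.001)

    def test_zero_delta_t_is_chance(self):
        obs = observer(lapse=0.0)
        assert p_comparison_longer(obs, AUD, 0.0) == pytest.approx(0.5)
        assert p_comparison_longer(obs, VIS, 0.0) == pytest.approx(0.5)

    def test_noiseless_limit_is_deterministic(self, rng):
        obs = observer(sigma_central=1e-9, sigma_aud=0.0, lapse=0.0)
        assert p_comparison_longer(obs, AUD, 6.7) == pytest.approx(1.0)
        assert simulate_tid_choice(obs, AUD, 6.7, rng) == "comparison_longer"

    @given(
        dt=st.floats(0.1, 90.0),
        sigma=st.floats(1.0, 60.0),
    )
    def test_point_symmetry_without_lapses(self, dt, sigma):
        """P(+dt) + P(-dt) = 1 for lapse-free observers."""
        obs = observer(sigma_central=sigma, sigma_aud=0.0, lapse=0.0)
        total = p_comparison_longer(obs, AUD, dt) + p_comparison_longer(
            obs, AUD, -dt
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_magnitude(self):
        obs = observer()
        dts = np.linspace(0, 60, 30)
        ps = [p_comparison_longer(obs, VIS, d) for d in dts]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_rejects_bad_inputs(self, rng):
        obs = observer()
        with pytest.raises(ValueError):
            simulate_tid_choice(obs, "tactile", 5.0, rng)
        with pytest.raises(ValueError):
            simulate_tid_choice(obs, AUD, math.nan, rng)
        with pytest.raises(ValueError):
            simulate_tid_choice(obs, AUD, 150.0, rng)

    def test_default_auditory_threshold_about_half_visual(self):
        obs = observer()
        ratio = obs.tid_threshold(AUD) / obs.tid_threshold(VIS)
        assert ratio == pytest.approx(0.5, abs=0.05)


class TestFdChoice:
    def test_no_signal_is_chance(self):
        assert p_correct_fd(observer(lapse=0.0), 0.0) == pytest.approx(0.5)

    def test_matches_closed_form_by_monte_carlo(self, rng):
        obs = observer(freq_jnd=0.05, lapse=0.0)
        n = 100_000
        hits = sum(
            simulate_fd_choice(obs, 0.05, rng) == "comparison" for _ in range(n)
        )
        assert hits / n == pytest.approx(ndtr(1 / math.sqrt(2)), abs=0.005)

    def test_staircase_start_is_near_perfect(self):
        assert p_correct_fd(observer(freq_jnd=0.05, lapse=0.0), 0.50) > 0.999

    def test_monotone_in_delta_f(self):
        obs = observer()
        dfs = np.linspace(0, 0.5, 20)
        ps = [p_correct_fd(obs, d) for d in dfs]
        assert all(b >= a for a, b in zip(ps, ps[1:]))

    def test_rejects_negative_delta_f(self, rng):
        with pytest.raises(ValueError):
            simulate_fd_choice(observer(), -0.1, rng)


class TestCdResponse:
    def test_null_sensitivity_gives_zero_dprime(self, rng):
        obs = observer(contrast_sens=0.0, lapse=0.0)
        recs = run_cd_block(10_000, obs, rng, same_fraction=0.5)
        assert abs(dprime_same_different(recs).dprime) < 0.1

    def test_recovers_generating_dprime(self, rng):
        obs = observer(contrast_sens=2.0, lapse=0.0)
        recs = run_cd_block(20_000, obs, rng, same_fraction=0.5)
        assert dprime_same_different(recs).dprime == pytest.approx(2.0, abs=0.1)


class TestEvolution:
    def test_no_learning_leaves_parameters_unchanged(self):
        design = DEFAULT_DESIGNS["auditory_single"]
        obs = observer(learn_rate=0.0)
        assert evolve_observer(obs, design, 2) == obs

    def test_trained_auditory_improvement_is_0p30_log_units(self):
        """Five training sessions at the default rate halve the auditory
        threshold (0.30 log10 units), by the multiplicative schedule."""
        design = DEFAULT_DESIGNS["auditory_single"]
        obs = default_observer(design)
        state = obs
        for s in design.training_sessions:
            state = evolve_observer(state, design, s)
        drop = math.log10(obs.tid_threshold(AUD) / state.tid_threshold(AUD))
        assert drop == pytest.approx(0.30, abs=1e-9)
        transfer = math.log10(obs.tid_threshold(VIS) / state.tid_threshold(VIS))
        assert transfer == pytest.approx(0.12, abs=1e-9)

    def test_visual_training_does_not_transfer_to_audition(self):
        design = DEFAULT_DESIGNS["visual_single"]
        obs = default_observer(design)
        state = obs
        for s in design.training_sessions:
            state = evolve_observer(state, design, s)
        assert state.tid_threshold(AUD) == pytest.approx(
            obs.tid_threshold(AUD), rel=1e-12
        )
        drop = math.log10(obs.tid_threshold(VIS) / state.tid_threshold(VIS))
        assert drop == pytest.approx(0.20, abs=1e-9)

    def test_double_training_opens_full_transfer(self):
        design = DEFAULT_DESIGNS["auditory_double_CD"]
        obs = default_observer(design)
        assert obs.transfer_gate_av == 1.0
        state = obs
        for s in design.training_sessions:
            state = evolve_observer(state, design, s)
        trained = math.log10(obs.tid_threshold(AUD) / state.tid_threshold(AUD))
        transferred = math.log10(
            obs.tid_threshold(VIS) / state.tid_threshold(VIS)
        )
        assert transferred == pytest.approx(trained, rel=1e-12)

    def test_rejects_non_training_session(self):
        design = DEFAULT_DESIGNS["auditory_single"]
        with pytest.raises(ValueError):
            evolve_observer(observer(), design, 1)
        with pytest.raises(ValueError):
            evolve_observer(observer(), design, 7)


class TestGroupDesigns:
    def test_default_group_sizes(self):
        sizes = [d.n_subjects for d in DEFAULT_DESIGNS.values()]
        assert sizes == [7, 9, 9, 8, 8, 8]
        assert sum(sizes) == 49

    def test_training_block_structure(self):
        single = DEFAULT_DESIGNS["auditory_single"]
        double = DEFAULT_DESIGNS["visual_double_FD"]
        assert single.blocks_single_training == 16
        assert 2 * double.blocks_double_training == 20


class TestGroupImprovementGenerator:
    def test_law_of_large_numbers_on_group_mean(self, rng):
        """Sampled improvements for the auditory single-training group
        average to the calibrated 0.30 log units."""
        means = [
            sample_group_improvements("auditory_single", 7, rng)[
                "improvement"
            ].mean()
            for _ in range(3000)
        ]
        # SD of a group mean is 0.08*sqrt(7)/sqrt(7) = 0.08
        assert np.mean(means) == pytest.approx(0.30, abs=0.01)

    def test_implied_t_statistic(self, rng):
        """At mu = 0.30 and SD = 0.08*sqrt(7), the one-sample t follows a
        noncentral t with noncentrality mu/SE = 3.75 (mean checked against
        the scipy noncentral-t expectation)."""
        from scipy import stats as sps

        from tidlearn.stats import one_sample_t

        ts = [
            one_sample_t(
                sample_group_improvements("auditory_single", 7, rng)[
                    "improvement"
                ]
            ).statistic
            for _ in range(2000)
        ]
        assert np.mean(ts) == pytest.approx(sps.nct.mean(6, 3.75), abs=0.2)

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(KeyError):
            sample_group_improvements("nonexistent", 5, rng)

    def test_determinism(self):
        a = sample_group_improvements(
            "visual_single", 9, np.random.default_rng(5)
        )
        b = sample_group_improvements(
            "visual_single", 9, np.random.default_rng(5)
        )
        assert a.equals(b)


def test_probit_half_iqr_identity():
    """The lapse-free TID threshold equals 0.954 * effective sigma."""
    obs = observer(lapse=0.0)
    for m in (AUD, VIS):
        assert obs.tid_threshold(m) == pytest.approx(
            0.9539 * obs.effective_sigma(m), rel=1e-3
        )


def test_parameter_validation():
    with pytest.raises(ValueError):
        observer(sigma_central=0.0)
    with pytest.raises(ValueError):
        observer(lapse=0.5)
    with pytest.raises(ValueError):
        observer(learn_rate=1.0)
    with pytest.raises(ValueError):
        observer(transfer_gate_av=1.5)
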