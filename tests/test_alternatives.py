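"""Heuristic, fill-in, logistic and importance-sampling models."""

import numpy as np
import pytest
from scipy.special import expit

from masscollide.alternatives import (
    HeuristicParams,
    ImportanceSampler,
    LogisticWeights,
    design_mean_finals,
    fillin_predict,
    gp_predict,
    importance_sampling_predict,
    logistic_predict,
)
from masscollide.observer import cell_observations
from masscollide.physics import VisibleObservation, final_velocities, generate_design, trial_observation


class TestHeuristicModel:
    def test_motor_occluded_is_exactly_chance(self, design):
        """With the motor final velocity hidden neither heuristic applies."""
        for trial in generate_design(design, "p000"):
            obs = VisibleObservation(trial.u_a, None, trial.v_b)
            assert gp_predict(obs) == 0.5

    def test_projectile_occluded_without_ricochet_is_chance(self, design):
        # no design ratio falls below e = 0.1, so e = 0.1 never ricochets
        for r in (1 / 3, 0.8, 1.25, 3.0):
            for u in design.velocity_grid:
                v_a, _ = final_velocities(u, r, 0.1)
                assert gp_predict(VisibleObservation(u, v_a, None)) == 0.5

    def test_projectile_occluded_ricochet_pushes_below_chance(self, design):
        v_a, _ = final_velocities(3.0, 1 / 3, 1.0)
        assert v_a < 0
        assert gp_predict(VisibleObservation(3.0, v_a, None)) < 0.5

    def test_unoccluded_motor_bias_with_mild_ricochet(self, design):
        """The final-speed cue dominates at r = 4/5, e = 1: motor bias."""
        ps = [gp_predict(o) for o in cell_observations(design, (0.8, 1.0, "none"))]
        assert np.mean(ps) > 0.5

    def test_unoccluded_strong_ricochet_overcomes_motor_bias(self, design):
        ps = [gp_predict(o) for o in cell_observations(design, (1 / 3, 1.0, "none"))]
        assert np.mean(ps) < 0.5

    def test_no_ricochet_reduces_to_speed_cue(self):
        params = HeuristicParams(speed_gain=2.0, ricochet_strength=0.9)
        obs = VisibleObservation(3.0, 1.0, 2.5)
        assert gp_predict(obs, params) == pytest.approx(float(expit(2.0 * 1.5)))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HeuristicParams(speed_gain=-1.0)
        with pytest.raises(ValueError):
            HeuristicParams(ricochet_strength=1.5)


class TestFillInModel:
    def test_imputation_is_noop_when_nothing_missing(self, design):
        for cell in [(3.0, 0.1, "none"), (0.8, 1.0, "none")]:
            for obs in cell_observations(design, cell)[::5]:
                assert fillin_predict(obs, design=design) == gp_predict(obs)

    def test_imputed_means_match_bruteforce_average(self, design):
        """The fill-in values equal the arithmetic mean of each final
        velocity over the full signed (r, e, u) design grid."""
        vas, vbs = [], []
        for r in (1 / 3, 0.8, 1.25, 3.0):
            for e in design.restitutions:
                for u in design.velocity_grid:
                    va, vb = final_velocities(u, r, e)
                    vas.append(va)
                    vbs.append(vb)
        mean_va, mean_vb = design_mean_finals(design)
        assert mean_va == pytest.approx(np.mean(vas), abs=1e-12)
        assert mean_vb == pytest.approx(np.mean(vbs), abs=1e-12)

    def test_motor_occluded_accuracy_above_chance_below_observer(
        self, design, grid_cell_predictions
    ):
        ratios = (1 / 3, 0.8, 1.25, 3.0)
        accs_fill, accs_nn = [], []
        for r in ratios:
            for e in design.restitutions:
                obs = cell_observations(design, (r, e, "motor"))
                p_fill = np.mean([fillin_predict(o, design=design) for o in obs])
                p_nn = grid_cell_predictions[(r, e, "motor")]
                accs_fill.append(p_fill if r > 1 else 1 - p_fill)
                accs_nn.append(p_nn if r > 1 else 1 - p_nn)
        assert 0.5 < np.mean(accs_fill) < np.mean(accs_nn)

    def test_requires_a_visible_final_velocity(self, design):
        with pytest.raises(ValueError):
            fillin_predict(VisibleObservation(3.0, None, None), design=design)


class TestLogisticModel:
    def test_zero_weights_give_chance(self):
        w = LogisticWeights(intercept=0.0, w_ua=0.0, w_va=0.0, w_vb=0.0)
        assert logistic_predict(VisibleObservation(3.0, -1.0, 2.0), w) == 0.5

    def test_closed_form_values_at_reported_weights(self):
        w = LogisticWeights()
        assert logistic_predict(VisibleObservation(0.0, 0.0, 0.0), w) == pytest.approx(
            1 / (1 + np.exp(1.0)), abs=1e-10
        )
        p = logistic_predict(VisibleObservation(3.0, 2.175, 2.475), w)
        assert p == pytest.approx(1 / (1 + np.exp(-2.47925)), abs=1e-10)

    def test_missing_channels_contribute_zero(self):
        w = LogisticWeights()
        assert logistic_predict(VisibleObservation(None, None, None), w) == pytest.approx(
            float(expit(w.intercept))
        )

    def test_coefficient_signs_match_velocity_sum_rule(self):
        """More final velocity raises, more initial velocity lowers P(motor)."""
        w = LogisticWeights()
        assert w.w_va > 0 and w.w_vb > 0 and w.w_ua < 0
        base = logistic_predict(VisibleObservation(3.0, 1.0, 2.0), w)
        assert logistic_predict(VisibleObservation(3.0, 1.5, 2.0), w) > base
        assert logistic_predict(VisibleObservation(3.0, 1.0, 2.5), w) > base
        assert logistic_predict(VisibleObservation(3.5, 1.0, 2.0), w) < base


class TestImportanceSampling:
    def test_deterministic_given_seed(self, params):
        obs = VisibleObservation(3.0, None, 2.5)
        a = importance_sampling_predict(obs, params, 50, 100, seed=7)
        b = importance_sampling_predict(obs, params, 50, 100, seed=7)
        assert a == b
        assert a != importance_sampling_predict(obs, params, 50, 100, seed=8)

    def test_fully_occluded_near_half(self, params):
        p = importance_sampling_predict(
            VisibleObservation(None, None, None), params, 200, 200, seed=0
        )
        assert p == pytest.approx(0.5, abs=0.05)

    def test_underflow_falls_back_to_chance_with_warning(self, params):
        sampler = ImportanceSampler(params, n_samples=20, n_participants=10, seed=0)
        with pytest.warns(RuntimeWarning, match="no memory"):
            p = sampler.predict(VisibleObservation(1e4, 1e4, 1e4))
        assert p == 0.5

    def test_large_sample_limit_matches_grid_posterior(self, engine, design):
        sampler = ImportanceSampler(engine.params, n_samples=4000, n_participants=50, seed=2)
        for cell in [(0.8, 1.0, "motor"), (1.25, 1.0, "projectile"), (3.0, 0.1, "none")]:
            obs = cell_observations(design, cell)[10]
            assert sampler.predict(obs) == pytest.approx(engine.posterior(obs), abs=0.02)

    def test_invalid_sizes_rejected(self, params):
        with pytest.raises(ValueError):
            ImportanceSampler(params, n_samples=0)
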