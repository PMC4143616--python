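"""Condition summaries, t-tests, JZS Bayes factors and NLL comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from masscollide.simulate import simulate_dataset
from masscollide.stats import (
    NLL_CLIP,
    chance_nll,
    compare_models,
    e_difference,
    jzs_bayes_factor,
    model_nll,
    one_sample_t,
    summarize,
)


def _tiny_dataset(rows):
    """Hand-built response table; rows are dicts of overriding fields."""
    base = dict(
        participant_id="p000",
        trial_index=0,
        is_practice=False,
        mass_ratio_r=3.0,
        e=1.0,
        occlusion="none",
        heavier_side="left",
        u_a=3.0,
        v_a=1.5,
        v_b=4.5,
        generating_model="hand",
        p_motor_true=0.5,
        response="motor",
        correct=True,
    )
    records = []
    for i, row in enumerate(rows):
        rec = dict(base, trial_index=i, **row)
        rec["correct"] = (rec["response"] == "motor") == (rec["mass_ratio_r"] > 1)
        records.append(rec)
    return pd.DataFrame(records)


class TestSummarize:
    def test_all_motor_responses(self):
        data = _tiny_dataset([{"response": "motor"} for _ in range(6)])
        cells = summarize(data).cells
        assert (cells["p_motor_chosen"] == 1.0).all()

    def test_two_thirds_proportion(self):
        data = _tiny_dataset(
            [{"response": r} for r in ("motor", "motor", "projectile")]
        )
        summary = summarize(data)
        assert summary.cells["p_motor_chosen"].iloc[0] == pytest.approx(2 / 3)
        assert summary.cells["accuracy"].iloc[0] == pytest.approx(2 / 3)

    def test_practice_trials_excluded_by_default(self):
        data = _tiny_dataset(
            [{"response": "motor"}, {"response": "projectile", "is_practice": True}]
        )
        assert summarize(data).cells["p_motor_chosen"].iloc[0] == 1.0
        assert summarize(data, include_practice=True).cells["p_motor_chosen"].iloc[0] == 0.5

    def test_participant_then_group_pooling(self):
        # p000 has 3 trials (2/3 motor), p001 has 1 trial (all motor):
        # participant-weighted mean is (2/3 + 1)/2, not the pooled 3/4.
        data = _tiny_dataset(
            [
                {"response": "motor"},
                {"response": "motor"},
                {"response": "projectile"},
                {"response": "motor", "participant_id": "p001"},
            ]
        )
        assert summarize(data).cells["p_motor_chosen"].iloc[0] == pytest.approx(
            (2 / 3 + 1.0) / 2
        )

    def test_simulated_proportions_near_generating_probability(self, design):
        p_gen = 0.73
        data = simulate_dataset(design, lambda obs: p_gen, n_participants=12, seed=4)
        cells = summarize(data).cells
        se = np.sqrt(p_gen * (1 - p_gen) / cells["n_trials"])
        assert (np.abs(cells["p_motor_chosen"] - p_gen) < 3 * se).all()


class TestEDifference:
    def _two_level_dataset(self):
        rows = []
        # p(e=1) = 0.3 (3/10), p(e=0.1) = 0.55 (11/20) -> difference -0.25
        rows += [{"e": 1.0, "response": "motor"}] * 3
        rows += [{"e": 1.0, "response": "projectile"}] * 7
        rows += [{"e": 0.1, "response": "motor"}] * 11
        rows += [{"e": 0.1, "response": "projectile"}] * 9
        return _tiny_dataset(rows)

    def test_hand_computed_difference(self):
        diff = e_difference(summarize(self._two_level_dataset()), "none")
        assert diff.loc["p000"] == pytest.approx(-0.25)

    def test_identical_proportions_give_zero(self):
        rows = [{"e": e, "response": r} for e in (1.0, 0.1) for r in ("motor", "projectile")]
        diff = e_difference(summarize(_tiny_dataset(rows)), "none")
        assert diff.loc["p000"] == pytest.approx(0.0)

    def test_missing_level_rejected(self):
        data = _tiny_dataset([{"e": 1.0, "response": "motor"}] * 4)
        with pytest.raises(ValueError):
            e_difference(summarize(data), "none")


class TestOneSampleT:
    def test_matches_hand_computation(self):
        # values {0.6, 0.7, 0.65} vs 0.5: mean 0.65, sd 0.05,
        # t = 0.15 / (0.05 / sqrt(3)) = 3 sqrt(3)
        t, df, p = one_sample_t([0.6, 0.7, 0.65], 0.5)
        assert t == pytest.approx(0.15 / (0.05 / math.sqrt(3)), rel=1e-12)
        assert df == 2
        assert 0 < p < 0.05

    def test_zero_when_values_equal_reference_mean(self):
        t, _, p = one_sample_t([0.4, 0.5, 0.6], 0.5)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_location_invariance(self):
        t1, _, _ = one_sample_t([0.6, 0.7, 0.65], 0.5)
        t2, _, _ = one_sample_t([1.6, 1.7, 1.65], 1.5)
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([0.5], 0.5)
        with pytest.raises(ValueError):
            one_sample_t([0.5, 0.5, 0.5], 0.4)


def _jzs_dense_oracle(t, n, r=1.0, npts=400_001):
    """Independent dense-quadrature route: inverse-gamma mixture over the
    effect-size variance g (substituted to the unit interval)."""
    nu = n - 1
    w = np.linspace(1e-9, 1 - 1e-9, npts)
    g = (1.0 - w) / w
    prior_g = (
        (r**2 / 2) ** 0.5 / math.gamma(0.5) * g**-1.5 * np.exp(-(r**2) / (2 * g))
    )
    num = (
        (1 + n * g) ** -0.5
        * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
        * prior_g
        / w**2
    )
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return float(np.trapezoid(num, w) / den)


class TestJZSBayesFactor:
    def test_null_favoured_at_t_zero(self):
        for n in (2, 10, 42):
            assert jzs_bayes_factor(0.0, n) < 1.0

    def test_monotone_in_absolute_t(self):
        bfs = [jzs_bayes_factor(t, 20) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(bfs) > 0)
        assert jzs_bayes_factor(-3.0, 20) == pytest.approx(jzs_bayes_factor(3.0, 20))

    def test_diverges_for_large_t(self):
        assert jzs_bayes_factor(12.0, 22) > 1e6

    @pytest.mark.parametrize("t,n", [(2.5, 20), (5.7, 20), (-3.0, 42), (1.0, 5)])
    def test_agrees_with_dense_quadrature_oracle(self, t, n):
        assert jzs_bayes_factor(t, n) == pytest.approx(
            _jzs_dense_oracle(t, n), rel=1e-4
        )

    @pytest.mark.parametrize("t,n", [(2.5, 20), (5.7, 20)])
    def test_agrees_with_reference_implementation(self, t, n):
        pingouin = pytest.importorskip("pingouin")
        ref = float(pingouin.bayesfactor_ttest(t, n, paired=True, r=1.0))
        assert jzs_bayes_factor(t, n) == pytest.approx(ref, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bayes_factor(1.0, 10, scale_r=0.0)


class TestModelNLL:
    def test_chance_model_closed_form(self, design):
        data = simulate_dataset(design, lambda obs: 0.5, n_participants=2, seed=0)
        entry = model_nll(data, model=lambda obs: 0.5, model_name="chance")
        assert entry.nll == pytest.approx(chance_nll(entry.n_responses), rel=1e-12)
        assert entry.n_responses == 2 * 180

    def test_perfect_predictions_near_zero(self):
        data = _tiny_dataset([{"response": "motor"}] * 4)
        entry = model_nll(data, predictions=np.ones(4))
        assert entry.nll == pytest.approx(4 * -math.log1p(-NLL_CLIP), rel=1e-6)
        assert entry.nll < 1e-4

    def test_hand_computed_value(self):
        data = _tiny_dataset(
            [{"response": r} for r in ("motor", "motor", "projectile")]
        )
        entry = model_nll(data, predictions=[0.8, 0.6, 0.3])
        assert entry.nll == pytest.approx(
            -(math.log(0.8) + math.log(0.6) + math.log(0.7)), rel=1e-12
        )

    def test_missing_or_invalid_predictions_rejected(self):
        data = _tiny_dataset([{"response": "motor"}] * 3)
        with pytest.raises(ValueError):
            model_nll(data, predictions=[0.5, 0.5])
        with pytest.raises(ValueError):
            model_nll(data, predictions=[0.5, np.nan, 0.5])
        with pytest.raises(ValueError):
            model_nll(data, predictions=[0.5, 1.5, 0.5])

    def test_compare_models_table(self, design):
        data = simulate_dataset(design, lambda obs: 0.9, n_participants=2, seed=2)
        table = compare_models(
            data, {"biased": lambda obs: 0.9, "chance": lambda obs: 0.5}
        )
        assert set(table["model"]) == {"biased", "chance"}
        biased = table.set_index("model").loc["biased", "nll"]
        chance = table.set_index("model").loc["chance", "nll"]
        assert biased < chance
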