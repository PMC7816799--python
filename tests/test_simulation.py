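import copy

import numpy as np
import pandas as pd
import pytest

from whalecost.dose_response import ContinuousER
from whalecost.simulate import (
    SourceScenario,
    run_scenarios,
    simulate_day,
    summarize,
)


def _mean_loss(model, scenario, er, whale, krill, reps, seed):
    rng = np.random.default_rng(seed)
    return np.mean(
        [
            simulate_day(model, scenario, er, whale, krill, rng).proportional_loss
            for _ in range(reps)
        ]
    )


@pytest.fixture(scope="module")
def reference_er(er_functions):
    return er_functions["discrete:moderate-median"]


class TestScenarioValidation:
    def test_duration_bounds(self):
        with pytest.raises(ValueError):
            SourceScenario(210.0, 2000.0)

    def test_named_positions(self):
        assert SourceScenario(210.0, 60.0, "center").source_xy == (50.0, 50.0)
        assert SourceScenario(210.0, 60.0, "corner").source_xy == (0.0, 0.0)
        assert SourceScenario(210.0, 60.0, "midside").source_xy == (50.0, 0.0)
        with pytest.raises(ValueError):
            SourceScenario(210.0, 60.0, "offshore")

    def test_explicit_position_must_be_inside(self):
        with pytest.raises(ValueError):
            SourceScenario(210.0, 60.0, (120.0, 10.0))


class TestNullExposure:
    def test_zero_duration_reproduces_undisturbed_budget(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = simulate_day(
                activity_model,
                SourceScenario(235.0, 0.0),
                reference_er,
                whale22,
                krill_lower,
                rng,
            )
            assert r.lost_lunges == 0
            assert r.lost_MJ == 0
            assert r.proportional_loss == 0
            assert r.net_disturbed_MJ == r.net_undisturbed_MJ
            assert r.expended_disturbed_MJ == r.expended_MJ

    def test_source_below_ambient_floor_has_no_effect(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        """A source too weak to exceed ambient noise anywhere produces
        exactly the undisturbed budget."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            r = simulate_day(
                activity_model,
                SourceScenario(85.0, 1440.0),
                reference_er,
                whale22,
                krill_lower,
                rng,
            )
            assert r.proportional_loss == 0
            assert r.net_disturbed_MJ == r.net_undisturbed_MJ


class TestSaturatedExposure:
    def test_certain_response_with_day_long_gap_loses_everything(
        self, activity_model, whale22, krill_lower
    ):
        """With a response probability of 1 everywhere, an all-day source and
        a 226-h gap, the first interval responds and the entire day is lost."""
        always = ContinuousER(
            dose_kind="range",
            bin_upper=(np.inf,),
            means=(1.0,),
            sds=(0.0,),
        )
        model = copy.copy(activity_model)
        model.gaps_h = np.array([226])
        rng = np.random.default_rng(2)
        for _ in range(20):
            r = simulate_day(
                model, SourceScenario(235.0, 1440.0), always, whale22, krill_lower, rng
            )
            assert r.proportional_loss == pytest.approx(1.0)
            assert r.lost_DF_h + r.lost_SF_h + r.lost_NF_h == pytest.approx(24.0)

    def test_zero_probability_curve_never_responds(
        self, activity_model, whale22, krill_lower
    ):
        never = ContinuousER(
            dose_kind="range", bin_upper=(np.inf,), means=(0.0,), sds=(0.0,)
        )
        rng = np.random.default_rng(3)
        for _ in range(30):
            r = simulate_day(
                activity_model,
                SourceScenario(235.0, 1440.0),
                never,
                whale22,
                krill_lower,
                rng,
            )
            assert r.proportional_loss == 0
            assert r.net_disturbed_MJ == r.net_undisturbed_MJ


class TestMonotonicity:
    def test_mean_loss_non_decreasing_in_source_level(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        means = [
            _mean_loss(
                activity_model,
                SourceScenario(sl, 360.0),
                reference_er,
                whale22,
                krill_lower,
                reps=150,
                seed=11,
            )
            for sl in (160.0, 180.0, 210.0, 235.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_mean_loss_non_decreasing_in_duration(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        means = [
            _mean_loss(
                activity_model,
                SourceScenario(210.0, d),
                reference_er,
                whale22,
                krill_lower,
                reps=150,
                seed=12,
            )
            for d in (6.0, 60.0, 360.0, 1440.0)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))


class TestInvariantsPerReplicate:
    def test_losses_bounded_and_consistent(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        rng = np.random.default_rng(5)
        for _ in range(200):
            r = simulate_day(
                activity_model,
                SourceScenario(235.0, 720.0),
                reference_er,
                whale22,
                krill_lower,
                rng,
            )
            assert 0.0 <= r.proportional_loss <= 1.0
            assert r.lost_MJ <= r.gross_MJ + 1e-9
            assert r.lost_DF_h + r.lost_SF_h + r.lost_NF_h <= 24.0 + 1e-9
            assert r.lost_lunges >= 0
            assert r.expended_disturbed_MJ <= r.expended_MJ + 1e-9

    def test_proportional_loss_independent_of_body_size(
        self, activity_model, reference_er, bio_config, krill_lower
    ):
        """Larger whales lose more MJ but the same proportion, under common
        random numbers."""
        from whalecost.bioenergetics import WhaleParams

        w22 = WhaleParams.from_config(bio_config, 22.0)
        w27 = WhaleParams.from_config(bio_config, 27.0)
        scenario = SourceScenario(235.0, 720.0)
        for seed in range(30):
            a = simulate_day(
                activity_model, scenario, reference_er, w22, krill_lower,
                np.random.default_rng(seed),
            )
            b = simulate_day(
                activity_model, scenario, reference_er, w27, krill_lower,
                np.random.default_rng(seed),
            )
            assert b.proportional_loss == pytest.approx(a.proportional_loss)
            assert b.gross_MJ > a.gross_MJ
            if a.lost_MJ > 0:
                assert b.lost_MJ > a.lost_MJ


class TestScenarioRunner:
    def test_row_count_is_factorial_times_reps(self, activity_model):
        factors = {
            "sl_db": [210.0, 235.0],
            "duration_min": [6.0, 60.0],
            "position": ["center"],
            "length_m": [22.0],
            "krill": ["lower"],
            "er": ["discrete:moderate-median"],
        }
        tab = run_scenarios(activity_model, factors, reps=10, seed=21)
        assert len(tab) == 2 * 2 * 1 * 1 * 1 * 10

    def test_same_master_seed_bit_identical(self, activity_model):
        factors = {
            "sl_db": [210.0],
            "duration_min": [30.0],
            "position": ["center", "corner"],
            "length_m": [22.0],
            "krill": ["lower"],
            "er": ["discrete:moderate-median"],
        }
        a = run_scenarios(activity_model, factors, reps=15, seed=33)
        b = run_scenarios(activity_model, factors, reps=15, seed=33)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_levels_rejected_before_simulation(self, activity_model):
        with pytest.raises(ValueError, match="ER"):
            run_scenarios(
                activity_model, {"er": ["discrete:nonexistent"]}, reps=1, seed=0
            )
        with pytest.raises(ValueError, match="position"):
            run_scenarios(
                activity_model, {"position": ["offshore"]}, reps=1, seed=0
            )

    def test_source_centrality_orders_mean_losses(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        """Center >= mid-side >= corner in expected loss (paired seeds)."""
        means = {
            pos: _mean_loss(
                activity_model,
                SourceScenario(235.0, 720.0, pos),
                reference_er,
                whale22,
                krill_lower,
                reps=400,
                seed=44,
            )
            for pos in ("center", "midside", "corner")
        }
        assert means["center"] >= means["midside"] >= means["corner"]


class TestSummaries:
    def test_all_zero_losses_give_unit_no_change_fraction(
        self, activity_model, reference_er, whale22, krill_lower
    ):
        factors = {
            "sl_db": [235.0],
            "duration_min": [0.0],
            "position": ["center"],
            "length_m": [22.0],
            "krill": ["lower"],
            "er": ["discrete:moderate-median"],
        }
        tab = run_scenarios(activity_model, factors, reps=25, seed=2)
        s = summarize(tab)
        assert s["frac_no_change"].iloc[0] == 1.0
        assert s["frac_net_decreased"].iloc[0] == 0.0

    def test_outcome_classes_partition(self, activity_model):
        factors = {
            "sl_db": [235.0],
            "duration_min": [720.0],
            "position": ["center"],
            "length_m": [22.0],
            "krill": ["lower"],
            "er": ["discrete:moderate-median"],
        }
        tab = run_scenarios(activity_model, factors, reps=200, seed=3)
        s = summarize(tab).iloc[0]
        assert s["frac_no_change"] + s["frac_net_decreased"] == pytest.approx(1.0)
        assert s["frac_sign_flip"] <= s["frac_net_decreased"]

    def test_quantiles_match_sort_based_oracle(self, activity_model):
        factors = {
            "sl_db": [235.0],
            "duration_min": [360.0],
            "position": ["center"],
            "length_m": [22.0],
            "krill": ["lower"],
            "er": ["discrete:moderate-median"],
        }
        tab = run_scenarios(activity_model, factors, reps=101, seed=4)
        s = summarize(tab).iloc[0]
        v = np.sort(tab["proportional_loss"].to_numpy())
        assert s["proportional_loss_q0.5"] == pytest.approx(v[50])
        for q in (0.025, 0.25, 0.75, 0.975):
            assert s[f"proportional_loss_q{q}"] == pytest.approx(
                np.quantile(v, q)
            )

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize(pd.DataFrame())
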