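import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetmix.efficacy import (
    bliss_synergy,
    evaluate_combo,
    mann_whitney_u,
    mixture_proliferation,
    normalized_growth_area,
)
from hetmix.presets import (
    complementary_combo_scenario,
    synergy_combo_scenario,
)
from hetmix.synthgen import generate_growth_experiment

from _oracles import mwu_exact_p


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "channel", "area_start", "area_end"]
    )


class TestNormalizedGrowth:
    def test_ratio_arithmetic(self):
        obs = _obs([("v", 1, "A", 100.0, 100.0), ("v", 1, "B", 50.0, 100.0)])
        norm = normalized_growth_area(obs)
        assert norm["norm_growth"].tolist() == [1.0, 2.0]

    def test_zero_start_area_identifies_well(self):
        obs = _obs([("v", 2, "B", 0.0, 10.0)])
        with pytest.raises(ValueError, match="replicate 2.*'B'"):
            normalized_growth_area(obs)

    def test_matches_simulator_count_ratio(self):
        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params,
            scenario.seeding,
            {"vehicle": []},
            n_replicates=1,
            well_noise_sd=0.0,
        )
        from hetmix.mixsim import simulate_mixture

        traj = simulate_mixture(scenario.params, scenario.seeding, [])
        norm = normalized_growth_area(obs).set_index("channel")["norm_growth"]
        for line in scenario.params.lines:
            assert norm[line] == pytest.approx(
                traj[line].iloc[-1] / traj[line].iloc[0], rel=1e-9
            )


class TestMixtureProliferation:
    def test_sum_over_channels(self):
        obs = _obs(
            [
                ("v", 1, "A", 1.0, 2.0),
                ("v", 1, "B", 1.0, 1.0),
                ("v", 1, "C", 1.0, 0.5),
            ]
        )
        mix = mixture_proliferation(obs)
        assert mix.loc[("v", 1)] == pytest.approx(3.5)

    def test_channel_order_irrelevant(self):
        rows = [("v", 1, c, 1.0, r) for c, r in [("A", 2.0), ("B", 1.0), ("C", 0.5)]]
        a = mixture_proliferation(_obs(rows))
        b = mixture_proliferation(_obs(rows[::-1]))
        assert a.loc[("v", 1)] == b.loc[("v", 1)]

    def test_missing_channel_rejected(self):
        obs = _obs(
            [
                ("v", 1, "A", 1.0, 2.0),
                ("v", 1, "B", 1.0, 1.0),
                ("v", 2, "A", 1.0, 2.0),
            ]
        )
        with pytest.raises(ValueError, match="missing channels"):
            mixture_proliferation(obs)


class TestMannWhitney:
    def test_complete_separation_small(self):
        u, _ = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        _, p_less = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], "less")
        assert p_less == pytest.approx(1 / 20)

    def test_complete_separation_six_replicates(self):
        x = list(range(1, 7))
        y = [v + 10.0 for v in x]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(2 / 924)

    def test_tied_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p == pytest.approx(1.0)

    @given(
        n=st.integers(1, 6),
        m=st.integers(1, 6),
        data=st.data(),
    )
    def test_exact_branch_matches_enumeration(self, n, m, data):
        """The small-sample p-value equals the full-enumeration oracle."""
        pool = data.draw(
            st.lists(
                st.floats(-100, 100),
                min_size=n + m,
                max_size=n + m,
                unique=True,
            )
        )
        x, y = np.array(pool[:n]), np.array(pool[n:])
        for alternative in ("two-sided", "less", "greater"):
            _, p = mann_whitney_u(x, y, alternative)
            assert p == pytest.approx(mwu_exact_p(x, y, alternative), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestBlissSynergy:
    def test_exact_independence(self):
        assert bliss_synergy(0.5, 0.5, 0.75) == pytest.approx(0.0)

    def test_excess_inhibition(self):
        assert bliss_synergy(0.5, 0.5, 0.9) == pytest.approx(0.15)

    def test_saturated_single_agent_bounds_score(self):
        assert bliss_synergy(1.0, 0.3, 0.99) <= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bliss_synergy(1.2, 0.5, 0.5)


class TestEvaluateCombo:
    def test_complementary_scenario_mixture_detects_aggregate_misses(self):
        """The headline contrast: independent-action benefit is visible in
        the mixture readout but vanishes when per-line responses are pooled."""
        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, scenario.treatments, seed=17
        )
        report = evaluate_combo(obs)
        assert report.combo_superior_in_mixture
        assert not report.combo_superior_in_aggregate
        # no within-line interaction: the combo tracks each line's best mono
        assert all(s <= 0.1 for s in report.bliss_scores.values())

    def test_synergy_scenario_beats_monos_in_every_line(self):
        """Multiplicative within-line interaction inhibits every component
        line and the mixture beyond either monotherapy."""
        scenario = synergy_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, scenario.treatments, seed=23
        )
        report = evaluate_combo(obs)
        assert report.combo_superior_in_mixture
        for line in scenario.params.lines:
            assert report.per_line_p_combo_vs_best[line] < 0.05
            med = report.per_line_median
            assert med.loc[line, "combo"] < med.loc[line, "mono_a"]
            assert med.loc[line, "combo"] < med.loc[line, "mono_b"]

    def test_null_combo_changes_nothing(self):
        scenario = complementary_combo_scenario(seed=0)
        treatments = dict(scenario.treatments)
        treatments["mono_b"] = [(scenario.drug_b, 0.0)]
        treatments["combo"] = [(scenario.drug_a, scenario.dose_a), (scenario.drug_b, 0.0)]
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, treatments, seed=31
        )
        report = evaluate_combo(obs)
        assert not report.combo_superior_in_mixture
        assert not report.combo_superior_in_aggregate

    def test_untreated_outgrows_treated(self):
        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, scenario.treatments,
            well_noise_sd=0.0, n_replicates=6,
        )
        mix = mixture_proliferation(normalized_growth_area(obs))
        vehicle = mix.loc["vehicle"].min()
        for cond in ("mono_a", "mono_b", "combo"):
            assert vehicle > mix.loc[cond].max()

    def test_too_few_replicates_rejected(self):
        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, scenario.treatments, n_replicates=4
        )
        with pytest.raises(ValueError, match="fewer than 5"):
            evaluate_combo(obs)

    def test_missing_condition_rejected(self):
        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, {"vehicle": [], "mono_a": []}
        )
        with pytest.raises(ValueError, match="absent"):
            evaluate_combo(obs)

    def test_report_serializes_to_json(self):
        import json

        scenario = complementary_combo_scenario(seed=0)
        obs = generate_growth_experiment(
            scenario.params, scenario.seeding, scenario.treatments, seed=3
        )
        report = evaluate_combo(obs)
        payload = json.loads(report.to_json())
        assert set(payload) >= {"conditions", "best_mono", "mixture", "aggregate", "per_line"}
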