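import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetmix.ida import collateral_sensitivity, ida_combo_score, rank_combos
from hetmix.mixsim import (
    GrowthParams,
    HillParams,
    hill_ic50_for_viability,
    simulate_mixture,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["cell_line", "drug", "concentration", "viability"])


def _two_line_table():
    return _table(
        [
            ("L1", "A", 1.0, 0.2),
            ("L2", "A", 1.0, 0.9),
            ("L1", "B", 1.0, 0.9),
            ("L2", "B", 1.0, 0.2),
        ]
    )


class TestComboScore:
    def test_worked_example(self):
        """Complementary two-line panel: combo 0.2 mean vs best mono 0.55."""
        pred = ida_combo_score(_two_line_table(), "A", "B", 1.0, 1.0)
        assert pred.per_line["viability_combo"].tolist() == [0.2, 0.2]
        assert pred.mean_combo_viability == pytest.approx(0.2)
        assert pred.best_mono_mean_viability == pytest.approx(0.55)
        assert pred.score == pytest.approx(0.35)

    def test_self_combination_scores_zero(self):
        pred = ida_combo_score(_two_line_table(), "A", "A", 1.0, 1.0)
        assert pred.score == 0.0

    def test_inert_partner_scores_zero(self):
        table = pd.concat(
            [
                _two_line_table(),
                _table([("L1", "inert", 1.0, 1.0), ("L2", "inert", 1.0, 1.0)]),
            ]
        )
        pred = ida_combo_score(table, "A", "inert", 1.0, 1.0)
        assert pred.score == pytest.approx(0.0)
        assert pred.mean_combo_viability == pytest.approx(0.55)

    def test_lines_missing_a_measurement_dropped(self):
        table = pd.concat([_two_line_table(), _table([("L3", "A", 1.0, 0.5)])])
        pred = ida_combo_score(table, "A", "B", 1.0, 1.0)
        assert pred.n_lines == 2
        assert pred.n_dropped == 1

    def test_no_shared_lines_rejected(self):
        table = _table([("L1", "A", 1.0, 0.5), ("L2", "B", 1.0, 0.5)])
        with pytest.raises(ValueError, match="no cell lines"):
            ida_combo_score(table, "A", "B", 1.0, 1.0)

    @given(
        va=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
        vb=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
    )
    def test_score_non_negative(self, va, vb):
        """Under independent action a combo is never worse than best mono."""
        n = min(len(va), len(vb))
        rows = [("L%d" % i, "A", 1.0, va[i]) for i in range(n)]
        rows += [("L%d" % i, "B", 1.0, vb[i]) for i in range(n)]
        pred = ida_combo_score(_table(rows), "A", "B", 1.0, 1.0)
        assert pred.score >= -1e-12
        per_line = pred.per_line
        assert (
            per_line["viability_combo"]
            <= per_line[["viability_a", "viability_b"]].min(axis=1) + 1e-12
        ).all()

    def test_lowering_any_viability_never_raises_combo_viability(self, rng):
        rows = []
        va = rng.uniform(0.2, 1.0, 5)
        vb = rng.uniform(0.2, 1.0, 5)
        for i in range(5):
            rows += [(f"L{i}", "A", 1.0, va[i]), (f"L{i}", "B", 1.0, vb[i])]
        base = ida_combo_score(_table(rows), "A", "B", 1.0, 1.0)
        for i in range(5):
            perturbed = [list(r) for r in rows]
            perturbed[2 * i][3] = max(0.0, va[i] - 0.3)
            pred = ida_combo_score(_table([tuple(r) for r in perturbed]), "A", "B", 1.0, 1.0)
            assert pred.mean_combo_viability <= base.mean_combo_viability + 1e-12


class TestRankCombos:
    def _panel_table(self):
        # anchor hits L1 only; P1 complements (hits L2), P2 duplicates the
        # anchor's coverage, `copy` is an exact clone of the anchor
        rows = []
        for line, va in (("L1", 0.2), ("L2", 0.95)):
            rows.append((line, "anchor", 1.0, va))
            rows.append((line, "copy", 1.0, va))
        rows += [("L1", "P1", 1.0, 0.95), ("L2", "P1", 1.0, 0.2)]
        rows += [("L1", "P2", 1.0, 0.25), ("L2", "P2", 1.0, 0.9)]
        return _table(rows)

    def test_collateral_partner_outranks_redundant(self):
        ranked = rank_combos(self._panel_table(), "anchor", 1.0)
        assert list(ranked["partner"])[0] == "P1"
        assert ranked.set_index("partner").loc["P1", "score"] > ranked.set_index(
            "partner"
        ).loc["P2", "score"]

    def test_anchor_clone_ranks_last_with_zero_score(self):
        ranked = rank_combos(self._panel_table(), "anchor", 1.0).set_index("partner")
        assert ranked.loc["copy", "score"] == pytest.approx(0.0)
        assert ranked.index[-1] == "copy"

    def test_partner_cap_limits_grid(self):
        rows = [
            ("L1", "anchor", 1.0, 0.5),
            ("L1", "P", 1.0, 0.9),
            ("L1", "P", 10.0, 0.1),
        ]
        ranked = rank_combos(_table(rows), "anchor", 1.0, max_conc={"P": 2.0})
        assert ranked.iloc[0]["conc_partner"] == 1.0

    def test_empty_partner_set_rejected(self):
        with pytest.raises(ValueError, match="empty partner"):
            rank_combos(_two_line_table(), "A", 1.0, partner_drugs=[])

    def test_best_dose_recorded_per_partner(self):
        # partner covers the anchor-resistant line better at higher dose
        rows = [("L1", "anchor", 1.0, 0.4), ("L2", "anchor", 1.0, 0.95)]
        rows += [("L1", "P", c, v) for c, v in [(0.5, 1.0), (1.0, 0.95), (2.0, 0.9)]]
        rows += [("L2", "P", c, v) for c, v in [(0.5, 0.9), (1.0, 0.7), (2.0, 0.3)]]
        ranked = rank_combos(_table(rows), "anchor", 1.0)
        assert ranked.iloc[0]["conc_partner"] == 2.0
        # score at 2.0: best mono P (mean 0.6) minus combo mean 0.35
        assert ranked.iloc[0]["score"] == pytest.approx(0.25)


class TestCollateralSensitivity:
    def test_perfect_anti_rank(self):
        rho, verdict = collateral_sensitivity([0.8, 0.5, 0.2], [0.2, 0.5, 0.8])
        assert rho == pytest.approx(-1.0)
        assert verdict == "collateral"

    def test_identical_profiles_redundant(self):
        rho, verdict = collateral_sensitivity([0.8, 0.5, 0.2], [0.8, 0.5, 0.2])
        assert rho == pytest.approx(1.0)
        assert verdict == "redundant"

    def test_constant_vector_flagged(self):
        rho, verdict = collateral_sensitivity([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert np.isnan(rho)
        assert verdict == "undefined"

    def test_null_simulation_centers_on_zero(self):
        rng = np.random.default_rng(99)
        rhos = [
            collateral_sensitivity(rng.uniform(size=5), rng.uniform(size=5))[0]
            for _ in range(100)
        ]
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError):
            collateral_sensitivity([0.1, 0.2], [0.2, 0.1])


class TestSimulatorConsistency:
    def test_top_ranked_combo_matches_simulated_mixture(self):
        """IDA ranking agrees with simulated mixture inhibition (top-1)."""
        agree = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            lines = [f"L{i}" for i in range(4)]
            drugs = ["anchor", "P1", "P2", "P3"]
            targets = {
                (line, drug): float(rng.uniform(0.3, 0.98))
                for line in lines
                for drug in drugs
            }
            rows = [
                (line, drug, 1.0, targets[(line, drug)])
                for line in lines
                for drug in drugs
            ]
            table = _table(rows)
            ranked = rank_combos(table, "anchor", 1.0, partner_drugs=["P1", "P2", "P3"])

            dr = {
                line: {
                    drug: HillParams(
                        hill_ic50_for_viability(targets[(line, drug)], 1.0, 2.0, 1.0),
                        2.0,
                        1.0,
                    )
                    for drug in drugs
                }
                for line in lines
            }
            # matched growth rates and a short horizon keep the endpoint
            # readout in the near-linear regime where the panel-mean score
            # and the mixture endpoint order combos identically
            params = GrowthParams(
                doubling_time={line: 36.0 for line in lines},
                cell_area={line: 1.0 for line in lines},
                capacity=1e9,
                combo_model="ida-min",
                dose_response=dr,
            )
            seeding = {line: 1000.0 for line in lines}

            def mixture_growth(treatment):
                traj = simulate_mixture(params, seeding, treatment, duration=24.0)
                return float(traj.iloc[-1].sum())

            # simulated analog of the score: endpoint benefit of the combo
            # over the better monotherapy, relative to vehicle growth
            vehicle = mixture_growth([])
            anchor_growth = mixture_growth([("anchor", 1.0)])
            benefits = {}
            for p in ["P1", "P2", "P3"]:
                best_mono = min(anchor_growth, mixture_growth([(p, 1.0)]))
                combo = mixture_growth([("anchor", 1.0), (p, 1.0)])
                benefits[p] = (best_mono - combo) / vehicle
            sim_best = max(sorted(benefits), key=benefits.get)
            agree += int(ranked.iloc[0]["partner"] == sim_best)
        assert agree >= 9
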