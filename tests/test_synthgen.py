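import numpy as np
import pandas as pd
import pytest

from hetmix.datatypes import log2_to_linear
from hetmix.mixsim import GrowthParams, HillParams
from hetmix.presets import unstratified_crpc
from hetmix.synthgen import (
    CohortConfig,
    SubtypeSpec,
    generate_cell_line_panel,
    generate_cohort,
    generate_growth_experiment,
    generate_monotherapy_table,
    generate_reference_profiles,
)


def _tiny_config(**overrides) -> CohortConfig:
    genes = pd.Index([f"g{i}" for i in range(20)])
    base = pd.Series(np.linspace(2.0, 6.0, 20), index=genes)
    tumor = SubtypeSpec(
        name="T",
        marker_genes=tuple(genes[:5]),
        base_profile=base.add(pd.Series(2.0, index=genes[:5]), fill_value=0.0),
        doubling_time=30.0,
        cell_lines=("T-line",),
    )
    stroma = base.add(pd.Series(2.0, index=genes[5:10]), fill_value=0.0)
    kwargs = dict(
        subtypes=(tumor,),
        nontumor_profiles={"stroma": stroma},
        n_patients=5,
        noise_sd=0.0,
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        seed=7,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


class TestGenerateCohort:
    def test_pure_tumor_no_noise_reproduces_profile(self):
        """A 100% tumor, noiseless biopsy is exactly the subtype profile."""
        config = _tiny_config(tumor_fraction=1.0)
        bulk, truth, _ = generate_cohort(config)
        profile = config.subtypes[0].base_profile
        for sample in bulk.sample_ids:
            np.testing.assert_allclose(bulk.values[sample], profile, atol=1e-9)

    def test_two_component_mixture_is_weighted_sum(self):
        """Noiseless bulk equals the fraction-weighted linear mixture."""
        config = _tiny_config(tumor_fraction=0.6)
        bulk, truth, signatures = generate_cohort(config)
        expected = 0.6 * signatures.values["T"] + 0.4 * signatures.values["stroma"]
        for sample in bulk.sample_ids:
            np.testing.assert_allclose(
                log2_to_linear(bulk.values[sample]), expected, atol=1e-9
            )
        assert (truth["tumor_fraction"] == 0.6).all()

    def test_crpc_preset_patient_count(self):
        config = unstratified_crpc(seed=3, n_genes=700, markers_per_type=60)
        bulk, truth, _ = generate_cohort(config)
        assert bulk.n_samples == 208
        assert len(truth) == 208
        assert set(bulk.sample_role) == {"patient"}

    def test_determinism(self):
        a, truth_a, _ = generate_cohort(_tiny_config(noise_sd=0.3))
        b, truth_b, _ = generate_cohort(_tiny_config(noise_sd=0.3))
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_zero_tumor_fraction_rejected(self):
        with pytest.raises(ValueError, match="tumor_fraction"):
            _tiny_config(tumor_fraction=0.0)

    def test_gene_universe_smaller_than_markers_rejected(self):
        genes = pd.Index(["g0", "g1"])
        base = pd.Series([2.0, 3.0], index=genes)
        spec = SubtypeSpec("T", ("g0", "g1"), base, 30.0)
        tiny = pd.Series([1.0], index=pd.Index(["g0"]))
        with pytest.raises(ValueError):
            CohortConfig(
                subtypes=(spec, SubtypeSpec("U", ("g0",), tiny, 30.0)),
                nontumor_profiles={},
            )


class TestCellLinePanel:
    def test_identity_batch_reproduces_profile(self):
        config = _tiny_config()
        panel = generate_cell_line_panel(config)
        np.testing.assert_allclose(
            panel.values["T-line"], config.subtypes[0].base_profile, atol=1e-12
        )
        assert panel.sample_role["T-line"] == "cell-line"
        assert panel.batch["T-line"] == "cell-line"

    def test_constant_shift_offsets_panel(self):
        config = _tiny_config(batch_shift=np.full(20, 2.0), batch_scale=np.ones(20))
        panel = generate_cell_line_panel(config)
        diff = panel.values["T-line"] - config.subtypes[0].base_profile
        np.testing.assert_allclose(diff, 2.0, atol=1e-12)

    def test_resistant_clone_stays_near_parent(self, small_taxane):
        """Resistance perturbations are below the between-subtype distance."""
        config, clones = small_taxane
        quiet = CohortConfig(
            subtypes=config.subtypes,
            nontumor_profiles=config.nontumor_profiles,
            n_patients=5,
            noise_sd=0.0,
            batch_shift_sd=0.0,
            batch_scale_sd=0.0,
            seed=config.seed,
        )
        panel = generate_cell_line_panel(quiet, resistant_clones=clones)
        profiles = {s.name: s.base_profile for s in config.subtypes}
        min_subtype_dist = min(
            np.linalg.norm(profiles[a] - profiles[b])
            for a in profiles
            for b in profiles
            if a < b
        )
        for clone in clones:
            d = np.linalg.norm(panel.values[clone.name] - panel.values[clone.parent_line])
            assert d < min_subtype_dist


class TestMonotherapyTable:
    def _specs(self):
        genes = pd.Index(["g0"])
        base = pd.Series([3.0], index=genes)
        dr = {
            "d1": HillParams(ic50=1.0, hill=2.0, emax=1.0),
            "d2": HillParams(ic50=4.0, hill=1.0, emax=0.8),
        }
        return [
            SubtypeSpec(f"S{i}", (), base, 30.0, dose_response=dr, cell_lines=(f"L{i}",))
            for i in range(3)
        ]

    def test_zero_dose_full_viability(self):
        table = generate_monotherapy_table(self._specs(), ["d1", "d2"], [0.0, 1.0])
        assert (table.loc[table["concentration"] == 0.0, "viability"] == 1.0).all()

    def test_hill_midpoint(self):
        table = generate_monotherapy_table(self._specs(), ["d1"], [1.0])
        assert table["viability"].to_numpy() == pytest.approx(0.5)

    def test_full_grid_shape_and_range(self):
        grid = [0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
        table = generate_monotherapy_table(self._specs(), ["d1", "d2"], grid)
        assert len(table) == 8 * 2 * 3
        assert table["viability"].between(0.0, 1.0).all()

    def test_per_drug_grids(self):
        table = generate_monotherapy_table(
            self._specs(), ["d1", "d2"], {"d1": [0.5, 1.0], "d2": [2.0]}
        )
        assert len(table) == 3 * (2 + 1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_monotherapy_table(self._specs(), ["d1"], [-1.0, 0.0])


class TestGrowthExperiment:
    def _setup(self):
        params = GrowthParams(
            doubling_time={"A": 24.0, "B": 48.0},
            cell_area={"A": 1.0, "B": 2.0},
            capacity=1e9,
            dose_response={"A": {}, "B": {}},
        )
        return params, {"A": 1000.0, "B": 2000.0}

    def test_noiseless_vehicle_matches_doubling(self):
        params, seeding = self._setup()
        obs = generate_growth_experiment(
            params, seeding, {"vehicle": []}, n_replicates=2, well_noise_sd=0.0
        )
        ratios = obs.set_index("channel")["area_end"] / obs.set_index("channel")["area_start"]
        assert ratios.loc["A"].to_numpy() == pytest.approx(2 ** (120 / 24), rel=0.01)
        assert ratios.loc["B"].to_numpy() == pytest.approx(2 ** (120 / 48), rel=0.01)

    def test_six_replicates_per_condition(self):
        params, seeding = self._setup()
        obs = generate_growth_experiment(params, seeding, {"vehicle": [], "t": []})
        counts = obs.groupby("condition")["replicate"].nunique()
        assert (counts == 6).all()

    def test_same_seed_identical(self):
        params, seeding = self._setup()
        a = generate_growth_experiment(params, seeding, {"vehicle": []}, seed=5)
        b = generate_growth_experiment(params, seeding, {"vehicle": []}, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_mixture_rejected(self):
        params, _ = self._setup()
        with pytest.raises(ValueError):
            generate_growth_experiment(params, {"A": 0.0, "B": 0.0}, {"vehicle": []})

    def test_negative_dose_rejected(self):
        params, seeding = self._setup()
        with pytest.raises(ValueError):
            generate_growth_experiment(params, seeding, {"t": [("d", -1.0)]})


class TestReferenceProfiles:
    def test_labels_and_replicates(self, small_config):
        profiles, labels = generate_reference_profiles(small_config, n_per_type=4)
        assert profiles.shape[1] == 4 * (len(small_config.subtype_names) + 2)
        assert set(labels) == set(small_config.subtype_names) | {"stroma", "immune"}
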