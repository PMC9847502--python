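"""Synthetic-screen generator: construction contracts and stochastic
invariants (conservation of cells, monotone death counts, determinism,
dose response)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kirscreen as ks
from kirscreen.errors import MissingControlError, ValidationError
from kirscreen.simulate import DEFAULT_DOSE_LADDER_UM, screen_phenotypes_from_truth


class TestPanel:
    def test_expression_split_is_exact(self):
        p = ks.generate_panel(369, 200, seed=1)
        assert int((p.expression >= 1.5).sum()) == 200
        assert len(p.kinase_ids) == 369

    def test_all_below_cutoff_when_none_expressed(self):
        p = ks.generate_panel(5, 0, seed=1)
        assert np.all(p.expression < 1.5)

    def test_deterministic_given_seed(self):
        a = ks.generate_panel(50, 20, seed=7)
        b = ks.generate_panel(50, 20, seed=7)
        assert a.kinase_ids == b.kinase_ids
        np.testing.assert_array_equal(a.expression, b.expression)

    def test_too_many_expressed_rejected(self):
        with pytest.raises(ValidationError):
            ks.generate_panel(5, 6, seed=1)


class TestInhibitionMatrix:
    def test_hit_sets_cover_panel(self):
        p = ks.generate_panel(10, 10, seed=1)
        m = ks.generate_inhibition_matrix(p, n_inhibitors=10, hits_per_inhibitor=1, seed=2)
        hit = (m.residual <= 0.2).any(axis=0)
        assert hit.all()

    def test_zero_hits_gives_weak_only(self, small_panel):
        m = ks.generate_inhibition_matrix(small_panel, 4, 0, seed=2)
        assert np.all(m.residual >= 0.8)

    def test_entries_clipped_to_unit_interval(self, small_inhibition):
        assert np.all(small_inhibition.residual >= 0.0)
        assert np.all(small_inhibition.residual <= 1.0)

    def test_empty_panel_rejected(self):
        empty = ks.KinasePanel((), np.array([]))
        with pytest.raises(ValidationError):
            ks.generate_inhibition_matrix(empty, 3, 1, seed=0)


class TestDoseMapping:
    def test_reference_point_self_consistency(self):
        # at the profiling concentration, inhibition is 1 - residual
        assert ks.inhibition_at_dose(0.5, 1.0, 1.0) == pytest.approx(0.5)
        assert ks.inhibition_at_dose(0.8, 1.0, 1.0) == pytest.approx(0.2)

    def test_zero_dose_gives_zero_inhibition(self):
        assert ks.inhibition_at_dose(0.5, 1.0, 0.0) == 0.0

    def test_single_site_extrapolation(self):
        # residual 0.5 at 1 uM -> Kd = 1 uM -> 3/(3+1)
        assert ks.inhibition_at_dose(0.5, 1.0, 3.0) == pytest.approx(0.75)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            ks.inhibition_at_dose(0.5, 1.0, -1.0)

    @settings(derandomize=True, deadline=None)
    @given(
        r=st.floats(0.0, 1.0),
        d1=st.floats(0.0, 100.0),
        d2=st.floats(0.0, 100.0),
    )
    def test_monotone_in_dose(self, r, d1, d2):
        lo, hi = sorted((d1, d2))
        assert ks.inhibition_at_dose(r, 1.0, lo) <= ks.inhibition_at_dose(
            r, 1.0, hi
        ) + 1e-12


class TestSimulateWell:
    def test_quiescent_deathless_well_is_static(self, exact_config):
        import dataclasses

        cfg = dataclasses.replace(exact_config, basal_death_rate=0.0)
        t = ks.simulate_well(cfg, ks.WellCondition(), seed=1)
        assert np.all(t.nuclei == t.nuclei[0])
        assert np.all(t.dead == 0)

    def test_caspase_inhibitor_abolishes_death(self, exact_config):
        t = ks.simulate_well(
            exact_config, ks.WellCondition(caspase_inhibitor=True), seed=1
        )
        assert np.all(t.dead == 0)

    def test_cell_conservation_against_event_log(self, small_truth, small_inhibition):
        cfg = ks.SimConfig()  # defaults include detection thinning
        t = ks.simulate_well(
            cfg,
            ks.WellCondition(growth_factor="FGF2", gf_dose=20.0),
            truth=small_truth,
            inhibition=small_inhibition,
            seed=11,
        )
        ev = t.events
        births_cum = np.searchsorted(ev["birth_times"], t.times, side="right")
        np.testing.assert_array_equal(
            ev["true_nuclei"] + ev["true_dead"] - ev["n_start"], births_cum
        )

    def test_dead_count_never_decreases(self, small_truth, small_inhibition):
        for seed in range(5):
            t = ks.simulate_well(
                ks.SimConfig(),
                ks.WellCondition(growth_factor="VEGFA", gf_dose=20.0),
                truth=small_truth,
                inhibition=small_inhibition,
                seed=seed,
            )
            assert np.all(np.diff(t.dead) >= 0)

    def test_same_seed_reproduces_trajectory(self, exact_config, small_truth):
        cond = ks.WellCondition(growth_factor="FGF2", gf_dose=5.0)
        a = ks.simulate_well(exact_config, cond, truth=small_truth, seed=3)
        b = ks.simulate_well(exact_config, cond, truth=small_truth, seed=3)
        np.testing.assert_array_equal(a.nuclei, b.nuclei)
        np.testing.assert_array_equal(a.dead, b.dead)

    def test_unknown_ids_rejected(self, exact_config, small_truth, small_inhibition):
        with pytest.raises(ValidationError):
            ks.simulate_well(
                exact_config,
                ks.WellCondition(growth_factor="EGF", gf_dose=1.0),
                truth=small_truth,
                seed=0,
            )
        with pytest.raises(ValidationError):
            ks.simulate_well(
                exact_config,
                ks.WellCondition(
                    growth_factor="FGF2",
                    gf_dose=1.0,
                    inhibitor_id="NOPE",
                    inhibitor_dose_uM=1.0,
                ),
                truth=small_truth,
                inhibition=small_inhibition,
                seed=0,
            )

    def test_mean_final_count_nondecreasing_in_dose(self, exact_config):
        means = []
        for dose in (0.0, 0.5, 5.0, 50.0):
            finals = [
                ks.simulate_well(
                    exact_config,
                    ks.WellCondition(growth_factor="FGF2", gf_dose=dose),
                    truth=ks.GroundTruth({"FGF2": {}}, ()),
                    seed=s,
                ).nuclei[-1]
                for s in range(100)
            ]
            means.append(np.mean(finals))
        diffs = np.diff(means)
        assert np.all(diffs > -3.0)  # non-decreasing within Monte-Carlo error
        assert means[-1] > means[0] + 20


class TestScreen:
    def test_dose_ladder_matches_screen_design(self):
        ladder = DEFAULT_DOSE_LADDER_UM
        assert len(ladder) == 6
        assert ladder[0] == pytest.approx(5.0)
        ratios = [ladder[i] / ladder[i + 1] for i in range(5)]
        assert ratios == pytest.approx([3.0] * 5)

    def test_well_count_matches_design(self, exact_config, small_truth, small_inhibition):
        design = ks.simulate.default_screen_design(
            small_inhibition, {"FGF2": 1.25, "VEGFA": 20.0}, n_replicates=2
        )
        trajs, platemap = ks.simulate_screen(
            exact_config, design, small_truth, small_inhibition, seed=5
        )
        n_inh = len(small_inhibition.inhibitor_ids)
        expected = 2 * 2 * (n_inh * 6 + design.controls_per_plate)
        assert len(trajs) == expected == len(platemap)
        # every plate carries vehicle controls for its growth factor
        per_plate = platemap.groupby("plate_id")["is_control"].sum()
        assert (per_plate == design.controls_per_plate).all()

    def test_screen_deterministic(self, exact_config, small_truth, small_inhibition):
        design = ks.simulate.default_screen_design(
            small_inhibition, {"FGF2": 1.25}, n_replicates=1
        )
        a, pa = ks.simulate_screen(exact_config, design, small_truth, small_inhibition, 5)
        b, pb = ks.simulate_screen(exact_config, design, small_truth, small_inhibition, 5)
        assert pa.equals(pb)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.nuclei, tb.nuclei)

    def test_plate_without_control_rejected(self, exact_config, small_truth, small_inhibition):
        design = ks.ScreenDesign(
            growth_factors={"FGF2": 1.25},
            inhibitors=small_inhibition.inhibitor_ids[:2],
            controls_per_plate=0,
            n_replicates=1,
        )
        with pytest.raises(MissingControlError):
            ks.simulate_screen(exact_config, design, small_truth, small_inhibition, 5)


class TestLinearPhenotypes:
    def test_phenotypes_are_linear_in_weighted_inhibition(self, small_truth, small_inhibition):
        phen = screen_phenotypes_from_truth(
            small_truth, small_inhibition, noise_sd_frac=0.0, seed=0
        )
        # noiseless: every delta is -0.02 * weighted inhibition, hence <= 0
        assert (phen["delta_kp"] <= 1e-12).all()
        assert set(phen["growth_factor"]) == set(small_truth.weights)
        n_inh = len(small_inhibition.inhibitor_ids)
        assert len(phen) == len(small_truth.weights) * n_inh * 6
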