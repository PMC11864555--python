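"""Generator contracts: crossing placement, pulses, determinism, truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from chumrun.errors import ScenarioError
from chumrun.phenology import mdmt
from chumrun.simulate import (
    MIXED_13YR_SEQUENCE,
    Scenario,
    make_scenario_preset,
    simulate_catch,
    simulate_dataset,
    simulate_sst,
)


def scenario_with(**kwargs) -> Scenario:
    base = dict(regime_sequence=("T1",), seed=0)
    base.update(kwargs)
    return Scenario(**base)


class TestSimulateSst:
    def test_t1_crossing_shifts_early_everywhere(self):
        sc = scenario_with(
            regime_sequence=("T1",), base_cross_day=30.0, early_shift=10.0,
            sst_noise_sd=0.0, arrival_lag=3.0, residence_mean=10,
        )
        series = simulate_sst(sc, "CR1", 2006)
        first_below = int(np.argmax(series < 20.0))
        assert first_below == 20

    def test_t2_delays_southern_crossing_by_ns_offset(self):
        sc = scenario_with(
            regime_sequence=("T2",), base_cross_day=30.0, ns_offset=8.0,
            sst_noise_sd=0.0, arrival_lag=3.0, residence_mean=10,
            t2_arrival_advance=0.0,
        )
        series = simulate_sst(sc, "CR6", 2006)
        assert int(np.argmax(series < 20.0)) == 38

    def test_same_seed_reproduces_bitwise(self):
        sc = make_scenario_preset("mixed-13yr", seed=5)
        a = simulate_sst(sc, "CR3", 2010)
        b = simulate_sst(sc, "CR3", 2010)
        np.testing.assert_array_equal(a, b)

    def test_series_length_and_strict_mean_monotonicity(self):
        sc = make_scenario_preset("mixed-13yr", seed=0).without_noise()
        series = simulate_sst(sc, "CR2", 2007)
        assert series.shape == (92,)
        assert (np.diff(series) < 0).all()


class TestSimulateCatch:
    def test_degenerate_pulse_concentrates_on_center(self):
        sc = scenario_with(pulse_sd=0.0, base_cross_day=30.0, arrival_lag=5.0,
                           residence_mean=10).without_noise()
        coastal, riverine, truth = simulate_catch(sc, "CR1", 2006)
        assert coastal.sum() == coastal[truth["coastal_mdmt"]]
        assert mdmt(coastal) == truth["coastal_mdmt"] == 35

    def test_riverine_is_coastal_shifted_by_residence(self):
        sc = scenario_with(base_cross_day=30.0, arrival_lag=5.0,
                           residence_mean=15, river_return_rate=1.0).without_noise()
        coastal, riverine, truth = simulate_catch(sc, "CR1", 2006)
        assert truth["residence_days"] == 15
        assert mdmt(riverine) - mdmt(coastal) == 15

    def test_no_fish_created_in_river(self):
        sc = make_scenario_preset("mixed-13yr", seed=3)
        for year in sc.years:
            coastal, riverine, _ = simulate_catch(sc, "CR4", year)
            assert riverine.sum() <= coastal.sum()
            assert (coastal >= 0).all() and (riverine >= 0).all()

    def test_mdmt_estimator_unbiased_over_replicates(self):
        """Monte-Carlo: mean computed MDMT within 0.5 day of the pulse center."""
        errors = []
        for seed in range(200):
            sc = scenario_with(
                base_cross_day=30.0, arrival_lag=5.0, residence_mean=10,
                pulse_sd=4.0, run_size=1000.0, seed=seed,
                arrival_noise_sd=0.0, residence_noise_sd=0.0, sst_noise_sd=0.0,
            )
            coastal, _, truth = simulate_catch(sc, "CR1", 2006)
            errors.append(mdmt(coastal) - truth["coastal_mdmt"])
        assert abs(np.mean(errors)) < 0.5

    def test_pulse_center_outside_window_is_rejected(self):
        with pytest.raises(ScenarioError, match="outside window"):
            scenario_with(base_cross_day=85.0, arrival_lag=5.0, residence_mean=10)


class TestScenario:
    def test_unknown_regime_label_rejected(self):
        with pytest.raises(ScenarioError, match="regime"):
            scenario_with(regime_sequence=("T4",))

    def test_inverted_ramp_rejected(self):
        with pytest.raises(ScenarioError, match="sst_start > threshold"):
            scenario_with(sst_start=18.0, sst_end=12.0)

    def test_ns_offset_monotonically_widens_t2_gap(self):
        gaps = []
        for offset in (4.0, 8.0, 12.0):
            sc = scenario_with(regime_sequence=("T2",), ns_offset=offset,
                               t2_arrival_advance=0.0)
            north = np.mean([sc.cross_day(r, 2006) for r in ("CR1", "CR2", "CR3")])
            south = np.mean([sc.cross_day(r, 2006) for r in ("CR4", "CR5", "CR6")])
            base_n = np.mean([sc.base_cross(r) for r in ("CR1", "CR2", "CR3")])
            base_s = np.mean([sc.base_cross(r) for r in ("CR4", "CR5", "CR6")])
            gaps.append((south - base_s) - (north - base_n))
        assert gaps[0] < gaps[1] < gaps[2]


class TestPresets:
    def test_mixed_13yr_composition(self):
        sc = make_scenario_preset("mixed-13yr")
        assert len(sc.regime_sequence) == 13
        counts = pd.Series(list(sc.regime_sequence)).value_counts()
        assert counts["T1"] == 3 and counts["T2"] == 5 and counts["T3"] == 5
        assert tuple(sc.regime_sequence) == MIXED_13YR_SEQUENCE

    def test_single_regime_presets(self):
        for name in ("T1-like", "T2-like", "T3-like"):
            sc = make_scenario_preset(name)
            assert set(sc.regime_sequence) == {name[:2]}

    def test_default_t2_advance_is_four_days(self):
        assert make_scenario_preset("mixed-13yr").t2_arrival_advance == 4.0

    def test_unknown_preset(self):
        with pytest.raises(ScenarioError):
            make_scenario_preset("T9-like")


class TestDataset:
    def test_fixed_seed_fixes_dataset_bitwise(self):
        a = simulate_dataset(make_scenario_preset("mixed-13yr", seed=9))
        b = simulate_dataset(make_scenario_preset("mixed-13yr", seed=9))
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.truth == b.truth

    def test_truth_covers_every_region_year(self, noise_free_dataset):
        scenario, ds = noise_free_dataset
        for key in ("crossings", "coastal_mdmt", "riverine_mdmt", "residence_days"):
            for region in scenario.regions:
                assert set(ds.truth[key][region.id]) == {str(y) for y in scenario.years}

    def test_write_read_roundtrip(self, tmp_path, noise_free_dataset):
        from chumrun.simulate import SyntheticDataset

        _, ds = noise_free_dataset
        ds.write(tmp_path)
        back = SyntheticDataset.read(tmp_path)
        pd.testing.assert_frame_equal(
            ds.data.reset_index(drop=True), back.data.reset_index(drop=True),
            check_dtype=False,
        )
        assert back.truth == ds.truth

    def test_adding_a_region_does_not_perturb_existing_series(self):
        sc6 = make_scenario_preset("mixed-13yr", seed=4)
        five = dataclasses.replace(sc6, regions=sc6.regions[:5])
        np.testing.assert_array_equal(
            simulate_sst(sc6, "CR2", 2009), simulate_sst(five, "CR2", 2009)
        )
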