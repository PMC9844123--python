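"""Throughput arithmetic, Poisson occupancy and the run simulator."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from acoustosort.acoustics import AcousticField, FluidSpec
from acoustosort.gating import Gate
from acoustosort.sorter import (
    ChannelGeometry,
    FlowConfig,
    SortPhysics,
    max_in_channel_concentration,
    max_sample_concentration,
    max_sorting_rate,
    occupancy_statistics,
    purity_vs_concentration,
    residence_time,
    simulate_sort,
)
from acoustosort.synthetic import (
    bead_mixture_populations,
    generate_arrival_stream,
    sample_events_for_stream,
)

PER_ML = 1e6  # SI (1/m^3) in one 1/ml


class TestThroughputArithmetic:
    def test_residence_time(self, geometry, flow):
        assert residence_time(geometry, flow) == pytest.approx(2.5e-3)

    def test_residence_time_inverse_in_flow(self, geometry):
        double = FlowConfig(sample_flow=0.02e-9, sheath_flow=0.14e-9)
        assert residence_time(geometry, double) == pytest.approx(1.25e-3)

    def test_residence_time_geometric_volume(self, flow):
        geom = ChannelGeometry()  # 50 x 130 x 30 um^3 = 0.195 nl
        assert residence_time(geom, flow) == pytest.approx(2.44e-3, abs=0.01e-3)

    def test_max_concentration(self, geometry):
        assert max_in_channel_concentration(geometry) == pytest.approx(5e6 * PER_ML)
        half = ChannelGeometry(deformation_channel_side=60e-6,
                               sorting_region_volume=0.4e-12)
        assert max_in_channel_concentration(half) == pytest.approx(2.5e6 * PER_ML)

    def test_max_sorting_rate(self, geometry):
        c_max = max_in_channel_concentration(geometry)
        assert max_sorting_rate(c_max, 0.08e-9) == pytest.approx(400.0)
        assert max_sorting_rate(c_max, 0.04e-9) == pytest.approx(200.0)
        assert max_sorting_rate(c_max, 0.0) == 0.0

    def test_max_sample_concentration(self, geometry):
        c_max = max_in_channel_concentration(geometry)
        assert max_sample_concentration(c_max, 7.0) == pytest.approx(40e6 * PER_ML)
        assert max_sample_concentration(c_max, 0.0) == pytest.approx(c_max)
        assert max_sample_concentration(c_max, 3.0) == pytest.approx(20e6 * PER_ML)

    def test_volume_override_must_match_geometry(self):
        with pytest.raises(ValueError, match="5 %"):
            ChannelGeometry(sorting_region_volume=0.3e-12)


class TestOccupancy:
    def test_mean_occupancy_at_concentration_cap(self, geometry):
        stats_ = occupancy_statistics(5e6 * PER_ML, geometry)
        assert stats_["mean_occupancy"] == pytest.approx(1.0)
        assert stats_["p_at_least_two"] == pytest.approx(0.264, abs=0.001)

    def test_zero_concentration(self, geometry):
        assert occupancy_statistics(0.0, geometry)["p_at_least_one"] == 0.0

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0])
    def test_simulated_occupancy_matches_poisson(self, geometry, flow, lam,
                                                 tsaw_physics, wide_small_gate):
        # choose the concentration giving mean occupancy lam
        conc = lam / geometry.sorting_region_volume
        rate = conc * flow.total_flow
        n_target = 30_000
        rng = np.random.default_rng(100 + int(10 * lam))
        stream = generate_arrival_stream(conc, flow.total_flow, n_target / rate,
                                         mixture={"small": 1.0}, rng=rng)
        pops = bead_mixture_populations(seed=0)
        events = sample_events_for_stream(stream, pops, rng=rng)
        outcome, _ = simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                                   geometry, flow, rng=rng)
        observed = outcome["n_residents_at_arrival"].to_numpy()
        kmax = int(observed.max())
        f_obs = np.bincount(observed, minlength=kmax + 1).astype(float)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), lam)
        pmf[-1] += stats.poisson.sf(kmax, lam)
        f_exp = pmf * len(observed)
        # merge sparse tail bins (expected < 5)
        while len(f_exp) > 2 and f_exp[-1] < 5:
            f_exp[-2] += f_exp[-1]
            f_obs[-2] += f_obs[-1]
            f_exp, f_obs = f_exp[:-1], f_obs[:-1]
        res = stats.chisquare(f_obs, f_exp * f_obs.sum() / f_exp.sum())
        assert res.pvalue > 0.01


class TestSimulateSort:
    def _run(self, geometry, flow, physics, gate, mixture, lam, n_events, seed):
        conc = lam / geometry.sorting_region_volume
        rate = conc * flow.total_flow
        rng = np.random.default_rng(seed)
        stream = generate_arrival_stream(conc, flow.total_flow, n_events / rate,
                                         mixture=mixture, rng=rng)
        pops = bead_mixture_populations(seed=0)
        events = sample_events_for_stream(stream, pops, rng=rng)
        return stream, events, rng

    def test_all_target_dilute_stream_is_perfect(self, geometry, flow,
                                                 tsaw_physics, wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate, {"small": 1.0},
                                        lam=0.001, n_events=2000, seed=1)
        _, rep = simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                               geometry, flow, rng=rng)
        assert rep.target_purity == pytest.approx(100.0)
        assert rep.recovery == pytest.approx(100.0, abs=0.5)

    def test_zero_force_sorts_nothing(self, geometry, flow, wide_small_gate):
        weak = SortPhysics(field=AcousticField(mode="tsaw", frequency=135e6,
                                               energy_density=0.0))
        stream, events, rng = self._run(geometry, flow, weak, wide_small_gate,
                                        {"small": 1.0}, 0.01, 1000, 2)
        outcome, rep = simulate_sort(stream, events, wide_small_gate, weak,
                                     geometry, flow, rng=rng)
        assert rep.recovery == 0.0
        assert (outcome["outlet"] == "default").all()

    def test_contamination_matches_closed_form(self, geometry, flow,
                                               tsaw_physics, separable):
        # 50/50 mixture at total occupancy 0.1 -> bystander occupancy of the
        # other population is 0.05; P(>=1 contaminant at onset) = 1 - e^-0.05
        populations, gate = separable
        conc = 0.1 / geometry.sorting_region_volume
        rate = conc * flow.total_flow
        rng = np.random.default_rng(3)
        stream = generate_arrival_stream(conc, flow.total_flow, 40_000 / rate,
                                         mixture={"target": 0.5, "other": 0.5},
                                         rng=rng)
        events = sample_events_for_stream(stream, populations, rng=rng)
        _, rep = simulate_sort(stream, events, gate, tsaw_physics,
                               geometry, flow, rng=rng)
        lam_other = 0.05
        expected = 1.0 - math.exp(-lam_other)
        se = math.sqrt(expected * (1 - expected) / rep.n_actuated)
        assert abs(rep.pulse_contamination_rate - expected) < 3 * se

    def test_conservation_every_event_has_one_outlet(self, geometry, flow,
                                                     tsaw_physics,
                                                     wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate,
                                        {"small": 0.5, "large": 0.5},
                                        0.5, 5000, 4)
        outcome, rep = simulate_sort(stream, events, wide_small_gate,
                                     tsaw_physics, geometry, flow, rng=rng)
        n_target = (outcome["outlet"] == "target").sum()
        n_default = (outcome["outlet"] == "default").sum()
        assert n_target + n_default == rep.n_total
        assert n_target == rep.n_target_outlet

    def test_throughput_identity(self, geometry, flow, tsaw_physics,
                                 wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate, {"small": 1.0},
                                        0.2, 5000, 5)
        _, rep = simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                               geometry, flow, rng=rng)
        assert rep.throughput == pytest.approx(rep.n_total / rep.duration_s,
                                               rel=0.01)

    def test_abort_policy_trades_recovery_for_purity(self, geometry, flow,
                                                     tsaw_physics,
                                                     wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate,
                                        {"small": 0.5, "large": 0.5},
                                        1.0, 10_000, 6)
        _, rep = simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                               geometry, flow, coincidence_policy="abort",
                               rng=np.random.default_rng(6))
        assert rep.target_purity == pytest.approx(100.0)
        assert rep.n_aborted > 0
        # abort probability should be near 1 - e^-lambda at occupancy 1
        frac_aborted = rep.n_aborted / rep.n_gated
        assert frac_aborted == pytest.approx(1 - math.exp(-1.0), abs=0.03)

    def test_actuated_implies_gated(self, geometry, flow, tsaw_physics,
                                    wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate,
                                        {"small": 0.5, "large": 0.5},
                                        0.5, 3000, 7)
        outcome, _ = simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                                   geometry, flow, rng=rng)
        assert (outcome.loc[outcome["actuated"], "gated"]).all()

    def test_misaligned_inputs_rejected(self, geometry, flow, tsaw_physics,
                                        wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate, {"small": 1.0},
                                        0.1, 200, 8)
        with pytest.raises(ValueError, match="align"):
            simulate_sort(stream, events.iloc[:-1], wide_small_gate,
                          tsaw_physics, geometry, flow)

    def test_long_pulse_warns(self, geometry, flow, tsaw_physics,
                              wide_small_gate):
        stream, events, rng = self._run(geometry, flow, tsaw_physics,
                                        wide_small_gate, {"small": 1.0},
                                        0.01, 100, 9)
        with pytest.warns(UserWarning, match="residence"):
            simulate_sort(stream, events, wide_small_gate, tsaw_physics,
                          geometry, flow, pulse_duration=5e-3, rng=rng)


class TestPurityVsConcentration:
    def test_contamination_monotone_in_concentration(self, geometry, flow,
                                                     tsaw_physics,
                                                     wide_small_gate):
        pops = bead_mixture_populations(seed=0)
        curve = purity_vs_concentration(
            pops, {"small": 0.5, "large": 0.5}, wide_small_gate, tsaw_physics,
            geometry, flow,
            sample_concentrations=np.array([3, 12, 24, 36]) * 1e6 * PER_ML,
            reps=3, n_events=4000, coincidence_policy="co-sort", seed=11)
        tp = curve["tp_mean"].to_numpy()
        assert np.all(np.diff(tp) < 1.0)  # non-increasing within noise

    def test_over_capacity_concentration_warns(self, geometry, flow,
                                               tsaw_physics, wide_small_gate):
        pops = bead_mixture_populations(seed=0)
        with pytest.warns(UserWarning, match="single-occupancy"):
            purity_vs_concentration(
                pops, {"small": 1.0}, wide_small_gate, tsaw_physics, geometry,
                flow, sample_concentrations=[60e6 * PER_ML], reps=1,
                n_events=500, seed=12)

    def test_single_point_consistent_with_simulate_sort(self, geometry, flow,
                                                        tsaw_physics,
                                                        separable):
        populations, gate = separable
        curve = purity_vs_concentration(
            populations, {"target": 1.0}, gate, tsaw_physics, geometry,
            flow, sample_concentrations=[8e6 * PER_ML], reps=1, n_events=2000,
            coincidence_policy="co-sort", seed=13)
        assert curve["tp_mean"].iloc[0] == pytest.approx(100.0)
        assert curve["recovery_mean"].iloc[0] == pytest.approx(100.0, abs=0.5)
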