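import numpy as np
import pytest

from channelflux.core_io.events import EventLog, PermeationEvent
from channelflux.permeation import (
    DetectorParams,
    SiteModel,
    axial_density,
    detect_events,
    flux_summary,
    flux_to_current,
    relative_influx_timing,
    scale_current_linear,
    segment_conductive_phases,
    site_occupancy,
)
from channelflux.synthetic_data import preset_params, simulate_knockon


class TestDetectEvents:
    def test_monotone_influx(self, simple_trajectory):
        z = np.linspace(-2.0, 2.0, 101)
        traj = simple_trajectory({1: z}, times=np.linspace(0, 10, 101))
        events = detect_events(traj, DetectorParams(reference="fixed"))
        assert len(events) == 1
        e = events[0]
        assert e.direction == "influx"
        # crossings of -1.5 and +1.5 on a linear path from -2 to 2 over 10 ns
        assert e.entry_ns == pytest.approx(10 * (0.5 / 4.0), abs=1e-6)
        assert e.exit_ns == pytest.approx(10 * (3.5 / 4.0), abs=1e-6)
        assert e.transit_ns == pytest.approx(7.5, abs=1e-6)

    def test_oscillation_no_event(self, simple_trajectory):
        t = np.linspace(0, 20, 201)
        z = -1.5 + 0.5 * np.sin(t)
        traj = simple_trajectory({1: z}, times=t)
        assert len(detect_events(traj, DetectorParams(reference="fixed"))) == 0

    def test_efflux_detected(self, simple_trajectory):
        z = np.linspace(2.0, -2.0, 101)
        traj = simple_trajectory({1: z}, times=np.linspace(0, 10, 101))
        events = detect_events(traj, DetectorParams(reference="fixed"))
        assert len(events) == 1 and events[0].direction == "efflux"

    def test_return_before_exit_resets_entry(self, simple_trajectory):
        # dip back past the cytosolic plane mid-transit: entry is the LAST crossing
        z = np.concatenate([
            np.linspace(-2.0, -1.0, 21),
            np.linspace(-1.0, -1.8, 17),
            np.linspace(-1.8, 2.0, 39),
        ])
        traj = simple_trajectory({1: z}, times=np.arange(len(z), dtype=float))
        events = detect_events(traj, DetectorParams(reference="fixed"))
        assert len(events) == 1
        assert events[0].entry_ns > 30

    def test_offset_larger_than_half_box_rejected(self, simple_trajectory):
        traj = simple_trajectory({1: np.zeros(5)}, box_z=2.0)
        with pytest.raises(ValueError, match="half the box"):
            detect_events(traj, DetectorParams(boundary_offset_nm=1.5, reference="fixed"))

    def test_translation_invariance_with_com_reference(self, simple_trajectory):
        z = np.linspace(-2.0, 2.0, 101)
        traj = simple_trajectory({1: z}, times=np.linspace(0, 10, 101), box_z=20.0)
        shifted = simple_trajectory({1: z + 3.0}, times=np.linspace(0, 10, 101), box_z=20.0)
        shifted.coords[:, -2:, 2] += 3.0  # protein reference moves too
        e1 = detect_events(traj, DetectorParams(reference="com"))
        e2 = detect_events(shifted, DetectorParams(reference="com"))
        assert len(e1) == len(e2) == 1
        assert e1[0].entry_ns == pytest.approx(e2[0].entry_ns, abs=1e-9)

    @pytest.mark.parametrize("preset", ["malate-high", "chloride-high", "mixed"])
    def test_oracle_equivalence_seed7(self, preset):
        p = preset_params(preset, seed=7, duration_ns=600)
        traj, truth = simulate_knockon(p)
        detected = detect_events(traj)
        assert len(detected) == len(truth.events)
        np.testing.assert_allclose(
            detected.exit_times(), truth.events.exit_times(), atol=p.frame_interval_ns
        )

    def test_conservation_influx_minus_efflux(self, simple_trajectory):
        # A transits in, B transits out, C stays put: net plane flow matches
        # the change of the vacuolar-side population
        zA = np.linspace(-2.0, 2.0, 101)
        zB = np.linspace(2.0, -2.0, 101)
        zC = np.full(101, -2.0)
        traj = simple_trajectory({1: zA, 2: zB, 3: zC}, times=np.linspace(0, 10, 101), box_z=20.0)
        events = detect_events(traj, DetectorParams(reference="fixed"))
        n_in = len(events.filter(direction="influx"))
        n_out = len(events.filter(direction="efflux"))
        vac0 = np.sum(traj.coords[0, :3, 2] > 1.5)
        vac1 = np.sum(traj.coords[-1, :3, 2] > 1.5)
        assert n_in - n_out == vac1 - vac0


class TestFluxArithmetic:
    def test_flow_rate_definition(self):
        events = EventLog(
            [PermeationEvent(i, "chloride", i * 7.0, i * 7.0 + 1.0, "influx") for i in range(142)]
        )
        s = flux_summary(events, duration_ns=1000.0, species="chloride")
        assert s.flow_rate_per_us == pytest.approx(142.0)

    def test_empty_log(self):
        s = flux_summary(EventLog(), duration_ns=1000.0, species="chloride")
        assert s.n_events == 0 and s.current_pA == 0.0 and s.transit_mean_ns is None

    def test_summary_flux_equals_truth_flux(self):
        p = preset_params("mixed", seed=4, duration_ns=800)
        traj, truth = simulate_knockon(p)
        detected = detect_events(traj)
        s = flux_summary(detected, p.duration_ns, species="chloride")
        assert s.flow_rate_per_us == pytest.approx(truth.mean_flux("chloride"))

    def test_paper_rate_142(self):
        assert flux_to_current(142, 1, "influx") == pytest.approx(-22.8, abs=0.05)

    def test_paper_rate_177(self):
        assert flux_to_current(177, 1, "influx") == pytest.approx(-28.4, abs=0.05)

    def test_one_pA_equivalence(self):
        assert abs(flux_to_current(6.24, 1)) == pytest.approx(1.00, abs=0.005)

    def test_zero_rate(self):
        assert flux_to_current(0.0, 1) == 0.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            flux_to_current(-1.0, 1)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            flux_to_current(1.0, 0)

    def test_scaling_identity(self):
        assert scale_current_linear(-22.756, -500, -500) == pytest.approx(-22.756)

    def test_scaling_paper_values(self):
        i142 = flux_to_current(142, 1, "influx")
        i177 = flux_to_current(177, 1, "influx")
        assert scale_current_linear(i142, -500, -80) == pytest.approx(-3.64, abs=0.005)
        assert scale_current_linear(i177, -500, -80) == pytest.approx(-4.54, abs=0.005)

    def test_scaling_is_linear(self):
        assert scale_current_linear(-10.0, -500, -250) == pytest.approx(-5.0)

    def test_scale_from_zero_rejected(self):
        with pytest.raises(ValueError):
            scale_current_linear(-10.0, 0, -80)


class TestConductivePhases:
    def test_gap_rule(self):
        events = EventLog(
            [PermeationEvent(i, "chloride", t - 1, t, "influx") for i, t in enumerate([10, 20, 30, 500, 510])]
        )
        phases = segment_conductive_phases(events, max_gap_ns=50.0)
        assert [(p.n_events, p.start_ns, p.end_ns) for p in phases] == [
            (3, 10.0, 30.0),
            (2, 500.0, 510.0),
        ]

    def test_empty(self):
        assert segment_conductive_phases(EventLog(), 50.0) == []

    def test_poisson_single_phase(self):
        # with max_gap >> 1/lambda all events almost surely form one phase
        n_single = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = np.cumsum(rng.exponential(1.0, size=200))
            events = EventLog(
                [PermeationEvent(i, "chloride", x - 0.5, x, "influx") for i, x in enumerate(t)]
            )
            phases = segment_conductive_phases(events, max_gap_ns=50.0)
            n_single += len(phases) == 1
        # P(any gap > 50) ~ 200 * exp(-50) ~ 0
        assert n_single == 10


class TestSiteOccupancy:
    def _model(self):
        return SiteModel.around({"S1": -1.0, "S2": 0.0, "S3": 1.0}, half_width=0.3)

    def test_parked_ion(self, simple_trajectory):
        traj = simple_trajectory({1: np.zeros(50)})
        occ = site_occupancy(traj, self._model(), params=DetectorParams(reference="fixed"))
        assert np.all(occ.counts["S2"] == 1)
        assert np.all(occ.counts["S1"] == 0) and np.all(occ.counts["S3"] == 0)

    def test_no_ions(self, simple_trajectory):
        traj = simple_trajectory({1: np.zeros(10)})
        occ = site_occupancy(traj, self._model(), species="malate")
        assert all(np.all(v == 0) for v in occ.counts.values())

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SiteModel({"a": (0.0, 1.0), "b": (0.5, 1.5)})

    def test_matches_truth_occupancy(self):
        p = preset_params("chloride-high", seed=2, duration_ns=800)
        traj, truth = simulate_knockon(p)
        occ = site_occupancy(traj, self._model())
        agree = np.ones(len(truth.frame_times), dtype=bool)
        for name in ("S1", "S2", "S3"):
            agree &= occ.counts[name] == (truth.occupancy[name] != "").astype(int)
        assert agree.mean() >= 0.99


class TestRelativeTiming:
    def test_constructed_lags(self):
        mal = EventLog([PermeationEvent(1, "malate", 99, 100, "influx")])
        cl = EventLog(
            [PermeationEvent(i, "chloride", t - 1, t, "influx") for i, t in enumerate([105, 110, 120])]
        )
        hist = relative_influx_timing(cl, mal, window_ns=50.0)
        assert sorted(hist.lags_ns.tolist()) == [5.0, 10.0, 20.0]
        assert hist.n_no_antecedent == 0

    def test_no_conditioning_events(self):
        cl = EventLog([PermeationEvent(1, "chloride", 1, 2, "influx")])
        hist = relative_influx_timing(cl, EventLog(), window_ns=50.0)
        assert hist.n_no_antecedent == 1 and len(hist.lags_ns) == 0

    def test_facilitation_contrast_paired_seeds(self):
        from dataclasses import replace

        mass_on = mass_off = 0
        for seed in range(3):
            p_on = preset_params("mixed", seed=seed, duration_ns=1500)
            _, t_on = simulate_knockon(p_on)
            _, t_off = simulate_knockon(replace(p_on, facilitation=1.0))
            for truth, acc in ((t_on, "on"), (t_off, "off")):
                h = relative_influx_timing(
                    truth.events.filter(species="chloride", direction="influx"),
                    truth.events.filter(species="malate", direction="influx"),
                    window_ns=20.0,
                )
                if acc == "on":
                    mass_on += len(h.lags_ns)
                else:
                    mass_off += len(h.lags_ns)
        assert mass_on > mass_off


class TestAxialDensity:
    def test_stationary_ion_single_bin(self, simple_trajectory):
        traj = simple_trajectory({1: np.full(20, 0.3)})
        edges, dens = axial_density(traj, bins=30, params=DetectorParams(reference="fixed"))
        assert np.sum(dens > 0) == 1

    def test_normalization(self, simple_trajectory):
        rng = np.random.default_rng(0)
        traj = simple_trajectory({i: rng.uniform(-2, 2, 50) for i in range(1, 6)})
        edges, dens = axial_density(traj, bins=20, params=DetectorParams(reference="fixed"))
        assert np.sum(dens * np.diff(edges)) == pytest.approx(5.0)

    def test_uniform_positions_flat(self, simple_trajectory):
        rng = np.random.default_rng(1)
        traj = simple_trajectory(
            {i: rng.uniform(-4.5, 4.5, 2000) for i in range(1, 4)}, box_z=9.0
        )
        edges, dens = axial_density(traj, bins=9, params=DetectorParams(reference="fixed"))
        expected = 3.0 / 9.0
        np.testing.assert_allclose(dens, expected, rtol=0.1)
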