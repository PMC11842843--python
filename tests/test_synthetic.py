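import itertools

import numpy as np
import pytest

from channelflux.synthetic_data import (
    KnockOnParams,
    make_toy_pore,
    preset_params,
    simulate_knockon,
    synth_activation_trace,
)


class TestParamsValidation:
    def test_all_rates_zero(self):
        p = KnockOnParams(entry_rate={}, exit_rate={}, hop_rate={})
        with pytest.raises(ValueError, match="no dynamics"):
            p.validate()

    def test_site_spacing_vs_jitter(self):
        p = KnockOnParams(site_z=(-0.1, 0.0, 0.1), jitter_sd=0.05)
        with pytest.raises(ValueError, match="jitter"):
            p.validate()

    def test_unordered_sites(self):
        with pytest.raises(ValueError, match="increasing"):
            KnockOnParams(site_z=(0.0, -1.0, 1.0)).validate()


class TestKnockOnSimulation:
    def test_seed_reproducibility(self):
        p1 = preset_params("mixed", seed=5, duration_ns=200)
        p2 = preset_params("mixed", seed=5, duration_ns=200)
        t1, tr1 = simulate_knockon(p1)
        t2, tr2 = simulate_knockon(p2)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        assert [e.exit_ns for e in tr1.events] == [e.exit_ns for e in tr2.events]

    def test_different_seeds_differ(self):
        t1, _ = simulate_knockon(preset_params("mixed", seed=1, duration_ns=200))
        t2, _ = simulate_knockon(preset_params("mixed", seed=2, duration_ns=200))
        assert not np.array_equal(t1.coords, t2.coords)

    def test_symmetric_rates_zero_net_flux(self):
        p = KnockOnParams(
            entry_rate={"chloride": 0.3},
            exit_rate={"chloride": 0.5},
            hop_rate={"chloride": 0.5},
            bias=1.0,
            n_chloride=10,
            duration_ns=10000,
            frame_interval_ns=1.0,
            seed=42,
        )
        _, truth = simulate_knockon(p)
        n_in = len(truth.events.filter(direction="influx"))
        n_out = len(truth.events.filter(direction="efflux"))
        assert abs(n_in - n_out) < 3 * np.sqrt(n_in + n_out)

    def test_malate_high_occupancy(self):
        _, truth = simulate_knockon(preset_params("malate-high", seed=0, duration_ns=1000))
        occ = np.mean(truth.total_site_occupancy())
        assert 2.5 <= occ <= 3.0
        # near-continuous truth-event stream: no long silent gaps
        gaps = np.diff(truth.events.filter(direction="influx").exit_times())
        assert np.max(gaps) < 50.0

    def test_chloride_trapping_is_bursty(self):
        _, truth = simulate_knockon(preset_params("chloride-high", seed=0, duration_ns=2000))
        t = truth.events.filter(species="chloride", direction="influx").exit_times()
        counts, _ = np.histogram(t, bins=np.arange(0.0, 2000.1, 50.0))
        assert counts.mean() > 0
        assert counts.var(ddof=1) / counts.mean() > 1.0

    @pytest.mark.parametrize("preset", ["malate-high", "chloride-high", "mixed"])
    def test_no_teleport_except_wrap(self, preset):
        p = preset_params(preset, seed=3, duration_ns=300)
        traj, _ = simulate_knockon(p)
        ions = ~traj.protein_mask
        dz = np.abs(np.diff(traj.coords[:, ions, 2], axis=0))
        box_z = p.box_z
        dz = np.where(dz > box_z / 2, box_z - dz, dz)  # fold periodic wraps
        max_gap = np.max(np.diff(np.asarray(p.site_z)))
        allowed = max_gap + 2 * 0.5 * max_gap  # one site spacing plus jitter clip
        # chained knock-on moves can fire within one frame interval, so a
        # small fraction of steps legitimately exceeds one spacing; every
        # step must stay below half the box so wraps remain unambiguous
        assert np.mean(dz <= allowed) > 0.995
        assert dz.max() < p.box_z / 2

    def test_truth_events_match_coordinates(self):
        """Each truth influx corresponds to a continuous crossing of both planes."""
        p = preset_params("chloride-high", seed=1, duration_ns=500)
        traj, truth = simulate_knockon(p)
        id_to_col = {pid: j for j, pid in enumerate(traj.ids)}
        for e in list(truth.events)[:20]:
            j = id_to_col[e.particle_id]
            i0 = np.searchsorted(traj.times, e.entry_ns) - 1
            i1 = np.searchsorted(traj.times, e.exit_ns) + 1
            z = traj.coords[max(i0, 0) : i1 + 1, j, 2]
            lo, hi = (-p.boundary_nm, p.boundary_nm) if e.direction == "influx" else (
                p.boundary_nm,
                -p.boundary_nm,
            )
            assert np.min(np.abs(z - lo)) < 0.75  # starts near the entry plane
            assert np.min(np.abs(z - hi)) < 0.75  # reaches the exit plane


def _stationary_flux_oracle(entry, hop, exit_, bias, n_sites=3):
    """Net stationary flux (ions/ns) through the vacuolar plane by direct
    solve of the single-species occupancy CTMC with symmetric knock-on
    cascades (independent re-implementation of the documented move rules)."""
    states = list(itertools.product((0, 1), repeat=n_sites))
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))
    vac_flow = np.zeros(len(states))

    def add(s_from, s_to, rate):
        i, j = index[s_from], index[s_to]
        if i != j:
            Q[i, j] += rate

    for s in states:
        s = tuple(s)
        # cytosolic entry with forward cascade
        empties = [k for k in range(n_sites) if s[k] == 0]
        if empties:
            j = min(empties)
            new = list(s)
            new[: j + 1] = [1] * (j + 1)
            add(s, tuple(new), entry * bias)
        else:
            vac_flow[index[s]] += entry * bias  # full chain: entry pushes one out
        # vacuolar entry with backward cascade
        if empties:
            j = max(empties)
            new = list(s)
            new[j:] = [1] * (n_sites - j)
            add(s, tuple(new), entry / bias)
            vac_flow[index[s]] -= entry / bias
        else:
            vac_flow[index[s]] -= entry / bias  # pushes one out the cytosolic side
        for k in range(n_sites):
            if s[k] != 1:
                continue
            # forward hop (cascade; may push the last ion out)
            if k + 1 < n_sites:
                ahead = [j for j in range(k + 1, n_sites) if s[j] == 0]
                new = list(s)
                new[k] = 0
                if ahead:
                    new[k + 1 : min(ahead) + 1] = [1] * (min(ahead) - k)
                else:
                    new[k + 1 :] = [1] * (n_sites - k - 1)
                    vac_flow[index[s]] += hop * bias
                add(s, tuple(new), hop * bias)
            else:
                new = list(s)
                new[k] = 0
                add(s, tuple(new), exit_ * bias)  # vacuolar exit
                vac_flow[index[s]] += exit_ * bias
            # backward hop (mirror cascade)
            if k > 0:
                behind = [j for j in range(k) if s[j] == 0]
                new = list(s)
                new[k] = 0
                if behind:
                    new[max(behind) : k] = [1] * (k - max(behind))
                else:
                    new[:k] = [1] * k
                add(s, tuple(new), hop / bias)
            else:
                new = list(s)
                new[k] = 0
                add(s, tuple(new), exit_ / bias)  # cytosolic exit

    np.fill_diagonal(Q, -Q.sum(axis=1))
    # stationary distribution: pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(len(states))])
    b = np.zeros(len(states) + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(pi @ vac_flow)


class TestStationaryFluxOracle:
    def test_truth_flux_matches_ctmc(self):
        entry, hop, exit_, bias = 0.05, 1.0, 1.0, 1.3
        p = KnockOnParams(
            entry_rate={"chloride": entry},
            exit_rate={"chloride": exit_},
            hop_rate={"chloride": hop},
            bias=bias,
            n_chloride=12,
            recycle_ns=0.5,
            duration_ns=40000,
            frame_interval_ns=10.0,
            seed=7,
        )
        _, truth = simulate_knockon(p)
        n_in = len(truth.events.filter(direction="influx"))
        n_out = len(truth.events.filter(direction="efflux"))
        observed = (n_in - n_out) / p.duration_ns
        expected = _stationary_flux_oracle(entry, hop, exit_, bias)
        se = np.sqrt(n_in + n_out) / p.duration_ns
        assert observed == pytest.approx(expected, abs=4 * se)


class TestToyPores:
    def test_ring_analytic_radius(self):
        _, r = make_toy_pore("ring", wall_radius=5.0, n_per_ring=12, vdw=1.7)
        assert r(np.array([0.0]))[0] == pytest.approx(5.0 - 1.7)

    def test_cylinder_constant_profile(self):
        _, r = make_toy_pore("cylinder", wall_radius=6.0, vdw=1.5, length=20, ring_spacing=1.0)
        z = np.linspace(-9, 9, 50)
        np.testing.assert_allclose(r(z), 4.5, atol=0.05)

    def test_hourglass_waist(self):
        _, r = make_toy_pore(
            "hourglass", waist_radius=3.0, end_radius=8.0, length=20, vdw=1.7, ring_spacing=0.5
        )
        assert r(np.array([0.0]))[0] == pytest.approx(3.0 - 1.7)

    def test_sparse_wall_rejected(self):
        with pytest.raises(ValueError, match="leak"):
            make_toy_pore("ring", wall_radius=8.0, n_per_ring=8, vdw=1.2)

    def test_coarse_ring_spacing_rejected(self):
        with pytest.raises(ValueError, match="leak"):
            make_toy_pore("cylinder", wall_radius=6.0, vdw=1.0, length=20, ring_spacing=3.0)


class TestActivationTraces:
    def test_value_at_zero(self):
        tr = synth_activation_trace(-7.5, -50, -100, 50, 600, 100, dt_ms=1.0)
        assert tr.current_pA[0] == pytest.approx(-7.5)

    def test_asymptote(self):
        tr = synth_activation_trace(-5, -50, -100, 5, 10, 100 * 10, dt_ms=10.0)
        assert tr.current_pA[-1] == pytest.approx(-5 - 50 - 100, abs=1e-6)

    def test_closed_form_single_component(self):
        tr = synth_activation_trace(-5, -40, 0, 50, 1.0, 100, dt_ms=1.0)
        y50 = tr.current_pA[np.searchsorted(tr.time_ms, 50.0)]
        assert y50 == pytest.approx(-5 + -40 * (1 - np.exp(-1.0)), abs=1e-9)

    def test_non_positive_tau_rejected(self):
        with pytest.raises(ValueError):
            synth_activation_trace(0, -50, -100, 0.0, 600, 100)

    def test_seed_reproducible(self):
        a = synth_activation_trace(0, -50, -100, 50, 600, 100, noise_sd=2, seed=9)
        b = synth_activation_trace(0, -50, -100, 50, 600, 100, noise_sd=2, seed=9)
        np.testing.assert_array_equal(a.current_pA, b.current_pA)
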