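"""Per-event metric definitions: amplitude, FDHM, spread, velocity,
initiation sites, firing-site clustering and frequency."""

import numpy as np
import pytest

from caxstm.core import CaEvent, STMap, ValidationError
from caxstm.detect import detect_events
from caxstm.metrics import (amplitude, cluster_sites, fdhm, frequency,
                            initiation_site, spatial_spread, velocity)
from caxstm.synthetic import render_stmap

DT = 1 / 33
PITCH = 0.5


def _event(origin_um, eid=0):
    return CaEvent(id=eid, cell_id="c", onset_time=0.0, peak_time=0.1,
                   amplitude=1.0, fdhm_ms=200.0, spread_um=10.0,
                   velocity_um_s=0.0, origin_um=origin_um,
                   pixels=np.array([[0, 0]]))


class TestAmplitude:
    def test_max_over_footprint(self):
        dff = np.zeros((5, 5))
        dff[2, 3] = 0.9
        pix = np.array([[2, 2], [2, 3], [3, 3]])
        assert amplitude(pix, dff) == 0.9

    def test_scales_linearly_with_dff(self):
        rng = np.random.default_rng(0)
        dff = rng.uniform(0, 1, (10, 10))
        pix = np.argwhere(dff > 0.5)
        assert amplitude(pix, 2 * dff) == pytest.approx(
            2 * amplitude(pix, dff))


class TestFdhm:
    def test_rectangular_pulse_width(self):
        dff = np.zeros((3, 60))
        dff[1, 20:30] = 1.0  # 10-frame pulse
        pix = np.argwhere(dff >= 0.5)
        # half-max crossings interpolate half a frame outside the pulse
        assert fdhm(pix, dff, DT) == pytest.approx(10 * DT * 1000,
                                                   abs=DT * 1000)

    def test_gaussian_profile_closed_form(self):
        # FDHM of a Gaussian = 2 sqrt(2 ln 2) sigma = 235.48 ms for
        # sigma = 100 ms
        t = np.arange(200) * DT
        sigma = 0.1
        trace = np.exp(-0.5 * ((t - 3.0) / sigma) ** 2)
        dff = np.tile(trace, (3, 1))
        pix = np.argwhere(dff >= 0.5)
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma * 1000
        assert fdhm(pix, dff, DT) == pytest.approx(expected,
                                                   abs=DT * 1000 / 2)

    def test_planted_event_recovered(self, single_event):
        stm = render_stmap(single_event(fdhm=200.0, noise_sd=0.0))
        ev = detect_events(stm, noise_sd=0.001)[0]
        assert ev.fdhm_ms == pytest.approx(200.0, abs=DT * 1000)

    def test_clipped_event_flagged(self, single_event):
        # event onsets right at the end of the map: no decay crossing
        stm = render_stmap(single_event(onset=5.85, duration=6.0,
                                        noise_sd=0.0))
        events = detect_events(stm, noise_sd=0.001)
        assert any("fdhm_clipped" in e.flags and np.isnan(e.fdhm_ms)
                   for e in events)

    def test_invariant_to_dff_scaling(self):
        t = np.arange(100) * DT
        trace = np.exp(-0.5 * ((t - 1.5) / 0.08) ** 2)
        dff = np.tile(trace, (3, 1))
        pix = np.argwhere(dff >= 0.5)
        assert fdhm(pix, dff, DT) == pytest.approx(
            fdhm(pix, 5 * dff, DT), abs=1e-9)


class TestSpread:
    def test_single_bin_event_spans_one_pitch(self):
        assert spatial_spread(np.array([[7, 3], [7, 4]]), PITCH) == PITCH

    def test_stationary_gaussian_fwhm(self, single_event):
        stm = render_stmap(single_event(spread=10.0, noise_sd=0.0))
        ev = detect_events(stm, noise_sd=0.001)[0]
        assert ev.spread_um == pytest.approx(10.0, abs=PITCH)

    def test_moving_event_spread_adds_travel(self, single_event):
        # union-across-frames extent for a travelling event: compare
        # against the closed-form envelope of the kinetic model,
        # extent = max_t [c(t) + w(t)] - min_t [c(t) - w(t)] with
        # w(t) = sigma sqrt(2 ln(2 f(t))) where f >= 1/2
        from caxstm.synthetic import temporal_profile, peak_lag
        v, fdhm_ms, fwhm = 40.0, 250.0, 8.0
        stm = render_stmap(single_event(spread=fwhm, vel=v, fdhm=fdhm_ms,
                                        noise_sd=0.0))
        ev = detect_events(stm, noise_sd=0.001)[0]
        t = np.linspace(0, 4.0, 40001)
        f = temporal_profile(t, 2.0, fdhm_ms / 1000.0, 1.0)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        half = f >= 0.5
        w = sigma * np.sqrt(2 * np.log(2 * f[half]))
        c = 30.0 + v * (t[half] - 2.0)
        expected = (c + w).max() - (c - w).min()
        assert ev.spread_um > fwhm + 2 * PITCH  # travel widens the event
        assert ev.spread_um == pytest.approx(expected, abs=2 * PITCH)


class TestVelocity:
    def test_stationary_event_near_zero(self, single_event):
        stm = render_stmap(single_event(vel=0.0))
        ev = detect_events(stm)[0]
        dur = ev.end_time - ev.onset_time
        assert abs(ev.velocity_um_s) <= PITCH / dur + 1.0

    def test_planted_wave_recovered(self, single_event):
        stm = render_stmap(single_event(vel=20.0))
        ev = detect_events(stm)[0]
        assert ev.velocity_um_s == pytest.approx(20.0, rel=0.10)

    def test_sign_flips_with_direction(self, single_event):
        fwd = detect_events(render_stmap(single_event(vel=15.0,
                                                      origin=30.0)))[0]
        bwd = detect_events(render_stmap(single_event(vel=-15.0,
                                                      origin=70.0)))[0]
        assert fwd.velocity_um_s > 0 > bwd.velocity_um_s
        assert abs(fwd.velocity_um_s + bwd.velocity_um_s) < 2.0

    def test_too_brief_event_undefined(self):
        dff = np.zeros((5, 10))
        dff[2, 3:5] = 1.0
        pix = np.argwhere(dff > 0.5)
        assert np.isnan(velocity(pix, dff, PITCH, DT))


class TestInitiationSite:
    def test_single_bin_birth(self):
        pix = np.array([[10, 5], [10, 6], [11, 6]])
        assert initiation_site(pix, PITCH) == (10 + 0.5) * PITCH

    def test_symmetric_two_bin_birth_is_midpoint(self):
        pix = np.array([[10, 5], [12, 5], [11, 6]])
        assert initiation_site(pix, PITCH) == (11 + 0.5) * PITCH

    def test_planted_origin_recovered(self, single_event):
        stm = render_stmap(single_event(origin=40.0, noise_sd=0.0))
        ev = detect_events(stm, noise_sd=0.001)[0]
        assert ev.origin_um == pytest.approx(40.0, abs=2 * PITCH)


class TestClusterSites:
    def test_identical_origins_one_site(self):
        events = [_event(25.0, i) for i in range(4)]
        assert len(cluster_sites(events)) == 1

    def test_forced_two_clusters(self):
        events = [_event(10.0, 0), _event(11.0, 1), _event(40.0, 2)]
        sites = cluster_sites(events, merge_radius=2.0)
        assert len(sites) == 2
        assert sorted(s.n_events for s in sites) == [1, 2]

    def test_chaining_is_single_linkage(self):
        # 10, 11.5, 13 chain into one site at radius 2 though the
        # extremes are 3 apart
        events = [_event(x, i) for i, x in enumerate([10.0, 11.5, 13.0])]
        assert len(cluster_sites(events, merge_radius=2.0)) == 1

    def test_well_separated_planted_sites_recovered(self):
        from caxstm.synthetic import SimulationConfig, plan_events
        sites = [10.0, 25.0, 45.0, 70.0, 90.0]
        cfg = SimulationConfig(duration=40.0, base_rate=1.0,
                               site_positions=sites, seed=2,
                               velocity_range=(0.0, 0.0))
        stm = render_stmap(plan_events(cfg))
        events = detect_events(stm)
        found = cluster_sites(events, merge_radius=3.0)
        assert len(found) == 5
        for s, p in zip(sorted(x.position_um for x in found), sites):
            assert s == pytest.approx(p, abs=2.0)


class TestFrequency:
    def test_events_per_cell_per_second(self):
        assert frequency(10, 5.0, 1) == 2.0
        assert frequency(0, 5.0, 1) == 0.0
        assert frequency(12, 3.0, 4) == 1.0

    def test_additive_over_disjoint_windows(self):
        n1, n2, w = 7, 5, 10.0
        f_joint = frequency(n1 + n2, 2 * w)
        assert f_joint == pytest.approx(
            (frequency(n1, w) + frequency(n2, w)) / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            frequency(1, 0.0)
        with pytest.raises(ValidationError):
            frequency(1, 1.0, 0)
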