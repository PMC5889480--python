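"""Detection-chain contracts: differentiation, smoothing, SNR
thresholding, particle labeling and end-to-end event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caxstm.core import STMap, ValidationError
from caxstm.detect import (DetectionParams, detect_events, differentiate,
                           estimate_noise_sd, label_particles, smooth,
                           threshold_snr)
from caxstm.synthetic import render_stmap


def _stmap(dff, dt=1 / 33, pitch=0.5):
    f0 = 100.0
    return STMap(raw_F=f0 * (1 + dff), dff=dff, position_pitch=pitch,
                 frame_interval=dt)


class TestDifferentiate:
    def test_constant_map_is_zero(self):
        D = differentiate(_stmap(np.full((10, 100), 0.3)), 0.5)
        k = round(0.5 * 33)
        assert np.isnan(D[:, :k]).all()
        np.testing.assert_allclose(D[:, k:], 0.0, atol=1e-12)

    def test_linear_ramp_returns_slope(self):
        t = np.arange(100) / 33
        dff = np.tile(0.7 * t, (5, 1))
        D = differentiate(_stmap(dff), 0.5)
        np.testing.assert_allclose(D[:, 17:], 0.7, atol=1e-9)

    def test_diff_dt_below_frame_interval_rejected(self):
        with pytest.raises(ValidationError):
            differentiate(_stmap(np.zeros((5, 100))), 0.01)

    def test_rate_peak_not_after_dff_peak(self, single_event):
        stm = render_stmap(single_event(noise_sd=0.0))
        dmax = np.where(np.isnan(differentiate(stm, 0.5)), -np.inf,
                        differentiate(stm, 0.5)).max(axis=0)
        t_dff = np.argmax(stm.dff.max(axis=0))
        # with the 0.5-s window the difference tracks dF/F0 itself, so
        # the rate peak coincides with the fluorescence peak ...
        assert np.argmax(dmax) <= t_dff
        # ... and strictly precedes it once the window is shorter than
        # the event's rise time (use a slow event so the rise spans
        # several frames)
        slow = render_stmap(single_event(fdhm=600.0, noise_sd=0.0))
        dmax_short = np.where(
            np.isnan(differentiate(slow, 0.1)), -np.inf,
            differentiate(slow, 0.1)).max(axis=0)
        assert np.argmax(dmax_short) < np.argmax(slow.dff.max(axis=0))


class TestSmooth:
    def test_constant_preserved_exactly(self):
        out = smooth(np.full((50, 20), 3.14), 1.0, 3.3, 0.5)
        np.testing.assert_allclose(out, 3.14, atol=1e-12)

    def test_impulse_response_is_unit_sum_kernel(self):
        arr = np.zeros((41, 1))
        arr[20, 0] = 1.0
        out = smooth(arr, 1.0, 3.3, 0.5)
        kernel = out[out[:, 0] > 0, 0]
        assert kernel.size == 7  # 3.3 um / 0.5 um/bin -> radius 3
        assert kernel.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(out[:, 0]) == 20

    def test_column_sums_preserved(self):
        rng = np.random.default_rng(0)
        arr = np.zeros((60, 10))
        arr[20:40] = rng.uniform(0, 1, (20, 10))  # mass away from borders
        out = smooth(arr, 1.0, 3.3, 0.5)
        np.testing.assert_allclose(out.sum(axis=0), arr.sum(axis=0),
                                   atol=1e-10)


class TestThreshold:
    def test_threshold_level_analytic(self):
        # 25 dB amplitude ratio: 10^(25/20) * 0.01 = 0.1778279...
        arr = np.array([[0.1778, 0.1779]])
        mask = threshold_snr(arr, 25.0, 0.01)
        assert mask.tolist() == [[False, True]]
        assert 0.01 * 10 ** (25 / 20) == pytest.approx(0.17783, abs=5e-6)

    def test_all_below_threshold_empty(self):
        assert not threshold_snr(np.full((5, 5), 0.1), 25.0, 0.01).any()

    def test_mask_monotone_in_snr(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 0.5, (30, 30))
        m_lo = threshold_snr(arr, 20.0, 0.01)
        m_hi = threshold_snr(arr, 25.0, 0.01)
        assert np.all(m_lo[m_hi])  # higher-dB mask is a subset

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValidationError):
            threshold_snr(np.zeros((2, 2)), 25.0, 0.0)

    def test_power_convention_switch(self):
        arr = np.array([[0.2, 3.2]])
        assert threshold_snr(arr, 25.0, 0.01,
                             db_convention="power").tolist() == \
            [[False, True]]


class TestNoiseEstimate:
    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 0.02, (200, 100))
        assert estimate_noise_sd(arr) == pytest.approx(0.02, rel=0.10)

    def test_constant_map_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_noise_sd(np.full((10, 10), 5.0)) == 0.0

    def test_robust_to_sparse_events(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(0, 0.02, (200, 100))
        idx = rng.choice(arr.size, size=int(0.08 * arr.size), replace=False)
        arr.ravel()[idx] += 1.0  # <10% active pixels
        assert estimate_noise_sd(arr) == pytest.approx(0.02, rel=0.15)


def _flood_fill_oracle(mask, connectivity):
    """Brute-force BFS labeling, independent of scipy."""
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                stack = [(r, c)]
                labels[r, c] = nxt
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        r2, c2 = rr + dr, cc + dc
                        if 0 <= r2 < mask.shape[0] and \
                                0 <= c2 < mask.shape[1] and \
                                mask[r2, c2] and labels[r2, c2] == 0:
                            labels[r2, c2] = nxt
                            stack.append((r2, c2))
    return labels


class TestLabelParticles:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        assert len(label_particles(mask)) == 2

    def test_min_area_discards_isolated_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert label_particles(mask, min_area=2) == []
        assert len(label_particles(mask, min_area=1)) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        for _ in range(100):
            mask = rng.uniform(size=(20, 50)) < 0.35
            got = label_particles(mask, min_area=1,
                                  connectivity=connectivity)
            oracle = _flood_fill_oracle(mask, connectivity)
            assert len(got) == oracle.max()
            # identical partitions: every particle maps to exactly one
            # oracle label covering the same pixel set
            for p in got:
                labs = oracle[p.pixels[:, 0], p.pixels[:, 1]]
                assert len(set(labs.tolist())) == 1
                assert (oracle == labs[0]).sum() == p.area

    def test_ids_ordered_by_first_frame_then_bin(self):
        mask = np.zeros((10, 20), bool)
        mask[7:9, 2:4] = True    # early frame, high bin
        mask[1:3, 2:4] = True    # early frame, low bin
        mask[4:6, 10:12] = True  # later frame
        parts = label_particles(mask)
        firsts = [(p.pixels[:, 1].min(), p.pixels[:, 0].min())
                  for p in parts]
        assert firsts == sorted(firsts)


class TestDetectEvents:
    def test_noiseless_single_event_detected_once(self, single_event):
        stm = render_stmap(single_event(noise_sd=0.0))
        events = detect_events(stm, noise_sd=0.001)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(1.0, abs=0.02)

    def test_empty_map_yields_no_events(self):
        rng = np.random.default_rng(6)
        dff = rng.normal(0, 0.01, (50, 200))
        assert detect_events(_stmap(dff)) == []

    def test_event_count_monotone_in_snr_threshold(self, single_event):
        # monotonicity holds for well-separated events (dense activity
        # can merge under a lower threshold, reducing the count)
        from caxstm.synthetic import SimulationConfig, plan_events
        cfg = SimulationConfig(duration=20.0, seed=11, base_rate=0.25,
                               site_positions=[15.0, 50.0, 85.0])
        stm = render_stmap(plan_events(cfg))
        counts = [len(detect_events(stm, DetectionParams(snr_db=db)))
                  for db in (20.0, 25.0, 30.0)]
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > 0

    def test_intensity_equivariance(self, single_event):
        # scaling dff and noise_sd together leaves detections unchanged
        stm = render_stmap(single_event(seed=3))
        e1 = detect_events(stm, noise_sd=0.015)
        stm2 = STMap(raw_F=stm.raw_F, dff=stm.dff * 2.5,
                     position_pitch=stm.position_pitch,
                     frame_interval=stm.frame_interval)
        e2 = detect_events(stm2, noise_sd=0.015 * 2.5)
        assert len(e1) == len(e2) == 1
        np.testing.assert_array_equal(e1[0].pixels, e2[0].pixels)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(db=st.floats(min_value=15.0, max_value=35.0),
           min_area=st.integers(min_value=1, max_value=6))
    def test_counts_never_increase_with_stricter_params(self, db, min_area):
        from caxstm.synthetic import SimulationConfig, plan_events
        stm = render_stmap(plan_events(
            SimulationConfig(duration=10.0, seed=21, base_rate=0.3,
                             site_positions=[20.0, 55.0, 90.0])))
        lo = len(detect_events(stm, DetectionParams(snr_db=db,
                                                    min_area=min_area)))
        hi = len(detect_events(stm, DetectionParams(snr_db=db + 3.0,
                                                    min_area=min_area + 1)))
        assert hi <= lo
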