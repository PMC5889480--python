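import warnings

import numpy as np
import pytest

from caxstm.synthetic import (GroundTruth, GroundTruthEvent,
                              SimulationConfig, peak_lag)


@pytest.fixture(autouse=True)
def _quiet_clipping_warnings():
    """Event-clipping warnings are expected for random event times near
    the end of a map and are irrelevant to most tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*clipped.*")
        yield


@pytest.fixture
def single_event():
    """Factory for a one-event ground truth with controllable kinetics."""

    def make(fdhm=200.0, spread=11.0, vel=0.0, amp=1.0, seed=0,
             origin=None, onset=2.0, duration=6.0, noise_sd=1.0,
             **config_kw):
        if origin is None:
            origin = 50.0 if vel <= 0 else 30.0
        cfg = SimulationConfig(duration=duration, base_rate=0.0,
                               noise_sd=noise_sd, seed=seed, **config_kw)
        ev = GroundTruthEvent(
            site_id=0, onset_time=onset,
            peak_time=onset + peak_lag(fdhm / 1000.0),
            amplitude=amp, fdhm=fdhm, spread_fwhm=spread, velocity=vel,
            origin_position=origin)
        return GroundTruth(events=[ev], config=cfg,
                           site_positions=np.array([origin]))

    return make
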