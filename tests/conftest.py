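"""Shared fixtures: seeded synthetic fusion-event ensembles.

The heavy ensembles are session-scoped: rendered once, analyzed by the
full detection/linking/segmentation/fitting pipeline, and reused by the
round-trip, distribution and acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

from cubofuse import fusion_kinetics as fk
from cubofuse import synthetic_tirf as st


def _analyze_ensemble(batches):
    """Run the full pipeline on each movie and match events to ground truth."""
    analyzed = []
    for scene, events, movie, gt in batches:
        evs = fk.analyze_movie(movie, scene.pixel_size, scene.frame_interval)
        matches = []
        for ev in evs:
            d = np.hypot(gt["x_um"] - ev.position[0], gt["y_um"] - ev.position[1])
            matches.append(gt.iloc[int(d.idxmin())])
        analyzed.append({"scene": scene, "gt": gt, "events": evs,
                         "matches": matches})
    return analyzed


@pytest.fixture(scope="session")
def sixth_exponent_ensemble():
    """200 fusion events decaying with the finite-source exponent n = 1/6.

    Lognormal sizes (mean 200 nm, sigma_log 0.3) modulate amplitudes,
    Poisson + Gaussian (sigma 2) camera noise at SNR ~10, 0.03 s frames.
    """
    batches = st.fusion_event_ensemble(n_events=200, seed=1)
    return _analyze_ensemble(batches)


@pytest.fixture(scope="session")
def fast_decay_ensemble():
    """100 point-source-like events (n = 1) that fully fuse in-movie.

    Rendered brighter (SNR ~20): a decay this steep leaves only ~a/floor
    usable samples, so dim fast events are legitimately refused by the
    fitter — physically these are the bright, rapid flashes.
    """
    batches = st.fusion_event_ensemble(n_events=100, seed=2, n=1.0,
                                       n_frames=160, snr=20.0)
    return _analyze_ensemble(batches)


@pytest.fixture(scope="session")
def half_exponent_ensemble():
    """60 events with an intermediate decay exponent n = 0.5."""
    batches = st.fusion_event_ensemble(n_events=60, seed=3, n=0.5,
                                       n_frames=160, snr=20.0)
    return _analyze_ensemble(batches)


def peak_pixel_amplitude(row, ev, scene):
    """Ground-truth amplitude of the trace's peak pixel.

    The extractor reads the pixel nearest the docked position, so the
    amplitude it can recover is the continuous peak attenuated by the
    sub-pixel offset through the PSF.
    """
    xpix = round(ev.position[0] / scene.pixel_size)
    ypix = round(ev.position[1] / scene.pixel_size)
    d = np.hypot(row["x_um"] / scene.pixel_size - xpix,
                 row["y_um"] / scene.pixel_size - ypix)
    return row["a"] * np.exp(-d**2 / (2 * scene.psf_sigma_px**2))
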