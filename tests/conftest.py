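"""Shared fixtures: phantom scenes and one full measured-velocimetry session.

The expensive fixtures are session-scoped so the displacement-estimation run
on the 96^3 breathing phantom is performed once and shared between the
velocimetry accuracy tests and the expansion-map fidelity tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import xvlung as xv


def make_speckle(shape=(48, 48, 48), grain=4.0, seed=0, mean=0.22, contrast=0.06):
    """Band-passed speckle texture for controlled-shift velocimetry tests."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(shape)
    g = grain / 4.0
    band = ndimage.gaussian_filter(w, g) - ndimage.gaussian_filter(w, 2.5 * g)
    return mean + contrast * band / band.std()


@pytest.fixture(scope="session")
def speckle48():
    return make_speckle()


@pytest.fixture(scope="session")
def measured_run_96():
    """One noise-free breathing phantom analysed by the measured engine.

    Conditions: 96^3 grid, heterogeneous profile with the expansion noise
    correlated over ~2 XV voxels (kernel 16 at stride 8) so the XV grid can
    resolve it, speckle grain 2 so 16^3 interrogation windows contain ~500
    grains (proportionate to the reference 64^3-window configuration).
    """
    cfg = xv.PhantomConfig(
        grid_shape=(96, 96, 96),
        profile="heterogeneous",
        sigma_main=0.03,
        smooth_vox=16.0,
        speckle_grain=2.0,
        seed=3,
    )
    res = xv.simulate_animal(cfg, with_images=True)
    fields = xv.estimate_displacements(
        res["volumes"], window_size=16, overlap_fraction=0.5, mask=res["truth"].lung_mask
    )
    truth_fields = xv.ground_truth_fields(res["truth"], 16, 0.5)
    return {
        "config": cfg,
        "volumes": res["volumes"],
        "truth": res["truth"],
        "curve": res["curve"],
        "fields": fields,
        "truth_fields": truth_fields,
    }


@pytest.fixture(scope="session")
def healthy_truth_64():
    """Truth-engine phantom (no rendered images) at 64^3, healthy profile."""
    from xvlung.pipeline import _attach_truth_fields

    cfg = xv.PhantomConfig(grid_shape=(64, 64, 64), profile="healthy", seed=11)
    res = xv.simulate_animal(cfg)
    _, truth = _attach_truth_fields(res["truth"], res["curve"], cfg)
    return {"config": cfg, "truth": truth, "curve": res["curve"]}


def window_mean_truth(truth, window: int, stride: int):
    """Lung-restricted window means of the true expansion, plus coverage."""
    from xvlung.velocimetry import _grid_positions

    e, lm = truth.expansion_map, truth.lung_mask
    starts = [_grid_positions(n, window, stride) for n in lm.shape]
    shape = tuple(len(s) for s in starts)
    gt = np.full(shape, np.nan)
    cov = np.zeros(shape)
    for i, z0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, x0 in enumerate(starts[2]):
                bm = lm[z0 : z0 + window, y0 : y0 + window, x0 : x0 + window]
                cov[i, j, k] = bm.mean()
                if bm.any():
                    gt[i, j, k] = e[z0 : z0 + window, y0 : y0 + window, x0 : x0 + window][bm].mean()
    return gt, cov
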