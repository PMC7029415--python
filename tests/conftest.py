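"""Shared fixtures: small synthetic movies with ground truth.

All fixtures are generated programmatically at session scope so the slower
rendered movies are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import erktrace as ek


@pytest.fixture(scope="session")
def quiet_acq() -> ek.AcquisitionConfig:
    """Noise-free acquisition for exactness oracles (20 frames, 200x200)."""
    return ek.AcquisitionConfig(
        n_frames=20, image_size=(200, 200), noise=ek.NoiseModel(0.0, 0.0), seed=0
    )


@pytest.fixture(scope="session")
def quiet_movie(quiet_acq):
    """Six non-dividing cells, noise-free render, plus ground truth."""
    truth = ek.simulate_cohort(
        6, ek.FatePreset("quiet", p_mitosis=0.0), ek.basal_stochastic(), quiet_acq, seed=3
    )
    stack = ek.render_frames(truth, quiet_acq, seed=None)
    return truth, stack


@pytest.fixture(scope="session")
def quiet_result(quiet_movie, quiet_acq):
    truth, stack = quiet_movie
    return truth, ek.process_movie(stack, quiet_acq)


@pytest.fixture(scope="session")
def mitosis_movie():
    """Eight cells all programmed to divide early; noise-free render."""
    acq = ek.AcquisitionConfig(
        n_frames=120, image_size=(300, 300), noise=ek.NoiseModel(0.0, 0.0), seed=0
    )
    preset = ek.FatePreset(
        "mito",
        p_mitosis=1.0,
        window_hours=4.0,
        g2_delay_mu_log=float(np.log(2.0)),
        g2_delay_sigma_log=0.3,
    )
    truth = ek.simulate_cohort(8, preset, ek.basal_stochastic(), acq, seed=7)
    stack = ek.render_frames(truth, acq, seed=None)
    result = ek.process_movie(stack, acq)
    return truth, result, acq


def match_tracks_to_truth(truth: ek.GroundTruthTable, tracks_df) -> dict[int, int]:
    """Map measured cell_id -> ground-truth cell_id by frame-0 centroid."""
    t0 = truth.frame_rows(0)
    mapping = {}
    for row in tracks_df[tracks_df["frame"] == 0].itertuples(index=False):
        d2 = (t0["y"] - row.centroid_y) ** 2 + (t0["x"] - row.centroid_x) ** 2
        mapping[row.cell_id] = int(t0.iloc[int(np.argmin(d2.values))]["cell_id"])
    return mapping
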