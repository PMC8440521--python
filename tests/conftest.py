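"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fusionmode import KineticParams, ImagingParams, RoiGeometry
from fusionmode.config import load_config
from fusionmode.pipeline import analyze_cell, match_events
from fusionmode.render import default_channels, generate_dataset

MASTER_SEED = 7


@pytest.fixture()
def kinetics() -> KineticParams:
    return KineticParams()


@pytest.fixture()
def small_imaging() -> ImagingParams:
    """64 x 64 field, 80 frames at 2 Hz: enough for single-event renders."""
    return ImagingParams(field_size=(64, 64), n_frames=80, seed=0)


@pytest.fixture()
def geometry() -> RoiGeometry:
    return RoiGeometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(MASTER_SEED)


def _run_pipeline(cells, cfg):
    """Analyze every cell; return (ground truth + matches, calls) frames."""
    import pandas as pd

    matched, calls_all = [], []
    for cell in cells:
        events, calls = analyze_cell(cell.movies, cfg, cell.cell_id)
        m = match_events(cell.ground_truth, events)
        det_mode = calls.set_index("event_id")["mode"]
        m["called_mode"] = [
            det_mode.get(d, "none") if d >= 0 else "none" for d in m["det_event_id"]
        ]
        matched.append(m)
        calls["cell_id"] = cell.cell_id
        calls_all.append(calls)
    return pd.concat(matched, ignore_index=True), pd.concat(calls_all, ignore_index=True)


@pytest.fixture(scope="session")
def mixture_config():
    return load_config(None, {
        "simulate.field_size": [192, 192],
        "simulate.seed": MASTER_SEED,
        "simulate.mode_probabilities": [0.6, 0.3, 0.1],
    })


@pytest.fixture(scope="session")
def mixture_dataset(mixture_config):
    """10 cells x 20 events, mode mix (0.6, 0.3, 0.1), default SNR, high HEPES."""
    cfg = mixture_config
    return generate_dataset(10, 20, cfg.kinetics, default_channels(),
                            cfg.imaging, "high", noise=True)


@pytest.fixture(scope="session")
def mixture_results(mixture_dataset, mixture_config):
    """Full detect -> quantify -> classify run over the mixture dataset."""
    return _run_pipeline(mixture_dataset, mixture_config)


@pytest.fixture(scope="session")
def clean_results(mixture_config):
    """Noise-disabled pipeline run (smaller: 3 cells x 15 events)."""
    cfg = mixture_config
    imaging = dataclasses.replace(cfg.imaging, seed=MASTER_SEED + 1)
    cells = generate_dataset(3, 15, cfg.kinetics, default_channels(),
                             imaging, "high", noise=False)
    return _run_pipeline(cells, cfg)
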