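"""Shared fixtures: small synthetic movies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from memfoci import (ImagingConfig, TrackingConfig, analyze_movie,
                     render_movie, simulate_cell_population, wt_scenario)


@pytest.fixture(scope="session")
def imaging_small() -> ImagingConfig:
    return ImagingConfig(image_shape=(256, 256), frames=120)


@pytest.fixture(scope="session")
def tracking_cfg() -> TrackingConfig:
    return TrackingConfig()


@pytest.fixture(scope="session")
def wt_bundle(imaging_small, tracking_cfg):
    """One small rendered wild-type movie with ground truth and full
    pipeline results (segmentation, tracks, fits, per-cell table)."""
    scenario = wt_scenario(n_cells=4)
    rng = np.random.default_rng(424242)
    truth, cells = simulate_cell_population(scenario, imaging_small, rng)
    movie, bright_field = render_movie(truth, imaging_small, rng, cells=cells)
    result = analyze_movie(movie, bright_field, imaging_small, tracking_cfg,
                           name="wt")
    return {"scenario": scenario, "truth": truth, "cells": cells,
            "movie": movie, "bright_field": bright_field, "result": result}
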