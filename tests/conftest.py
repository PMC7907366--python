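"""Shared fixtures: small rendered scenes and one full recovery run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conformetry.afm_image import analyze_heightmap
from conformetry.synthetic_afm import (ScanConfig, reduced_condition_model,
                                       render_heightmap, sample_population)


@pytest.fixture(scope="session")
def quiet_scan() -> ScanConfig:
    """Noise-free, tilt-free imaging geometry for deterministic checks."""
    return ScanConfig(noise_sigma_nm=0.0, line_offset_sigma_nm=0.0,
                      plane_tilt=(0.0, 0.0))


@pytest.fixture(scope="session")
def default_scan() -> ScanConfig:
    return ScanConfig()


@pytest.fixture(scope="session")
def rendered_scene(default_scan):
    """One default-noise image of 40 molecules plus its ground truth."""
    specs = sample_population(40, reduced_condition_model(seed=11),
                              geometry_defaults=default_scan)
    hmap, truth = render_heightmap(specs, default_scan, seed=12)
    return hmap, truth


@pytest.fixture(scope="session")
def afm_recovery():
    """End-to-end recovery run: 320 molecules at default imaging noise.

    Returns (records, truth) concatenated over batches; used by the
    open-fraction / mean-R recovery checks.
    """
    scan = ScanConfig()
    recs, truths = [], []
    for batch in range(8):
        specs = sample_population(40, reduced_condition_model(seed=300 + batch),
                                  geometry_defaults=scan)
        hmap, truth = render_heightmap(specs, scan, seed=400 + batch)
        recs.append(analyze_heightmap(hmap, tip_radius_nm=scan.tip_radius_nm))
        truths.append(truth)
    return pd.concat(recs, ignore_index=True), pd.concat(truths, ignore_index=True)
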