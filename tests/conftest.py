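"""Shared fixtures: generated datasets and their feature tables.

Everything is generated at test time from the synthetic notochord module;
session scope keeps the (cheap) generation and feature extraction from
repeating across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from notomorph import morphospace as ms

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from notomorph import shape_metrics as sm
from notomorph import synthetic as syn


@pytest.fixture(scope="session")
def fixture_shapes():
    """Label volume of analytic shapes + expected closed-form metric table."""
    return syn.generate_fixture_shapes(voxel_size_um=0.5)


@pytest.fixture(scope="session")
def fixture_features(fixture_shapes):
    volume, expected = fixture_shapes
    cells = sm.extract_cells(volume, 0.5)
    feats = sm.feature_table(cells)
    return feats, expected


@pytest.fixture(scope="session")
def trunk_data():
    """Trunk-region central-cell dataset: 5 stages x 100 cells, fixed seed."""
    data = syn.generate_notochord(syn.trunk_config(seed=11))
    cells = sm.extract_cells(data.volume, data.voxel_size_um, data.nucleus_table)
    feats = sm.feature_table(cells, data.annotations)
    return data, feats


@pytest.fixture(scope="session")
def default_data():
    """Full dataset with central + Müller rows and the mid-to-tips gradient."""
    data = syn.generate_notochord(syn.default_config(seed=7))
    cells = sm.extract_cells(data.volume, data.voxel_size_um, data.nucleus_table)
    feats = sm.feature_table(cells, data.annotations)
    return data, feats


@pytest.fixture(scope="session")
def trunk_morphospace(trunk_data):
    _, feats = trunk_data
    model = ms.fit_morphospace(feats, n_components=5)
    coords = ms.embed(model, feats)
    return model, coords


@pytest.fixture(scope="session")
def default_morphospace(default_data):
    _, feats = default_data
    model = ms.fit_morphospace(feats, n_components=5)
    coords = ms.embed(model, feats)
    return model, coords


@pytest.fixture(scope="session")
def superellipsoid_cells():
    return syn.random_superellipsoid_cells(n=50, voxel_size_um=0.5, seed=3)
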