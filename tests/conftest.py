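import warnings

import numpy as np
import pytest

import dbsconn
from dbsconn.grids import GridSpec
from dbsconn.stimulation_model import ScalarField, VAT, point_source_field


@pytest.fixture(scope="session")
def default_cohort():
    """One fully synthesised default study cohort, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dbsconn.synthesise_cohort(seed=1)


@pytest.fixture(scope="session")
def table1():
    participants, endpoints = dbsconn.make_table1_fixture()
    return participants, endpoints


def toy_instance(seed=0, n_participants=4, grid_shape=(5, 5, 4)):
    """A <=100-voxel toy: 5 short streamlines, one field/VAT per participant.

    Geometry is randomised but kept inside the grid; contacts move between
    participants so connection patterns differ.
    """
    rng = np.random.default_rng(seed)
    grid = GridSpec(grid_shape, voxel_size=1.0)
    streamlines = []
    for _ in range(5):
        start = rng.uniform([0.3, 0.3, 0.3], [1.5, 1.5, 1.2])
        end = rng.uniform([3.0, 3.0, 2.2], [4.6, 4.6, 3.6])
        mid = (start + end) / 2 + rng.normal(0, 0.3, 3)
        streamlines.append(np.vstack([start, mid, end]))
    centres = grid.voxel_centres().reshape(-1, 3)
    fields, vats = [], []
    for i in range(n_participants):
        contact = rng.uniform([1.0, 1.0, 0.8], [4.0, 4.0, 3.0])
        vals = point_source_field(centres, contact[None, :], 2.0).reshape(grid.shape)
        field = ScalarField(vals, grid)
        thr = np.quantile(vals, 0.6)  # keeps the VAT partial but non-empty
        vats.append(VAT(mask=vals >= thr, grid=grid, threshold=float(thr)))
        fields.append(field)
    improvement = rng.normal(40.0, 15.0, n_participants)
    return grid, streamlines, fields, vats, improvement
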