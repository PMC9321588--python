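"""Shared fixtures: the base synthetic tank and hand-built small models."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from lagcomp import DEFAULT_TANK, build_stirred_tank_field, compartmentize
from lagcomp.compartments import CompartmentLayout, _model_from_matrices


@pytest.fixture(scope="session")
def base_field():
    """52 x 12 x 1 synthetic flow field of the 54 m3 two-Rushton tank."""
    return build_stirred_tank_field(DEFAULT_TANK, (52, 12, 1))


@pytest.fixture(scope="session")
def base_model(base_field):
    """Base-case compartment model A26R6T1 (156 compartments)."""
    return compartmentize(base_field, "A26R6T1")


@pytest.fixture(scope="session")
def coarse_model(base_field):
    """Coarse 13 x 3 layout for cheap reactive runs."""
    return compartmentize(base_field, "A13R3T1")


def make_hand_model(phi_c: np.ndarray, phi_t: np.ndarray, volumes: np.ndarray,
                    rho: float = 1000.0):
    """Build a compartment model directly from dense flux matrices.

    The matrices are given *without* diagonals (pure off-diagonal flows,
    entry [i, j] = flow from j to i); conservative diagonals are added
    here.
    """
    phi_c = np.asarray(phi_c, dtype=float)
    phi_t = np.asarray(phi_t, dtype=float)
    nc = phi_c.shape[0]
    volumes = np.asarray(volumes, dtype=float)
    pc = sparse.csc_matrix(phi_c - np.diag(phi_c.sum(axis=0)))
    pt = sparse.csc_matrix(phi_t - np.diag(phi_t.sum(axis=0)))
    layout = CompartmentLayout(nax=nc, nr=1, ntheta=1,
                               cell_to_compartment=np.arange(nc))
    centers = np.arange(nc, dtype=float)
    return _model_from_matrices(layout, rho, volumes, centers,
                                np.zeros(nc), np.zeros(nc), pc, pt)


@pytest.fixture()
def two_box_model():
    """Two equal 1 m3 compartments exchanging 500 kg/s both ways."""
    phi = np.array([[0.0, 500.0], [500.0, 0.0]])
    return make_hand_model(phi, np.zeros((2, 2)), np.array([1.0, 1.0]))


@pytest.fixture()
def ring_model():
    """Four-compartment directed ring, equal masses, 500 kg/s circulating."""
    f = 500.0
    phi = np.zeros((4, 4))
    for i in range(4):
        phi[(i + 1) % 4, i] = f  # flow i -> i+1
    return make_hand_model(phi, np.zeros((4, 4)), np.full(4, 1.0))


@pytest.fixture()
def unequal_ring_model():
    """Directed ring with volumes 1..4 m3; flux-balanced (in = out = f)."""
    f = 500.0
    phi = np.zeros((4, 4))
    for i in range(4):
        phi[(i + 1) % 4, i] = f
    return make_hand_model(phi, np.zeros((4, 4)), np.array([1.0, 2.0, 3.0, 4.0]))
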