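import numpy as np
import pytest

from condensotherm import synth
from condensotherm.constants import KB
from condensotherm.trajectory import Frame, Topology, VelocitySeries, WaterModel


@pytest.fixture(scope="session")
def water_model() -> WaterModel:
    return WaterModel()


def make_rigid_water_frame(
    com_positions, com_velocities, omegas, model=None, box=5.0, seed=0
):
    """Build a frame of rigid waters with exact rigid-body site velocities.

    Returns (Topology, Frame).  ``omegas`` are lab-frame angular
    velocities, one per water.
    """
    from condensotherm.synth import _water_topology
    from condensotherm.waterbox import _random_rotations

    model = model or WaterModel()
    com_positions = np.atleast_2d(np.asarray(com_positions, dtype=float))
    com_velocities = np.atleast_2d(np.asarray(com_velocities, dtype=float))
    omegas = np.atleast_2d(np.asarray(omegas, dtype=float))
    n = len(com_positions)
    rng = np.random.default_rng(seed)
    rots = _random_rotations(rng, n)
    sites_local = model.site_positions()[:3]
    m = model.site_masses()[:3]
    com_local = (m[:, None] * sites_local).sum(axis=0) / m.sum()
    rel_local = sites_local - com_local
    positions = np.empty((n, 3, 3))
    velocities = np.empty((n, 3, 3))
    for i in range(n):
        rel = rel_local @ rots[i].T
        positions[i] = com_positions[i] + rel
        velocities[i] = com_velocities[i] + np.cross(omegas[i], rel)
    top = _water_topology(n, model)
    frame = Frame(
        positions=positions.reshape(-1, 3),
        box=np.full(3, float(box)),
        time=0.0,
        velocities=velocities.reshape(-1, 3),
    )
    return top, frame


@pytest.fixture
def rigid_water_factory():
    return make_rigid_water_frame


@pytest.fixture(scope="session")
def langevin_fluid():
    """Small soft-sphere fluid trajectory (shared; generation ~seconds)."""
    return synth.gen_langevin_fluid(
        n_waters=96, box=1.62, T=300.0, duration=4.0, seed=11
    )


@pytest.fixture(scope="session")
def toy_condensate_series():
    """Three-concentration toy condensate at reduced water fill."""
    return synth.gen_toy_condensate(
        [150.0, 250.0, 350.0], n_chains=8, chain_mass=4.0, n_residues=12,
        water_fill=0.25, seed=5,
    )


def constant_velocity_series(n_mol=4, n_frames=50, dt=0.01, mass=18.0, seed=0):
    rng = np.random.default_rng(seed)
    v0 = rng.normal(scale=np.sqrt(KB * 300.0 / mass), size=(n_mol, 3))
    v = np.broadcast_to(v0, (n_frames, n_mol, 3)).copy()
    return VelocitySeries(dt=dt, com_velocities=v, masses=np.full(n_mol, mass))
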