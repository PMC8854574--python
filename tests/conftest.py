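"""Shared fixtures.

The expensive session fixtures (simulation runs, the trained classifier,
the H_n table) are shared between the unit/property suite and the
acceptance suite so each heavy computation happens once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pgcam.geometry import build_default_scene, build_single_module_scene
from pgcam.mlfilter import train_classifier
from pgcam.physics import scattered_energy
from pgcam.recon import precompute_hn
from pgcam.selection import SelectionCriteria, select_events
from pgcam.simulate import PointSource, UniformCubeSource, default_pg_source, run_simulation

# problem sizes of the standard study conditions
N_POINT_HISTORIES = 200_000
N_PHANTOM_HISTORIES = 90_000_000
N_TRAIN_HISTORIES = 600_000_000
N_HELD_HISTORIES = 150_000_000


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hn70():
    return precompute_hn(n_max=70)


@pytest.fixture(scope="session")
def point_run_1mev():
    """1 MeV point source 50 mm from a single default module, 2e5 histories."""
    scene = build_single_module_scene()
    return scene, run_simulation(scene, PointSource(1000.0), N_POINT_HISTORIES, seed=101)


@pytest.fixture(scope="session")
def phantom_scene():
    return build_default_scene()


@pytest.fixture(scope="session")
def pg_source():
    return default_pg_source()


@pytest.fixture(scope="session")
def phantom_run_a(phantom_scene, pg_source):
    return run_simulation(phantom_scene, pg_source, N_PHANTOM_HISTORIES, seed=201)


@pytest.fixture(scope="session")
def phantom_run_b(phantom_scene, pg_source):
    return run_simulation(phantom_scene, pg_source, N_PHANTOM_HISTORIES, seed=202)


@pytest.fixture(scope="session")
def training_scene():
    return build_single_module_scene()


@pytest.fixture(scope="session")
def training_split(training_scene):
    """Synthetic classifier data: uniform 200-7000 keV emissions from a
    200 mm cube 50 mm from the detector face; independent training and
    held-out runs."""
    src = UniformCubeSource(center=(-100.0, 0.0, 0.0))
    train = run_simulation(training_scene, src, N_TRAIN_HISTORIES, seed=301).events.reset_index(drop=True)
    held = run_simulation(training_scene, src, N_HELD_HISTORIES, seed=302).events.reset_index(drop=True)
    return train, held


@pytest.fixture(scope="session")
def trained_classifier(training_split, training_scene):
    train, _ = training_split
    return train_classifier(train, training_scene, per_class_cap=50_000, seed=77)


@pytest.fixture(scope="session")
def c12_events_a(phantom_run_a):
    sel, _ = select_events(phantom_run_a.events, SelectionCriteria.from_preset("c12"))
    return sel


def synthetic_point_source_events(n, e_gamma=4400.0, source=(0.0, 0.0, 0.0), seed=0, module=0, apex_x=107.0):
    """Noise-free coincidences from a point source: exact Compton
    kinematics and geometry, for reconstruction oracles."""
    rng = np.random.default_rng(seed)
    src = np.asarray(source, float)
    rows = []
    for _ in range(n):
        s = np.array([apex_x, rng.uniform(-20, 20), rng.uniform(-20, 20)]) + np.array([0.0, src[1], src[2]])
        d_in = s - src
        d_in = d_in / np.linalg.norm(d_in)
        cosw = rng.uniform(0.7, 0.95)
        ap = np.cross(d_in, [0.0, 0.0, 1.0])
        ap /= np.linalg.norm(ap)
        bp = np.cross(d_in, ap)
        phi = rng.uniform(0, 2 * np.pi)
        d_sc = cosw * d_in + np.sqrt(1 - cosw**2) * (np.cos(phi) * ap + np.sin(phi) * bp)
        a = s + d_sc * 30.0
        e_sc = scattered_energy(e_gamma, cosw)
        rows.append(
            dict(
                module=module,
                xs=s[0], ys=s[1], zs=s[2],
                xa=a[0], ya=a[1], za=a[2],
                Es_keV=e_gamma - e_sc, Ea_keV=e_sc,
                t_ns=0.0,
                truth_E_keV=e_gamma, truth_x=src[0], truth_y=src[1], truth_z=src[2],
                full_energy=True, particle="gamma",
            )
        )
    return pd.DataFrame(rows)
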