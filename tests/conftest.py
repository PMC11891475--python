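"""Shared fixtures: small analytic fields and phantoms built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lvflow.field_model import VelocityField4D
from lvflow.phantoms import PhantomSpec, make_channel_phantom, make_lv_phantom


def uniform_field(v=(0.0, 0.0, 0.0), shape=(8, 8, 8), spacing=1.0,
                  origin=(0.0, 0.0, 0.0), n_phases=2, cycle=1000.0, venc=1e9):
    vel = np.zeros((n_phases, 3) + shape)
    for c in range(3):
        vel[:, c] = v[c]
    times = np.linspace(0.0, cycle * (n_phases - 1) / n_phases, n_phases)
    return VelocityField4D(vel, np.full(3, float(spacing)), np.asarray(origin, float),
                           times, cycle, venc=venc)


def exponential_field(k=0.5, n=65, spacing=1.0):
    """Stationary field v_x = k * x (cm/s) on a line-resolving grid."""
    shape = (n, 5, 5)
    x = np.arange(n) * spacing
    vel = np.zeros((2, 3) + shape)
    vel[:, 0] = (k * x)[None, :, None, None]
    return VelocityField4D(vel, [spacing] * 3, [0.0, 0.0, 0.0],
                           [0.0, 500.0], 1000.0, venc=1e12)


def rotation_field(omega=2 * np.pi / 3600.0, n=41, spacing=1.0, nz=3):
    """Solid rotation about the z axis: angular speed ``omega`` rad/ms."""
    c = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y = np.meshgrid(c, c, indexing="ij")
    vel = np.zeros((2, 3, n, n, nz))
    vel[:, 0] = (-omega * Y / 0.01)[None, :, :, None]  # mm/ms -> cm/s
    vel[:, 1] = (omega * X / 0.01)[None, :, :, None]
    return VelocityField4D(vel, [spacing] * 3, [c[0], c[0], 0.0],
                           [0.0, 500.0], 1000.0, venc=1e12)


SMALL_LV_SPEC = PhantomSpec(
    geometry="ellipsoid", spacing=2.5, semi_axis=24.0, apex_depth=40.0,
    stroke_volume_ml=30.0, mitral_centre_x=-10.5, mitral_radius=9.5,
    aortic_centre_x=10.5, aortic_radius=9.5, jet_spread_length=8.0,
)


@pytest.fixture(scope="session")
def channel_phantom():
    return make_channel_phantom(PhantomSpec(geometry="channel"))


@pytest.fixture(scope="session")
def lv_phantom():
    """Default, full-size ellipsoidal phantom (the study conditions)."""
    return make_lv_phantom(PhantomSpec(geometry="ellipsoid"))


@pytest.fixture(scope="session")
def lv_phantom_small():
    """Down-scaled ellipsoidal phantom for fast unit tests."""
    return make_lv_phantom(SMALL_LV_SPEC)
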