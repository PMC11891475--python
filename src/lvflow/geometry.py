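"""LV models, signed distances, valve planes, rigid transforms, and seeding.

Geometry lives in a right-handed world frame in mm with voxel-centre
addressing: voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

__all__ = [
    "LVModel",
    "ValvePlane",
    "PlaneGeometry",
    "RigidTransform",
    "DistanceMap",
    "build_lv_model",
    "seed_positions",
    "apply_rigid_transform",
    "load_mask",
    "save_mask",
    "load_valve_plane",
    "save_valve_plane",
    "load_rigid_transform",
    "save_rigid_transform",
]


class DistanceMap:
    """Signed Euclidean distance to a binary mask's boundary surface.

    Negative inside the mask, positive outside.  Built once per mask from the
    Euclidean distance transform; queries interpolate the precomputed grid
    trilinearly.  Voxel-centre distances are shifted half a voxel toward the
    boundary so that points on the surface read ``|d| <= 0.5`` voxel.
    Positions outside the grid return ``+inf`` (unknowable, treated as far
    outside).
    """

    def __init__(self, mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        self.spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(origin, dtype=np.float64).reshape(3)
        self.shape = np.array(mask.shape)
        half = 0.5 * float(np.mean(self.spacing))
        if mask.all():
            signed = -distance_transform_edt(mask, sampling=self.spacing) + half
        elif not mask.any():
            signed = distance_transform_edt(~mask, sampling=self.spacing) - half
        else:
            d_in = distance_transform_edt(mask, sampling=self.spacing)
            d_out = distance_transform_edt(~mask, sampling=self.spacing)
            signed = np.where(mask, -(d_in - half), d_out - half)
        self.grid = signed

    def at(self, positions: np.ndarray) -> np.ndarray:
        """Signed distance (mm) at world positions, shape (N,)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=np.float64))
        idx = ((pos - self.origin) / self.spacing).T
        inside = np.all((idx >= 0.0) & (idx <= (self.shape - 1)[:, None]), axis=0)
        vals = map_coordinates(self.grid, idx, order=1, mode="nearest")
        vals[~inside] = np.inf
        return vals


@dataclass
class LVModel:
    """End-diastolic and end-systolic LV geometry on a shared grid.

    Volumes are voxel counts times the voxel volume; EDV doubles as the
    indexing denominator for kinetic energy and vorticity.
    """

    ed_mask: np.ndarray
    es_mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    edv: float  # mL
    esv: float  # mL
    _ed_dist: DistanceMap | None = field(default=None, repr=False, compare=False)
    _es_dist: DistanceMap | None = field(default=None, repr=False, compare=False)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def ed_distance(self) -> DistanceMap:
        if self._ed_dist is None:
            self._ed_dist = DistanceMap(self.ed_mask, self.spacing, self.origin)
        return self._ed_dist

    def es_distance(self) -> DistanceMap:
        if self._es_dist is None:
            self._es_dist = DistanceMap(self.es_mask, self.spacing, self.origin)
        return self._es_dist


def build_lv_model(
    ed_mask: np.ndarray,
    es_mask: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
) -> LVModel:
    """Assemble an :class:`LVModel`; EDV/ESV from voxel counts.

    An empty end-diastolic mask is an error (no cavity to seed); an empty
    end-systolic mask only warns (ESV = 0 is degenerate but representable).
    """
    ed_mask = np.asarray(ed_mask, dtype=bool)
    es_mask = np.asarray(es_mask, dtype=bool)
    if ed_mask.shape != es_mask.shape:
        raise ValueError(f"mask shapes differ: {ed_mask.shape} vs {es_mask.shape}")
    if not ed_mask.any():
        raise ValueError("end-diastolic mask is empty")
    if not es_mask.any():
        warnings.warn("end-systolic mask is empty; ESV set to 0", stacklevel=2)
    spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    voxvol = float(np.prod(spacing))  # mm^3
    edv = ed_mask.sum() * voxvol / 1000.0
    esv = es_mask.sum() * voxvol / 1000.0
    return LVModel(ed_mask, es_mask, spacing, origin, edv, esv)


def signed_distance(
    mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """One-shot signed distance query; prefer :class:`DistanceMap` in loops."""
    return DistanceMap(mask, spacing, origin).at(positions)


def seed_positions(model: LVModel, margin: float = 2.5) -> np.ndarray:
    """Seeds at the centre of every end-diastolic voxel at least ``margin``
    mm inside the wall, shape (N, 3) in world mm.

    The wall margin guards against segmentation inaccuracy at the
    endocardial border.  Zero eligible voxels is an error: no analysis is
    possible without seeds.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    dist = model.ed_distance().grid
    sel = model.ed_mask & (dist <= -margin)
    idx = np.argwhere(sel)
    if idx.shape[0] == 0:
        raise ValueError(f"no seeds: margin {margin} mm leaves no interior voxels")
    return model.origin + idx * model.spacing


# ---------------------------------------------------------------------------
# Valve planes
# ---------------------------------------------------------------------------


@dataclass
class PlaneGeometry:
    """A single oriented disc: centre (mm), unit normal, radius (mm)."""

    centre: np.ndarray
    normal: np.ndarray
    radius: float


@dataclass
class ValvePlane:
    """Per-phase tracked annulus plane, modelled as an oriented disc.

    ``normals`` point along physiologic forward flow (into the LV for the
    mitral valve, out of it for the aortic valve).  Entries are interpolated
    linearly and cyclically between phases; interpolated normals are
    renormalised.
    """

    label: str  # "mitral" | "aortic"
    phase_times: np.ndarray  # (P,) ms
    centres: np.ndarray  # (P, 3) mm
    normals: np.ndarray  # (P, 3) unit vectors
    radii: np.ndarray  # (P,) mm
    cycle_length: float  # ms

    def __post_init__(self) -> None:
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        self.centres = np.atleast_2d(np.asarray(self.centres, dtype=np.float64))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=np.float64))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        n = self.phase_times.shape[0]
        if not (self.centres.shape == (n, 3) and self.normals.shape == (n, 3) and self.radii.shape == (n,)):
            raise ValueError("valve plane arrays must have one entry per phase")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("valve plane normals must be unit length")
        if np.any(self.radii <= 0):
            raise ValueError("valve plane radii must be positive")

    def at_time(self, time: float) -> PlaneGeometry:
        """Disc interpolated at an arbitrary (cyclic) time."""
        t = float(time) % self.cycle_length
        pt = self.phase_times
        if pt.shape[0] == 1:
            i0 = i1 = 0
            w = 0.0
        elif t >= pt[-1]:
            i0, i1 = pt.shape[0] - 1, 0
            w = (t - pt[-1]) / (self.cycle_length - pt[-1])
        else:
            i0 = int(np.searchsorted(pt, t, side="right") - 1)
            i1 = i0 + 1
            w = (t - pt[i0]) / (pt[i1] - pt[i0])
        centre = (1 - w) * self.centres[i0] + w * self.centres[i1]
        normal = (1 - w) * self.normals[i0] + w * self.normals[i1]
        normal = normal / np.linalg.norm(normal)
        radius = (1 - w) * self.radii[i0] + w * self.radii[i1]
        return PlaneGeometry(centre=centre, normal=normal, radius=float(radius))


def plane_at_time(valve: ValvePlane, time: float) -> PlaneGeometry:
    """Functional alias for :meth:`ValvePlane.at_time`."""
    return valve.at_time(time)


def static_valve_plane(
    label: str,
    centre: np.ndarray,
    normal: np.ndarray,
    radius: float,
    phase_times: np.ndarray,
    cycle_length: float,
) -> ValvePlane:
    """A valve plane that does not move over the cycle (phantom use)."""
    phase_times = np.asarray(phase_times, dtype=np.float64)
    n = phase_times.shape[0]
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    return ValvePlane(
        label=label,
        phase_times=phase_times,
        centres=np.tile(np.asarray(centre, dtype=np.float64), (n, 1)),
        normals=np.tile(normal, (n, 1)),
        radii=np.full(n, float(radius)),
        cycle_length=cycle_length,
    )


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` aligning cine space to flow space."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation matrix must have determinant +1 (no reflection)")

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rotation=rot, translation=-rot @ self.translation)


def apply_rigid_transform(transform: RigidTransform, geometry):
    """Apply a rigid transform to an LV model, valve plane, or point set.

    Points map as ``p -> R p + t``, normals as ``n -> R n``; radii are
    invariant.  Binary masks are resampled nearest-neighbour onto the same
    grid (labels preserved; volumes recomputed from the resampled masks).
    """
    if isinstance(geometry, np.ndarray):
        return transform.apply_points(geometry)
    if isinstance(geometry, ValvePlane):
        return ValvePlane(
            label=geometry.label,
            phase_times=geometry.phase_times.copy(),
            centres=transform.apply_points(geometry.centres),
            normals=geometry.normals @ transform.rotation.T,
            radii=geometry.radii.copy(),
            cycle_length=geometry.cycle_length,
        )
    if isinstance(geometry, LVModel):
        inv = transform.inverse()
        shape = geometry.ed_mask.shape
        idx = np.indices(shape).reshape(3, -1).T
        world = geometry.origin + idx * geometry.spacing
        src = (inv.apply_points(world) - geometry.origin) / geometry.spacing
        def resample(mask: np.ndarray) -> np.ndarray:
            vals = map_coordinates(mask.astype(np.float32), src.T, order=0, mode="constant", cval=0.0)
            return vals.reshape(shape) > 0.5
        ed = resample(geometry.ed_mask)
        es = resample(geometry.es_mask)
        voxvol = geometry.voxel_volume
        return LVModel(
            ed_mask=ed,
            es_mask=es,
            spacing=geometry.spacing.copy(),
            origin=geometry.origin.copy(),
            edv=ed.sum() * voxvol / 1000.0,
            esv=es.sum() * voxvol / 1000.0,
        )
    raise TypeError(f"cannot transform object of type {type(geometry).__name__}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_mask(mask: np.ndarray, spacing, origin, path: str | Path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    aff[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), aff), str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary NIfTI volume -> (mask, spacing, origin)."""
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0.5
    spacing = np.abs(np.diag(img.affine)[:3])
    origin = img.affine[:3, 3]
    return mask, spacing, origin


def save_valve_plane(valve: ValvePlane, path: str | Path) -> None:
    payload = {
        "label": valve.label,
        "cycle_length_ms": valve.cycle_length,
        "phase_times_ms": valve.phase_times.tolist(),
        "entries": [
            {
                "centre": valve.centres[i].tolist(),
                "normal": valve.normals[i].tolist(),
                "radius": float(valve.radii[i]),
            }
            for i in range(valve.phase_times.shape[0])
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_valve_plane(path: str | Path) -> ValvePlane:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"valve plane file not found: {path}")
    payload = json.loads(path.read_text())
    entries = payload["entries"]
    return ValvePlane(
        label=payload["label"],
        phase_times=np.asarray(payload["phase_times_ms"], dtype=float),
        centres=np.asarray([e["centre"] for e in entries], dtype=float),
        normals=np.asarray([e["normal"] for e in entries], dtype=float),
        radii=np.asarray([e["radius"] for e in entries], dtype=float),
        cycle_length=float(payload["cycle_length_ms"]),
    )


def save_rigid_transform(transform: RigidTransform, path: str | Path) -> None:
    payload = {
        "rotation_row_major": transform.rotation.reshape(-1).tolist(),
        "translation_mm": transform.translation.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rigid_transform(path: str | Path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transform file not found: {path}")
    payload = json.loads(path.read_text())
    return RigidTransform(
        rotation=np.asarray(payload["rotation_row_major"], dtype=float).reshape(3, 3),
        translation=np.asarray(payload["translation_mm"], dtype=float),
    )
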