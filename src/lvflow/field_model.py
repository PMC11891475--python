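"""Time-resolved 3-D velocity fields: data model, NIfTI I/O, and interpolation.

A 4D-flow acquisition reconstructs one scalar volume per velocity component per
cardiac phase on a regular grid.  :class:`VelocityField4D` holds the full
``(T, 3, nx, ny, nz)`` array in cm/s together with the world-coordinate mapping
(voxel-centre convention, mm) and the cyclic time axis (ms).  Interpolation is
trilinear in space and linear in time, with the gap between the last
reconstructed phase and phase 0 spanned by ``cycle_length - phase_times[-1]``
so that sampling is continuous across the cyclic seam.

Positions outside the grid bounding box are an error signal
(:class:`OutOfDomainError`), never extrapolated: the particle tracer treats
them as trace termination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VelocityField4D",
    "OutOfDomainError",
    "FieldFormatError",
    "FieldValidationReport",
    "load_velocity_field",
    "save_velocity_field",
    "validate_field",
]


class OutOfDomainError(ValueError):
    """A spatial query fell outside the grid bounding box."""


class FieldFormatError(ValueError):
    """Velocity volumes or metadata are inconsistent."""


@dataclass
class VelocityField4D:
    """Cyclic, time-resolved three-component velocity field on a regular grid.

    Parameters
    ----------
    velocity
        Array of shape ``(T, 3, nx, ny, nz)`` in cm/s.
    spacing
        Voxel spacing in mm, one value per axis.
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    phase_times
        Strictly increasing phase timestamps in ms; the first must be 0.
    cycle_length
        RR interval in ms; must exceed the last phase time.
    venc
        Velocity-encoding limit in cm/s.  Components beyond it indicate
        aliasing and are flagged by :func:`validate_field`.
    """

    velocity: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    phase_times: np.ndarray
    cycle_length: float
    venc: float = 150.0

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.phase_times = np.asarray(self.phase_times, dtype=np.float64)
        self.cycle_length = float(self.cycle_length)
        if self.velocity.ndim != 5 or self.velocity.shape[1] != 3:
            raise FieldFormatError(
                f"velocity must have shape (T, 3, nx, ny, nz), got {self.velocity.shape}"
            )
        if self.velocity.shape[0] != self.phase_times.shape[0]:
            raise FieldFormatError(
                f"{self.velocity.shape[0]} phases but {self.phase_times.shape[0]} timestamps"
            )
        if self.phase_times.shape[0] < 2:
            raise FieldFormatError("need at least 2 cardiac phases")
        if self.phase_times[0] != 0.0:
            raise FieldFormatError("phase_times must start at 0")
        if np.any(np.diff(self.phase_times) <= 0):
            raise FieldFormatError(f"phase_times not strictly increasing: {self.phase_times}")
        if self.cycle_length <= self.phase_times[-1]:
            raise FieldFormatError("cycle_length must exceed the last phase time")
        if np.any(self.spacing <= 0):
            raise FieldFormatError("spacing must be positive componentwise")

    # -- grid geometry ---------------------------------------------------

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[2:]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame bounding box spanned by the voxel centres (mm)."""
        hi = self.origin + (np.array(self.grid_shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def index_coords(self, positions: np.ndarray) -> np.ndarray:
        """World mm -> fractional voxel indices, shape (N, 3)."""
        return (np.atleast_2d(positions) - self.origin) / self.spacing

    def contains(self, positions: np.ndarray) -> np.ndarray:
        idx = self.index_coords(positions)
        shape = np.array(self.grid_shape)
        return np.all((idx >= 0.0) & (idx <= shape - 1), axis=1)

    # -- sampling --------------------------------------------------------

    def _time_bracket(self, time: float) -> tuple[int, int, float]:
        """Bracketing phase indices and interpolation weight for a cyclic time."""
        t = float(time) % self.cycle_length
        pt = self.phase_times
        if t >= pt[-1]:
            gap = self.cycle_length - pt[-1]
            return self.n_phases - 1, 0, (t - pt[-1]) / gap
        i = int(np.searchsorted(pt, t, side="right") - 1)
        return i, i + 1, (t - pt[i]) / (pt[i + 1] - pt[i])

    def sample_many(
        self, positions: np.ndarray, time: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate velocity at many positions and one time.

        Returns ``(velocity (N, 3) cm/s, inside (N,) bool)``.  Rows whose
        position falls outside the bounding box hold the value clamped to the
        nearest edge; callers must honour the ``inside`` mask.
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=np.float64))
        idx = self.index_coords(pos)
        shape = np.array(self.grid_shape)
        inside = np.all((idx >= 0.0) & (idx <= shape - 1), axis=1)
        i0, i1, w = self._time_bracket(time)
        coords = idx.T
        out = np.empty((pos.shape[0], 3))
        for c in range(3):
            v0 = map_coordinates(self.velocity[i0, c], coords, order=1, mode="nearest")
            if w == 0.0:
                out[:, c] = v0
            else:
                v1 = map_coordinates(self.velocity[i1, c], coords, order=1, mode="nearest")
                out[:, c] = (1.0 - w) * v0 + w * v1
        return out, inside

    def sample(self, position: np.ndarray, time: float) -> np.ndarray:
        """Velocity (cm/s) at one world position (mm) and time (ms).

        Raises :class:`OutOfDomainError` outside the grid bounding box.
        """
        vel, inside = self.sample_many(np.asarray(position, dtype=np.float64)[None, :], time)
        if not inside[0]:
            raise OutOfDomainError(f"position {np.asarray(position)} outside grid bounding box")
        return vel[0]


def sample_velocity(field: VelocityField4D, position: np.ndarray, time: float) -> np.ndarray:
    """Functional alias for :meth:`VelocityField4D.sample`."""
    return field.sample(position, time)


# ---------------------------------------------------------------------------
# I/O: one 4D NIfTI per component (or per-phase 3D volumes) + JSON sidecar
# ---------------------------------------------------------------------------

_COMPONENTS = ("x", "y", "z")


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_velocity_field(field: VelocityField4D, directory: str | Path) -> Path:
    """Write the field as ``velocity_{x,y,z}.nii.gz`` plus ``field.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.spacing, field.origin)
    for c, name in enumerate(_COMPONENTS):
        # (T, nx, ny, nz) -> (nx, ny, nz, T): NIfTI stores time last
        vol = np.moveaxis(field.velocity[:, c], 0, -1)
        nib.save(nib.Nifti1Image(vol, aff), directory / f"velocity_{name}.nii.gz")
    meta = {
        "phase_times_ms": field.phase_times.tolist(),
        "cycle_length_ms": field.cycle_length,
        "venc_cm_per_s": field.venc,
    }
    (directory / "field.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_velocity_field(
    source: str | Path | dict[str, Sequence[str | Path] | str | Path],
    metadata: dict | str | Path | None = None,
) -> VelocityField4D:
    """Load a velocity field from NIfTI volumes plus a time/Venc descriptor.

    ``source`` may be a directory written by :func:`save_velocity_field`, or a
    mapping ``{"x": path, "y": path, "z": path}`` where each entry is either a
    single 4D NIfTI or a list of per-phase 3D NIfTIs.  ``metadata`` (dict or
    JSON path) must supply ``phase_times_ms``, ``cycle_length_ms`` and
    optionally ``venc_cm_per_s``; it defaults to ``field.json`` in the source
    directory.
    """
    if not isinstance(source, dict):
        directory = Path(source)
        source = {name: directory / f"velocity_{name}.nii.gz" for name in _COMPONENTS}
        if metadata is None:
            metadata = directory / "field.json"
    if metadata is None:
        raise FieldFormatError("metadata (phase times, cycle length) is required")
    if not isinstance(metadata, dict):
        meta_path = Path(metadata)
        if not meta_path.exists():
            raise FileNotFoundError(f"field metadata not found: {meta_path}")
        metadata = json.loads(meta_path.read_text())

    comps = []
    spacing = origin = None
    for name in _COMPONENTS:
        if name not in source:
            raise FieldFormatError(f"missing velocity component {name!r}")
        entry = source[name]
        if isinstance(entry, (str, Path)):
            img = nib.load(str(entry))
            data = np.asarray(img.dataobj, dtype=np.float64)
            if data.ndim == 3:
                data = data[..., None]
            if data.ndim != 4:
                raise FieldFormatError(f"{entry}: expected a 3D or 4D volume")
            vol = np.moveaxis(data, -1, 0)
            aff = img.affine
        else:
            phases = []
            aff = None
            for p in entry:
                img = nib.load(str(p))
                d = np.asarray(img.dataobj, dtype=np.float64)
                if d.ndim != 3:
                    raise FieldFormatError(f"{p}: expected a 3D volume per phase")
                if aff is None:
                    aff = img.affine
                phases.append(d)
            vol = np.stack(phases, axis=0)
        sp = np.abs(np.diag(aff)[:3])
        og = aff[:3, 3]
        if spacing is None:
            spacing, origin = sp, og
        elif not (np.allclose(sp, spacing) and np.allclose(og, origin)):
            raise FieldFormatError("velocity components disagree on grid geometry")
        comps.append(vol)

    shapes = {c.shape for c in comps}
    if len(shapes) != 1:
        raise FieldFormatError(f"velocity components have mismatched shapes: {shapes}")
    velocity = np.stack(comps, axis=1)
    return VelocityField4D(
        velocity=velocity,
        spacing=spacing,
        origin=origin,
        phase_times=np.asarray(metadata["phase_times_ms"], dtype=np.float64),
        cycle_length=float(metadata["cycle_length_ms"]),
        venc=float(metadata.get("venc_cm_per_s", 150.0)),
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class FieldValidationReport:
    """Report-only screen for aliasing and corrupt samples."""

    aliasing_fraction: float
    n_samples: int
    n_nonfinite: int
    nonfinite_indices: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.aliasing_fraction == 0.0 and self.n_nonfinite == 0


def validate_field(field: VelocityField4D, max_reported: int = 10) -> FieldValidationReport:
    """Flag samples with any component beyond Venc, and non-finite values.

    Speeds beyond the velocity-encoding limit cannot have been measured
    faithfully (phase wrap-around), so their fraction is a basic data-quality
    screen.  The check never modifies the field.
    """
    v = field.velocity
    over = np.abs(v) > field.venc
    bad = ~np.isfinite(v)
    n_samples = int(np.prod(v.shape[:1] + v.shape[2:]))  # per (phase, voxel)
    aliased = np.any(over, axis=1)
    frac = float(np.count_nonzero(aliased)) / n_samples
    nonfinite_idx = np.argwhere(bad)
    return FieldValidationReport(
        aliasing_fraction=frac,
        n_samples=n_samples,
        n_nonfinite=int(nonfinite_idx.shape[0]),
        nonfinite_indices=[tuple(int(i) for i in row) for row in nonfinite_idx[:max_reported]],
    )
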