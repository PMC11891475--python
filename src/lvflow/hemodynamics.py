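"""Voxel-wise kinetic energy and vorticity, valve flux curves, phase peaks.

Kinetic energy per voxel is ``1/2 * rho * |v|^2 * V_voxel`` with blood density
rho = 1060 kg/m^3 by default, reported in microjoules.  Vorticity is the curl
magnitude per voxel from central differences (one-sided at grid borders), in
1/s; "total vorticity" sums voxel curl magnitudes (a vector sum would cancel).
Totals over the LV mask are indexed against end-diastolic volume.

Valve-plane flux curves integrate the through-plane velocity component over a
regular in-plane raster across the tracked annulus disc, one point per stored
cardiac phase.  The systolic/diastolic landmark phases (peak-systole, E-peak,
A-peak) and the end-systole time are identified from these curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_model import VelocityField4D
from .geometry import ValvePlane

__all__ = [
    "BLOOD_DENSITY",
    "FluxCurve",
    "CardiacPhases",
    "HemoResult",
    "kinetic_energy_map",
    "vorticity_map",
    "plane_flux_curve",
    "identify_peaks",
    "hemo_at_phases",
]

BLOOD_DENSITY = 1060.0  # kg/m^3


def _nearest_phase(field: VelocityField4D, time: float) -> int:
    """Index of the stored phase nearest a cyclic time."""
    t = float(time) % field.cycle_length
    dt = np.abs(field.phase_times - t)
    dt = np.minimum(dt, field.cycle_length - dt)
    return int(np.argmin(dt))


def kinetic_energy_map(
    field: VelocityField4D,
    mask: np.ndarray,
    time: float,
    density: float = BLOOD_DENSITY,
) -> np.ndarray:
    """Per-voxel kinetic energy (microjoules) inside ``mask`` at the stored
    phase nearest ``time``; zero outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {field.grid_shape}")
    if not mask.any():
        raise ValueError("empty mask")
    i = _nearest_phase(field, time)
    speed2 = np.sum(field.velocity[i] ** 2, axis=0)  # (cm/s)^2
    voxvol_m3 = float(np.prod(field.spacing)) * 1e-9
    ke_joule = 0.5 * density * speed2 * 1e-4 * voxvol_m3  # (cm/s)^2 -> (m/s)^2
    return np.where(mask, ke_joule * 1e6, 0.0)  # J -> uJ


def vorticity_map(field: VelocityField4D, mask: np.ndarray, time: float) -> np.ndarray:
    """Per-voxel curl magnitude (1/s) inside ``mask`` at the nearest phase.

    Derivatives are central differences on the full velocity grid, so voxels
    at the mask border use neighbours outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {field.grid_shape}")
    if not mask.any():
        raise ValueError("empty mask")
    i = _nearest_phase(field, time)
    v = field.velocity[i] * 10.0  # cm/s -> mm/s; d(mm/s)/d(mm) = 1/s
    sx, sy, sz = field.spacing
    dvz_dy = np.gradient(v[2], sy, axis=1)
    dvy_dz = np.gradient(v[1], sz, axis=2)
    dvx_dz = np.gradient(v[0], sz, axis=2)
    dvz_dx = np.gradient(v[2], sx, axis=0)
    dvy_dx = np.gradient(v[1], sx, axis=0)
    dvx_dy = np.gradient(v[0], sy, axis=1)
    curl = np.sqrt(
        (dvz_dy - dvy_dz) ** 2 + (dvx_dz - dvz_dx) ** 2 + (dvy_dx - dvx_dy) ** 2
    )
    return np.where(mask, curl, 0.0)


@dataclass
class FluxCurve:
    """Through-plane flow rate per stored phase, and its net forward volume."""

    label: str
    times: np.ndarray  # ms
    flow_rate: np.ndarray  # mL/s, positive along the valve's forward normal
    net_forward_volume: float  # mL

    def forward(self) -> np.ndarray:
        return np.maximum(self.flow_rate, 0.0)


def plane_flux_curve(
    field: VelocityField4D,
    valve: ValvePlane,
    raster_spacing: float | None = None,
) -> FluxCurve:
    """Flow-rate curve through a tracked valve disc.

    At every stored phase the disc is rastered with in-plane spacing
    ``raster_spacing`` (default: a quarter of the smallest grid spacing, so
    the disc boundary is resolved sub-voxel) and the through-plane velocity
    is summed as ``flow = sum(v . n dA)``.  The net forward volume integrates
    the positive part of the curve over the full cycle (trapezoidal, cyclic).
    """
    if raster_spacing is None:
        raster_spacing = 0.25 * float(np.min(field.spacing))
    rates = np.empty(field.n_phases)
    bad_phases = []
    for i, t in enumerate(field.phase_times):
        plane = valve.at_time(float(t))
        # in-plane orthonormal basis
        n = plane.normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        r = plane.radius
        m = int(np.ceil(r / raster_spacing))
        g = (np.arange(-m, m + 1) + 0.0) * raster_spacing
        aa, bb = np.meshgrid(g, g, indexing="ij")
        keep = aa**2 + bb**2 <= r**2
        pts = (
            plane.centre
            + aa[keep][:, None] * e1
            + bb[keep][:, None] * e2
        )
        vel, inside = field.sample_many(pts, float(t))
        if not inside.all():
            bad_phases.append(i)
            rates[i] = np.nan
            continue
        vn_mm_s = (vel @ n) * 10.0  # cm/s -> mm/s
        rates[i] = float(np.sum(vn_mm_s) * raster_spacing**2 / 1000.0)  # mL/s
    if bad_phases:
        raise ValueError(
            f"valve '{valve.label}' disc extends outside the grid at phases {bad_phases}"
        )
    # cyclic trapezoidal integral of the positive part, ms -> s
    t_ext = np.append(field.phase_times, field.cycle_length)
    f_ext = np.append(np.maximum(rates, 0.0), max(rates[0], 0.0))
    net = float(np.trapezoid(f_ext, t_ext) / 1000.0)
    return FluxCurve(label=valve.label, times=field.phase_times.copy(),
                     flow_rate=rates, net_forward_volume=net)


@dataclass
class CardiacPhases:
    """Landmark times (ms) identified from the valve flux curves."""

    peak_systole: float
    e_peak: float
    a_peak: float | None
    es_time: float
    a_peak_defined: bool = True


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-on-one-side interior local maxima."""
    idx = []
    for i in range(1, y.shape[0] - 1):
        if y[i] > 0 and y[i] >= y[i - 1] and y[i] >= y[i + 1] and (y[i] > y[i - 1] or y[i] > y[i + 1]):
            idx.append(i)
    return np.asarray(idx, dtype=int)


def identify_peaks(mitral: FluxCurve, aortic: FluxCurve) -> CardiacPhases:
    """Peak-systole, E-peak, A-peak, and end-systole from flux curves.

    Peak-systole is the maximum of aortic forward flow.  End-systole is the
    end of the contiguous aortic forward-flow interval containing that peak
    (linearly interpolated zero crossing).  E-peak is the first local maximum
    of mitral forward flow after end-systole and A-peak the last one before
    the cycle end; a monophasic inflow leaves the A-peak undefined and
    flagged.
    """
    if mitral.times.shape != aortic.times.shape or not np.allclose(mitral.times, aortic.times):
        raise ValueError("mitral and aortic curves must share one time axis")
    times = aortic.times
    af = aortic.forward()
    if not np.any(af > 0):
        raise ValueError("aortic curve has no forward flow; cannot locate systole")
    i_peak = int(np.argmax(af))
    peak_systole = float(times[i_peak])
    # walk right to the end of the contiguous forward-flow run
    j = i_peak
    while j + 1 < af.shape[0] and af[j + 1] > 0:
        j += 1
    if j + 1 < af.shape[0]:
        f0, f1 = aortic.flow_rate[j], aortic.flow_rate[j + 1]
        es_time = float(times[j] + (times[j + 1] - times[j]) * (f0 / (f0 - f1))) if f0 > 0 > f1 else float(times[j + 1] if f1 == 0 else times[j])
    else:
        es_time = float(times[j])

    mf = mitral.forward()
    maxima = _local_maxima(mf)
    maxima = maxima[times[maxima] > es_time]
    if maxima.shape[0] == 0:
        raise ValueError("mitral curve has no diastolic forward-flow maximum")
    e_peak = float(times[maxima[0]])
    if maxima.shape[0] >= 2:
        a_peak = float(times[maxima[-1]])
        a_defined = True
    else:
        a_peak = None
        a_defined = False
    return CardiacPhases(
        peak_systole=peak_systole, e_peak=e_peak, a_peak=a_peak,
        es_time=es_time, a_peak_defined=a_defined,
    )


@dataclass
class HemoResult:
    """Total and EDV-indexed kinetic energy and vorticity at one phase."""

    phase: str  # "peak_systole" | "e_peak" | "a_peak"
    time: float  # ms
    total_ke: float  # uJ
    total_vorticity: float  # 1/s (sum of voxel curl magnitudes)
    indexed_ke: float  # uJ/mL
    indexed_vorticity: float  # 1/s/mL


def hemo_at_phases(
    field: VelocityField4D,
    mask: np.ndarray,
    edv: float,
    peaks: CardiacPhases,
    density: float = BLOOD_DENSITY,
) -> list[HemoResult]:
    """KE and vorticity totals at peak-systole, E-peak, and A-peak.

    ``mask`` is the endocardial mask used for all three phases (the
    end-diastolic one unless per-phase masks are available); totals are
    divided by ``edv`` (mL) for the indexed values.  An undefined A-peak is
    skipped.
    """
    out = []
    phases = [("peak_systole", peaks.peak_systole), ("e_peak", peaks.e_peak)]
    if peaks.a_peak_defined and peaks.a_peak is not None:
        phases.append(("a_peak", peaks.a_peak))
    for name, t in phases:
        ke = float(np.sum(kinetic_energy_map(field, mask, t, density=density)))
        vort = float(np.sum(vorticity_map(field, mask, t)))
        out.append(
            HemoResult(
                phase=name, time=float(t), total_ke=ke, total_vorticity=vort,
                indexed_ke=ke / edv, indexed_vorticity=vort / edv,
            )
        )
    return out
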