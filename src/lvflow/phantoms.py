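"""Synthetic flow phantoms with analytically known particle fates.

Two phantom geometries make the full pipeline testable without a scan:

* **channel** — a straight rectangular duct with spatially uniform plug flow
  ``u(t)`` along its axis, a mitral disc at the inlet and an aortic disc at
  the outlet.  Particle motion is 1-D advection, so the four component
  fractions are closed-form functions of the systolic displacement ``Ds`` and
  diastolic displacement ``Dd`` relative to the duct length.

* **ellipsoid** — a half-ellipsoidal cavity (apex down) closed by a base
  plane carrying a mitral and an aortic disc.  Each disc drives a confined
  transvalvular jet built from an axisymmetric Stokes streamfunction: a
  Poiseuille velocity profile whose radius grows away from the valve plane,
  gated by a biphasic inflow waveform (E and A lobes) or a systolic outflow
  lobe.  The streamfunction construction is exactly divergence-free, carries
  the full prescribed flux through every jet cross-section (so mitral and
  aortic net volumes both equal the prescribed stroke volume by
  construction), and has zero velocity on the base plane outside its own
  disc — particles can only leave the cavity through a valve.

A respiratory-corruption model emulates scanning without gating: the field is
replaced by the average over several respiratory states of itself rigidly
displaced along a direction, with displacements drawn from a raised-cosine
breathing trajectory (end-expiratory plateau); a gating window keeps only
states within a diaphragm-position acceptance band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import shift as nd_shift

from .field_model import VelocityField4D, save_velocity_field
from .geometry import (
    LVModel,
    ValvePlane,
    build_lv_model,
    save_mask,
    save_valve_plane,
    seed_positions,
    static_valve_plane,
)

__all__ = [
    "Lobe",
    "PhantomSpec",
    "GroundTruth",
    "Phantom",
    "RespiratoryCorruption",
    "make_channel_phantom",
    "make_lv_phantom",
    "reference_fates",
    "apply_respiratory_corruption",
    "add_velocity_noise",
    "save_phantom",
]


@dataclass(frozen=True)
class Lobe:
    """A raised-cosine (Hann) flow lobe: zero outside [centre +/- width/2]."""

    centre: float  # ms
    width: float  # ms

    def unit(self, t: np.ndarray) -> np.ndarray:
        """Normalised lobe with unit time integral (1/ms)."""
        t = np.asarray(t, dtype=np.float64)
        x = (t - self.centre) / self.width
        inside = np.abs(x) < 0.5
        return np.where(inside, (2.0 / self.width) * np.cos(np.pi * x) ** 2, 0.0)


@dataclass
class PhantomSpec:
    """Conditions for phantom generation.

    Defaults emulate a resting healthy adult: 1 s cycle, 30 reconstructed
    phases, 2 mm isotropic reconstruction, systole ending ~330 ms after the
    R-wave, biphasic inflow with a dominant E-wave (65 % of filling), stroke
    volume 70 mL for the ellipsoidal cavity.
    """

    geometry: str = "ellipsoid"  # "channel" | "ellipsoid"
    spacing: float = 2.0  # mm, isotropic
    cycle_length: float = 1000.0  # ms
    n_phases: int = 30
    margin: float = 2.5  # mm, seed clearance used for ground-truth fractions
    # waveform timing
    systolic_lobe: Lobe = dc_field(default_factory=lambda: Lobe(175.0, 340.0))
    e_lobe: Lobe = dc_field(default_factory=lambda: Lobe(500.0, 260.0))
    a_lobe: Lobe = dc_field(default_factory=lambda: Lobe(810.0, 180.0))
    e_fraction: float = 0.65  # share of diastolic volume in the E-wave
    # channel geometry; the duct is long relative to the seed margin so that
    # margin truncation of the seeded span distorts the closed-form fractions
    # by well under a percentage point per margin-length
    length: float = 160.0  # mm
    cross_section: float = 24.0  # mm, square duct side
    systolic_displacement: float = 80.0  # mm
    diastolic_displacement: float = 80.0  # mm
    # ellipsoid geometry
    semi_axis: float = 34.0  # mm, base radius a
    apex_depth: float = 54.0  # mm, apex distance c below the base
    stroke_volume_ml: float = 70.0
    mitral_centre_x: float = -15.0  # mm, on the base plane
    mitral_radius: float = 13.5  # mm
    aortic_centre_x: float = 15.0
    aortic_radius: float = 13.5  # mm
    jet_spread_length: float = 10.0  # mm, axial scale of jet widening
    # measurement imperfections
    noise_sd: float = 0.0  # cm/s
    rng_seed: int = 0
    venc: float = 150.0  # cm/s

    @property
    def phase_times(self) -> np.ndarray:
        return np.arange(self.n_phases) * (self.cycle_length / self.n_phases)

    @property
    def systole_end(self) -> float:
        return self.systolic_lobe.centre + 0.5 * self.systolic_lobe.width

    def inflow_unit(self, t: np.ndarray) -> np.ndarray:
        """Diastolic waveform with unit integral (E + A lobes)."""
        return self.e_fraction * self.e_lobe.unit(t) + (1.0 - self.e_fraction) * self.a_lobe.unit(t)


@dataclass
class GroundTruth:
    """Analytic truth for a phantom: component fractions and volumes."""

    fractions: dict[str, float] | None
    sv_ml: float
    inflow_ml: float
    seed_labels: np.ndarray | None = None
    description: str = ""


@dataclass
class Phantom:
    field: VelocityField4D
    model: LVModel
    mitral: ValvePlane
    aortic: ValvePlane
    ground_truth: GroundTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Channel phantom
# ---------------------------------------------------------------------------


def _discrete_displacements(spec: PhantomSpec, u_phase: np.ndarray) -> tuple[float, float]:
    """Systolic and diastolic displacement of the sampled, linearly
    interpolated waveform (mm) — what the pipeline actually integrates."""
    t = np.append(spec.phase_times, spec.cycle_length)
    u = np.append(u_phase, u_phase[0])
    t_es = spec.systole_end
    dense_t = np.union1d(np.linspace(0.0, spec.cycle_length, 20001), [t_es])
    dense_u = np.interp(dense_t, t, u)
    sys_sel = dense_t <= t_es
    ds = float(np.trapezoid(dense_u[sys_sel], dense_t[sys_sel]))
    dd = float(np.trapezoid(dense_u[~sys_sel | (dense_t == t_es)], dense_t[~sys_sel | (dense_t == t_es)]))
    return ds, dd


def _overlap(lo1: float, hi1: float, lo2: float, hi2: float) -> float:
    return max(0.0, min(hi1, hi2) - max(lo1, lo2))


def make_channel_phantom(spec: PhantomSpec) -> Phantom:
    """Straight-duct plug-flow phantom with closed-form particle fates.

    The duct spans ``x in [0, length]``; flow is ``u(t) x-hat`` everywhere
    (always non-negative: systolic outflow toward the aortic disc at the
    outlet, diastolic inflow from the mitral disc at the inlet).  A seed at
    ``x0`` is ejected iff ``x0 > length - Ds`` and of mitral origin iff
    ``x0 < Dd``, which fixes the component fractions over the seeded span.
    """
    if spec.geometry != "channel":
        spec = replace(spec, geometry="channel")
    L, w, s = spec.length, spec.cross_section, spec.spacing
    ds_req, dd_req = spec.systolic_displacement, spec.diastolic_displacement
    if ds_req >= L or dd_req >= L:
        raise ValueError(
            f"displacement ({ds_req}, {dd_req}) must be smaller than the channel length {L}"
        )

    # plug-flow waveform in mm/ms, scaled to the requested displacements
    t_phase = spec.phase_times
    u_phase = ds_req * spec.systolic_lobe.unit(t_phase) + dd_req * spec.inflow_unit(t_phase)

    pad = 6.0
    origin = np.array([-pad, -(w / 2 + pad), -(w / 2 + pad)])
    nx = int(np.round((L + 2 * pad) / s)) + 1
    nyz = int(np.round((w + 2 * pad) / s)) + 1
    shape = (nx, nyz, nyz)

    velocity = np.zeros((spec.n_phases, 3) + shape)
    velocity[:, 0] = (u_phase * 100.0)[:, None, None, None]  # mm/ms -> cm/s

    fld = VelocityField4D(
        velocity=velocity, spacing=np.full(3, s), origin=origin,
        phase_times=t_phase, cycle_length=spec.cycle_length, venc=spec.venc,
    )

    # channel mask (ED = ES: rigid duct)
    idx = np.indices(shape)
    coords = origin[:, None, None, None] + idx * s
    mask = (
        (coords[0] > 0.0) & (coords[0] < L)
        & (np.abs(coords[1]) < w / 2) & (np.abs(coords[2]) < w / 2)
    )
    model = build_lv_model(mask, mask, np.full(3, s), origin)

    disc_r = w / np.sqrt(2.0) + 1.0  # covers the square cross-section
    mitral = static_valve_plane("mitral", [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                                disc_r, t_phase, spec.cycle_length)
    aortic = static_valve_plane("aortic", [L, 0.0, 0.0], [1.0, 0.0, 0.0],
                                disc_r, t_phase, spec.cycle_length)

    # ground truth from the discrete waveform and 1-D advection
    ds_d, dd_d = _discrete_displacements(spec, u_phase)
    a, b = spec.margin, L - spec.margin
    span = b - a
    f_av = _overlap(L - ds_d, np.inf, a, b) / span
    f_mv = _overlap(-np.inf, dd_d, a, b) / span
    f_df = _overlap(L - ds_d, b, a, dd_d) / span
    fractions = {
        "DF": f_df,
        "DEF": f_av - f_df,
        "RI": f_mv - f_df,
        "RV": 1.0 - f_av - f_mv + f_df,
    }
    area = w * w  # mm^2
    seeds = seed_positions(model, spec.margin)
    x0 = seeds[:, 0]
    labels = np.where(
        x0 < dd_d,
        np.where(x0 > L - ds_d, "DF", "RI"),
        np.where(x0 > L - ds_d, "DEF", "RV"),
    )
    truth = GroundTruth(
        fractions=fractions,
        sv_ml=ds_d * area / 1000.0,
        inflow_ml=dd_d * area / 1000.0,
        seed_labels=labels,
        description="1-D plug-flow advection, closed form",
    )
    if spec.noise_sd > 0:
        fld = add_velocity_noise(fld, spec.noise_sd, spec.rng_seed)
    return Phantom(field=fld, model=model, mitral=mitral, aortic=aortic,
                   ground_truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Ellipsoidal LV phantom
# ---------------------------------------------------------------------------


def _jet_unit_field(points: np.ndarray, centre: np.ndarray, normal: np.ndarray,
                    radius: float, spread: float) -> np.ndarray:
    """Velocity of a confined transvalvular jet, per unit volumetric flux.

    Axisymmetric Stokes streamfunction ``psi = Phi(rho / R(z)) / (2 pi)``
    with a Poiseuille profile ``Phi(u) = u^2 (2 - u^2)`` for ``u < 1`` (1
    beyond) and a jet radius ``R(z) = radius * sqrt(1 + (z / spread)^2)``
    that widens away from the valve plane.  The field is exactly
    divergence-free, transports the full flux through every cross-section
    (along ``+normal`` for positive flux), and vanishes on the valve plane
    outside the disc as well as everywhere outside the jet cone.  Returns
    mm/ms per (mm^3/ms) of flux, shape (N, 3).
    """
    p = np.atleast_2d(points) - centre
    n = np.asarray(normal, dtype=np.float64)
    z = p @ n
    rvec = p - np.outer(z, n)
    rho = np.sqrt(np.einsum("ij,ij->i", rvec, rvec))
    rz = radius * np.sqrt(1.0 + (z / spread) ** 2)
    drz = radius**2 * z / (spread**2 * rz)
    u = rho / rz
    inside = u < 1.0
    u = np.where(inside, u, 1.0)
    # v_axial = (1/rho) dpsi/drho, v_radial = -(1/rho) dpsi/dz
    v_axial = np.where(inside, (2.0 / np.pi) * (1.0 - u**2) / rz**2, 0.0)
    phi_prime = 4.0 * u * (1.0 - u**2)
    v_radial_over_rho = np.where(inside, phi_prime * drz / (2.0 * np.pi * rz**2 *
                                                            np.where(rho > 0, rho, 1.0)), 0.0)
    v = v_axial[:, None] * n + v_radial_over_rho[:, None] * rvec
    return v


def make_lv_phantom(spec: PhantomSpec) -> Phantom:
    """Half-ellipsoidal cavity driven by confined jets at two valve discs.

    The cavity is the lower half of an ellipsoid with base radius
    ``semi_axis`` and apex ``apex_depth`` below the base plane.  Mitral and
    aortic discs lie on the base plane; their inflow and outflow jet fields
    are gated by the diastolic and systolic waveforms, each normalised so the
    cycle-integrated flux equals the prescribed stroke volume.  Per-seed
    fates have no closed form; :func:`reference_fates` provides the oracle
    labelling by fine-step integration.
    """
    if spec.geometry != "ellipsoid":
        spec = replace(spec, geometry="ellipsoid")
    a, c, s = spec.semi_axis, spec.apex_depth, spec.spacing
    c_mv = np.array([spec.mitral_centre_x, 0.0, 0.0])
    c_ao = np.array([spec.aortic_centre_x, 0.0, 0.0])
    if abs(spec.aortic_centre_x - spec.mitral_centre_x) <= spec.mitral_radius + spec.aortic_radius:
        raise ValueError("mitral and aortic discs overlap")
    if max(abs(spec.mitral_centre_x) + spec.mitral_radius,
           abs(spec.aortic_centre_x) + spec.aortic_radius) >= a:
        raise ValueError("valve discs extend beyond the base of the cavity")

    pad = 5.0
    top = 8.0
    origin = np.array([-(a + pad), -(a + pad), -(c + pad)])
    # keep voxel centres off the base plane (where the jet profile kinks)
    if abs((0.0 - origin[2]) / s - np.round((0.0 - origin[2]) / s)) < 1e-9:
        origin[2] += 0.5 * s
    nxy = int(np.round(2 * (a + pad) / s)) + 1
    nz = int(np.round((c + pad + top) / s)) + 1
    shape = (nxy, nxy, nz)

    idx = np.indices(shape)
    coords = (origin[:, None, None, None] + idx * s).reshape(3, -1).T

    w_mv = _jet_unit_field(coords, c_mv, [0.0, 0.0, -1.0], spec.mitral_radius,
                           spec.jet_spread_length)
    w_ao = _jet_unit_field(coords, c_ao, [0.0, 0.0, 1.0], spec.aortic_radius,
                           spec.jet_spread_length)

    sv_mm3 = spec.stroke_volume_ml * 1000.0
    t_phase = spec.phase_times
    q_in = sv_mm3 * spec.inflow_unit(t_phase)  # mm^3/ms
    q_out = sv_mm3 * spec.systolic_lobe.unit(t_phase)

    velocity = np.empty((spec.n_phases, 3) + shape)
    for i in range(spec.n_phases):
        v = q_in[i] * w_mv + q_out[i] * w_ao  # mm/ms
        velocity[i] = (v * 100.0).T.reshape((3,) + shape)  # -> cm/s

    fld = VelocityField4D(
        velocity=velocity, spacing=np.full(3, s), origin=origin,
        phase_times=t_phase, cycle_length=spec.cycle_length, venc=spec.venc,
    )

    xx = origin[0] + idx[0] * s
    yy = origin[1] + idx[1] * s
    zz = origin[2] + idx[2] * s
    mask = ((xx / a) ** 2 + (yy / a) ** 2 + (zz / c) ** 2 <= 1.0) & (zz < 0.0)
    model = build_lv_model(mask, mask, np.full(3, s), origin)

    mitral = static_valve_plane("mitral", c_mv, [0.0, 0.0, -1.0],
                                spec.mitral_radius, t_phase, spec.cycle_length)
    aortic = static_valve_plane("aortic", c_ao, [0.0, 0.0, 1.0],
                                spec.aortic_radius, t_phase, spec.cycle_length)

    truth = GroundTruth(
        fractions=None,
        sv_ml=spec.stroke_volume_ml,
        inflow_ml=spec.stroke_volume_ml,
        description="confined-jet cavity; per-seed fates via reference_fates()",
    )
    if spec.noise_sd > 0:
        fld = add_velocity_noise(fld, spec.noise_sd, spec.rng_seed)
    return Phantom(field=fld, model=model, mitral=mitral, aortic=aortic,
                   ground_truth=truth, spec=spec)


def reference_fates(phantom: Phantom, step: float = 1.0, es_time: float | None = None):
    """Oracle component labels by fine-step integration (default 1 ms).

    Runs the same tracer at a 10x finer step than the analysis default; used
    to ground-truth per-seed fates where no closed form exists.
    """
    from .components import classify_pathlines
    from .tracing import TraceConfig, trace_all

    cfg = TraceConfig(step=step, margin=phantom.spec.margin)
    seeds = seed_positions(phantom.model, phantom.spec.margin)
    pset = trace_all(seeds, phantom.field, phantom.mitral, phantom.aortic,
                     phantom.model, cfg, ed_time=0.0,
                     es_time=es_time if es_time is not None else phantom.spec.systole_end)
    return classify_pathlines(pset, phantom.model, cfg.es_tolerance)


# ---------------------------------------------------------------------------
# Measurement corruption
# ---------------------------------------------------------------------------


@dataclass
class RespiratoryCorruption:
    """Respiratory blurring model: image-domain averaging over breathing states.

    ``amplitude`` is the peak diaphragm excursion (mm); the heart is assumed
    to move by ``heart_scale`` times the diaphragm along ``direction``.  The
    default direction is oblique (30 degrees off the phantom long axis):
    the LV long axis is tilted with respect to the craniocaudal breathing
    motion, so respiratory displacement has components both along and across
    the transvalvular jets.  Displacements follow a raised-cosine trajectory
    with an end-expiratory plateau, sampled at ``n_states`` breathing phases
    (state 0 is always the end-expiratory reference).  With a
    ``gating_window`` (mm, diaphragm position), states displaced beyond the
    window are rejected before averaging — emulating navigator gating; with
    ``None`` every state is averaged (non-compensated scan).
    """

    amplitude: float  # mm diaphragm excursion
    period: float = 4000.0  # ms (nominal; averaging is phase-based)
    direction: tuple[float, float, float] = (0.5, 0.0, 0.8660254037844387)
    gating_window: float | None = None
    n_states: int = 12
    heart_scale: float = 0.6
    rng_seed: int = 0

    def displacements(self) -> np.ndarray:
        """Diaphragm displacement (mm) of each sampled breathing state."""
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        rng = np.random.default_rng(self.rng_seed)
        # stratified breathing phases; state 0 anchored at end-expiration
        k = np.arange(self.n_states - 1)
        tau = (k + rng.uniform(size=self.n_states - 1)) / (self.n_states - 1)
        tau = np.concatenate([[0.0], tau])
        return self.amplitude * ((1.0 - np.cos(2.0 * np.pi * tau)) / 2.0) ** 2


def apply_respiratory_corruption(
    field: VelocityField4D, corruption: RespiratoryCorruption
) -> VelocityField4D:
    """Average the field over rigidly displaced respiratory states.

    Each retained state sees the heart displaced by
    ``heart_scale * d_k * direction``; its field is the original sampled at
    the displaced position (linear interpolation).  Deterministic given
    ``corruption.rng_seed``.
    """
    d = corruption.displacements()
    if corruption.gating_window is not None:
        if corruption.gating_window < 0:
            raise ValueError("gating window must be >= 0")
        d = d[np.abs(d) <= corruption.gating_window]
        if d.size == 0:
            raise ValueError("gating window excludes every respiratory state")
    direction = np.asarray(corruption.direction, dtype=np.float64)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("direction must be non-zero")
    direction = direction / nrm

    if np.allclose(d, 0.0):
        return replace(field, velocity=field.velocity.copy())

    out = np.zeros_like(field.velocity)
    for dk in d:
        shift_vox = corruption.heart_scale * dk * direction / field.spacing
        if np.allclose(shift_vox, 0.0):
            out += field.velocity
            continue
        for ti in range(field.n_phases):
            for ci in range(3):
                out[ti, ci] += nd_shift(
                    field.velocity[ti, ci], shift_vox, order=1, mode="nearest"
                )
    out /= d.size
    return replace(field, velocity=out)


def add_velocity_noise(field: VelocityField4D, sd: float, rng_seed: int) -> VelocityField4D:
    """Add i.i.d. zero-mean Gaussian noise (cm/s) to every sample."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    if sd == 0:
        return replace(field, velocity=field.velocity.copy())
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, sd, size=field.velocity.shape)
    return replace(field, velocity=field.velocity + noise)


# ---------------------------------------------------------------------------
# Persistence (the layout the pipeline consumes)
# ---------------------------------------------------------------------------


def save_phantom(phantom: Phantom, directory: str | Path) -> Path:
    """Write field, masks, valve planes, and ground truth to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_velocity_field(phantom.field, directory)
    save_mask(phantom.model.ed_mask, phantom.model.spacing, phantom.model.origin,
              directory / "ed_mask.nii.gz")
    save_mask(phantom.model.es_mask, phantom.model.spacing, phantom.model.origin,
              directory / "es_mask.nii.gz")
    save_valve_plane(phantom.mitral, directory / "mitral.json")
    save_valve_plane(phantom.aortic, directory / "aortic.json")
    gt = phantom.ground_truth
    payload = {
        "fractions": gt.fractions,
        "sv_ml": gt.sv_ml,
        "inflow_ml": gt.inflow_ml,
        "description": gt.description,
    }
    (directory / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    return directory
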