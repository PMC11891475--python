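"""Bidirectional pathline integration with stopping rules.

Massless virtual particles are released at end-diastole and advected through
the measured velocity field with classical fourth-order Runge-Kutta steps
(default 10 ms).  Forward traces advance through systole to end-systole;
backward traces run back through diastole to the end-systole of the previous
reconstructed cycle, so that forward traces capture ejection and backward
traces capture filling.  A trace halts early when the particle crosses a
valve plane, strays more than a displacement limit (default 3 cm) outside the
end-diastolic LV model, or leaves the imaged volume.

Everything is deterministic: two runs on identical inputs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .field_model import OutOfDomainError, VelocityField4D
from .geometry import LVModel, PlaneGeometry, ValvePlane

__all__ = [
    "TraceConfig",
    "Termination",
    "Pathline",
    "PathlineSet",
    "rk4_step",
    "detect_plane_crossing",
    "trace_particle",
    "trace_all",
    "TERMINATION_KINDS",
]

# cm/s -> mm/ms
_VEL = 0.01

# Termination codes (columnar storage)
REACHED_END = 0
CROSSED_MITRAL = 1
CROSSED_AORTIC = 2
DISPLACEMENT_EXCEEDED = 3
LEFT_DOMAIN = 4
_ACTIVE = -1

TERMINATION_KINDS = {
    REACHED_END: "reached_end",
    CROSSED_MITRAL: "crossed_mitral",
    CROSSED_AORTIC: "crossed_aortic",
    DISPLACEMENT_EXCEEDED: "displacement_exceeded",
    LEFT_DOMAIN: "left_domain",
}
_KIND_CODES = {v: k for k, v in TERMINATION_KINDS.items()}


@dataclass
class TraceConfig:
    """Integration and stopping parameters (all ms / mm).

    ``step``: RK4 time step.  ``displacement_limit``: maximum signed distance
    outside the end-diastolic model before a trace is halted.
    ``es_tolerance``: how far a retained particle may end outside the
    end-systolic model before it is excluded from analysis.  ``margin``: seed
    clearance from the end-diastolic wall.
    """

    step: float = 10.0
    displacement_limit: float = 30.0
    es_tolerance: float = 5.0
    margin: float = 2.5

    def __post_init__(self) -> None:
        for name in ("step", "displacement_limit", "es_tolerance", "margin"):
            if getattr(self, name) < 0 or (name == "step" and self.step <= 0):
                raise ValueError(f"{name} must be positive")


@dataclass
class Termination:
    kind: str
    time: float  # ms, unwrapped along the trace direction
    position: np.ndarray  # (3,) mm


@dataclass
class Pathline:
    """One particle trajectory in one trace direction."""

    seed_id: int
    direction: Literal["forward", "backward"]
    samples: list  # [(time ms, position (3,)), ...] in trace order
    termination: Termination


@dataclass
class PathlineSet:
    """Columnar forward/backward trace results for a full seed set."""

    seeds: np.ndarray  # (N, 3) mm
    ed_time: float
    es_time: float
    fwd_kind: np.ndarray  # (N,) int codes
    fwd_time: np.ndarray
    fwd_position: np.ndarray  # (N, 3) termination positions
    bwd_kind: np.ndarray
    bwd_time: np.ndarray
    bwd_position: np.ndarray
    fwd_paths: np.ndarray | None = field(default=None, repr=False)  # (S, N, 3)
    bwd_paths: np.ndarray | None = field(default=None, repr=False)
    fwd_path_times: np.ndarray | None = field(default=None, repr=False)
    bwd_path_times: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_seeds(self) -> int:
        return self.seeds.shape[0]

    def pathline(self, seed_id: int, direction: str) -> Pathline:
        """Reconstruct a single :class:`Pathline` (requires stored paths for
        full trajectories; otherwise samples hold seed and endpoint only)."""
        if direction == "forward":
            kind, time, pos, paths, ptimes = (
                self.fwd_kind, self.fwd_time, self.fwd_position, self.fwd_paths, self.fwd_path_times)
        else:
            kind, time, pos, paths, ptimes = (
                self.bwd_kind, self.bwd_time, self.bwd_position, self.bwd_paths, self.bwd_path_times)
        term = Termination(TERMINATION_KINDS[int(kind[seed_id])], float(time[seed_id]), pos[seed_id].copy())
        samples = [(self.ed_time, self.seeds[seed_id].copy())]
        if paths is not None:
            for s in range(paths.shape[0]):
                p = paths[s, seed_id]
                if np.any(np.isnan(p)):
                    break
                samples.append((float(ptimes[s]), p.copy()))
        samples.append((term.time, term.position.copy()))
        return Pathline(seed_id=seed_id, direction=direction, samples=samples, termination=term)

    def save(self, path) -> None:
        arrays = {
            "seeds": self.seeds, "fwd_kind": self.fwd_kind, "fwd_time": self.fwd_time,
            "fwd_position": self.fwd_position, "bwd_kind": self.bwd_kind,
            "bwd_time": self.bwd_time, "bwd_position": self.bwd_position,
            "times": np.array([self.ed_time, self.es_time]),
        }
        if self.fwd_paths is not None:
            arrays.update(fwd_paths=self.fwd_paths, bwd_paths=self.bwd_paths,
                          fwd_path_times=self.fwd_path_times, bwd_path_times=self.bwd_path_times)
        np.savez_compressed(path, **arrays)


# ---------------------------------------------------------------------------
# Single-step primitives
# ---------------------------------------------------------------------------


def rk4_step(field: VelocityField4D, position: np.ndarray, time: float, h: float) -> np.ndarray:
    """One classical RK4 update of a particle position (mm), step ``h`` ms.

    Negative ``h`` steps backward in time.  Raises
    :class:`~lvflow.field_model.OutOfDomainError` if any sub-step samples
    outside the grid.
    """
    p = np.asarray(position, dtype=np.float64)
    k1 = _VEL * field.sample(p, time)
    k2 = _VEL * field.sample(p + 0.5 * h * k1, time + 0.5 * h)
    k3 = _VEL * field.sample(p + 0.5 * h * k2, time + 0.5 * h)
    k4 = _VEL * field.sample(p + h * k3, time + h)
    return p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@dataclass
class Crossing:
    position: np.ndarray
    parameter: float  # fraction along the segment in [0, 1]
    direction: int  # +1 along the plane normal, -1 against it


def detect_plane_crossing(p0: np.ndarray, p1: np.ndarray, plane: PlaneGeometry) -> Crossing | None:
    """Intersection of segment ``p0 -> p1`` with a bounded disc, if any.

    A crossing requires the signed plane distances of the endpoints to change
    sign strictly, and the interpolated intersection point to lie within
    ``radius`` of the disc centre in-plane.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    if np.array_equal(p0, p1):
        return None
    s0 = float(np.dot(p0 - plane.centre, plane.normal))
    s1 = float(np.dot(p1 - plane.centre, plane.normal))
    if not (s0 * s1 < 0.0):
        return None
    u = s0 / (s0 - s1)
    x = p0 + u * (p1 - p0)
    inplane = x - plane.centre
    inplane = inplane - np.dot(inplane, plane.normal) * plane.normal
    if np.linalg.norm(inplane) > plane.radius:
        return None
    return Crossing(position=x, parameter=u, direction=1 if s1 > s0 else -1)


# ---------------------------------------------------------------------------
# Vectorised tracing kernel
# ---------------------------------------------------------------------------


def _segment_crossings(p0, p1, plane: PlaneGeometry):
    """Vectorised disc-crossing test for many segments.

    Returns ``(hit (N,) bool, u (N,), x (N, 3))``; u and x are only valid
    where hit is True.
    """
    d0 = (p0 - plane.centre) @ plane.normal
    d1 = (p1 - plane.centre) @ plane.normal
    hit = d0 * d1 < 0.0
    denom = np.where(hit, d0 - d1, 1.0)
    u0 = np.where(hit, d0 / denom, 0.0)
    x = p0 + u0[:, None] * (p1 - p0)
    inplane = x - plane.centre
    inplane = inplane - np.outer(inplane @ plane.normal, plane.normal)
    hit &= np.einsum("ij,ij->i", inplane, inplane) <= plane.radius**2
    return hit, np.where(hit, u0, np.inf), x


def _trace_direction(
    seeds: np.ndarray,
    field_: VelocityField4D,
    mitral: ValvePlane,
    aortic: ValvePlane,
    model: LVModel,
    cfg: TraceConfig,
    t0: float,
    duration: float,
    sign: float,
    store_paths: bool,
):
    """Advect all seeds simultaneously in one time direction."""
    n = seeds.shape[0]
    pos = seeds.astype(np.float64).copy()
    kind = np.full(n, _ACTIVE, dtype=np.int8)
    term_time = np.full(n, t0, dtype=np.float64)
    term_pos = pos.copy()
    dist_ed = model.ed_distance()

    n_full = int(np.floor(duration / cfg.step + 1e-9))
    steps = [cfg.step] * n_full
    rem = duration - n_full * cfg.step
    if rem > 1e-9:
        steps.append(rem)

    paths = [] if store_paths else None
    path_times = [] if store_paths else None

    elapsed = 0.0
    for h_abs in steps:
        h = sign * h_abs
        t = t0 + sign * elapsed
        active = kind == _ACTIVE
        if not active.any():
            break
        idx = np.flatnonzero(active)
        p = pos[idx]

        # RK4 with cm/s -> mm/ms conversion; sub-steps outside the grid
        # terminate the particle at its pre-step position.
        ok = np.ones(idx.shape[0], dtype=bool)
        v1, in1 = field_.sample_many(p, t)
        ok &= in1
        k1 = _VEL * v1
        v2, in2 = field_.sample_many(p + 0.5 * h * k1, t + 0.5 * h)
        ok &= in2
        k2 = _VEL * v2
        v3, in3 = field_.sample_many(p + 0.5 * h * k2, t + 0.5 * h)
        ok &= in3
        k3 = _VEL * v3
        v4, in4 = field_.sample_many(p + h * k3, t + h)
        ok &= in4
        k4 = _VEL * v4
        newp = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        lost = idx[~ok]
        kind[lost] = LEFT_DOMAIN
        term_time[lost] = t
        term_pos[lost] = pos[lost]

        live = idx[ok]
        p_live = pos[live]
        newp_live = newp[ok]

        # Valve crossings, planes evaluated at the segment mid-time.  Mitral is
        # checked first; a segment crossing both is resolved by the smaller
        # interpolation parameter along the segment (mitral wins ties).
        t_mid = t + 0.5 * h
        hit_m, u_m, x_m = _segment_crossings(p_live, newp_live, mitral.at_time(t_mid))
        hit_a, u_a, x_a = _segment_crossings(p_live, newp_live, aortic.at_time(t_mid))
        mitral_first = hit_m & (~hit_a | (u_m <= u_a))
        aortic_first = hit_a & ~mitral_first

        mi = live[mitral_first]
        kind[mi] = CROSSED_MITRAL
        term_time[mi] = t + u_m[mitral_first] * h
        term_pos[mi] = x_m[mitral_first]
        ai = live[aortic_first]
        kind[ai] = CROSSED_AORTIC
        term_time[ai] = t + u_a[aortic_first] * h
        term_pos[ai] = x_a[aortic_first]

        # Displacement stop: too far outside the end-diastolic model.
        surv = live[~(mitral_first | aortic_first)]
        newp_surv = newp_live[~(mitral_first | aortic_first)]
        too_far = dist_ed.at(newp_surv) > cfg.displacement_limit
        di = surv[too_far]
        kind[di] = DISPLACEMENT_EXCEEDED
        term_time[di] = t + h
        term_pos[di] = newp_surv[too_far]

        keep = surv[~too_far]
        pos[keep] = newp_surv[~too_far]
        elapsed += h_abs

        if store_paths:
            snap = np.full((n, 3), np.nan)
            snap[keep] = pos[keep]
            paths.append(snap)
            path_times.append(t0 + sign * elapsed)

    still = kind == _ACTIVE
    kind[still] = REACHED_END
    term_time[still] = t0 + sign * duration
    term_pos[still] = pos[still]
    if store_paths:
        paths = np.array(paths) if paths else np.empty((0, n, 3))
        path_times = np.asarray(path_times, dtype=np.float64)
    return kind, term_time, term_pos, paths, path_times


def trace_all(
    seeds: np.ndarray,
    field_: VelocityField4D,
    mitral: ValvePlane,
    aortic: ValvePlane,
    model: LVModel,
    cfg: TraceConfig | None = None,
    ed_time: float = 0.0,
    es_time: float | None = None,
    store_paths: bool = False,
) -> PathlineSet:
    """Trace every seed forward (through systole) and backward (through
    diastole) from end-diastole to end-systole.

    ``es_time`` is usually taken from the aortic flux curve (aortic-valve
    closure, see :func:`lvflow.hemodynamics.identify_peaks`); it must be
    provided explicitly here.  If the step does not divide the interval the
    final partial step uses the remainder, so traces end exactly at
    end-systole.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.shape[0] < 1:
        raise ValueError("need at least one seed")
    if es_time is None:
        raise ValueError("es_time is required (derive it from the aortic flux curve)")
    cfg = cfg or TraceConfig()
    cycle = field_.cycle_length
    dur_fwd = (es_time - ed_time) % cycle
    dur_bwd = cycle - dur_fwd
    f_kind, f_time, f_pos, f_paths, f_pt = _trace_direction(
        seeds, field_, mitral, aortic, model, cfg, ed_time, dur_fwd, +1.0, store_paths)
    b_kind, b_time, b_pos, b_paths, b_pt = _trace_direction(
        seeds, field_, mitral, aortic, model, cfg, ed_time, dur_bwd, -1.0, store_paths)
    return PathlineSet(
        seeds=seeds, ed_time=ed_time, es_time=es_time,
        fwd_kind=f_kind, fwd_time=f_time, fwd_position=f_pos,
        bwd_kind=b_kind, bwd_time=b_time, bwd_position=b_pos,
        fwd_paths=f_paths, bwd_paths=b_paths,
        fwd_path_times=f_pt, bwd_path_times=b_pt,
    )


def trace_particle(
    field_: VelocityField4D,
    seed: np.ndarray,
    mitral: ValvePlane,
    aortic: ValvePlane,
    model: LVModel,
    cfg: TraceConfig | None = None,
    direction: Literal["forward", "backward"] = "forward",
    ed_time: float = 0.0,
    es_time: float | None = None,
) -> Pathline:
    """Trace a single particle and return its full :class:`Pathline`."""
    pset = trace_all(
        np.asarray(seed, dtype=np.float64)[None, :], field_, mitral, aortic, model,
        cfg=cfg, ed_time=ed_time, es_time=es_time, store_paths=True)
    return pset.pathline(0, direction)
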