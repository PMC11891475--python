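"""Orchestration: load inputs, trace, classify, quantify, write artifacts.

:func:`analyze_case` is the in-memory pipeline (field + model + valves in,
component/quality/haemodynamic results out); :func:`run_pipeline` wraps it
with file I/O and a deterministic output directory; :func:`run_comparison`
pairs two completed cohorts.  Every output is reproducible bit-exactly from
the config snapshot and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import ComparisonReport, compare_conditions
from .components import (
    ComponentResult,
    QualityReport,
    classify_pathlines,
    quality_assess,
    summarize_components,
)
from .field_model import VelocityField4D, load_velocity_field, validate_field
from .geometry import (
    LVModel,
    ValvePlane,
    apply_rigid_transform,
    build_lv_model,
    load_mask,
    load_rigid_transform,
    load_valve_plane,
    seed_positions,
)
from .hemodynamics import (
    BLOOD_DENSITY,
    CardiacPhases,
    FluxCurve,
    HemoResult,
    hemo_at_phases,
    identify_peaks,
    plane_flux_curve,
)
from .tracing import TraceConfig, trace_all

__all__ = ["RunConfig", "AnalysisResult", "analyze_case", "run_pipeline", "run_comparison"]

log = logging.getLogger("lvflow")


@dataclass
class RunConfig:
    """Paths and parameters for one analysis run (YAML-serialisable)."""

    field_dir: str
    ed_mask: str
    es_mask: str
    mitral: str
    aortic: str
    out_dir: str
    transform: str | None = None
    subject: str = "case"
    condition: str = "default"
    step: float = 10.0
    displacement_limit: float = 30.0
    es_tolerance: float = 5.0
    margin: float = 2.5
    density: float = BLOOD_DENSITY
    raster_spacing: float | None = None
    ed_time: float = 0.0
    es_time: float | None = None  # None: from the aortic flux curve
    store_paths: bool = False
    strict: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def trace_config(self) -> TraceConfig:
        return TraceConfig(
            step=self.step, displacement_limit=self.displacement_limit,
            es_tolerance=self.es_tolerance, margin=self.margin,
        )


@dataclass
class AnalysisResult:
    """Everything one analysis produces, in memory."""

    components: ComponentResult
    quality: QualityReport
    peaks: CardiacPhases
    mitral_flux: FluxCurve
    aortic_flux: FluxCurve
    hemo: list[HemoResult]
    n_seeds: int
    pathlines: object = field(default=None, repr=False)

    def flat_row(self, subject: str = "case", condition: str = "default") -> dict:
        """One flat record per analysis (the comparison stage's input)."""
        c = self.components
        row = {
            "subject": subject,
            "condition": condition,
            "n_seeded": c.n_seeded,
            **{f"n_{k}": v for k, v in c.counts.items()},
            **{f"frac_{k}": v for k, v in c.fractions.items()},
            "sv": c.sv,
            "mitral_inflow": c.mitral_inflow,
            "ef": c.ef,
            "edv": c.edv,
            "def_ri_mismatch": c.def_ri_mismatch,
            "abs_def_ri_mismatch": abs(c.def_ri_mismatch),
            "valvular_mismatch": c.valvular_mismatch,
            "excluded_fraction": c.excluded_fraction,
            "quality_excluded_pass": self.quality.excluded_pass,
            "quality_mismatch_pass": self.quality.mismatch_pass,
            "mitral_net_forward_ml": self.mitral_flux.net_forward_volume,
            "aortic_net_forward_ml": self.aortic_flux.net_forward_volume,
            "peak_systole_ms": self.peaks.peak_systole,
            "e_peak_ms": self.peaks.e_peak,
            "a_peak_ms": self.peaks.a_peak if self.peaks.a_peak_defined else np.nan,
            "es_time_ms": self.peaks.es_time,
        }
        for h in self.hemo:
            row[f"total_ke_{h.phase}"] = h.total_ke
            row[f"indexed_ke_{h.phase}"] = h.indexed_ke
            row[f"total_vorticity_{h.phase}"] = h.total_vorticity
            row[f"indexed_vorticity_{h.phase}"] = h.indexed_vorticity
        return row


def analyze_case(
    field_: VelocityField4D,
    model: LVModel,
    mitral: ValvePlane,
    aortic: ValvePlane,
    trace_cfg: TraceConfig | None = None,
    density: float = BLOOD_DENSITY,
    raster_spacing: float | None = None,
    ed_time: float = 0.0,
    es_time: float | None = None,
    store_paths: bool = False,
) -> AnalysisResult:
    """Full in-memory analysis of one case.

    Valve flux curves are computed first; if ``es_time`` is not given it is
    taken from the aortic curve (aortic-valve closure).  Particles are then
    traced bidirectionally from end-diastole, classified into the four flow
    components, gated for quality, and KE/vorticity totals are evaluated at
    the three landmark phases on the end-diastolic mask.
    """
    trace_cfg = trace_cfg or TraceConfig()
    mitral_flux = plane_flux_curve(field_, mitral, raster_spacing)
    aortic_flux = plane_flux_curve(field_, aortic, raster_spacing)
    peaks = identify_peaks(mitral_flux, aortic_flux)
    if es_time is None:
        es_time = peaks.es_time
    seeds = seed_positions(model, trace_cfg.margin)
    log.info("seeded %d particles (margin %.2f mm)", seeds.shape[0], trace_cfg.margin)
    pset = trace_all(seeds, field_, mitral, aortic, model, trace_cfg,
                     ed_time=ed_time, es_time=es_time, store_paths=store_paths)
    labels = classify_pathlines(pset, model, trace_cfg.es_tolerance)
    comp = summarize_components(labels, model.voxel_volume, model.edv)
    quality = quality_assess(comp)
    hemo = hemo_at_phases(field_, model.ed_mask, model.edv, peaks, density=density)
    return AnalysisResult(
        components=comp, quality=quality, peaks=peaks,
        mitral_flux=mitral_flux, aortic_flux=aortic_flux,
        hemo=hemo, n_seeds=seeds.shape[0],
        pathlines=pset if store_paths else None,
    )


def _load_inputs(config: RunConfig):
    field_ = load_velocity_field(config.field_dir)
    ed_mask, spacing, origin = load_mask(config.ed_mask)
    es_mask, sp2, og2 = load_mask(config.es_mask)
    if not (np.allclose(spacing, sp2) and np.allclose(origin, og2)):
        raise ValueError("end-diastolic and end-systolic masks are on different grids")
    model = build_lv_model(ed_mask, es_mask, spacing, origin)
    mitral = load_valve_plane(config.mitral)
    aortic = load_valve_plane(config.aortic)
    if config.transform:
        transform = load_rigid_transform(config.transform)
        model = apply_rigid_transform(transform, model)
        mitral = apply_rigid_transform(transform, mitral)
        aortic = apply_rigid_transform(transform, aortic)
    return field_, model, mitral, aortic


def run_pipeline(config: RunConfig) -> AnalysisResult:
    """Run one case from files and write a deterministic artifact directory.

    Outputs: ``config.yaml`` snapshot, ``results.json`` (nested),
    ``results.csv`` (one flat row), ``flux.csv``, ``hemo.csv``,
    ``quality.json``, optional ``pathlines.npz``, and ``run.log``.  With
    ``strict=True`` a failed quality gate raises instead of only being
    recorded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        field_, model, mitral, aortic = _load_inputs(config)
        report = validate_field(field_)
        if report.aliasing_fraction > 0:
            log.warning("%.3f%% of samples exceed Venc", 100 * report.aliasing_fraction)
        result = analyze_case(
            field_, model, mitral, aortic,
            trace_cfg=config.trace_config(), density=config.density,
            raster_spacing=config.raster_spacing, ed_time=config.ed_time,
            es_time=config.es_time, store_paths=config.store_paths,
        )
        config.to_yaml(out / "config.yaml")
        row = result.flat_row(config.subject, config.condition)
        pd.DataFrame([row]).to_csv(out / "results.csv", index=False)
        payload = {
            "subject": config.subject,
            "condition": config.condition,
            "components": {
                "counts": result.components.counts,
                "fractions": result.components.fractions,
                "sv_ml": result.components.sv,
                "mitral_inflow_ml": result.components.mitral_inflow,
                "ef": result.components.ef,
                "edv_ml": result.components.edv,
                "ef_denominator": "LVModel.edv (end-diastolic mask volume)",
                "def_ri_mismatch": result.components.def_ri_mismatch,
                "valvular_mismatch_ml": result.components.valvular_mismatch,
                "excluded_fraction": result.components.excluded_fraction,
            },
            "quality": {
                "excluded_fraction": result.quality.excluded_fraction,
                "abs_def_ri_mismatch": result.quality.abs_def_ri_mismatch,
                "excluded_pass": result.quality.excluded_pass,
                "mismatch_pass": result.quality.mismatch_pass,
                "gates": {"excluded": result.quality.excluded_gate,
                          "mismatch": result.quality.mismatch_gate},
            },
            "peaks": {
                "peak_systole_ms": result.peaks.peak_systole,
                "e_peak_ms": result.peaks.e_peak,
                "a_peak_ms": result.peaks.a_peak,
                "es_time_ms": result.peaks.es_time,
            },
            "hemodynamics": [
                {"phase": h.phase, "time_ms": h.time, "total_ke_uJ": h.total_ke,
                 "indexed_ke_uJ_per_ml": h.indexed_ke,
                 "total_vorticity_per_s": h.total_vorticity,
                 "indexed_vorticity_per_s_per_ml": h.indexed_vorticity,
                 "vorticity_convention": "sum of voxel curl magnitudes"}
                for h in result.hemo
            ],
            "field_validation": {
                "aliasing_fraction": report.aliasing_fraction,
                "n_nonfinite": report.n_nonfinite,
            },
        }
        (out / "results.json").write_text(json.dumps(payload, indent=2))
        flux = pd.DataFrame({
            "time_ms": result.mitral_flux.times,
            "mitral_ml_per_s": result.mitral_flux.flow_rate,
            "aortic_ml_per_s": result.aortic_flux.flow_rate,
        })
        flux.to_csv(out / "flux.csv", index=False)
        pd.DataFrame([
            {"phase": h.phase, "time_ms": h.time, "total_ke_uJ": h.total_ke,
             "indexed_ke_uJ_per_ml": h.indexed_ke,
             "total_vorticity_per_s": h.total_vorticity,
             "indexed_vorticity_per_s_per_ml": h.indexed_vorticity}
            for h in result.hemo
        ]).to_csv(out / "hemo.csv", index=False)
        if config.store_paths and result.pathlines is not None:
            result.pathlines.save(out / "pathlines.npz")
        if config.strict and not result.quality.overall_pass:
            raise RuntimeError(
                f"quality gates failed: excluded={result.quality.excluded_fraction:.3f}, "
                f"|DEF-RI|={result.quality.abs_def_ri_mismatch:.3f}"
            )
        return result
    finally:
        log.removeHandler(handler)
        handler.close()


def run_comparison(
    results_a: str | Path | pd.DataFrame,
    results_b: str | Path | pd.DataFrame,
    out_dir: str | Path | None = None,
    mismatch_exclusion_gate: float | None = None,
) -> ComparisonReport:
    """Compare two cohorts of flat result rows (CSV paths or DataFrames)."""
    def load(x):
        if isinstance(x, pd.DataFrame):
            return x
        p = Path(x)
        if not p.exists():
            raise FileNotFoundError(f"results file not found: {p}")
        return pd.read_csv(p)

    report = compare_conditions(load(results_a), load(results_b),
                                mismatch_exclusion_gate=mismatch_exclusion_gate)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "comparison.csv")
        (out / "comparison.txt").write_text(report.to_text() + "\n")
    return report
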