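"""Four-component flow classification, derived volumes, and quality gates.

Each seeded particle represents one voxel of end-diastolic blood.  Its origin
(backward trace) and fate (forward trace) assign it to one of the classical
intracardiac flow components:

* **DF** (direct flow) — enters through the mitral valve and is ejected
  through the aortic valve within the same cycle;
* **DEF** (delayed ejection flow) — resident at end-diastole, ejected in
  systole;
* **RI** (retained inflow) — enters through the mitral valve and stays;
* **RV** (residual volume) — resident throughout.

Particles whose traces left the imaged volume, exceeded the displacement
limit, or ended retained but further than a tolerance outside the
end-systolic model are **EXCLUDED**.  Stroke volume is (DF+DEF) particle
count times the voxel volume; mitral inflow is (DF+RI) likewise.  In a
normally functioning heart DEF and RI carry equal volumes, so their
signed fraction difference (``mismatch = DEF - RI``) is a data-quality
metric, gated at 10 % in absolute value; the excluded-particle fraction is
gated at 20 %.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .geometry import LVModel
from .tracing import (
    CROSSED_AORTIC,
    CROSSED_MITRAL,
    DISPLACEMENT_EXCEEDED,
    LEFT_DOMAIN,
    REACHED_END,
    Pathline,
    PathlineSet,
    _KIND_CODES,
)

__all__ = [
    "ComponentLabel",
    "ComponentResult",
    "QualityReport",
    "classify_particle",
    "classify_pathlines",
    "summarize_components",
    "quality_assess",
    "EXCLUDED_FRACTION_GATE",
    "MISMATCH_GATE",
]

EXCLUDED_FRACTION_GATE = 0.20
MISMATCH_GATE = 0.10


class ComponentLabel(str, Enum):
    DF = "DF"
    DEF = "DEF"
    RI = "RI"
    RV = "RV"
    EXCLUDED = "EXCLUDED"


_INCLUDED = (ComponentLabel.DF, ComponentLabel.DEF, ComponentLabel.RI, ComponentLabel.RV)


def classify_pathlines(
    pathlines: PathlineSet, es_model: LVModel, es_tolerance: float = 5.0
) -> np.ndarray:
    """Vectorised component labels for a full traced seed set.

    Origin is the mitral valve if the backward trace crossed it, otherwise
    the LV; fate is the aortic valve if the forward trace crossed it,
    otherwise retained.  A particle is excluded when either trace left the
    domain or hit the displacement limit, or when it ended retained more than
    ``es_tolerance`` mm outside the end-systolic model without having been
    affected by any valve plane.
    """
    fwd, bwd = pathlines.fwd_kind, pathlines.bwd_kind
    broken = np.isin(fwd, (LEFT_DOMAIN, DISPLACEMENT_EXCEEDED)) | np.isin(
        bwd, (LEFT_DOMAIN, DISPLACEMENT_EXCEEDED)
    )
    retained_fwd = fwd == REACHED_END
    es_dist = np.full(pathlines.n_seeds, -np.inf)
    if retained_fwd.any():
        es_dist[retained_fwd] = es_model.es_distance().at(pathlines.fwd_position[retained_fwd])
    stranded = retained_fwd & (es_dist > es_tolerance)

    origin_mv = bwd == CROSSED_MITRAL
    fate_av = fwd == CROSSED_AORTIC

    labels = np.where(
        origin_mv,
        np.where(fate_av, ComponentLabel.DF.value, ComponentLabel.RI.value),
        np.where(fate_av, ComponentLabel.DEF.value, ComponentLabel.RV.value),
    ).astype(object)
    labels[broken | stranded] = ComponentLabel.EXCLUDED.value
    return labels


def classify_particle(
    forward: Pathline, backward: Pathline, es_model: LVModel, es_tolerance: float = 5.0
) -> ComponentLabel:
    """Component label for one forward/backward pathline pair."""
    if forward.seed_id != backward.seed_id:
        raise ValueError(
            f"pathlines belong to different seeds: {forward.seed_id} vs {backward.seed_id}"
        )
    fwd = _KIND_CODES[forward.termination.kind]
    bwd = _KIND_CODES[backward.termination.kind]
    if fwd in (LEFT_DOMAIN, DISPLACEMENT_EXCEEDED) or bwd in (LEFT_DOMAIN, DISPLACEMENT_EXCEEDED):
        return ComponentLabel.EXCLUDED
    if fwd == REACHED_END:
        d = float(es_model.es_distance().at(forward.termination.position[None, :])[0])
        if d > es_tolerance:
            return ComponentLabel.EXCLUDED
    origin_mv = bwd == CROSSED_MITRAL
    fate_av = fwd == CROSSED_AORTIC
    if origin_mv and fate_av:
        return ComponentLabel.DF
    if origin_mv:
        return ComponentLabel.RI
    if fate_av:
        return ComponentLabel.DEF
    return ComponentLabel.RV


@dataclass
class ComponentResult:
    """Counts, fractions, and derived volumes for one analysis.

    Fractions are over *included* particles and sum to 1; the excluded
    fraction is over all seeded particles.  ``def_ri_mismatch`` is the signed
    DEF - RI fraction difference; ``valvular_mismatch`` is
    ``|mitral inflow - SV|`` in mL, both from particle counts.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    voxel_volume: float  # mm^3
    sv: float  # mL
    mitral_inflow: float  # mL
    ef: float  # unitless
    def_ri_mismatch: float  # signed fraction difference
    valvular_mismatch: float  # mL
    excluded_fraction: float
    n_seeded: int
    edv: float  # mL (denominator used for EF)


def summarize_components(
    labels: np.ndarray | list, voxel_volume: float, edv: float
) -> ComponentResult:
    """Aggregate per-seed labels into counts, fractions, and volumes."""
    labels = np.asarray([l.value if isinstance(l, ComponentLabel) else l for l in np.ravel(labels)])
    n_seeded = labels.shape[0]
    counts = {lab.value: int(np.count_nonzero(labels == lab.value)) for lab in ComponentLabel}
    n_included = sum(counts[lab.value] for lab in _INCLUDED)
    if n_included == 0:
        raise ValueError("all particles were excluded; no analysis possible")
    fractions = {lab.value: counts[lab.value] / n_included for lab in _INCLUDED}
    sv = (counts["DF"] + counts["DEF"]) * voxel_volume / 1000.0
    mitral_inflow = (counts["DF"] + counts["RI"]) * voxel_volume / 1000.0
    return ComponentResult(
        counts=counts,
        fractions=fractions,
        voxel_volume=float(voxel_volume),
        sv=sv,
        mitral_inflow=mitral_inflow,
        ef=sv / edv if edv > 0 else float("nan"),
        def_ri_mismatch=fractions["DEF"] - fractions["RI"],
        valvular_mismatch=abs(mitral_inflow - sv),
        excluded_fraction=counts["EXCLUDED"] / n_seeded,
        n_seeded=n_seeded,
        edv=float(edv),
    )


@dataclass
class QualityReport:
    """Pass/fail against the two data-quality gates (strict ``<``)."""

    excluded_fraction: float
    abs_def_ri_mismatch: float
    excluded_gate: float = EXCLUDED_FRACTION_GATE
    mismatch_gate: float = MISMATCH_GATE

    @property
    def excluded_pass(self) -> bool:
        return self.excluded_fraction < self.excluded_gate

    @property
    def mismatch_pass(self) -> bool:
        return self.abs_def_ri_mismatch < self.mismatch_gate

    @property
    def overall_pass(self) -> bool:
        return self.excluded_pass and self.mismatch_pass


def quality_assess(result: ComponentResult) -> QualityReport:
    """Gate an analysis at 20 % excluded particles and 10 % |DEF - RI|."""
    return QualityReport(
        excluded_fraction=result.excluded_fraction,
        abs_def_ri_mismatch=abs(result.def_ri_mismatch),
    )
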