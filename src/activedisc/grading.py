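"""DDLS / ICD-9 severity grading and the end-to-end image pipeline.

The disc damage likelihood scale (DDLS, revised 10-stage form) grades an eye
from the rim-to-disc ratio while some rim remains, and from the angular
extent of rim absence once the cup reaches the disc boundary:

    rim present:  RDR >= 0.30 -> stages 1-2;  [0.20, 0.30) -> 3;
                  [0.10, 0.20) -> 4;  (0, 0.10) -> 5
    rim absent:   extent < 45 deg -> 6;  [45, 90) -> 7;  [90, 180] -> 8;
                  > 180 deg -> stages 9-10

The printed staging tables leave small rounding gaps between bands and an
ambiguity in the very last band; the intervals above are the contiguous
half-open resolution, so the classifier is total.  Stages 1-4 map to
"not definitely damaged" (normal), 5-7 to "asymptomatic glaucoma damage"
(moderate), 8-10 to "glaucomatous disease/disability" (severe); an
alternative, stricter reading with only stages 1-2 normal is available via
``normal_span="1-2"``.  The ICD-9 rule grades severity from the CDR alone
with thresholds 0.5 and 0.8 (half-open on the right).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .active_disc import FitOptions, FitResult, segment_optic_disc
from .clinical_geometry import Circle, ClinicalParams, clinical_params, isnt_satisfied
from .cup_segmentation import segment_optic_cup
from .errors import ActiveDiscError, InvalidArgumentError, PipelineError
from .localization import localize_disc

__all__ = [
    "DdlsStage",
    "Severity",
    "GradingReport",
    "ddls_stage",
    "ddls_three_stage",
    "icd9_three_stage",
    "two_stage",
    "grade_image",
]


class DdlsStage(str, enum.Enum):
    """Revised DDLS stage bands (stages 1-2 and 9-10 are reported merged)."""

    S1_2 = "S1_2"
    S3 = "S3"
    S4 = "S4"
    S5 = "S5"
    S6 = "S6"
    S7 = "S7"
    S8 = "S8"
    S9_10 = "S9_10"


class Severity(enum.IntEnum):
    """Three-stage severity, totally ordered normal < moderate < severe."""

    normal = 0
    moderate = 1
    severe = 2

    @property
    def label(self) -> str:
        return self.name


_STAGE_SEVERITY = {
    "1-4": {
        DdlsStage.S1_2: Severity.normal,
        DdlsStage.S3: Severity.normal,
        DdlsStage.S4: Severity.normal,
        DdlsStage.S5: Severity.moderate,
        DdlsStage.S6: Severity.moderate,
        DdlsStage.S7: Severity.moderate,
        DdlsStage.S8: Severity.severe,
        DdlsStage.S9_10: Severity.severe,
    },
    "1-2": {
        DdlsStage.S1_2: Severity.normal,
        DdlsStage.S3: Severity.moderate,
        DdlsStage.S4: Severity.moderate,
        DdlsStage.S5: Severity.moderate,
        DdlsStage.S6: Severity.moderate,
        DdlsStage.S7: Severity.moderate,
        DdlsStage.S8: Severity.severe,
        DdlsStage.S9_10: Severity.severe,
    },
}


def ddls_stage(params: ClinicalParams) -> DdlsStage:
    """Map clinical parameters to the DDLS stage band (total function)."""
    if params.narrowest_rim_width > 0.0:
        r = params.rdr
        if r >= 0.30:
            return DdlsStage.S1_2
        if r >= 0.20:
            return DdlsStage.S3
        if r >= 0.10:
            return DdlsStage.S4
        return DdlsStage.S5
    ext = params.rim_absence_extent
    if ext < 45.0:
        return DdlsStage.S6
    if ext < 90.0:
        return DdlsStage.S7
    if ext <= 180.0:
        return DdlsStage.S8
    return DdlsStage.S9_10


def ddls_three_stage(stage: DdlsStage, normal_span: str = "1-4") -> Severity:
    """Collapse a DDLS stage band to the three-stage severity."""
    try:
        table = _STAGE_SEVERITY[normal_span]
    except KeyError:
        raise InvalidArgumentError(f"normal_span must be '1-4' or '1-2', got {normal_span!r}")
    return table[DdlsStage(stage)]


def icd9_three_stage(cdr: float) -> Severity:
    """ICD-9 CDR rule: normal <= 0.5 < moderate <= 0.8 < severe <= 1."""
    if not (0.0 <= cdr <= 1.0):
        raise InvalidArgumentError(f"CDR must lie in [0, 1], got {cdr}")
    if cdr <= 0.5:
        return Severity.normal
    if cdr <= 0.8:
        return Severity.moderate
    return Severity.severe


def two_stage(severity: Severity) -> str:
    """Collapse the three-stage severity to normal / glaucomatous."""
    return "normal" if Severity(severity) == Severity.normal else "glaucomatous"


@dataclass(frozen=True)
class GradingReport:
    """Full output of the image-to-grade pipeline."""

    disc: Circle
    cup: Circle
    params: ClinicalParams
    ddls: DdlsStage
    ddls_severity: Severity
    icd9_severity: Severity
    two_stage: str
    isnt_two_stage: str
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "disc": {"cx": self.disc.cx, "cy": self.disc.cy, "r": self.disc.r},
            "cup": {"cx": self.cup.cx, "cy": self.cup.cy, "r": self.cup.r},
            "params": self.params.to_dict(),
            "ddls_stage": self.ddls.value,
            "ddls_severity": self.ddls_severity.label,
            "icd9_severity": self.icd9_severity.label,
            "two_stage": self.two_stage,
            "isnt_two_stage": self.isnt_two_stage,
            "provenance": dict(self.provenance),
        }


def grade_from_circles(disc: Circle, cup: Circle, laterality: str = "right",
                       normal_span: str = "1-4") -> tuple[ClinicalParams, DdlsStage, Severity, Severity, str, str]:
    """Grading given already-known circles (used for ground-truth grading too)."""
    params = clinical_params(disc, cup, laterality)
    stage = ddls_stage(params)
    ddls_sev = ddls_three_stage(stage, normal_span)
    icd9_sev = icd9_three_stage(min(1.0, params.cdr))
    isnt2 = "normal" if isnt_satisfied(params.isnt) else "glaucomatous"
    return params, stage, ddls_sev, icd9_sev, two_stage(ddls_sev), isnt2


def grade_image(rgb, opts: Optional[FitOptions] = None, laterality: str = "right",
                normal_span: str = "1-4", template=None,
                provenance: Optional[dict] = None) -> GradingReport:
    """Run the full pipeline: localize -> disc fit -> cup fit -> geometry -> grade.

    Deterministic for a given image and options.  A failure in any stage
    raises :class:`PipelineError` carrying the stage name and the results of
    the stages that did complete.
    """
    img = np.asarray(rgb, dtype=np.float64)
    partial: dict = {}
    try:
        loc = localize_disc(img, template=template)
    except ActiveDiscError as exc:
        raise PipelineError("localization", exc, partial) from exc
    partial["localization"] = loc
    try:
        disc_fit: FitResult = segment_optic_disc(img, loc, opts)
    except ActiveDiscError as exc:
        raise PipelineError("disc_segmentation", exc, partial) from exc
    partial["disc_fit"] = disc_fit
    try:
        cup_fit: FitResult = segment_optic_cup(img, disc_fit.object_circle, opts)
    except ActiveDiscError as exc:
        raise PipelineError("cup_segmentation", exc, partial) from exc
    partial["cup_fit"] = cup_fit
    try:
        params, stage, ddls_sev, icd9_sev, two, isnt2 = grade_from_circles(
            disc_fit.object_circle, cup_fit.object_circle, laterality, normal_span
        )
    except ActiveDiscError as exc:
        raise PipelineError("clinical_geometry", exc, partial) from exc
    return GradingReport(
        disc=disc_fit.object_circle,
        cup=cup_fit.object_circle,
        params=params,
        ddls=stage,
        ddls_severity=ddls_sev,
        icd9_severity=icd9_sev,
        two_stage=two_stage(ddls_sev),
        isnt_two_stage=isnt2,
        provenance=dict(provenance or {}),
    )
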