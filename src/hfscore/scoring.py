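"""HRCT fibrosis score (HFS) and Goddard emphysema score (GS).

The HFS grades pre-existing interstitial lung disease on chest HRCT. Each of
six lung regions (right and left lung at the level of the carina, at the level
of the right inferior pulmonary vein, and midway between the two) is read as a
partition of the regional lung area into four finding categories, each carrying
a weight:

====================================  ======
category                              weight
====================================  ======
normal attenuation                    1
reticular abnormality                 2
reticular + traction bronchiectasis   3
honeycombing                          4
====================================  ======

Extents are estimated in 5% steps and must sum to 100% per region. The region
score is ``sum(weight * extent%)``, so a fully normal region scores 100 and a
region of pure honeycombing scores 400. A reader's HFS is the mean over the
six regions; the patient's HFS is the mean over readers. HFS = 100 means no
interstitial lung disease (ILD); bands (100, 200], (200, 300] and (300, 400]
are mild, moderate and severe ILD.

The Goddard score grades emphysema: each region's low-attenuation-area (LAA)
percentage maps to a 0-4 band score, the six band scores are summed (0-24) and
averaged over readers. GS = 0 is no emphysema; (0, 7], (7, 15] and (15, 24]
are mild, moderate and severe.

For risk stratification the HFS is additionally cut at 100 and 110 points:
no ILD (HFS = 100), minimal fibrosis (100 < HFS <= 110), and HFS > 110.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

from .errors import ValidationError

__all__ = [
    "FibrosisCategory",
    "CATEGORY_WEIGHTS",
    "REGION_IDS",
    "RegionRead",
    "LAARead",
    "ReaderAssessment",
    "PatientScore",
    "region_points",
    "reader_hfs",
    "reader_gs",
    "patient_hfs",
    "patient_gs",
    "gs_region_score",
    "ild_severity",
    "emphysema_severity",
    "hfs_stratum",
    "score_patient",
    "score_assessments",
    "snap_to_grid",
]


class FibrosisCategory(str, Enum):
    """HRCT finding category for interstitial fibrosis."""

    NORMAL = "normal"
    RETICULAR = "reticular"
    RETICULAR_TB = "reticular_tb"  # reticular abnormality + traction bronchiectasis
    HONEYCOMB = "honeycomb"


#: Fixed, total weight mapping for the four finding categories.
CATEGORY_WEIGHTS: dict[FibrosisCategory, int] = {
    FibrosisCategory.NORMAL: 1,
    FibrosisCategory.RETICULAR: 2,
    FibrosisCategory.RETICULAR_TB: 3,
    FibrosisCategory.HONEYCOMB: 4,
}

#: Three axial levels (carina, midpoint, right inferior pulmonary vein) x two lungs.
REGION_IDS: tuple[str, ...] = (
    "carina_R",
    "carina_L",
    "mid_R",
    "mid_L",
    "ipv_R",
    "ipv_L",
)

_EXTENT_GRID = 5.0  # extents are read in 5% steps


def snap_to_grid(extents: Mapping[FibrosisCategory, float]) -> dict[FibrosisCategory, float]:
    """Round off-grid extents to the nearest 5% step, ties away from normal.

    After rounding, any residual needed to restore a 100% total is absorbed by
    the normal category, which is the only category guaranteed non-degenerate
    in practice. Used by the readers behind the ``--allow-offgrid`` switch;
    the default pipeline rejects off-grid extents instead.
    """
    snapped: dict[FibrosisCategory, float] = {}
    for cat, pct in extents.items():
        steps = pct / _EXTENT_GRID
        frac = steps - int(steps)
        if abs(frac - 0.5) < 1e-9:
            # tie: normal rounds down, abnormal categories round up
            steps = int(steps) if cat is FibrosisCategory.NORMAL else int(steps) + 1
        else:
            steps = round(steps)
        snapped[cat] = steps * _EXTENT_GRID
    residual = 100.0 - sum(snapped.values())
    base = snapped.get(FibrosisCategory.NORMAL, 0.0) + residual
    if base < -1e-9:
        raise ValidationError(
            f"cannot renormalise off-grid extents {dict(extents)}: normal extent would be negative"
        )
    snapped[FibrosisCategory.NORMAL] = max(base, 0.0)
    return snapped


@dataclass(frozen=True)
class RegionRead:
    """One reader's fibrosis partition of one lung region.

    ``extents`` maps finding categories to percentages on the 5% grid;
    omitted categories are implicitly 0%. The partition must total 100%.
    """

    region_id: str
    extents: Mapping[FibrosisCategory, float]

    def __post_init__(self) -> None:
        if self.region_id not in REGION_IDS:
            raise ValidationError(
                f"unknown region_id {self.region_id!r}; expected one of {REGION_IDS}"
            )
        total = 0.0
        for cat, pct in self.extents.items():
            cat = FibrosisCategory(cat)
            if pct < 0:
                raise ValidationError(
                    f"region {self.region_id}: negative extent {pct}% for {cat.value}"
                )
            if abs(pct / _EXTENT_GRID - round(pct / _EXTENT_GRID)) > 1e-9:
                raise ValidationError(
                    f"region {self.region_id}: extent {pct}% for {cat.value} is not a"
                    f" multiple of {_EXTENT_GRID:g}% (pass allow_offgrid to snap)"
                )
            total += pct
        if abs(total - 100.0) > 1e-9:
            raise ValidationError(
                f"region {self.region_id}: extents sum to {total:g}%, expected 100%"
            )


@dataclass(frozen=True)
class LAARead:
    """One reader's low-attenuation-area estimate for one lung region."""

    region_id: str
    laa_percent: float

    def __post_init__(self) -> None:
        if self.region_id not in REGION_IDS:
            raise ValidationError(
                f"unknown region_id {self.region_id!r}; expected one of {REGION_IDS}"
            )
        if not 0.0 <= self.laa_percent <= 100.0:
            raise ValidationError(
                f"region {self.region_id}: LAA {self.laa_percent}% outside [0, 100]"
            )


@dataclass(frozen=True)
class ReaderAssessment:
    """A single reader's complete assessment of one patient (six regions)."""

    reader_id: str
    patient_id: str
    fibrosis: Sequence[RegionRead]
    emphysema: Sequence[LAARead] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self._check_coverage("fibrosis", [r.region_id for r in self.fibrosis])
        if self.emphysema:
            self._check_coverage("emphysema", [r.region_id for r in self.emphysema])

    def _check_coverage(self, what: str, seen: list[str]) -> None:
        missing = set(REGION_IDS) - set(seen)
        if missing:
            raise ValidationError(
                f"patient {self.patient_id}, reader {self.reader_id}: missing"
                f" {what} region(s) {sorted(missing)}"
            )
        if len(seen) != len(REGION_IDS):
            dupes = sorted({r for r in seen if seen.count(r) > 1})
            raise ValidationError(
                f"patient {self.patient_id}, reader {self.reader_id}: duplicate"
                f" {what} region(s) {dupes}"
            )


@dataclass(frozen=True)
class PatientScore:
    """Reader-averaged scores and derived categories for one patient."""

    patient_id: str
    hfs: float
    gs: float | None
    ild_severity: str
    emphysema_severity: str | None
    hfs_stratum: str


def region_points(read: RegionRead) -> float:
    """Weighted region score sum(weight * extent%), in [100, 400]."""
    return sum(
        CATEGORY_WEIGHTS[FibrosisCategory(cat)] * pct for cat, pct in read.extents.items()
    )


def reader_hfs(assessment: ReaderAssessment) -> float:
    """One reader's HFS: mean of the six region scores."""
    return sum(region_points(r) for r in assessment.fibrosis) / len(REGION_IDS)


def gs_region_score(read: LAARead) -> int:
    """Goddard band score for one region.

    Bands are contiguous half-open intervals: <=5% -> 0, (5, 25] -> 1,
    (25, 50] -> 2, (50, 75] -> 3, >75% -> 4.
    """
    p = read.laa_percent
    if p <= 5:
        return 0
    if p <= 25:
        return 1
    if p <= 50:
        return 2
    if p <= 75:
        return 3
    return 4


def reader_gs(assessment: ReaderAssessment) -> int:
    """One reader's Goddard score: sum of the six region band scores (0-24)."""
    if not assessment.emphysema:
        raise ValidationError(
            f"patient {assessment.patient_id}, reader {assessment.reader_id}:"
            " no emphysema reads"
        )
    return sum(gs_region_score(r) for r in assessment.emphysema)


def _check_same_patient(assessments: Sequence[ReaderAssessment]) -> None:
    if not assessments:
        raise ValidationError("need at least one reader assessment")
    patient_ids = {a.patient_id for a in assessments}
    if len(patient_ids) > 1:
        raise ValidationError(f"mixed patient_ids {sorted(patient_ids)} in one averaging call")


def patient_hfs(assessments: Sequence[ReaderAssessment] | Sequence[float]) -> float:
    """Patient-level HFS: mean of the per-reader HFS values.

    Readers may be supplied as full assessments or as pre-computed
    reader-level scores (e.g. transcribed from a report).
    """
    if assessments and not isinstance(assessments[0], ReaderAssessment):
        if not all(isinstance(v, (int, float)) for v in assessments):
            raise ValidationError("expected assessments or numeric reader scores")
        return sum(float(v) for v in assessments) / len(assessments)
    _check_same_patient(assessments)
    return sum(reader_hfs(a) for a in assessments) / len(assessments)


def patient_gs(assessments: Sequence[ReaderAssessment] | Sequence[float]) -> float:
    """Patient-level Goddard score: mean of the per-reader sums.

    Accepts full assessments or pre-computed reader-level Goddard scores.
    """
    if assessments and not isinstance(assessments[0], ReaderAssessment):
        if not all(isinstance(v, (int, float)) for v in assessments):
            raise ValidationError("expected assessments or numeric reader scores")
        return sum(float(v) for v in assessments) / len(assessments)
    _check_same_patient(assessments)
    return sum(reader_gs(a) for a in assessments) / len(assessments)


def ild_severity(hfs: float) -> str:
    """ILD severity band for an HFS value: none / mild / moderate / severe."""
    if not 100.0 <= hfs <= 400.0:
        raise ValidationError(f"HFS {hfs} outside [100, 400]")
    if hfs == 100.0:
        return "none"
    if hfs <= 200.0:
        return "mild"
    if hfs <= 300.0:
        return "moderate"
    return "severe"


def emphysema_severity(gs: float) -> str:
    """Emphysema severity band for a Goddard score: none / mild / moderate / severe."""
    if not 0.0 <= gs <= 24.0:
        raise ValidationError(f"GS {gs} outside [0, 24]")
    if gs == 0.0:
        return "none"
    if gs <= 7.0:
        return "mild"
    if gs <= 15.0:
        return "moderate"
    return "severe"


def hfs_stratum(hfs: float, cutoffs: tuple[float, float] = (100.0, 110.0)) -> str:
    """Risk stratum for the trend analysis: eq100 / gt100_le110 / gt110."""
    lo, hi = cutoffs
    if not 100.0 <= hfs <= 400.0:
        raise ValidationError(f"HFS {hfs} outside [100, 400]")
    if hfs <= lo:
        return "eq100"
    if hfs <= hi:
        return "gt100_le110"
    return "gt110"


def score_patient(assessments: Sequence[ReaderAssessment]) -> PatientScore:
    """Average one patient's reader assessments into a :class:`PatientScore`."""
    _check_same_patient(assessments)
    hfs = patient_hfs(assessments)
    has_gs = all(a.emphysema for a in assessments)
    gs = patient_gs(assessments) if has_gs else None
    return PatientScore(
        patient_id=assessments[0].patient_id,
        hfs=hfs,
        gs=gs,
        ild_severity=ild_severity(hfs),
        emphysema_severity=emphysema_severity(gs) if gs is not None else None,
        hfs_stratum=hfs_stratum(hfs),
    )


def score_assessments(assessments: Iterable[ReaderAssessment]) -> list[PatientScore]:
    """Group assessments by patient and score every patient.

    Patients are scored over whichever readers are present (any subset of
    one or more readers is accepted). Output order follows first appearance.
    """
    by_patient: dict[str, list[ReaderAssessment]] = {}
    for a in assessments:
        by_patient.setdefault(a.patient_id, []).append(a)
    return [score_patient(group) for group in by_patient.values()]
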