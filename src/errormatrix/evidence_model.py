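"""Ordinal scales for systematic error and design error, and SE risk bands.

Systematic error ('bias') is expressed as a ten-step levels-of-evidence
scale from 1a (meta-analysis of randomized trials with low risk of bias)
down to 5 (expert opinion).  Design error is expressed through outcome
importance on the GRADE 1-9 scale (9 = most critical, e.g. mortality;
7-9 critical, 4-6 important but not critical, 1-3 not important).
Random error, quantified as the SE of the log effect measure, is
classified into five named bands:

    [0.00, 0.10)  ignorable
    [0.10, 0.20)  small
    [0.20, 0.30)  moderate
    [0.30, 0.50)  substantial
    [0.50, inf)   high

Bands are left-closed/right-open, so a boundary SE belongs to the upper
band (an SE of exactly 0.10 is a *small*, not ignorable, risk).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .effect_measures import EffectEstimate, MissingnessCode, TwoByTwoTable
from .errors import DomainError, NoEvidenceError, UnknownLevelError

__all__ = [
    "EvidenceLevel",
    "LEVELS",
    "GradeCategory",
    "OutcomeSpec",
    "RiskBand",
    "DEFAULT_BANDS",
    "StudyRecord",
    "parse_level",
    "classify_random_error",
    "best_available",
    "order_outcomes",
    "record_se",
]


@dataclass(frozen=True, order=True)
class EvidenceLevel:
    """One step of the levels-of-evidence scale; lower rank = less bias."""

    rank: int
    label: str = field(compare=False)
    description: str = field(compare=False)


#: The ten evidence levels in scale order.
LEVELS: tuple[EvidenceLevel, ...] = (
    EvidenceLevel(1, "1a", "Meta-analysis of randomized trials with low risk of bias"),
    EvidenceLevel(2, "1b", "Randomized trial with low risk of bias"),
    EvidenceLevel(3, "1c", "Meta-analysis of all randomized trials"),
    EvidenceLevel(4, "1d", "Randomized trial with high risk of bias"),
    EvidenceLevel(5, "2a", "Meta-analysis of cohort studies"),
    EvidenceLevel(6, "2b", "Cohort study"),
    EvidenceLevel(7, "3a", "Meta-analysis of case-control studies"),
    EvidenceLevel(8, "3b", "Case-control study"),
    EvidenceLevel(9, "4", "Case-series"),
    EvidenceLevel(10, "5", "Expert opinion"),
)

_LEVEL_BY_LABEL = {lv.label: lv for lv in LEVELS}


def parse_level(label: str) -> EvidenceLevel:
    """Resolve a level label (case-insensitive, whitespace-tolerant)."""
    key = str(label).strip().lower()
    try:
        return _LEVEL_BY_LABEL[key]
    except KeyError:
        raise UnknownLevelError(label, _LEVEL_BY_LABEL) from None


class GradeCategory(enum.Enum):
    """GRADE importance category of an outcome."""

    CRITICAL = "critical"
    IMPORTANT_NOT_CRITICAL = "important_not_critical"
    NOT_IMPORTANT = "not_important"


def _category_for_score(score: int) -> GradeCategory:
    if score >= 7:
        return GradeCategory.CRITICAL
    if score >= 4:
        return GradeCategory.IMPORTANT_NOT_CRITICAL
    return GradeCategory.NOT_IMPORTANT


@dataclass(frozen=True)
class OutcomeSpec:
    """An outcome with its GRADE importance score (1-9, 9 most critical).

    ``adverse`` records whether the event is undesirable (the default:
    a ratio below 1 then means benefit).  ``display_order`` breaks ties
    between outcomes with equal scores.
    """

    name: str
    grade_score: int
    adverse: bool = True
    display_order: int = 0

    def __post_init__(self):
        if not 1 <= self.grade_score <= 9:
            raise DomainError(f"GRADE score must be 1..9, got {self.grade_score}")

    @property
    def grade_category(self) -> GradeCategory:
        return _category_for_score(self.grade_score)


@dataclass(frozen=True)
class RiskBand:
    """A named half-open SE interval [lower, upper)."""

    name: str
    lower: float
    upper: float  # math.inf for the top band

    def __contains__(self, se: float) -> bool:
        return self.lower <= se < self.upper


#: Default random-error bands partitioning [0, inf).
DEFAULT_BANDS: tuple[RiskBand, ...] = (
    RiskBand("IGNORABLE", 0.00, 0.10),
    RiskBand("SMALL", 0.10, 0.20),
    RiskBand("MODERATE", 0.20, 0.30),
    RiskBand("SUBSTANTIAL", 0.30, 0.50),
    RiskBand("HIGH", 0.50, math.inf),
)


def classify_random_error(se: float, bands: tuple[RiskBand, ...] = DEFAULT_BANDS) -> RiskBand:
    """Map an SE to its risk band; boundary values go to the upper band."""
    if not (isinstance(se, (int, float)) and math.isfinite(se)) or se < 0:
        raise DomainError(f"standard error must be finite and non-negative, got {se!r}")
    for band in bands:
        if se in band:
            return band
    raise DomainError(f"bands do not cover se={se}")  # unreachable with defaults


Cell = TwoByTwoTable | EffectEstimate | MissingnessCode


@dataclass(frozen=True)
class StudyRecord:
    """One study's evidence level plus its per-outcome data cells.

    Each cell is a 2x2 table, an effect estimate (computed or as
    reported), or a missingness code (``Z`` zero events / ``N`` not
    reported).
    """

    study_id: str
    level: EvidenceLevel
    cells: dict[str, Cell]

    def cell(self, outcome: str) -> Cell | None:
        return self.cells.get(outcome)


def record_se(record: StudyRecord, outcome: str) -> float | None:
    """The computable SE of a record for an outcome, or None.

    Missingness codes and estimates without an SE yield None; a 2x2
    table cell yields the SE of its log relative risk when calculable.
    """
    from .effect_measures import se_ln_rr
    from .errors import ZeroEventError

    cell = record.cell(outcome)
    if cell is None or isinstance(cell, MissingnessCode):
        return None
    if isinstance(cell, TwoByTwoTable):
        try:
            return se_ln_rr(cell)
        except ZeroEventError:
            return None
    return cell.se_ln


def best_available(records: list[StudyRecord], outcome: str) -> tuple[StudyRecord, float]:
    """The best evidence for an outcome: lowest level rank, then lowest SE.

    Only records with a computable SE compete.  Ties on level rank are
    broken by smaller SE, then lexicographic study id, so the result is
    deterministic.
    """
    candidates = []
    for rec in records:
        se = record_se(rec, outcome)
        if se is not None:
            candidates.append((rec.level.rank, se, rec.study_id, rec))
    if not candidates:
        raise NoEvidenceError(f"no study has a computable SE for outcome {outcome!r}")
    rank, se, _, rec = min(candidates, key=lambda t: t[:3])
    return rec, se


def order_outcomes(specs: list[OutcomeSpec]) -> list[OutcomeSpec]:
    """Sort outcomes by importance: GRADE score descending, then display
    order, then name."""
    if not specs:
        raise DomainError("at least one outcome spec is required")
    return sorted(specs, key=lambda s: (-s.grade_score, s.display_order, s.name))
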