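"""Assembly of the four matrix steps from study records and outcome specs.

Step I scatters each study's (level rank, SE) for one outcome — no
filtering, so even very imprecise studies stay visible.  Step II grids
studies over (evidence level x outcome) in importance order.  Step III is
the 'Manhattan' figure: one bar per study-outcome estimate, split into
benefit and harm panels, with bars omitted when the evidence level is
worse than a cutoff (default 2b) or the SE exceeds a cutoff (default
1.0).  Bar height is linear in SE, (cutoff - SE)/cutoff, so the omission
threshold and zero height coincide and taller always means more precise.
Step IV summarises effect size and direction (NNT where counts exist),
but only for outcomes whose best evidence passes a validity screen;
outcomes failing the screen are reported as insufficient evidence rather
than given a number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .effect_measures import (
    Direction,
    EffectEstimate,
    MissingnessCode,
    RiskDifferenceSummary,
    TwoByTwoTable,
    effect_direction,
    relative_risk,
    risk_difference_nnt,
)
from .errors import NullEffectError, ZeroEventError
from .evidence_model import (
    DEFAULT_BANDS,
    EvidenceLevel,
    OutcomeSpec,
    StudyRecord,
    best_available,
    classify_random_error,
    order_outcomes,
    parse_level,
    record_se,
)
from .errors import NoEvidenceError

__all__ = [
    "StepIPoint",
    "StepIIGridCell",
    "ManhattanBar",
    "ValidityScreen",
    "OutcomeSummary",
    "StepIVSummary",
    "build_step1",
    "build_step2",
    "build_step3",
    "build_step4",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepIPoint:
    """One study's position in the step I scatter for one outcome."""

    study_id: str
    level_rank: int
    level_label: str
    se: float
    outcome: str


@dataclass(frozen=True)
class StepIIGridCell:
    """Studies occupying one (evidence level, outcome) cell of step II."""

    outcome: str
    level: EvidenceLevel
    studies: tuple[str, ...]


@dataclass(frozen=True)
class ManhattanBar:
    """One skyscraper of the step III figure."""

    outcome: str
    study_id: str
    level_rank: int
    level_label: str
    se: float
    band: str
    height: float
    panel: str  # "BENEFIT" | "HARM"


@dataclass(frozen=True)
class ValidityScreen:
    """Thresholds the best evidence must meet before step IV reports an
    effect size: maximum acceptable level rank and risk-band index."""

    max_level_rank: int = 6  # level 2b
    max_band: str = "MODERATE"

    def band_index(self, band_name: str) -> int:
        return [b.name for b in DEFAULT_BANDS].index(band_name)

    def failing_dimensions(self, level_rank: int, band_name: str) -> list[str]:
        fails = []
        if level_rank > self.max_level_rank:
            fails.append("systematic_error")
        if self.band_index(band_name) > self.band_index(self.max_band):
            fails.append("random_error")
        return fails


@dataclass(frozen=True)
class OutcomeSummary:
    """Step IV verdict for a single outcome."""

    outcome: str
    status: str  # "OK" | "INSUFFICIENT_EVIDENCE"
    failing: tuple[str, ...] = ()
    study_id: str | None = None
    level_label: str | None = None
    estimate: EffectEstimate | None = None
    direction: Direction | None = None
    risk_difference: RiskDifferenceSummary | None = None


@dataclass(frozen=True)
class StepIVSummary:
    """Per-outcome effect-size summaries from step IV."""

    outcomes: tuple[OutcomeSummary, ...]


def build_step1(records: list[StudyRecord], outcome: str) -> list[StepIPoint]:
    """Step I scatter: one point per record with a computable SE.

    No cutoff is applied at this step; cells coded Z or N simply have no
    point to plot.
    """
    points = []
    for rec in records:
        se = record_se(rec, outcome)
        if se is None:
            continue
        points.append(StepIPoint(rec.study_id, rec.level.rank, rec.level.label,
                                 se, outcome))
    return points


def build_step2(records: list[StudyRecord], specs: list[OutcomeSpec]) -> list[StepIIGridCell]:
    """Step II grid: studies per (level, outcome) cell.

    Columns follow outcome importance order, rows follow the evidence
    scale.  A study occupies a cell if it reports the outcome at all —
    zero-event (Z) cells count as reported, not-reported (N) cells do not.
    """
    ordered = order_outcomes(specs)
    grid = []
    for spec in ordered:
        by_level: dict[int, list[str]] = {}
        for rec in records:
            cell = rec.cell(spec.name)
            if cell is None or cell is MissingnessCode.N:
                continue
            by_level.setdefault(rec.level.rank, []).append(rec.study_id)
        from .evidence_model import LEVELS

        for level in LEVELS:
            studies = by_level.get(level.rank)
            if studies:
                grid.append(StepIIGridCell(spec.name, level, tuple(studies)))
    return grid


def _cell_estimate(cell) -> EffectEstimate | None:
    """An effect estimate for a cell, or None when no direction/SE exists."""
    if cell is None or isinstance(cell, MissingnessCode):
        return None
    if isinstance(cell, TwoByTwoTable):
        try:
            return relative_risk(cell)
        except ZeroEventError:
            return None
    return cell


def build_step3(
    records: list[StudyRecord],
    specs: list[OutcomeSpec],
    se_cutoff: float = 1.0,
    level_cutoff: str = "2b",
) -> dict[str, list[ManhattanBar]]:
    """Step III Manhattan panels: {"BENEFIT": [...], "HARM": [...]}.

    Bars beyond either cutoff are omitted (logged); estimates whose
    direction is null belong to neither panel and are logged as excluded.
    Within a panel, bars are grouped by outcome importance, then sorted
    by level rank and SE, so the best evidence sits first in each group.
    """
    max_rank = parse_level(level_cutoff).rank
    panels: dict[str, list[ManhattanBar]] = {"BENEFIT": [], "HARM": []}
    for spec in order_outcomes(specs):
        bars = []
        for rec in records:
            est = _cell_estimate(rec.cell(spec.name))
            if est is None or est.se_ln is None:
                continue
            se = est.se_ln
            if rec.level.rank > max_rank:
                log.info("step III: %s/%s omitted (level %s beyond cutoff %s)",
                         rec.study_id, spec.name, rec.level.label, level_cutoff)
                continue
            if se >= se_cutoff:
                log.info("step III: %s/%s omitted (SE %.2f beyond cutoff %.2f)",
                         rec.study_id, spec.name, se, se_cutoff)
                continue
            direction = effect_direction(est, adverse=spec.adverse)
            if direction is Direction.NULL:
                log.info("step III: %s/%s has a null effect; assigned to no panel",
                         rec.study_id, spec.name)
                continue
            bars.append((direction, ManhattanBar(
                outcome=spec.name,
                study_id=rec.study_id,
                level_rank=rec.level.rank,
                level_label=rec.level.label,
                se=se,
                band=classify_random_error(se).name,
                height=(se_cutoff - min(se, se_cutoff)) / se_cutoff,
                panel=direction.name,
            )))
        bars.sort(key=lambda db: (db[1].level_rank, db[1].se, db[1].study_id))
        for direction, bar in bars:
            panels[direction.name].append(bar)
    return panels


def panels_to_dict(panels: dict[str, list[ManhattanBar]]) -> dict:
    """JSON-ready structure: panel -> outcome -> list of bar objects."""
    out: dict[str, dict[str, list[dict]]] = {}
    for panel, bars in panels.items():
        grouped: dict[str, list[dict]] = {}
        for b in bars:
            grouped.setdefault(b.outcome, []).append({
                "study_id": b.study_id,
                "level": b.level_label,
                "level_rank": b.level_rank,
                "se": b.se,
                "band": b.band,
                "height": b.height,
            })
        out[panel] = grouped
    return out


def panels_to_rows(panels: dict[str, list[ManhattanBar]]) -> list[dict]:
    """Flat CSV-ready rows, one per bar."""
    return [{
        "panel": b.panel, "outcome": b.outcome, "study_id": b.study_id,
        "level": b.level_label, "level_rank": b.level_rank,
        "se": b.se, "band": b.band, "height": b.height,
    } for bars in panels.values() for b in bars]


def build_step4(
    records: list[StudyRecord],
    specs: list[OutcomeSpec],
    screen: ValidityScreen = ValidityScreen(),
) -> StepIVSummary:
    """Step IV effect-size summary gated by the validity screen.

    For each outcome the best available evidence (level first, then SE)
    is screened; only when it passes are the effect direction and — when
    2x2 counts exist — the NNT reported.  Failing outcomes get an
    INSUFFICIENT_EVIDENCE verdict naming the failing error dimension(s).
    """
    summaries = []
    for spec in order_outcomes(specs):
        try:
            rec, se = best_available(records, spec.name)
        except NoEvidenceError:
            summaries.append(OutcomeSummary(spec.name, "INSUFFICIENT_EVIDENCE",
                                            failing=("no_computable_se",)))
            continue
        band = classify_random_error(se).name
        failing = screen.failing_dimensions(rec.level.rank, band)
        if failing:
            summaries.append(OutcomeSummary(
                spec.name, "INSUFFICIENT_EVIDENCE", failing=tuple(failing),
                study_id=rec.study_id, level_label=rec.level.label,
            ))
            continue
        cell = rec.cell(spec.name)
        est = _cell_estimate(cell)
        rd = None
        if isinstance(cell, TwoByTwoTable):
            try:
                rd = risk_difference_nnt(cell)
            except NullEffectError:
                rd = None
        summaries.append(OutcomeSummary(
            spec.name, "OK",
            study_id=rec.study_id, level_label=rec.level.label,
            estimate=est,
            direction=effect_direction(est, adverse=spec.adverse) if est else None,
            risk_difference=rd,
        ))
    return StepIVSummary(tuple(summaries))
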