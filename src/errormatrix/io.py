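"""Study-table I/O, packaged example fixtures, synthetic trials, figures.

A study table has one row per (study, evidence level, outcome).  Exactly
one of four data forms must be populated per row:

* the 2x2 counts ``a, b, c, d``;
* a reported ratio with its interval ``estimate, ci_lower, ci_upper``
  (the SE is back-calculated from the interval on read);
* a reported standard error ``se`` (optionally with a ``direction`` flag
  of benefit/harm/null when the point estimate itself was not published);
* a missingness ``code``: ``Z`` (zero events, SE incalculable) or ``N``
  (outcome not reported).

Optional per-row columns ``grade_score``, ``adverse`` and the first
appearance order define the outcome specification.  Decimal commas are
normalised to decimal points on read.  CSV (UTF-8, comma, header) and a
versioned JSON rendering carry the same schema.

The packaged fixtures reproduce two published worked examples:
``example1`` (peri-operative beta-blockade versus placebo for major
non-cardiac surgery; four outcomes, ten study rows) and ``example2``
(class 1a antiarrhythmics for maintaining sinus rhythm after
cardioversion of atrial fibrillation; all-cause mortality only).  The
underlying 2x2 counts were not published, so fixture cells carry the
reported SEs (provenance AS_REPORTED) plus direction flags taken from the
published conclusions; they are inputs, not recomputations.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .effect_measures import (
    Direction,
    EffectEstimate,
    Measure,
    MissingnessCode,
    Provenance,
    TwoByTwoTable,
    se_from_ci,
)
from .errors import (
    ConfigError,
    ErrorMatrixError,
    RenderError,
    SchemaError,
    UnknownFixtureError,
)
from .evidence_model import OutcomeSpec, StudyRecord, parse_level
from .pooling import TrialSet

__all__ = [
    "COLUMNS",
    "read_study_table",
    "write_study_table",
    "load_fixture",
    "SyntheticTrialConfig",
    "generate_synthetic_trials",
    "render_manhattan",
    "AnalysisConfig",
    "load_config",
]

SCHEMA_VERSION = 1

COLUMNS = ["study_id", "level", "outcome", "grade_score", "adverse",
           "a", "b", "c", "d",
           "estimate", "ci_lower", "ci_upper", "se", "direction", "code"]

_COUNT_COLS = ("a", "b", "c", "d")
_CI_COLS = ("estimate", "ci_lower", "ci_upper")


def _norm(value) -> str:
    """Strip and normalise decimal commas ('0,28' -> '0.28')."""
    if value is None:
        return ""
    return str(value).strip().replace(",", ".")


def _parse_float(value, row, column):
    text = _norm(value)
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"not a number: {value!r}", row=row, column=column) from None


def _parse_int(value, row, column):
    f = _parse_float(value, row, column)
    if f is None:
        return None
    if f != int(f):
        raise SchemaError(f"not an integer: {value!r}", row=row, column=column)
    return int(f)


def _row_cell(row: dict, rownum: int):
    """Validate the mutually-exclusive population rule and build the cell."""
    counts = [_parse_int(row.get(k), rownum, k) for k in _COUNT_COLS]
    ci = [_parse_float(row.get(k), rownum, k) for k in _CI_COLS]
    se = _parse_float(row.get("se"), rownum, "se")
    code = _norm(row.get("code")).upper() or None
    direction = _norm(row.get("direction")).lower() or None

    has_counts = any(v is not None for v in counts)
    has_ci = any(v is not None for v in ci)
    forms = sum([has_counts, has_ci, se is not None, code is not None])
    if forms != 1:
        raise SchemaError(
            "exactly one of counts (a,b,c,d), estimate+CI, se, or code must be "
            f"populated; found {forms} forms", row=rownum)

    if has_counts:
        if any(v is None for v in counts):
            raise SchemaError("incomplete 2x2 counts", row=rownum, column="a..d")
        return TwoByTwoTable(*counts)
    if has_ci:
        if any(v is None for v in ci):
            raise SchemaError("incomplete estimate/CI triple", row=rownum,
                              column="estimate..ci_upper")
        point, lo, hi = ci
        try:
            back_se = se_from_ci(point, lo, hi)
        except ErrorMatrixError as exc:
            raise SchemaError(str(exc), row=rownum, column="estimate..ci_upper") from exc
        return EffectEstimate(Measure.REPORTED_RATIO, point, back_se,
                              Provenance.FROM_CI, ci_lower=lo, ci_upper=hi)
    if se is not None:
        try:
            d = Direction(direction) if direction else None
        except ValueError:
            raise SchemaError(f"unknown direction {direction!r}", row=rownum,
                              column="direction") from None
        return EffectEstimate(Measure.REPORTED_RATIO, None, se,
                              Provenance.AS_REPORTED, direction=d)
    if code not in ("Z", "N"):
        raise SchemaError(f"unknown missingness code {code!r} (expected Z or N)",
                          row=rownum, column="code")
    return MissingnessCode[code]


def _rows_to_records(rows: list[dict]) -> tuple[list[StudyRecord], list[OutcomeSpec]]:
    specs: dict[str, OutcomeSpec] = {}
    records: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(rows, start=1):
        study = str(row.get("study_id") or "").strip()
        outcome = str(row.get("outcome") or "").strip()
        if not study:
            raise SchemaError("missing study_id", row=i, column="study_id")
        if not outcome:
            raise SchemaError("missing outcome", row=i, column="outcome")
        try:
            level = parse_level(row.get("level", ""))
        except ErrorMatrixError as exc:
            raise SchemaError(str(exc), row=i, column="level") from exc

        grade = _parse_int(row.get("grade_score"), i, "grade_score")
        adverse_text = _norm(row.get("adverse")).lower()
        adverse = adverse_text not in ("false", "0", "no")
        if outcome not in specs:
            specs[outcome] = OutcomeSpec(outcome, grade if grade is not None else 9,
                                         adverse=adverse,
                                         display_order=len(specs))
        elif grade is not None and specs[outcome].grade_score != grade:
            raise SchemaError(
                f"inconsistent grade_score for outcome {outcome!r}",
                row=i, column="grade_score")

        cell = _row_cell(row, i)
        key = (study, level.label)
        if key not in records:
            records[key] = {"study_id": study, "level": level, "cells": {}}
            order.append(key)
        if outcome in records[key]["cells"]:
            raise SchemaError(f"duplicate cell for {study!r}/{outcome!r}", row=i)
        records[key]["cells"][outcome] = cell
    record_list = [StudyRecord(**records[k]) for k in order]
    return record_list, list(specs.values())


def read_study_table(path, format: str | None = None):
    """Read a study table; returns (records, outcome specs).

    ``format`` is "csv" or "json"; inferred from the file suffix when
    omitted.  Rows belonging to the same (study, level) pair merge into
    one record with one cell per outcome; row order is preserved.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file (no header)")
            unknown = set(reader.fieldnames) - set(COLUMNS)
            if unknown:
                raise SchemaError(f"{path}: unknown columns {sorted(unknown)}")
            rows = list(reader)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict) or "rows" not in doc:
            raise SchemaError(f"{path}: JSON study table must have a 'rows' key")
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: unsupported schema_version {doc.get('schema_version')!r}")
        rows = doc["rows"]
    else:
        raise SchemaError(f"unsupported study-table format {fmt!r}")
    return _rows_to_records(rows)


def _records_to_rows(records: list[StudyRecord], specs: list[OutcomeSpec]) -> list[dict]:
    spec_by_name = {s.name: s for s in specs}
    rows = []
    for rec in records:
        for outcome, cell in rec.cells.items():
            spec = spec_by_name[outcome]
            row = {k: "" for k in COLUMNS}
            row.update(study_id=rec.study_id, level=rec.level.label,
                       outcome=outcome, grade_score=spec.grade_score,
                       adverse=str(spec.adverse).lower())
            if isinstance(cell, TwoByTwoTable):
                row.update(a=cell.a, b=cell.b, c=cell.c, d=cell.d)
            elif isinstance(cell, MissingnessCode):
                row.update(code=cell.value)
            elif cell.provenance is Provenance.FROM_CI:
                row.update(estimate=repr(cell.point),
                           ci_lower=repr(cell.ci_lower),
                           ci_upper=repr(cell.ci_upper))
            else:
                row.update(se=repr(cell.se_ln),
                           direction=cell.direction.value if cell.direction else "")
            rows.append(row)
    return rows


def write_study_table(records, specs, path, format: str | None = None) -> None:
    """Write records back to CSV or JSON (inverse of :func:`read_study_table`)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    rows = _records_to_rows(records, specs)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        doc = {"schema_version": SCHEMA_VERSION,
               "rows": [{k: v for k, v in r.items() if v != ""} for r in rows]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise SchemaError(f"unsupported study-table format {fmt!r}")


FIXTURES = ("example1", "example2")


def load_fixture(name: str):
    """Load a packaged worked-example study table.

    ``example1``: peri-operative beta-blockade, four graded outcomes.
    ``example2``: antiarrhythmics after cardioversion, all-cause mortality.
    Returns (records, outcome specs).
    """
    if name not in FIXTURES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    ref = resources.files("errormatrix").joinpath(f"fixtures/{name}.csv")
    with resources.as_file(ref) as p:
        return read_study_table(p, format="csv")


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Settings for the seeded synthetic trial generator.

    ``p_control`` is the control-arm event probability; the intervention
    probability is ``true_rr * p_control`` clamped into (0, 1).  Per-arm
    sample sizes are drawn uniformly from ``size_range``.
    """

    n_trials: int = 10
    size_range: tuple[int, int] = (50, 500)
    p_control: float = 0.2
    true_rr: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ConfigError("n_trials must be at least 1")
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise ConfigError("size_range must satisfy 1 <= lo <= hi")
        if not 0 < self.p_control < 1:
            raise ConfigError("p_control must lie strictly in (0, 1)")
        if self.true_rr <= 0:
            raise ConfigError("true_rr must be positive")


def generate_synthetic_trials(config: SyntheticTrialConfig) -> TrialSet:
    """Simulate a set of two-arm trials with binomial event counts.

    All randomness flows through one seeded generator, so a given config
    always yields the same trial set.
    """
    rng = np.random.default_rng(config.seed)
    p2 = config.p_control
    p1 = min(max(config.true_rr * p2, 1e-12), 1 - 1e-12)
    tables, labels = [], []
    for i in range(config.n_trials):
        n1, n2 = rng.integers(config.size_range[0], config.size_range[1] + 1, size=2)
        a = int(rng.binomial(n1, p1))
        c = int(rng.binomial(n2, p2))
        tables.append(TwoByTwoTable(a, int(n1) - a, c, int(n2) - c))
        labels.append(f"sim-{i + 1:03d}")
    return TrialSet(tuple(tables), tuple(labels))


#: Default bar colours per outcome position in importance order.
DEFAULT_COLORS = ("red", "blue", "yellow", "green")

_BAND_LEGEND = (
    "SE 0 to 0.10 = ignorable risk of random error",
    "SE 0.10 to 0.20 = small risk of random error",
    "SE 0.20 to 0.30 = moderate risk of random error",
    "SE 0.30 to 0.50 = substantial risk of random error",
    "SE >0.50 = high risk of random error",
)


def render_manhattan(panels: dict, path, format: str | None = None,
                     colors=DEFAULT_COLORS, title: str | None = None) -> None:
    """Render the step III panels as a two-panel 3D bar figure.

    One horizontal axis groups outcomes (in the order they appear in the
    bars), the other runs over evidence-level ranks; bar height encodes
    precision.  An empty panel is drawn with its axes and a caption note,
    because an empty benefit panel is itself a finding.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fmt = (format or Path(path).suffix.lstrip(".") or "svg").lower()
    if fmt not in ("svg", "png"):
        raise RenderError(f"unsupported figure format {fmt!r}")

    outcome_order: list[str] = []
    for bars in panels.values():
        for bar in bars:
            if bar.outcome not in outcome_order:
                outcome_order.append(bar.outcome)
    color_of = {o: colors[i % len(colors)] for i, o in enumerate(outcome_order)}

    fig = plt.figure(figsize=(12, 5.5))
    for idx, (panel_name, nice) in enumerate([("BENEFIT", "a. Outcomes with benefit"),
                                              ("HARM", "b. Outcomes with harm")]):
        ax = fig.add_subplot(1, 2, idx + 1, projection="3d")
        bars = panels.get(panel_name, [])
        for bar in bars:
            x = outcome_order.index(bar.outcome)
            ax.bar3d(x, bar.level_rank, 0, 0.6, 0.6, bar.height,
                     color=color_of[bar.outcome], shade=True, alpha=0.9)
        ax.set_title(nice + ("" if bars else " (empty)"))
        ax.set_xticks(range(len(outcome_order)))
        ax.set_xticklabels(outcome_order, fontsize=6, rotation=15)
        ax.set_ylabel("level of evidence (rank)")
        ax.set_zlabel("precision (1 - SE/cutoff)")
        ax.set_zlim(0, 1)
        ax.invert_yaxis()  # best evidence toward the viewer's upper side
    fig.suptitle(title or "Error matrix, step III")
    fig.text(0.01, 0.01, "\n".join(_BAND_LEGEND), fontsize=6, va="bottom")
    try:
        fig.savefig(path, format=fmt)
    except OSError as exc:
        raise RenderError(f"cannot write figure to {path}: {exc}") from exc
    finally:
        plt.close(fig)


@dataclass(frozen=True)
class AnalysisConfig:
    """User-overridable analysis settings (YAML file).

    Schema::

        se_cutoff: 1.0          # step III SE omission threshold
        level_cutoff: "2b"      # step III worst admissible level
        bands:                  # optional custom SE bands
          - {name: IGNORABLE, lower: 0.0, upper: 0.1}
          - ...
        colors: [red, blue, yellow, green]
        outcomes:               # optional outcome specification
          - {name: mortality, grade_score: 9, adverse: true}
    """

    se_cutoff: float = 1.0
    level_cutoff: str = "2b"
    bands: tuple = ()
    colors: tuple = DEFAULT_COLORS
    outcomes: tuple = ()


def load_config(path) -> AnalysisConfig:
    """Parse a YAML analysis config; missing keys keep their defaults."""
    import yaml

    from .evidence_model import RiskBand

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    bands = tuple(
        RiskBand(b["name"], float(b["lower"]),
                 math.inf if b.get("upper") in (None, "inf") else float(b["upper"]))
        for b in doc.get("bands", [])
    )
    outcomes = tuple(
        OutcomeSpec(o["name"], int(o.get("grade_score", 9)),
                    adverse=bool(o.get("adverse", True)),
                    display_order=i)
        for i, o in enumerate(doc.get("outcomes", []))
    )
    return AnalysisConfig(
        se_cutoff=float(doc.get("se_cutoff", 1.0)),
        level_cutoff=str(doc.get("level_cutoff", "2b")),
        bands=bands,
        colors=tuple(doc.get("colors", DEFAULT_COLORS)),
        outcomes=outcomes,
    )
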