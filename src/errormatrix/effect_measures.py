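"""Per-study effect measures and standard errors of their natural logs.

The random-error dimension of the matrix is quantified as the standard
error (SE) of the log of a ratio effect measure.  For a single 2x2 table
with ``a`` events of ``n1`` patients in the intervention arm and ``c``
events of ``n2`` in the control arm:

* relative risk  RR = (a/n1) / (c/n2),
  SE[ln RR] = sqrt(1/a + 1/c - 1/n1 - 1/n2)
* Peto odds ratio  OR = exp(Z/V) with Z = a - n1*(a+c)/N the
  observed-minus-expected events in the intervention arm and
  V = n1*n2*(a+c)*(b+d) / (N^2*(N-1)) the hypergeometric variance,
  SE[ln OR] = 1/sqrt(V).

Natural logarithms are used throughout.  No continuity correction is
applied by default: a table with zero events in an arm raises
:class:`~errormatrix.errors.ZeroEventError` (missingness code ``Z``),
because its SE simply cannot be calculated.  An optional 0.5 correction
is available behind an explicit flag for users who want one anyway.

Meta-analyses that report only an estimate with a confidence interval are
placed on the same SE scale by back-calculation from the interval width
(:func:`se_from_ci`), assuming a symmetric normal interval on the log scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import (
    DegenerateTableError,
    DomainError,
    NullEffectError,
    ZeroEventError,
)

__all__ = [
    "TwoByTwoTable",
    "Measure",
    "Provenance",
    "Direction",
    "MissingnessCode",
    "EffectEstimate",
    "RiskDifferenceSummary",
    "relative_risk",
    "se_ln_rr",
    "peto_or",
    "se_ln_peto",
    "se_from_ci",
    "risk_difference_nnt",
    "effect_direction",
]

#: |ln(point)| below this is treated as a null effect for direction purposes.
NULL_TOLERANCE = 1e-12


class Measure(enum.Enum):
    """Which ratio effect measure an estimate carries."""

    RELATIVE_RISK = "relative_risk"
    PETO_OR = "peto_or"
    REPORTED_RATIO = "reported_ratio"


class Provenance(enum.Enum):
    """How an estimate was obtained."""

    FROM_COUNTS = "from_counts"
    FROM_CI = "from_ci"
    AS_REPORTED = "as_reported"


class Direction(enum.Enum):
    """Direction of an intervention effect for an adverse-event outcome."""

    BENEFIT = "benefit"
    HARM = "harm"
    NULL = "null"


class MissingnessCode(enum.Enum):
    """Why a study/outcome cell carries no standard error.

    ``Z``: the outcome had zero events, so the SE cannot be calculated.
    ``N``: the outcome was not reported by the study.
    """

    Z = "Z"
    N = "N"


@dataclass(frozen=True)
class TwoByTwoTable:
    """Event/non-event counts for the two arms of one study outcome.

    ``a``/``b`` are events/non-events in the intervention arm, ``c``/``d``
    in the control arm.  Both arms must contain at least one patient.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise DomainError(f"count {name} must be an integer, got {v!r}")
            if v < 0:
                raise DomainError(f"count {name} must be non-negative, got {v}")
        if self.n1 < 1 or self.n2 < 1:
            raise DomainError("each arm must contain at least one patient")

    @property
    def n1(self) -> int:
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n1 + self.n2

    def swapped(self) -> "TwoByTwoTable":
        """The same table with intervention and control arms exchanged."""
        return TwoByTwoTable(self.c, self.d, self.a, self.b)

    def continuity_corrected(self, amount: float = 0.5) -> "_CorrectedTable":
        """A real-valued copy with ``amount`` added to every cell.

        Only intended for the optional zero-event correction; off by
        default everywhere in the package.
        """
        return _CorrectedTable(self.a + amount, self.b + amount,
                               self.c + amount, self.d + amount)


@dataclass(frozen=True)
class _CorrectedTable:
    """Internal real-valued 2x2 table produced by a continuity correction."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n1(self):
        return self.a + self.b

    @property
    def n2(self):
        return self.c + self.d

    @property
    def total(self):
        return self.n1 + self.n2


@dataclass(frozen=True)
class EffectEstimate:
    """A ratio effect measure with the SE of its natural log.

    ``point`` may be None for as-reported cells where only the SE (and
    possibly a direction flag) was published.  ``direction`` overrides the
    point-derived direction for such cells.
    """

    measure: Measure
    point: float | None
    se_ln: float | None
    provenance: Provenance
    direction: Direction | None = None
    se_reason: MissingnessCode | None = None
    ci_lower: float | None = None  # retained when back-calculated from a CI
    ci_upper: float | None = None

    def __post_init__(self):
        if self.point is not None and self.point <= 0:
            raise DomainError(f"ratio point estimate must be positive, got {self.point}")
        if self.se_ln is not None and (self.se_ln < 0 or not math.isfinite(self.se_ln)):
            raise DomainError(f"se_ln must be finite and non-negative, got {self.se_ln}")
        if self.se_ln is None and self.se_reason is None:
            raise DomainError("an undefined se_ln requires a missingness reason")


@dataclass(frozen=True)
class RiskDifferenceSummary:
    """Absolute risks, their difference and the number needed to treat.

    ``arr`` is the signed absolute risk reduction p2 - p1 (positive when
    the intervention lowers the event risk of an adverse outcome).
    ``nnt`` is 1/|arr| kept exact; ``nnt_display`` rounds it up to the
    next whole patient, the conventional way an NNT is quoted.
    """

    p1: float
    p2: float
    arr: float
    nnt: float | None

    @property
    def nnt_display(self) -> int | None:
        return None if self.nnt is None else math.ceil(self.nnt - 1e-12)


def _as_table(table, zero_correction: bool):
    if zero_correction and (table.a == 0 or table.c == 0):
        return table.continuity_corrected()
    return table


def relative_risk(table: TwoByTwoTable, *, zero_correction: bool = False) -> EffectEstimate:
    """Relative risk (a/n1)/(c/n2) of one table, with SE of its log.

    Raises :class:`ZeroEventError` when either arm has zero events and no
    continuity correction was requested.
    """
    t = _as_table(table, zero_correction)
    if t.a == 0 or t.c == 0:
        raise ZeroEventError(
            f"relative risk undefined with zero events (a={table.a}, c={table.c})"
        )
    point = (t.a / t.n1) / (t.c / t.n2)
    se = math.sqrt(1 / t.a + 1 / t.c - 1 / t.n1 - 1 / t.n2)
    return EffectEstimate(Measure.RELATIVE_RISK, point, se, Provenance.FROM_COUNTS)


def se_ln_rr(table: TwoByTwoTable, *, zero_correction: bool = False) -> float:
    """SE of the log relative risk: sqrt(1/a + 1/c - 1/n1 - 1/n2).

    The radicand is non-negative for any valid table because a <= n1 and
    c <= n2; tiny negative floating-point residue is clamped to zero.
    """
    t = _as_table(table, zero_correction)
    if t.a == 0 or t.c == 0:
        raise ZeroEventError(
            f"SE[ln RR] undefined with zero events (a={table.a}, c={table.c})"
        )
    radicand = 1 / t.a + 1 / t.c - 1 / t.n1 - 1 / t.n2
    return math.sqrt(max(radicand, 0.0))


def peto_z_v(table: TwoByTwoTable) -> tuple[float, float]:
    """Peto components: observed-minus-expected Z and hypergeometric V."""
    n1, n2, n = table.n1, table.n2, table.total
    m1 = table.a + table.c  # total events
    m2 = table.b + table.d  # total non-events
    z = table.a - n1 * m1 / n
    if n < 2:
        return z, 0.0
    v = n1 * n2 * m1 * m2 / (n * n * (n - 1))
    return z, v


def peto_or(table: TwoByTwoTable) -> EffectEstimate:
    """Peto one-step odds ratio exp(Z/V) with SE[ln OR] = 1/sqrt(V)."""
    m1 = table.a + table.c
    m2 = table.b + table.d
    if m1 == 0:
        raise ZeroEventError("Peto odds ratio undefined with zero total events")
    if m2 == 0 or table.total < 2:
        raise DegenerateTableError(
            "Peto variance is zero (no non-events or fewer than two patients)"
        )
    z, v = peto_z_v(table)
    return EffectEstimate(Measure.PETO_OR, math.exp(z / v), 1 / math.sqrt(v),
                          Provenance.FROM_COUNTS)


def se_ln_peto(table: TwoByTwoTable) -> float:
    """SE of the log Peto odds ratio, 1/sqrt(V).

    Algebraically identical to the fully count-expanded rendering
    sqrt(N^2 (N-1) / (n1 n2 (a+c)(b+d))).
    """
    return peto_or(table).se_ln


def se_from_ci(point: float, lower: float, upper: float,
               confidence: float = 0.95) -> float:
    """Back-calculate SE of the log ratio from a reported interval.

    Assumes the interval is symmetric and normal on the log scale:
    SE = (ln upper - ln lower) / (2 z), with z the standard-normal
    quantile at (1+confidence)/2.
    """
    if not 0 < confidence < 1:
        raise DomainError(f"confidence must lie in (0,1), got {confidence}")
    if not (0 < lower <= point <= upper):
        raise DomainError(
            f"require 0 < lower <= point <= upper, got ({point}, {lower}, {upper})"
        )
    z = float(norm.ppf((1 + confidence) / 2))
    return (math.log(upper) - math.log(lower)) / (2 * z)


def risk_difference_nnt(table: TwoByTwoTable) -> RiskDifferenceSummary:
    """Arm risks, absolute risk reduction, and number needed to treat."""
    p1 = table.a / table.n1
    p2 = table.c / table.n2
    arr = p2 - p1
    if arr == 0:
        raise NullEffectError("absolute risk difference is zero; NNT undefined")
    return RiskDifferenceSummary(p1=p1, p2=p2, arr=arr, nnt=1 / abs(arr))


def effect_direction(estimate: EffectEstimate, *, adverse: bool = True) -> Direction:
    """Classify an estimate as benefit, harm, or null.

    For an adverse-event outcome a ratio below 1 is benefit.  ``adverse=False``
    inverts the mapping for desirable outcomes.  When the estimate has no
    point value, its stored direction flag is used instead.
    """
    if estimate.point is None:
        if estimate.direction is not None:
            d = estimate.direction
            if not adverse and d is not Direction.NULL:
                d = Direction.HARM if d is Direction.BENEFIT else Direction.BENEFIT
            return d
        raise DomainError("estimate has neither a point value nor a direction flag")
    lp = math.log(estimate.point)
    if abs(lp) < NULL_TOLERANCE:
        return Direction.NULL
    benefit = lp < 0
    if not adverse:
        benefit = not benefit
    return Direction.BENEFIT if benefit else Direction.HARM
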