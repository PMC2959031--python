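"""Fixed-effect pooling of 2x2 tables across trials.

Two pooled estimators are provided, matching the two per-study measures:

* Mantel-Haenszel pooled relative risk, point R/S with
  SE[ln RR_MH] = sqrt(P / (R*S)), where over trials i

      P = sum_i [n1_i n2_i (a_i+c_i) - a_i c_i N_i] / N_i^2
      R = sum_i a_i n2_i / N_i
      S = sum_i c_i n1_i / N_i

  (the Greenland-Robins variance for the log MH risk ratio);

* pooled Peto odds ratio exp(sum Z_i / sum V_i) with
  SE[ln OR_Peto] = 1 / sqrt(sum V_i).

Both are fixed-effect: no heterogeneity statistic is computed, and trials
with zero total events contribute nothing to any sum (they are skipped
with a warning rather than aborting the pool).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .effect_measures import (
    EffectEstimate,
    Measure,
    Provenance,
    TwoByTwoTable,
    peto_z_v,
)
from .errors import DomainError, NoEventsError

__all__ = ["TrialSet", "PooledComponents", "pooled_components",
           "mh_pooled_rr", "peto_pooled_or"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialSet:
    """An ordered collection of labelled 2x2 tables to be pooled."""

    tables: tuple[TwoByTwoTable, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.tables) == 0:
            raise DomainError("a trial set needs at least one trial")
        if len(self.labels) != len(self.tables):
            raise DomainError("one label per table required")
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("trial labels must be unique")

    @classmethod
    def from_tables(cls, tables, labels=None) -> "TrialSet":
        tables = tuple(tables)
        if labels is None:
            labels = tuple(f"trial-{i + 1}" for i in range(len(tables)))
        return cls(tables=tables, labels=tuple(labels))

    def __len__(self):
        return len(self.tables)


@dataclass(frozen=True)
class PooledComponents:
    """Sufficient statistics for both pooled estimators.

    P, R, S feed the Mantel-Haenszel log-RR standard error; sum_z and
    sum_v feed the pooled Peto odds ratio.  Each is the exact sum of its
    per-trial terms over trials with at least one event.
    """

    p: float
    r: float
    s: float
    sum_z: float
    sum_v: float
    n_trials: int
    n_skipped: int


def pooled_components(trial_set: TrialSet) -> PooledComponents:
    """Accumulate P, R, S and the Peto sums over a trial set.

    Trials with zero total events carry no information for either ratio
    measure; they are skipped (logged) instead of failing the pool.
    """
    p = r = s = sum_z = sum_v = 0.0
    skipped = 0
    for label, t in zip(trial_set.labels, trial_set.tables):
        if t.a + t.c == 0:
            log.warning("trial %s has zero events in both arms; skipped from pooling",
                        label)
            skipped += 1
            continue
        n = t.total
        p += (t.n1 * t.n2 * (t.a + t.c) - t.a * t.c * n) / (n * n)
        r += t.a * t.n2 / n
        s += t.c * t.n1 / n
        z, v = peto_z_v(t)
        sum_z += z
        sum_v += v
    return PooledComponents(p=p, r=r, s=s, sum_z=sum_z, sum_v=sum_v,
                            n_trials=len(trial_set) - skipped, n_skipped=skipped)


def mh_pooled_rr(trial_set: TrialSet) -> EffectEstimate:
    """Mantel-Haenszel pooled relative risk with its log-scale SE.

    Requires at least one event in each arm across the set (R > 0 and
    S > 0).  For a single trial the SE coincides with the per-study
    SE[ln RR] of that table.
    """
    comp = pooled_components(trial_set)
    if comp.r <= 0 or comp.s <= 0:
        raise NoEventsError(
            "Mantel-Haenszel pooling needs events in both arms across the set"
        )
    return EffectEstimate(
        Measure.RELATIVE_RISK,
        comp.r / comp.s,
        math.sqrt(comp.p / (comp.r * comp.s)),
        Provenance.FROM_COUNTS,
    )


def peto_pooled_or(trial_set: TrialSet) -> EffectEstimate:
    """Pooled Peto odds ratio exp(sum Z / sum V), SE = 1/sqrt(sum V)."""
    comp = pooled_components(trial_set)
    if comp.sum_v <= 0:
        raise NoEventsError("pooled Peto odds ratio needs positive total variance")
    return EffectEstimate(
        Measure.PETO_OR,
        math.exp(comp.sum_z / comp.sum_v),
        1 / math.sqrt(comp.sum_v),
        Provenance.FROM_COUNTS,
    )
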