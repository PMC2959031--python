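"""Per-study effect measures: worked values, error cases, and invariants."""

import math

import pytest
from hypothesis import given, strategies as st

from errormatrix import (
    Direction,
    EffectEstimate,
    Measure,
    Provenance,
    TwoByTwoTable,
    effect_direction,
    peto_or,
    relative_risk,
    risk_difference_nnt,
    se_from_ci,
    se_ln_peto,
    se_ln_rr,
)
from errormatrix.effect_measures import peto_z_v
from errormatrix.errors import (
    DegenerateTableError,
    DomainError,
    NullEffectError,
    ZeroEventError,
)


def valid_tables(min_a=0, min_c=0, min_nonevents=0):
    """Hypothesis strategy over valid 2x2 tables."""
    counts = st.tuples(
        st.integers(min_a, 400), st.integers(0, 400),
        st.integers(min_c, 400), st.integers(0, 400),
    ).filter(
        lambda t: t[0] + t[1] >= 1 and t[2] + t[3] >= 1
        and t[1] + t[3] >= min_nonevents
    )
    return counts.map(lambda t: TwoByTwoTable(*t))


class TestTwoByTwoTable:
    def test_derived_sizes(self):
        t = TwoByTwoTable(10, 90, 20, 80)
        assert (t.n1, t.n2, t.total) == (100, 100, 200)

    @pytest.mark.parametrize("counts", [(-1, 1, 1, 1), (0, 0, 1, 1), (1, 1, 0, 0)])
    def test_invalid_tables_rejected(self, counts):
        with pytest.raises(DomainError):
            TwoByTwoTable(*counts)


class TestRelativeRisk:
    @pytest.mark.parametrize("counts, point", [
        ((10, 90, 20, 80), 0.5),
        ((5, 5, 5, 5), 1.0),
        ((10, 90, 10, 90), 1.0),
    ])
    def test_point(self, counts, point):
        est = relative_risk(TwoByTwoTable(*counts))
        assert est.measure is Measure.RELATIVE_RISK
        assert est.provenance is Provenance.FROM_COUNTS
        assert est.point == pytest.approx(point)

    @pytest.mark.parametrize("counts, se", [
        ((10, 90, 10, 90), math.sqrt(0.18)),          # 0.42426
        ((100, 0, 100, 0), 0.0),                      # every patient has the event
        ((1, 999, 1, 999), math.sqrt(2 - 0.002)),     # 1.41350
    ])
    def test_se(self, counts, se):
        assert se_ln_rr(TwoByTwoTable(*counts)) == pytest.approx(se, abs=1e-10)

    @pytest.mark.parametrize("counts", [(0, 10, 5, 5), (5, 5, 0, 10)])
    def test_zero_events_raise(self, counts):
        t = TwoByTwoTable(*counts)
        with pytest.raises(ZeroEventError):
            relative_risk(t)
        with pytest.raises(ZeroEventError):
            se_ln_rr(t)

    def test_optional_continuity_correction(self):
        t = TwoByTwoTable(0, 10, 5, 5)
        est = relative_risk(t, zero_correction=True)
        assert est.point == pytest.approx((0.5 / 11) / (5.5 / 11))

    @given(valid_tables(min_a=1, min_c=1))
    def test_radicand_never_negative(self, t):
        # 1/a + 1/c - 1/n1 - 1/n2 >= 0 since a <= n1 and c <= n2
        assert se_ln_rr(t) >= 0.0


class TestPetoOddsRatio:
    def test_null_point_and_se(self):
        est = peto_or(TwoByTwoTable(5, 5, 5, 5))
        assert est.point == pytest.approx(1.0)
        assert est.se_ln == pytest.approx(1 / math.sqrt(10 * 10 * 10 * 10 / (400 * 19)))
        assert est.se_ln == pytest.approx(0.87178, abs=5e-6)

    def test_se_worked_values(self):
        assert se_ln_peto(TwoByTwoTable(1, 1, 1, 1)) == pytest.approx(math.sqrt(3))
        t = TwoByTwoTable(10, 90, 10, 90)
        v = 100 * 100 * 20 * 180 / (200 ** 2 * 199)
        assert peto_or(t).point == pytest.approx(1.0)
        assert se_ln_peto(t) == pytest.approx(1 / math.sqrt(v))

    def test_degenerate_tables(self):
        with pytest.raises(ZeroEventError):
            peto_or(TwoByTwoTable(0, 5, 0, 5))
        with pytest.raises(DegenerateTableError):
            peto_or(TwoByTwoTable(5, 0, 5, 0))

    @given(valid_tables(min_nonevents=1).filter(lambda t: t.a + t.c >= 1
                                                and t.total >= 2))
    def test_dual_formula_identity(self, t):
        """1/sqrt(V) equals the count-expanded rendering to 1e-12."""
        expanded = math.sqrt(t.total ** 2 * (t.total - 1)
                             / (t.n1 * t.n2 * (t.a + t.c) * (t.b + t.d)))
        assert se_ln_peto(t) == pytest.approx(expanded, rel=1e-12)

    @given(valid_tables(min_nonevents=1).filter(lambda t: t.a + t.c >= 1
                                                and t.total >= 2))
    def test_arm_swap_symmetry(self, t):
        """Swapping arms negates Z, preserves V, inverts the OR point."""
        z, v = peto_z_v(t)
        zs, vs = peto_z_v(t.swapped())
        assert zs == pytest.approx(-z, abs=1e-9)
        assert vs == pytest.approx(v, rel=1e-12)
        assert peto_or(t.swapped()).point == pytest.approx(1 / peto_or(t).point)
        assert se_ln_peto(t.swapped()) == pytest.approx(se_ln_peto(t), rel=1e-12)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 10))
    def test_equal_risks_give_null_or(self, events, nonevents, m):
        """a/n1 = c/n2 forces Z = 0 and a Peto OR of exactly 1."""
        t = TwoByTwoTable(events, nonevents, events * m, nonevents * m)
        z, _ = peto_z_v(t)
        assert z == pytest.approx(0.0, abs=1e-9)
        assert peto_or(t).point == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [2, 5, 10])
    def test_scaling_balanced_table_shrinks_se(self, m):
        base = TwoByTwoTable(8, 12, 8, 12)
        big = TwoByTwoTable(8 * m, 12 * m, 8 * m, 12 * m)
        assert se_ln_rr(big) < se_ln_rr(base)
        assert se_ln_peto(big) < se_ln_peto(base)


class TestSeFromCi:
    def test_published_cochrane_interval(self):
        assert se_from_ci(2.39, 1.03, 5.59) == pytest.approx(0.43, abs=0.005)

    def test_worked_values(self):
        assert se_from_ci(1.0, 1.0, 1.0) == 0.0
        assert se_from_ci(2.0, 1.0, 4.0) == pytest.approx(math.log(4) / 3.91993,
                                                          abs=1e-5)

    def test_ordering_enforced(self):
        with pytest.raises(DomainError):
            se_from_ci(2.0, 3.0, 4.0)
        with pytest.raises(DomainError):
            se_from_ci(2.0, 1.0, 4.0, confidence=1.5)

    @given(st.floats(0.01, 100), st.floats(1.01, 10), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, lower, spread, k):
        point = lower * math.sqrt(spread)
        upper = lower * spread
        base = se_from_ci(point, lower, upper)
        scaled = se_from_ci(point * k, lower * k, upper * k)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestRiskDifferenceNnt:
    @pytest.mark.parametrize("counts, arr, nnt", [
        ((10, 90, 20, 80), 0.10, 10),
        ((15, 85, 20, 80), 0.05, 20),
    ])
    def test_worked_values(self, counts, arr, nnt):
        rd = risk_difference_nnt(TwoByTwoTable(*counts))
        assert rd.arr == pytest.approx(arr)
        assert rd.nnt_display == nnt
        assert rd.nnt >= 1

    def test_null_effect(self):
        with pytest.raises(NullEffectError):
            risk_difference_nnt(TwoByTwoTable(10, 90, 10, 90))

    def test_display_rounds_up(self):
        rd = risk_difference_nnt(TwoByTwoTable(3, 97, 10, 90))
        assert rd.nnt == pytest.approx(1 / 0.07)
        assert rd.nnt_display == 15


class TestEffectDirection:
    @pytest.mark.parametrize("point, expected", [
        (0.5, Direction.BENEFIT), (2.39, Direction.HARM), (1.0, Direction.NULL),
    ])
    def test_adverse_outcomes(self, point, expected):
        est = EffectEstimate(Measure.REPORTED_RATIO, point, 0.1,
                             Provenance.AS_REPORTED)
        assert effect_direction(est) is expected

    def test_desirable_outcome_inverts(self):
        est = EffectEstimate(Measure.REPORTED_RATIO, 2.0, 0.1,
                             Provenance.AS_REPORTED)
        assert effect_direction(est, adverse=False) is Direction.BENEFIT

    def test_direction_flag_used_without_point(self):
        est = EffectEstimate(Measure.REPORTED_RATIO, None, 0.5,
                             Provenance.AS_REPORTED, direction=Direction.HARM)
        assert effect_direction(est) is Direction.HARM
        assert effect_direction(est, adverse=False) is Direction.BENEFIT
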