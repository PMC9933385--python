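"""t reconstruction, F gate, P recomputation, effect sizes, P verification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import betainc

from bfretest import (
    DomainError,
    PQualifier,
    PreconditionError,
    Procedure,
    ReportedTest,
    TestKind,
    VerificationStatus,
    effect_size,
    f_variance_test,
    p_from_t,
    t_from_summary,
    verify_reported_p,
)


def _indep(mean1, sd1, n1, mean2, sd2, n2, **kw):
    return ReportedTest(test_id="i", source="s", test_kind=TestKind.INDEPENDENT,
                        n1=n1, mean1=mean1, sd1=sd1, n2=n2, mean2=mean2, sd2=sd2, **kw)


def _dep(mean1, sd1, n1, kind=TestKind.DEPENDENT, **kw):
    return ReportedTest(test_id="d", source="s", test_kind=kind,
                        n1=n1, mean1=mean1, sd1=sd1, **kw)


# ---------------------------------------------------------------------------
# F test of variance equality
# ---------------------------------------------------------------------------


def test_f_test_identical_variances():
    vt = f_variance_test(1.5, 10, 1.5, 10)
    assert vt.f == 1.0 and vt.equal_variances
    assert vt.p == pytest.approx(1.0)


def test_f_test_against_incomplete_beta_oracle():
    # P(F_{9,9} > 4) via the regularized incomplete beta form of the F CDF
    vt = f_variance_test(2.0, 10, 1.0, 10, alpha_f=0.05)
    assert vt.f == 4.0 and (vt.df_num, vt.df_den) == (9, 9)
    p_oracle = 2.0 * betainc(9 / 2, 9 / 2, 9 / (9 + 9 * 4.0))
    assert vt.p == pytest.approx(p_oracle, rel=1e-12)
    assert vt.equal_variances == (vt.p > 0.05)
    assert vt.equal_variances  # p ~ 0.0527 is just above the 0.05 gate


def test_f_test_is_symmetric_in_group_order():
    a = f_variance_test(1.0, 12, 2.0, 9)
    b = f_variance_test(2.0, 9, 1.0, 12)
    assert a.f == b.f and a.p == b.p
    assert (a.df_num, a.df_den) == (b.df_num, b.df_den) == (8, 11)


def test_f_test_rejects_zero_sd_and_tiny_groups():
    with pytest.raises(DomainError):
        f_variance_test(0.0, 10, 1.0, 10)
    with pytest.raises(DomainError):
        f_variance_test(1.0, 1, 1.0, 10)


def test_f_test_p_capped_at_one():
    vt = f_variance_test(1.0, 5, 1.0000001, 5)
    assert vt.p <= 1.0


# ---------------------------------------------------------------------------
# t reconstruction
# ---------------------------------------------------------------------------


def test_equal_means_give_t_zero():
    gate = f_variance_test(1.0, 10, 2.0, 10)
    ts = t_from_summary(_indep(3.0, 1.0, 10, 3.0, 2.0, 10), gate)
    assert ts.t == 0.0


def test_pooled_hand_example():
    # sp = 1, SE = 1 -> t = 1, df = 2
    gate = f_variance_test(1.0, 2, 1.0, 2)
    ts = t_from_summary(_indep(1.0, 1.0, 2, 0.0, 1.0, 2), gate)
    assert ts.t == pytest.approx(1.0) and ts.df == 2.0
    assert ts.procedure is Procedure.POOLED


def test_welch_equals_pooled_for_balanced_equal_sds():
    rec = _indep(1.3, 0.9, 17, 0.2, 0.9, 17)
    gate_eq = f_variance_test(0.9, 17, 0.9, 17)
    pooled = t_from_summary(rec, gate_eq)
    from bfretest.core import _welch_df

    t_welch = (1.3 - 0.2) / math.sqrt(0.9**2 / 17 + 0.9**2 / 17)
    assert pooled.t == pytest.approx(t_welch, rel=1e-12)
    assert _welch_df(0.9, 17, 0.9, 17) == pytest.approx(pooled.df, rel=1e-12)


@pytest.mark.parametrize("equal_var", [True, False])
def test_independent_t_matches_scipy_from_stats(equal_var):
    rng = np.random.default_rng(42)
    for _ in range(25):
        n1, n2 = rng.integers(5, 40, size=2)
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.3, 3.0, size=2)
        rec = _indep(m1, s1, int(n1), m2, s2, int(n2))
        gate = f_variance_test(s1, int(n1), s2, int(n2),
                               alpha_f=1e-12 if equal_var else 1 - 1e-12)
        assert gate.equal_variances is equal_var
        ts = t_from_summary(rec, gate)
        ref_t, ref_p = stats.ttest_ind_from_stats(
            m1, s1, n1, m2, s2, n2, equal_var=equal_var
        )
        assert ts.t == pytest.approx(ref_t, rel=1e-10)
        assert p_from_t(ts.t, ts.df) == pytest.approx(ref_p, rel=1e-9)


def test_dependent_and_one_sample_t():
    ts = t_from_summary(_dep(0.5, 1.2, 16))
    assert ts.t == pytest.approx(0.5 / (1.2 / 4.0)) and ts.df == 15.0
    assert ts.procedure is Procedure.PAIRED
    one = t_from_summary(_dep(0.5, 1.2, 16, kind=TestKind.ONE_SAMPLE))
    assert one.t == ts.t and one.procedure is Procedure.ONE_SAMPLE


def test_reported_t_passthrough_infers_df_from_kind():
    rec = ReportedTest(test_id="p", source="s", test_kind=TestKind.ONE_SAMPLE,
                       n1=74, reported_t=-2.274)
    ts = t_from_summary(rec)
    assert ts.t == -2.274 and ts.df == 73.0
    assert ts.procedure is Procedure.REPORTED_PASSTHROUGH
    rec2 = ReportedTest(test_id="q", source="s", test_kind=TestKind.INDEPENDENT,
                        n1=28, n2=29, reported_t=-2.102)
    assert t_from_summary(rec2).df == 55.0


def test_missing_summaries_raise_named_precondition_errors():
    with pytest.raises(PreconditionError, match="variance_gate"):
        t_from_summary(_indep(1.0, 1.0, 10, 0.0, 1.0, 10), None)
    rec = ReportedTest(test_id="x", source="s", test_kind=TestKind.DEPENDENT, n1=10)
    with pytest.raises(PreconditionError, match="reported t"):
        t_from_summary(rec)


@given(
    n1=st.integers(2, 200),
    n2=st.integers(2, 200),
    s1=st.floats(0.1, 10.0),
    s2=st.floats(0.1, 10.0),
)
def test_welch_df_bounds(n1, n2, s1, s2):
    """min(n1,n2)-1 <= Welch df <= n1+n2-2."""
    from bfretest.core import _welch_df

    df = _welch_df(s1, n1, s2, n2)
    assert min(n1, n2) - 1 <= df * (1 + 1e-12)
    assert df <= (n1 + n2 - 2) * (1 + 1e-12)


# ---------------------------------------------------------------------------
# P from t
# ---------------------------------------------------------------------------


def test_p_matches_printed_worked_example():
    assert round(p_from_t(2.102, 55), 3) == 0.040


def test_p_at_t_zero_is_one():
    assert p_from_t(0.0, 7.3) == 1.0


def test_p_df1_matches_cauchy_closed_form():
    for t in (0.5, 1.0, 12.706, 60.0):
        closed = 1.0 - (2.0 / math.pi) * math.atan(t)
        assert p_from_t(t, 1.0) == pytest.approx(closed, rel=1e-10)


def test_p_large_df_matches_normal_approximation():
    for t in (0.3, 1.0, 1.96, 3.5):
        assert abs(p_from_t(t, 1e6) - 2.0 * stats.norm.sf(t)) < 1e-6


@given(t=st.floats(-30, 30, allow_nan=False))
def test_p_is_even_in_t(t):
    assert p_from_t(t, 17.0) == p_from_t(-t, 17.0)


@given(t=st.floats(0, 30), dt=st.floats(1e-6, 5.0))
def test_p_strictly_decreasing_in_abs_t(t, dt):
    assert p_from_t(t + dt, 9.0) < p_from_t(t, 9.0)


def test_p_rejects_bad_inputs():
    with pytest.raises(DomainError):
        p_from_t(float("nan"), 10.0)
    with pytest.raises(DomainError):
        p_from_t(1.0, 0.0)


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------


def test_effect_size_definitions():
    assert effect_size(_dep(0.0, 1.0, 10)) == 0.0
    assert effect_size(_dep(0.5, 1.0, 10)) == 0.5
    assert effect_size(_dep(-0.5, 1.0, 10)) == -0.5  # sign preserved
    assert effect_size(_indep(1.0, 1.0, 8, 0.0, 1.0, 8)) == pytest.approx(1.0)
    # pooled SD: sp = sqrt((7*4 + 7*1)/14) = sqrt(2.5)
    d = effect_size(_indep(2.0, 2.0, 8, 0.0, 1.0, 8))
    assert d == pytest.approx(2.0 / math.sqrt(2.5))


def test_effect_size_requires_summaries():
    rec = ReportedTest(test_id="p", source="s", test_kind=TestKind.ONE_SAMPLE,
                       n1=74, reported_t=-2.274)
    with pytest.raises(PreconditionError):
        effect_size(rec)


# ---------------------------------------------------------------------------
# verification of the printed P
# ---------------------------------------------------------------------------


def _verify(recomputed, reported, qualifier=PQualifier.EQ, **kw):
    rec = _dep(0.5, 1.0, 10, reported_p=reported, reported_p_qualifier=qualifier)
    return verify_reported_p(recomputed, rec, **kw)


def test_verify_rounding_rule_at_printed_precision():
    assert _verify(0.0402, 0.04).status is VerificationStatus.CONGRUENT
    assert _verify(0.0448, 0.04).status is VerificationStatus.CONGRUENT
    assert _verify(0.046, 0.04).status is VerificationStatus.INCONGRUENT


def test_verify_inequality_qualifiers():
    assert _verify(0.0005, 0.001, PQualifier.LT).status is VerificationStatus.CONGRUENT
    assert _verify(0.002, 0.001, PQualifier.LT).status is VerificationStatus.INCONGRUENT
    assert _verify(0.05, 0.05, PQualifier.LE).status is VerificationStatus.INCONGRUENT
    assert _verify(0.04, 0.05, PQualifier.LE).status is VerificationStatus.CONGRUENT


def test_verify_requires_same_side_of_alpha():
    # rounds fine at 2 dp is impossible here; clearly on opposite sides
    assert _verify(0.03, 0.21).status is VerificationStatus.INCONGRUENT
    # printed 0.05 is nonsignificant; a recomputed 0.0496 rounds to it and the
    # comparison at printed precision keeps them on the same side
    assert _verify(0.0496, 0.05).status is VerificationStatus.CONGRUENT
    assert _verify(0.0504, 0.05).status is VerificationStatus.CONGRUENT


def test_verify_missing_reported_p_is_unverifiable():
    rec = _dep(0.5, 1.0, 10)
    out = verify_reported_p(0.123, rec)
    assert out.status is VerificationStatus.UNVERIFIABLE and out.reported_p is None


def test_verify_respects_tolerance_cap():
    # printed at 4 dp but tolerance capped at 3: comparison happens at 3 dp
    assert _verify(0.12349, 0.1235, tolerance_dp=3).status is VerificationStatus.CONGRUENT


def test_verify_rejects_out_of_range_recomputed():
    with pytest.raises(DomainError):
        _verify(0.0, 0.05)
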