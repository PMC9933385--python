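"""Reconstruction of t statistics from summary statistics and P verification.

The retest of a published t test starts from the numbers an article actually
prints — group means, SDs and sample sizes — and rebuilds the test statistic:

* one-sample / dependent:  t = m / (s / sqrt(n)),  df = n - 1, where ``m``/``s``
  are the mean and SD of the (paired) differences;
* independent, equal variances:  pooled-SD t with df = n1 + n2 - 2;
* independent, unequal variances:  Welch t with Welch–Satterthwaite df.

Which two-sample formula applies is decided by a preliminary F test of
variance equality (larger sample variance over smaller, two-sided tail).
The recomputed two-sided P is then compared against the printed one to flag
transcription or computation errors before any downstream analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import Decimal

from scipy import stats

from .errors import DomainError, PreconditionError
from .records import PQualifier, ReportedTest, TestKind

__all__ = [
    "Procedure",
    "TStat",
    "VarianceTest",
    "VerificationStatus",
    "VerificationOutcome",
    "f_variance_test",
    "t_from_summary",
    "p_from_t",
    "effect_size",
    "pooled_sd",
    "verify_reported_p",
]


class Procedure(str, enum.Enum):
    POOLED = "pooled"
    WELCH = "welch"
    PAIRED = "paired"
    ONE_SAMPLE = "one_sample"
    REPORTED_PASSTHROUGH = "reported_passthrough"


@dataclass(frozen=True)
class TStat:
    """A reconstructed (or passed-through) t statistic with its df."""

    t: float
    df: float
    procedure: Procedure


@dataclass(frozen=True)
class VarianceTest:
    """Two-sided F test of variance equality, larger variance in the numerator."""

    f: float
    df_num: int
    df_den: int
    p: float
    equal_variances: bool


class VerificationStatus(str, enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"
    UNVERIFIABLE = "unverifiable"


@dataclass(frozen=True)
class VerificationOutcome:
    status: VerificationStatus
    recomputed_p: float
    reported_p: float | None


def f_variance_test(
    sd1: float, n1: int, sd2: float, n2: int, alpha_f: float = 0.05
) -> VarianceTest:
    """F test of H0: sigma1^2 == sigma2^2 against a two-sided alternative.

    The statistic is the larger sample variance over the smaller (so f >= 1,
    and the result is invariant to group order), with numerator/denominator
    df ordered accordingly. P is twice the upper tail, capped at 1. The
    ``equal_variances`` decision (p > alpha_f) selects pooled vs Welch t.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError(f"F test needs n1, n2 >= 2, got {n1}, {n2}")
    v1, v2 = sd1 * sd1, sd2 * sd2
    if min(v1, v2) <= 0.0:
        raise DomainError("F test undefined for a zero SD")
    if v1 >= v2:
        f, df_num, df_den = v1 / v2, n1 - 1, n2 - 1
    else:
        f, df_num, df_den = v2 / v1, n2 - 1, n1 - 1
    p = min(1.0, 2.0 * float(stats.f.sf(f, df_num, df_den)))
    return VarianceTest(
        f=float(f), df_num=df_num, df_den=df_den, p=p, equal_variances=bool(p > alpha_f)
    )


def _welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    a, b = sd1 * sd1 / n1, sd2 * sd2 / n2
    return (a + b) ** 2 / (a * a / (n1 - 1) + b * b / (n2 - 1))


def t_from_summary(test: ReportedTest, variance_gate: VarianceTest | None = None) -> TStat:
    """Rebuild the t statistic (and df) for one record.

    Uses the mean/SD/n summaries when they are complete; for independent tests
    the ``variance_gate`` decides pooled vs Welch. When summaries are missing
    but the article printed t, that t is passed through with the df implied by
    the test kind and sample sizes.
    """
    if not test.has_summaries():
        if test.reported_t is None:
            raise PreconditionError(
                f"test_id={test.test_id!r}: no summaries and no reported t"
            )
        if test.test_kind is TestKind.INDEPENDENT:
            if test.n2 is None:
                raise PreconditionError(f"test_id={test.test_id!r}: n2 missing")
            df = float(test.n1 + test.n2 - 2)
        else:
            df = float(test.n1 - 1)
        return TStat(t=float(test.reported_t), df=df, procedure=Procedure.REPORTED_PASSTHROUGH)

    if test.test_kind in (TestKind.ONE_SAMPLE, TestKind.DEPENDENT):
        se = test.sd1 / math.sqrt(test.n1)
        proc = Procedure.ONE_SAMPLE if test.test_kind is TestKind.ONE_SAMPLE else Procedure.PAIRED
        return TStat(t=test.mean1 / se, df=float(test.n1 - 1), procedure=proc)

    # independent
    if variance_gate is None:
        raise PreconditionError(
            f"test_id={test.test_id!r}: independent test requires a variance_gate"
        )
    n1, n2 = test.n1, test.n2
    diff = test.mean1 - test.mean2
    if variance_gate.equal_variances:
        sp = pooled_sd(test.sd1, n1, test.sd2, n2)
        t = diff / (sp * math.sqrt(1.0 / n1 + 1.0 / n2))
        return TStat(t=t, df=float(n1 + n2 - 2), procedure=Procedure.POOLED)
    t = diff / math.sqrt(test.sd1 ** 2 / n1 + test.sd2 ** 2 / n2)
    return TStat(t=t, df=_welch_df(test.sd1, n1, test.sd2, n2), procedure=Procedure.WELCH)


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Pooled standard deviation sp = sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2))."""
    if sd1 <= 0 or sd2 <= 0:
        raise DomainError("pooled SD undefined for non-positive SDs")
    return math.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))


def p_from_t(t: float, df: float) -> float:
    """Two-sided P value of Student's t: 2 * P(T_df > |t|)."""
    if not math.isfinite(t):
        raise DomainError(f"t must be finite, got {t!r}")
    if not df > 0:
        raise DomainError(f"df must be positive, got {df!r}")
    return min(1.0, 2.0 * float(stats.t.sf(abs(t), df)))


def effect_size(test: ReportedTest) -> float:
    """Cohen's d from the record's summaries, sign preserved.

    Dependent / one-sample: d = mean of differences / SD of differences.
    Independent: d = (mean1 - mean2) / pooled SD.
    """
    if not test.has_summaries():
        raise PreconditionError(
            f"test_id={test.test_id!r}: effect size needs mean/sd summaries"
        )
    if test.test_kind in (TestKind.ONE_SAMPLE, TestKind.DEPENDENT):
        if test.sd1 <= 0:
            raise DomainError("effect size undefined for zero SD")
        return test.mean1 / test.sd1
    sp = pooled_sd(test.sd1, test.n1, test.sd2, test.n2)
    return (test.mean1 - test.mean2) / sp


def _decimal_places(x: float, cap: int) -> int:
    """Number of decimals in the shortest decimal representation of x, capped."""
    exponent = Decimal(str(x)).normalize().as_tuple().exponent
    return min(max(0, -int(exponent)), cap)


def verify_reported_p(
    recomputed_p: float,
    test: ReportedTest,
    tolerance_dp: int = 3,
    alpha: float = 0.05,
) -> VerificationOutcome:
    """Compare a recomputed P against the printed one.

    A printed "P = x" is congruent when the recomputed P rounds (half-even) to
    x at the precision the article used (at most ``tolerance_dp`` decimals) and
    the two values sit on the same side of ``alpha`` — that side comparison is
    made at the printed precision, since the printed number is all a reader
    had. A printed "P < x" / "P <= x" is congruent when the recomputed P
    satisfies the inequality and agrees with x about significance at ``alpha``.
    Records without a printed P are unverifiable.
    """
    if not (0.0 < recomputed_p <= 1.0):
        raise DomainError(f"recomputed_p must lie in (0, 1], got {recomputed_p!r}")
    reported = test.reported_p
    if reported is None:
        return VerificationOutcome(VerificationStatus.UNVERIFIABLE, recomputed_p, None)

    qualifier = test.reported_p_qualifier
    if qualifier is PQualifier.EQ:
        dp = _decimal_places(reported, tolerance_dp)
        rounded = round(recomputed_p, dp)
        value_ok = math.isclose(rounded, round(reported, dp), abs_tol=1e-12)
        side_ok = (rounded < alpha) == (reported < alpha)
    else:
        value_ok = (
            recomputed_p < reported
            if qualifier is PQualifier.LT
            else recomputed_p <= reported
        )
        # "P < x" with x <= alpha is a significance claim; check the recomputed
        # P lands on the same side of alpha as the printed bound.
        side_ok = (recomputed_p < alpha) == (reported <= alpha)
    status = (
        VerificationStatus.CONGRUENT
        if (value_ok and side_ok)
        else VerificationStatus.INCONGRUENT
    )
    return VerificationOutcome(status, recomputed_p, reported)
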