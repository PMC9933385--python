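"""Default Jeffreys–Zellner–Siow (JZS) Bayes factor for t tests.

Under the alternative the standardized effect size delta follows a Cauchy
prior with scale ``r`` (default 0.707, the "medium" setting); under the null
delta = 0. Writing nu for the t-test degrees of freedom and N for the
effective sample size (N = n for a one-sample or paired design,
N = n1*n2/(n1+n2) for two independent groups), the Bayes factor in favour of
the alternative is

    BF10 = Integral_0^inf (1 + N g)^(-1/2)
             * (1 + t^2 / ((1 + N g) nu))^(-(nu+1)/2)
             * pi^(-1/2) (r^2/2)^(1/2) g^(-3/2) exp(-r^2 / (2 g)) dg
           / (1 + t^2/nu)^(-(nu+1)/2),

i.e. the Cauchy prior is expanded as a normal scale mixture, delta | g ~
Normal(0, g) with g ~ InverseGamma(1/2, r^2/2), and g is integrated out
numerically. The package reports BF01 = 1/BF10: values above 1 favour the
null, below 1 the alternative.

Numerics: the integral is mapped onto (0, 1) via g = u/(1-u) and evaluated by
adaptive Gauss–Kronrod quadrature on the log-scale integrand with the central
t density folded in, so the result stays finite for |t| as large as 50 without
overflow or underflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import ConfigError, DomainError, NumericError

__all__ = [
    "JZSConfig",
    "bf10_from_t",
    "bf01_one_sample",
    "bf01_independent",
    "PCategory",
    "BFCategory",
    "EffectCategory",
    "EvidenceLabels",
    "EvidenceCutoffs",
    "categorize",
]

_HALF_LOG_PI = 0.5 * math.log(math.pi)


@dataclass(frozen=True)
class JZSConfig:
    """Prior scale and quadrature controls for the JZS Bayes factor.

    rscale
        Cauchy prior scale on the standardized effect size (0.707 is the
        conventional "medium" default).
    rel_tolerance
        Relative-error target for the adaptive quadrature.
    limit
        Maximum number of subinterval bisections.
    """

    rscale: float = 0.707
    rel_tolerance: float = 1e-8
    limit: int = 200

    def __post_init__(self) -> None:
        if not self.rscale > 0:
            raise ConfigError(f"rscale must be positive, got {self.rscale!r}")
        if not (0.0 < self.rel_tolerance < 1e-3):
            raise ConfigError(
                f"rel_tolerance must lie in (0, 1e-3), got {self.rel_tolerance!r}"
            )


DEFAULT_JZS = JZSConfig()


def _log_integrand(u: float, t: float, nu: float, N: float, r: float) -> float:
    """log of the BF10 integrand after g = u/(1-u), central-t density folded in."""
    g = u / (1.0 - u)
    log_prior = 0.5 * math.log(r * r / 2.0) - _HALF_LOG_PI - 1.5 * math.log(g) - r * r / (2.0 * g)
    shrink = 1.0 + N * g
    log_lik_ratio = -0.5 * math.log(shrink) - 0.5 * (nu + 1.0) * (
        math.log1p(t * t / (shrink * nu)) - math.log1p(t * t / nu)
    )
    log_jacobian = -2.0 * math.log1p(-u)
    return log_prior + log_lik_ratio + log_jacobian


def bf10_from_t(t: float, nu: float, N: float, cfg: JZSConfig = DEFAULT_JZS) -> float:
    """JZS BF10 for a t statistic with df ``nu`` and effective sample size ``N``."""
    if not math.isfinite(t):
        raise DomainError(f"t must be finite, got {t!r}")
    if not (nu > 0 and N > 0):
        raise DomainError(f"need nu > 0 and N > 0, got nu={nu!r}, N={N!r}")

    def f(u: float) -> float:
        if u <= 0.0 or u >= 1.0:
            return 0.0 if u <= 0.0 else math.exp(_log_limit_at_one(t, nu, N, cfg.rscale))
        return math.exp(_log_integrand(u, t, nu, N, cfg.rscale))

    value, abserr = integrate.quad(
        f, 0.0, 1.0, epsabs=0.0, epsrel=cfg.rel_tolerance, limit=cfg.limit
    )
    if not (value > 0.0 and math.isfinite(value)):
        raise NumericError(f"BF10 quadrature returned {value!r} at t={t}, nu={nu}, N={N}")
    if abserr > 100.0 * cfg.rel_tolerance * value:
        raise NumericError(
            f"BF10 quadrature error {abserr:.3e} exceeds target at t={t}, nu={nu}, N={N}"
        )
    return value


def _log_limit_at_one(t: float, nu: float, N: float, r: float) -> float:
    # u -> 1 (g -> inf): prior tail ~ g^(-3/2), shrink term ~ (N g)^(-1/2),
    # Jacobian ~ g^2; the product tends to a finite positive constant.
    return (
        0.5 * math.log(r * r / 2.0)
        - _HALF_LOG_PI
        - 0.5 * math.log(N)
        + 0.5 * (nu + 1.0) * math.log1p(t * t / nu)
    )


def bf01_one_sample(t: float, n: int, cfg: JZSConfig = DEFAULT_JZS) -> float:
    """BF01 for a one-sample or paired t test: nu = n - 1, N = n."""
    if n < 2:
        raise DomainError(f"one-sample BF needs n >= 2, got {n}")
    return 1.0 / bf10_from_t(t, float(n - 1), float(n), cfg)


def bf01_independent(t: float, n1: int, n2: int, cfg: JZSConfig = DEFAULT_JZS) -> float:
    """BF01 for an independent-samples t test: nu = n1+n2-2, N = n1*n2/(n1+n2)."""
    if n1 < 2 or n2 < 2:
        raise DomainError(f"independent BF needs n1, n2 >= 2, got {n1}, {n2}")
    return 1.0 / bf10_from_t(t, float(n1 + n2 - 2), n1 * n2 / (n1 + n2), cfg)


# ---------------------------------------------------------------------------
# Evidence categorization on the three conventional scales
# ---------------------------------------------------------------------------


class PCategory(str, enum.Enum):
    DECISIVE = "decisive_against_h0"
    SUBSTANTIVE = "substantive_against_h0"
    POSITIVE = "positive_against_h0"
    NO_EVIDENCE = "no_evidence_against_h0"


class BFCategory(str, enum.Enum):
    EXTREME_H1 = "extreme_for_h1"
    VERY_STRONG_H1 = "very_strong_for_h1"
    STRONG_H1 = "strong_for_h1"
    MODERATE_H1 = "moderate_for_h1"
    ANECDOTAL_H1 = "anecdotal_for_h1"
    NO_EVIDENCE = "no_evidence"
    ANECDOTAL_H0 = "anecdotal_for_h0"
    MODERATE_H0 = "moderate_for_h0"
    STRONG_H0 = "strong_for_h0"
    VERY_STRONG_H0 = "very_strong_for_h0"
    EXTREME_H0 = "extreme_for_h0"


class EffectCategory(str, enum.Enum):
    SMALL = "small"
    SMALL_TO_MEDIUM = "small_to_medium"
    MEDIUM_TO_LARGE = "medium_to_large"
    LARGE_TO_VERY_LARGE = "large_to_very_large"


@dataclass(frozen=True)
class EvidenceLabels:
    p_category: PCategory
    bf_category: BFCategory
    effect_category: EffectCategory


@dataclass(frozen=True)
class EvidenceCutoffs:
    """Band edges for the three scales.

    P bands (left edges, ascending): below ``p_edges[0]`` is decisive evidence
    against the null, then substantive, positive, and no evidence at or above
    ``p_edges[2]``. Effect bands likewise on |d|. BF01 bands are the modified
    Jeffreys ladder: 1/100, 1/30, 1/10, 1/3, 1, 3, 10, 30, 100, with a value on
    a boundary assigned to the band further toward the null (>= closure), and
    BF01 exactly 1 a category of its own.
    """

    p_edges: tuple[float, float, float] = (0.001, 0.01, 0.05)
    effect_edges: tuple[float, float, float] = (0.2, 0.5, 0.8)
    bf_edges: tuple[float, ...] = (
        1.0 / 100.0,
        1.0 / 30.0,
        1.0 / 10.0,
        1.0 / 3.0,
        1.0,
        3.0,
        10.0,
        30.0,
        100.0,
    )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "EvidenceCutoffs":
        """Build from a key-value config (e.g. parsed YAML); keys optional."""
        kwargs = {}
        if "p_edges" in mapping:
            kwargs["p_edges"] = tuple(float(x) for x in mapping["p_edges"])
        if "effect_edges" in mapping:
            kwargs["effect_edges"] = tuple(float(x) for x in mapping["effect_edges"])
        if "bf_edges" in mapping:
            kwargs["bf_edges"] = tuple(float(x) for x in mapping["bf_edges"])
        return cls(**kwargs)


DEFAULT_CUTOFFS = EvidenceCutoffs()

_BF_LADDER = (
    BFCategory.EXTREME_H1,
    BFCategory.VERY_STRONG_H1,
    BFCategory.STRONG_H1,
    BFCategory.MODERATE_H1,
    BFCategory.ANECDOTAL_H1,
    BFCategory.ANECDOTAL_H0,
    BFCategory.MODERATE_H0,
    BFCategory.STRONG_H0,
    BFCategory.VERY_STRONG_H0,
    BFCategory.EXTREME_H0,
)


def categorize(
    p: float, bf01: float, effect: float, cutoffs: EvidenceCutoffs = DEFAULT_CUTOFFS
) -> EvidenceLabels:
    """Assign the three categorical evidence labels for one retested record."""
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p must lie in (0, 1], got {p!r}")
    if not bf01 > 0:
        raise DomainError(f"bf01 must be positive, got {bf01!r}")

    e1, e2, e3 = cutoffs.p_edges
    if p < e1:
        p_cat = PCategory.DECISIVE
    elif p < e2:
        p_cat = PCategory.SUBSTANTIVE
    elif p < e3:
        p_cat = PCategory.POSITIVE
    else:
        p_cat = PCategory.NO_EVIDENCE

    if bf01 == 1.0:
        bf_cat = BFCategory.NO_EVIDENCE
    else:
        idx = int(np.searchsorted(np.asarray(cutoffs.bf_edges), bf01, side="right"))
        bf_cat = _BF_LADDER[idx]

    a = abs(effect)
    f1, f2, f3 = cutoffs.effect_edges
    if a < f1:
        eff_cat = EffectCategory.SMALL
    elif a < f2:
        eff_cat = EffectCategory.SMALL_TO_MEDIUM
    elif a < f3:
        eff_cat = EffectCategory.MEDIUM_TO_LARGE
    else:
        eff_cat = EffectCategory.LARGE_TO_VERY_LARGE
    return EvidenceLabels(p_category=p_cat, bf_category=bf_cat, effect_category=eff_cat)
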