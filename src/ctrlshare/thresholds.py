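"""Baseline null hit rate P0 and the adjusted replication thresholds.

A variant is a "hit" when all three of its p-values clear their thresholds
with a consistent effect direction: method A requires ``p_d < alpha``,
``p_r < beta``, ``p_m < gamma``; method B replaces the replication test with
the shared-control one (``p_s < beta*``); method C additionally pools the
controls at discovery (``p_c < alpha``, ``p_s < beta_perp``).

Because sharing controls correlates the discovery and replication statistics,
keeping ``beta`` unchanged would inflate the joint null hit rate.  The
adjusted thresholds ``beta*`` (method B) and ``beta_perp`` (method C) are
solved so each method's null hit rate equals method A's baseline

    P0 = 2 * Pr(z_d > z_alpha, z_r > z_beta, z_m > z_gamma | H0),

the factor 2 coming from the two consistent sign patterns (+,+,+)/(-,-,-).
Always ``beta_perp < beta* < beta``; on the z-scale, ``z_{beta*}`` exceeds
both ``z_beta`` and the asymptote ``sqrt(1-rho^2) z_beta + rho z_alpha``
(``rho`` the discovery-replication correlation), which the solver uses as its
lower bracket anchor and initial guess.

Two-sided p-value thresholds map to z-scale as ``z_x = -Phi^{-1}(x/2)``
throughout (so ``x = 1`` gives ``z = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .correlations import CorrelationStructure, StudyDesign, derive_correlations
from .mvn_engine import TailRegion, tail_probability

__all__ = [
    "ThresholdSet",
    "AdjustedThresholds",
    "z_from_p",
    "p_from_z",
    "null_hit_rate",
    "solve_beta_star",
    "solve_beta_perp",
    "solve_adjusted",
    "solve_gamma_one",
    "asymptotic_beta_star",
]


def z_from_p(p: float) -> float:
    """Two-sided p-value threshold -> positive z threshold, z = -Phi^{-1}(p/2)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value threshold must be in (0, 1], got {p}")
    return float(-ndtri(p / 2.0))


def p_from_z(z: float) -> float:
    """Positive z threshold -> two-sided p-value, p = 2 Phi(-z)."""
    return float(2.0 * ndtr(-z))


@dataclass(frozen=True)
class ThresholdSet:
    """Two-sided p-value thresholds (alpha, beta, gamma) for the three stages."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    @property
    def z_alpha(self) -> float:
        return z_from_p(self.alpha)

    @property
    def z_beta(self) -> float:
        return z_from_p(self.beta)

    @property
    def z_gamma(self) -> float:
        return z_from_p(self.gamma)


@dataclass(frozen=True)
class AdjustedThresholds:
    """Solved replication thresholds conserving the null hit rate P0.

    ``beta_star`` applies to method B, ``beta_perp`` to method C;
    ``residual`` is the largest absolute conservation error on the
    probability scale.
    """

    beta_star: float
    beta_perp: float
    p0: float
    residual: float


def null_hit_rate(
    design: StudyDesign,
    thresholds: ThresholdSet,
    method: str,
    corr: CorrelationStructure | None = None,
) -> float:
    """Joint null hit rate of a method at the given thresholds.

    The ``beta`` slot of ``thresholds`` is interpreted as the method's
    replication-stage threshold (``beta`` for A, ``beta*`` for B,
    ``beta_perp`` for C).  Returns ``2 * Pr(all three Z's exceed their
    z-thresholds)`` under the method's null covariance.
    """
    if corr is None:
        corr = derive_correlations(design)
    region = TailRegion(
        lower_bounds=(thresholds.z_alpha, thresholds.z_beta, thresholds.z_gamma)
    )
    return 2.0 * tail_probability(corr.sigma(method), region)


def asymptotic_beta_star(
    design: StudyDesign,
    thresholds: ThresholdSet,
    method: str = "B",
    corr: CorrelationStructure | None = None,
) -> float:
    """Large-``z_alpha`` z-scale approximation sqrt(1-rho^2) z_beta + rho z_alpha.

    ``rho`` is ``rho_ds`` for method B and ``rho_cs`` for method C.  The exact
    solved threshold approaches this from above, so it doubles as the solver's
    lower bracket anchor.
    """
    if corr is None:
        corr = derive_correlations(design)
    rho = corr.rho_discovery_replication(method)
    return float(np.sqrt(1.0 - rho * rho) * thresholds.z_beta + rho * thresholds.z_alpha)


def _solve_adjusted_z(
    design: StudyDesign,
    thresholds: ThresholdSet,
    method: str,
    target: float,
    corr: CorrelationStructure,
) -> float:
    """Solve for the z-scale replication threshold of a shared-control method."""
    sigma = corr.sigma(method)
    z_a, z_g = thresholds.z_alpha, thresholds.z_gamma

    def rate(z_rep: float) -> float:
        return 2.0 * tail_probability(sigma, TailRegion((z_a, z_rep, z_g)))

    rho = abs(corr.rho_discovery_replication(method))
    lo = max(thresholds.z_beta, asymptotic_beta_star(design, thresholds, method, corr))
    hi = thresholds.z_beta + rho * z_a + 6.0
    # rate() is decreasing in z_rep; expand the bracket if the guaranteed
    # anchors fail numerically (degenerate thresholds).
    f_lo = rate(lo) - target
    tries = 0
    while f_lo < 0.0 and tries < 60:
        lo -= 0.5
        f_lo = rate(lo) - target
        tries += 1
    f_hi = rate(hi) - target
    tries = 0
    while f_hi > 0.0 and tries < 60:
        hi += 1.0
        f_hi = rate(hi) - target
        tries += 1
    if f_lo < 0.0 or f_hi > 0.0:
        raise RuntimeError(
            f"no bracket for the adjusted threshold of method {method}; "
            f"thresholds may be degenerate: {thresholds}"
        )
    z_star = brentq(lambda z: rate(z) - target, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(z_star)


def solve_adjusted(design: StudyDesign, thresholds: ThresholdSet) -> AdjustedThresholds:
    """Solve both adjusted thresholds (beta* and beta_perp) at once."""
    corr = derive_correlations(design)
    target = null_hit_rate(design, thresholds, "A", corr)
    z_star = _solve_adjusted_z(design, thresholds, "B", target, corr)
    z_perp = _solve_adjusted_z(design, thresholds, "C", target, corr)
    beta_star = p_from_z(z_star)
    beta_perp = p_from_z(z_perp)
    res_b = abs(
        null_hit_rate(design, ThresholdSet(thresholds.alpha, beta_star, thresholds.gamma), "B", corr)
        - target
    )
    res_c = abs(
        null_hit_rate(design, ThresholdSet(thresholds.alpha, beta_perp, thresholds.gamma), "C", corr)
        - target
    )
    return AdjustedThresholds(
        beta_star=beta_star,
        beta_perp=beta_perp,
        p0=target,
        residual=max(res_b, res_c),
    )


def solve_beta_star(design: StudyDesign, thresholds: ThresholdSet) -> AdjustedThresholds:
    """Solve the method-B replication threshold beta* conserving P0."""
    return solve_adjusted(design, thresholds)


def solve_beta_perp(design: StudyDesign, thresholds: ThresholdSet) -> AdjustedThresholds:
    """Solve the method-C replication threshold beta_perp conserving P0."""
    return solve_adjusted(design, thresholds)


def _two_sided_pair_rate(z_a: float, z_b: float, rho: float) -> float:
    """Pr(|Z1| > z_a, |Z2| > z_b) for standard bivariate normal, corr rho."""
    from .mvn_engine import _bvn_upper  # stable internal helper

    return float(2.0 * (_bvn_upper(z_a, z_b, rho) + _bvn_upper(z_a, z_b, -rho)))


def solve_gamma_one(
    design: StudyDesign,
    thresholds: ThresholdSet,
    convention: str = "directional",
) -> AdjustedThresholds:
    """Adjusted thresholds when no meta-analytic threshold is used (gamma = 1).

    ``directional`` (the package default everywhere) solves the usual
    three-statistic conservation with ``z_gamma = 0``, keeping the
    same-direction requirement.  ``nondirectional`` drops both the sign
    constraint and the meta statistic, solving
    ``Pr(|z_d| > z_alpha, |z_s| > z_{beta*}) = alpha * beta`` (and the
    method-C analogue) — the convention in which independent discovery and
    replication give exactly ``alpha * beta``.
    """
    if thresholds.gamma != 1.0:
        raise ValueError("solve_gamma_one requires gamma == 1")
    if convention == "directional":
        return solve_adjusted(design, thresholds)
    if convention != "nondirectional":
        raise ValueError(f"unknown convention {convention!r}")

    corr = derive_correlations(design)
    target = thresholds.alpha * thresholds.beta
    out = {}
    for method in ("B", "C"):
        rho = corr.rho_discovery_replication(method)
        z_a = thresholds.z_alpha

        def f(z_rep: float, rho=rho) -> float:
            return _two_sided_pair_rate(z_a, z_rep, rho) - target

        lo = thresholds.z_beta - 1e-9
        hi = thresholds.z_beta + abs(rho) * z_a + 6.0
        while f(hi) > 0.0:
            hi += 1.0
        out[method] = p_from_z(float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)))
    res = max(
        abs(_two_sided_pair_rate(thresholds.z_alpha, z_from_p(out["B"]), corr.rho_ds) - target),
        abs(_two_sided_pair_rate(thresholds.z_alpha, z_from_p(out["C"]), corr.rho_cs) - target),
    )
    return AdjustedThresholds(beta_star=out["B"], beta_perp=out["C"], p0=target, residual=res)
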