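"""Noncentrality (expected Z-score) calculus for effects and aberrance.

For a variant with population minor-allele frequencies ``mu0, mu1`` in the
discovery cohorts and ``mu0p, mu1p`` in the replication cohorts, each of the
five Z-statistics has expectation (to first order in the frequency
differences)

    zeta = sqrt(2 * n_eff) * (freq difference) / sqrt(mu_bar (1 - mu_bar))

where ``n_eff`` is the usual two-group effective size ``n_x n_y/(n_x+n_y)``
with pooled groups counted at their combined size, and ``mu_bar`` is a single
count-weighted mean frequency over all four cohorts (one consistent value is
used in every denominator, which keeps zeta ratios exactly equal to their
closed forms).  Counts are individuals; allele counts are ``2 n``.

Effects are specified either as explicit per-cohort frequencies, or as a
(log-odds-ratio, mean MAF) pair solved for ``(mu0, mu1)``; misascertainment
of replication controls (a fraction ``kappa`` actually drawn from the case
population) replaces ``mu0p`` with ``(1-kappa) mu0 + kappa mu1``.  Aberrance
(systematic frequency offsets in chosen cohorts, i.e. confounding rather
than sampling noise) is expressed on the frequency scale through the same
linear map, plus a direct zeta-scale entry point for limit studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .correlations import StudyDesign

__all__ = [
    "FrequencySpec",
    "NoncentralityVector",
    "freqs_from_or",
    "apply_misascertainment",
    "noncentralities",
    "aberrance_pattern",
    "zeta_coefficients",
    "scenario_zeta",
]

COHORTS = ("C0", "C1", "C0p", "C1p")


@dataclass(frozen=True)
class FrequencySpec:
    """Population minor-allele frequencies of the four cohorts."""

    mu0: float
    mu1: float
    mu0p: float
    mu1p: float

    def __post_init__(self) -> None:
        for name in ("mu0", "mu1", "mu0p", "mu1p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")

    def as_array(self) -> np.ndarray:
        """Frequencies in cohort order (C0, C1, C0p, C1p)."""
        return np.array([self.mu0, self.mu1, self.mu0p, self.mu1p])

    def mu_bar(self, design: StudyDesign) -> float:
        """Count-weighted mean frequency over all four cohorts."""
        w = np.array([design.n0, design.n1, design.n0p, design.n1p], dtype=float)
        return float(np.dot(w, self.as_array()) / w.sum())


@dataclass(frozen=True)
class NoncentralityVector:
    """Expected Z-scores (zeta_d, zeta_r, zeta_s, zeta_c, zeta_m)."""

    zeta_d: float
    zeta_r: float
    zeta_s: float
    zeta_c: float
    zeta_m: float

    def for_method(self, method: str) -> tuple[float, float, float]:
        """The (discovery, replication, meta) triple entering a method's test."""
        if method == "A":
            return (self.zeta_d, self.zeta_r, self.zeta_m)
        if method == "B":
            return (self.zeta_d, self.zeta_s, self.zeta_m)
        if method == "C":
            return (self.zeta_c, self.zeta_s, self.zeta_m)
        raise ValueError(f"method must be 'A', 'B' or 'C', got {method!r}")


def freqs_from_or(log_or: float, mean_maf: float, design: StudyDesign) -> FrequencySpec:
    """Solve (mu0, mu1) from a log-odds ratio and discovery-weighted mean MAF.

    Constraints: ``log(mu1 (1-mu0) / (mu0 (1-mu1))) = log_or`` and
    ``(n0 mu0 + n1 mu1)/(n0+n1) = mean_maf``; the replication cohorts inherit
    ``mu0p = mu0``, ``mu1p = mu1`` (a true association before any
    misascertainment).
    """
    if not 0.0 < mean_maf < 1.0:
        raise ValueError(f"mean_maf must be in (0, 1), got {mean_maf}")
    n0, n1 = design.n0, design.n1
    odds = np.exp(log_or)

    def mu1_of(mu0: float) -> float:
        o = odds * mu0 / (1.0 - mu0)
        return o / (1.0 + o)

    def constraint(mu0: float) -> float:
        return (n0 * mu0 + n1 * mu1_of(mu0)) / (n0 + n1) - mean_maf

    eps = 1e-14
    lo, hi = eps, 1.0 - eps
    if constraint(lo) > 0.0 or constraint(hi) < 0.0:
        raise ValueError(
            f"no frequencies in (0,1) satisfy log_or={log_or}, mean_maf={mean_maf}"
        )
    mu0 = float(brentq(constraint, lo, hi, xtol=1e-15, rtol=8.9e-16))
    mu1 = float(mu1_of(mu0))
    mu0 = min(max(mu0, eps), 1 - eps)
    mu1 = min(max(mu1, eps), 1 - eps)
    return FrequencySpec(mu0=mu0, mu1=mu1, mu0p=mu0, mu1p=mu1)


def apply_misascertainment(spec: FrequencySpec, kappa: float) -> FrequencySpec:
    """Contaminate replication controls with a fraction kappa of cases.

    Replaces ``mu0p`` with ``(1-kappa) mu0 + kappa mu1``; other frequencies
    are unchanged.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    return replace(spec, mu0p=(1.0 - kappa) * spec.mu0 + kappa * spec.mu1)


def _scales(design: StudyDesign, mu_bar: float) -> np.ndarray:
    """sqrt(2 n_eff / (mu_bar (1 - mu_bar))) per statistic (d, r, s, c, m)."""
    if not 0.0 < mu_bar < 1.0:
        raise ValueError("mu_bar outside (0, 1); frequencies too extreme")
    n0, n1, n0p, n1p = design.n0, design.n1, design.n0p, design.n1p
    N, M = n0 + n0p, n1 + n1p
    v = mu_bar * (1.0 - mu_bar)
    n_eff = np.array(
        [
            n0 * n1 / (n0 + n1),
            n0p * n1p / (n0p + n1p),
            N * n1p / (N + n1p),
            N * n1 / (N + n1),
            N * M / (N + M),
        ]
    )
    return np.sqrt(2.0 * n_eff / v)


def _diff_matrix(design: StudyDesign) -> np.ndarray:
    """Linear map (mu0, mu1, mu0p, mu1p) -> case-minus-control differences.

    Rows in statistic order (d, r, s, c, m); pooled cohorts enter as
    count-weighted means.
    """
    n0, n1, n0p, n1p = map(float, (design.n0, design.n1, design.n0p, design.n1p))
    N, M = n0 + n0p, n1 + n1p
    return np.array(
        [
            [-1.0, 1.0, 0.0, 0.0],                      # d: mu1 - mu0
            [0.0, 0.0, -1.0, 1.0],                      # r: mu1p - mu0p
            [-n0 / N, 0.0, -n0p / N, 1.0],              # s: mu1p - pooled ctrl
            [-n0 / N, 1.0, -n0p / N, 0.0],              # c: mu1 - pooled ctrl
            [-n0 / N, n1 / M, -n0p / N, n1p / M],       # m: pooled case - ctrl
        ]
    )


def noncentralities(design: StudyDesign, spec: FrequencySpec) -> NoncentralityVector:
    """Expected Z-scores of all five statistics for a frequency specification."""
    mu_bar = spec.mu_bar(design)
    diffs = _diff_matrix(design) @ spec.as_array()
    z = _scales(design, mu_bar) * diffs
    return NoncentralityVector(*map(float, z))


def aberrance_pattern(
    cohorts,
    magnitudes,
    base: FrequencySpec,
) -> FrequencySpec:
    """Offset the named cohorts' frequencies (systematic aberrance).

    ``cohorts`` is an iterable drawn from {"C0", "C1", "C0p", "C1p"};
    ``magnitudes`` is a matching iterable of frequency offsets (or a single
    float applied to every named cohort).
    """
    cohorts = list(cohorts)
    if np.isscalar(magnitudes):
        magnitudes = [float(magnitudes)] * len(cohorts)
    else:
        magnitudes = [float(m) for m in magnitudes]
    if len(cohorts) != len(magnitudes):
        raise ValueError("cohorts and magnitudes must have equal length")
    vals = dict(zip(("C0", "C1", "C0p", "C1p"), base.as_array()))
    for cohort, mag in zip(cohorts, magnitudes):
        if cohort not in vals:
            raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
        vals[cohort] += mag
        if not 0.0 < vals[cohort] < 1.0:
            raise ValueError(
                f"aberrance pushes {cohort} frequency to {vals[cohort]:.4g}, outside (0, 1)"
            )
    return FrequencySpec(vals["C0"], vals["C1"], vals["C0p"], vals["C1p"])


def zeta_coefficients(design: StudyDesign, cohort: str, mu_bar: float = 0.5) -> NoncentralityVector:
    """d(zeta)/d(frequency offset) for a unit aberrance in one cohort.

    Evaluated at a fixed ``mu_bar`` (the linearisation point); the ratios of
    the coefficients are independent of ``mu_bar``.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; expected one of {COHORTS}")
    e = np.zeros(4)
    e[COHORTS.index(cohort)] = 1.0
    z = _scales(design, mu_bar) * (_diff_matrix(design) @ e)
    return NoncentralityVector(*map(float, z))


def scenario_zeta(
    design: StudyDesign,
    cohort: str,
    reference: float,
    mu_bar: float = 0.5,
) -> NoncentralityVector:
    """Zeta vector for single-cohort aberrance, parameterised on the zeta scale.

    The vector is the unit-aberrance pattern of ``cohort`` rescaled so that
    its natural reference coordinate equals ``reference``: ``zeta_d`` for
    aberrance in a discovery cohort (C0, C1) and ``zeta_r`` for a replication
    cohort (C0p, C1p).  Being linear, the pattern is exact at arbitrarily
    large ``reference`` (limit studies), unlike a frequency offset bounded by
    (0, 1).
    """
    coef = zeta_coefficients(design, cohort, mu_bar)
    ref_coef = coef.zeta_d if cohort in ("C0", "C1") else coef.zeta_r
    if ref_coef == 0.0:
        raise ValueError(f"cohort {cohort} does not move the reference statistic")
    scale = reference / ref_coef
    return NoncentralityVector(
        zeta_d=coef.zeta_d * scale,
        zeta_r=coef.zeta_r * scale,
        zeta_s=coef.zeta_s * scale,
        zeta_c=coef.zeta_c * scale,
        zeta_m=coef.zeta_m * scale,
    )
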