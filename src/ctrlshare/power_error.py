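"""Power curves, power-difference metrics and type-1 error profiles.

The probability that a method rejects the null for a variant with
noncentrality vector zeta is the sum of two shifted orthant integrals over
the method's null covariance — one per consistent sign pattern:

    Pr(reject) = Pr(Z > z_thresh - zeta) + Pr(Z > z_thresh + zeta)

with Z ~ N(0, Sigma_method) three-dimensional and the thresholds
(z_alpha, z_rep, z_gamma) where z_rep is z_beta / z_{beta*} / z_{beta_perp}
for methods A / B / C.  At zeta = 0 this is the conserved null hit rate P0;
as all components grow it tends to 1.

Power is a function Power_method(x) of the underlying log-odds ratio x at a
given mean MAF.  Two scalar summaries compare methods: the average power
difference (the integral of the difference over x, also reported as a mean
over the integration window) and the maximum power difference over x.  A
practical companion asks how many extra independent replication controls
method A would need to match method B.

Type-1 error profiles trace each method's false-positive rate along a
single-cohort aberrance pattern parameterised by its reference zeta
(zeta_d for discovery-cohort aberrance, zeta_r for replication-cohort), and
closed-form large-|zeta| bounds on R_B - R_A are provided for replication
cohort aberrance in the gamma = 1 regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import CorrelationStructure, StudyDesign, derive_correlations
from .effects import (
    FrequencySpec,
    NoncentralityVector,
    apply_misascertainment,
    freqs_from_or,
    noncentralities,
    scenario_zeta,
)
from .mvn_engine import TailRegion, tail_probability
from .thresholds import AdjustedThresholds, ThresholdSet, solve_adjusted, z_from_p

__all__ = [
    "PowerCurve",
    "ErrorProfile",
    "rejection_probability",
    "power_at_log_or",
    "power_curve",
    "average_power_difference",
    "max_power_difference",
    "controls_needed_for_parity",
    "type1_profile",
    "rb_ra_bound",
    "aberrance_k",
]


@dataclass(frozen=True)
class PowerCurve:
    """Per-method rejection probabilities along a log-odds-ratio grid."""

    log_or_grid: np.ndarray
    power_by_method: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ErrorProfile:
    """False-positive rates along a single-cohort aberrance zeta grid."""

    scenario: str
    zeta_grid: np.ndarray
    rates: dict  # method -> array of rates


def _replication_z(method: str, thresholds: ThresholdSet, adjusted: AdjustedThresholds | None) -> float:
    if method == "A":
        return thresholds.z_beta
    if adjusted is None:
        raise ValueError(f"method {method} requires solved adjusted thresholds")
    if method == "B":
        return z_from_p(adjusted.beta_star)
    if method == "C":
        return z_from_p(adjusted.beta_perp)
    raise ValueError(f"method must be 'A', 'B' or 'C', got {method!r}")


def rejection_probability(
    method: str,
    design: StudyDesign,
    thresholds: ThresholdSet,
    zeta: NoncentralityVector,
    adjusted: AdjustedThresholds | None = None,
    corr: CorrelationStructure | None = None,
) -> float:
    """Probability the method declares a hit, for a given noncentrality vector."""
    if corr is None:
        corr = derive_correlations(design)
    z_rep = _replication_z(method, thresholds, adjusted)
    bounds = (thresholds.z_alpha, z_rep, thresholds.z_gamma)
    shift = zeta.for_method(method)
    sigma = corr.sigma(method)
    plus = tail_probability(sigma, TailRegion(bounds, shift))
    minus = tail_probability(sigma, TailRegion(bounds, tuple(-s for s in shift)))
    return plus + minus


def _spec_at(design: StudyDesign, log_or: float, mean_maf: float, kappa: float) -> FrequencySpec:
    spec = freqs_from_or(log_or, mean_maf, design)
    if kappa:
        spec = apply_misascertainment(spec, kappa)
    return spec


def power_at_log_or(
    method: str,
    design: StudyDesign,
    thresholds: ThresholdSet,
    log_or: float,
    mean_maf: float,
    adjusted: AdjustedThresholds | None = None,
    corr: CorrelationStructure | None = None,
    kappa: float = 0.0,
    design_for_effect: StudyDesign | None = None,
) -> float:
    """Power at a single log-odds ratio (zero log-OR gives P0-level rates).

    ``design_for_effect`` lets the frequency spec be anchored to a reference
    design while power is evaluated on a modified one (used by the
    controls-for-parity search so the variant itself does not change).
    """
    if log_or == 0.0 and kappa == 0.0:
        zeta = NoncentralityVector(0.0, 0.0, 0.0, 0.0, 0.0)
    else:
        spec = _spec_at(design_for_effect or design, log_or, mean_maf, kappa)
        zeta = noncentralities(design, spec)
    return rejection_probability(method, design, thresholds, zeta, adjusted, corr)


def power_curve(
    methods,
    design: StudyDesign,
    thresholds: ThresholdSet,
    log_or_grid,
    mean_maf: float,
    adjusted: AdjustedThresholds | None = None,
    kappa: float = 0.0,
) -> PowerCurve:
    """Evaluate per-method power along a log-odds-ratio grid."""
    grid = np.asarray(log_or_grid, dtype=float)
    corr = derive_correlations(design)
    if adjusted is None and any(m in ("B", "C") for m in methods):
        adjusted = solve_adjusted(design, thresholds)
    powers = {
        m: np.array(
            [
                power_at_log_or(m, design, thresholds, x, mean_maf, adjusted, corr, kappa)
                for x in grid
            ]
        )
        for m in methods
    }
    return PowerCurve(log_or_grid=grid, power_by_method=powers)


def _grow_window(
    design: StudyDesign,
    thresholds: ThresholdSet,
    mean_maf: float,
    adjusted: AdjustedThresholds,
    kappa: float,
    methods=("A", "B"),
) -> float:
    """Symmetric window half-width L such that power ~ 1 at both ends."""
    corr = derive_correlations(design)
    L = 0.5
    for _ in range(20):
        ok = True
        for sign in (-1.0, 1.0):
            for m in methods:
                try:
                    p = power_at_log_or(m, design, thresholds, sign * L, mean_maf, adjusted, corr, kappa)
                except ValueError:
                    # mean MAF unreachable at this OR: frequencies have
                    # saturated, power is as extreme as it can get
                    continue
                if p < 1.0 - 1e-6:
                    ok = False
        if ok:
            return L
        L *= 1.4
    return L


def average_power_difference(
    method_x: str,
    method_y: str,
    design: StudyDesign,
    thresholds: ThresholdSet,
    mean_maf: float,
    adjusted: AdjustedThresholds | None = None,
    kappa: float = 0.0,
    n_grid: int = 241,
) -> dict:
    """Integral of Power_x - Power_y over log-odds ratio.

    Returns the raw integral (log-OR x probability units), the window used,
    and the windowed mean (raw / (2L)) as a percent-style summary.
    """
    if method_x == method_y:
        return {"integral": 0.0, "window": 0.0, "mean": 0.0}
    if adjusted is None:
        adjusted = solve_adjusted(design, thresholds)
    L = _grow_window(design, thresholds, mean_maf, adjusted, kappa, (method_x, method_y))
    corr = derive_correlations(design)
    xs = np.linspace(-L, L, n_grid)

    def diff(x: float) -> float:
        px = power_at_log_or(method_x, design, thresholds, x, mean_maf, adjusted, corr, kappa)
        py = power_at_log_or(method_y, design, thresholds, x, mean_maf, adjusted, corr, kappa)
        return px - py

    ys = np.array([diff(x) for x in xs])
    # Simpson integration on the fixed grid; the integrand is smooth and
    # tiny (< 1e-8) outside the window by construction.
    from scipy.integrate import simpson

    integral = float(simpson(ys, x=xs))
    return {"integral": integral, "window": 2.0 * L, "mean": integral / (2.0 * L)}


def max_power_difference(
    method_x: str,
    method_y: str,
    design: StudyDesign,
    thresholds: ThresholdSet,
    mean_maf: float,
    adjusted: AdjustedThresholds | None = None,
    kappa: float = 0.0,
) -> dict:
    """max over log-OR of Power_x - Power_y: coarse grid then golden-section."""
    if method_x == method_y:
        return {"max_difference": 0.0, "argmax_log_or": 0.0}
    if adjusted is None:
        adjusted = solve_adjusted(design, thresholds)
    corr = derive_correlations(design)
    L = _grow_window(design, thresholds, mean_maf, adjusted, kappa, (method_x, method_y))

    def diff(x: float) -> float:
        px = power_at_log_or(method_x, design, thresholds, x, mean_maf, adjusted, corr, kappa)
        py = power_at_log_or(method_y, design, thresholds, x, mean_maf, adjusted, corr, kappa)
        return px - py

    xs = np.linspace(-L, L, 401)
    ys = np.array([diff(x) for x in xs])
    i = int(np.argmax(ys))
    lo = xs[max(i - 1, 0)]
    hi = xs[min(i + 1, len(xs) - 1)]
    # Golden-section refinement of the bracketed maximum.
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = diff(c), diff(d)
    for _ in range(60):
        if b - a < 1e-7:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = diff(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = diff(d)
    x_star = (a + b) / 2.0
    return {"max_difference": float(diff(x_star)), "argmax_log_or": float(x_star)}


def controls_needed_for_parity(
    design: StudyDesign,
    thresholds: ThresholdSet,
    mean_maf: float,
    log_or: float,
    adjusted: AdjustedThresholds | None = None,
    kappa: float = 0.0,
    cap: int = 200_000,
) -> dict:
    """Extra independent replication controls for method A to match method B.

    Finds the smallest integer x such that method A run on
    ``(n0, n1, n0p + x, n1p)`` attains at least method B's power on the
    unmodified design at the stated effect.  The variant's frequency spec is
    anchored to the original design so only the test changes.  Monotone
    bisection; if parity is unreachable within ``cap`` the cap is reported.
    """
    if adjusted is None:
        adjusted = solve_adjusted(design, thresholds)
    target = power_at_log_or("B", design, thresholds, log_or, mean_maf, adjusted, kappa=kappa)

    def power_a(extra: int) -> float:
        mod = design.with_extra_replication_controls(extra)
        return power_at_log_or(
            "A", mod, thresholds, log_or, mean_maf, kappa=kappa, design_for_effect=design
        )

    if power_a(0) >= target:
        return {"extra_controls": 0, "power_b": target, "power_a": power_a(0), "capped": False}
    if power_a(cap) < target:
        return {"extra_controls": cap, "power_b": target, "power_a": power_a(cap), "capped": True}
    lo, hi = 0, cap  # power_a(lo) < target <= power_a(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_a(mid) >= target:
            hi = mid
        else:
            lo = mid
    return {"extra_controls": hi, "power_b": target, "power_a": power_a(hi), "capped": False}


def type1_profile(
    methods,
    design: StudyDesign,
    thresholds: ThresholdSet,
    scenario: str,
    zeta_grid,
    adjusted: AdjustedThresholds | None = None,
) -> ErrorProfile:
    """False-positive rate of each method along a single-cohort aberrance grid.

    ``scenario`` names the aberrant cohort ("C0", "C1", "C0p" or "C1p");
    the grid is on the scenario's reference zeta (zeta_d for discovery
    cohorts, zeta_r for replication cohorts).
    """
    if adjusted is None:
        adjusted = solve_adjusted(design, thresholds)
    corr = derive_correlations(design)
    grid = np.asarray(zeta_grid, dtype=float)
    rates: dict = {m: np.empty(grid.shape) for m in methods}
    for j, z in enumerate(grid):
        if z == 0.0:
            zeta = NoncentralityVector(0.0, 0.0, 0.0, 0.0, 0.0)
        else:
            zeta = scenario_zeta(design, scenario, float(z))
        for m in methods:
            rates[m][j] = rejection_probability(m, design, thresholds, zeta, adjusted, corr)
    return ErrorProfile(scenario=scenario, zeta_grid=grid, rates=rates)


def aberrance_k(design: StudyDesign, which: str) -> float:
    """Large-aberrance ratio zeta_s / zeta_r for replication-cohort aberrance.

    ``which="C1p"`` gives k = sqrt((n0+n0')(n0'+n1') / (n0'(n0+n0'+n1')));
    ``which="C0p"`` gives k' = sqrt(n0'(n0'+n1') / ((n0+n0')(n0+n0'+n1'))).
    Always k' < 1 < k.
    """
    n0, n0p, n1p = design.n0, design.n0p, design.n1p
    if which == "C1p":
        return float(np.sqrt((n0 + n0p) * (n0p + n1p) / (n0p * (n0 + n0p + n1p))))
    if which == "C0p":
        return float(np.sqrt(n0p * (n0p + n1p) / ((n0 + n0p) * (n0 + n0p + n1p))))
    raise ValueError(f"which must be 'C1p' or 'C0p', got {which!r}")


def rb_ra_bound(design: StudyDesign, thresholds: ThresholdSet, which: str) -> float:
    """Approximate bound on |R_B - R_A| under replication-cohort aberrance.

    Valid in the gamma = 1 regime:  alpha/(2 sqrt(2 pi)) *
    (k / sqrt(1 - rho_ds^2) - 1) * z_beta, with k for aberrance in C1' and
    k' for aberrance in C0'.  Much smaller than alpha/2 at typical
    genome-wide thresholds.
    """
    corr = derive_correlations(design)
    k = aberrance_k(design, which)
    rho = corr.rho_ds
    return float(
        thresholds.alpha
        / (2.0 * np.sqrt(2.0 * np.pi))
        * (k / np.sqrt(1.0 - rho * rho) - 1.0)
        * thresholds.z_beta
    )
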