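"""Deterministic tail probabilities of 2- and 3-dimensional Gaussians.

Every probability in the package — the baseline null hit rate, the adjusted
thresholds, power, and aberrance error rates — is an upper-tail (shifted
orthant) probability

    Pr(Z_1 > l_1, Z_2 > l_2, Z_3 > l_3),   Z ~ N(0, Sigma)

for a 2x2 or 3x3 correlation matrix Sigma, where the bounds already include
any noncentrality shift (``l_i = z_threshold - zeta_i``).  The relevant
probabilities range from ~0.5 down to ~1e-18 (joint genome-wide tails), so
*relative* accuracy matters and Monte-Carlo / randomised quasi-Monte-Carlo
integrators are unusable as the kernel under a root-finder.

The kernel is therefore fully deterministic nested Gauss-Legendre quadrature:

* full-rank 3-D: outer integral over Z_1, conditional bivariate upper tail
  inside, itself a 1-D integral of ``phi * Phi-bar``;
* rank-2 ("singular") 3-D: the third coordinate is an exact linear
  combination ``Z_3 = a Z_1 + b Z_2``, so the event is a polygonal region of
  the plane; integrated over Z_1 with the half-plane constraint clipped
  against the rectangle (the crossing point becomes a panel break so the
  integrand stays smooth per panel);
* bounds of -inf drop their dimension.

Integrands are analytic and Gaussian-decaying; composite Gauss-Legendre with
panel width <= ~1.3 gives ~1e-13 relative accuracy.  Lower limits are clipped
at -CLIP (absolute error below Phi(-CLIP) ~ 1e-18, which only activates when
the probability itself is large), upper limits truncated 13 units past the
largest active bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .correlations import reduce_singular

__all__ = ["TailRegion", "tail_probability"]

CLIP = 8.6          # lower integration clip; Phi(-8.6) ~ 3.9e-18
TAIL_SPAN = 13.0    # integrate this far past a positive lower bound
_N_PANELS = 22
_N_NODES = 16

_GL_X, _GL_W = np.polynomial.legendre.leggauss(_N_NODES)
_GL_X = (_GL_X + 1.0) / 2.0   # nodes on [0, 1]
_GL_W = _GL_W / 2.0


@dataclass(frozen=True)
class TailRegion:
    """Lower bounds and noncentrality shifts defining a shifted orthant.

    The probability evaluated is ``Pr(Z_i > lower_bounds_i - shift_i)``;
    a lower bound of ``-inf`` removes that coordinate's constraint.
    """

    lower_bounds: tuple
    shift: tuple | None = None

    def effective_bounds(self) -> np.ndarray:
        lb = np.asarray(self.lower_bounds, dtype=float)
        if self.shift is None:
            return lb
        sh = np.asarray(self.shift, dtype=float)
        if lb.shape != sh.shape:
            raise ValueError("lower_bounds and shift must have equal length")
        return lb - sh


def _panels(lo: float, hi: float, breaks=()) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre nodes/weights on [lo, hi] with forced breaks."""
    edges = [lo, hi]
    for b in breaks:
        if lo < b < hi:
            edges.append(b)
    edges = np.array(sorted(edges))
    nodes, weights = [], []
    for left, right in zip(edges[:-1], edges[1:]):
        width = right - left
        k = max(1, int(np.ceil(width / ((hi - lo) / _N_PANELS))))
        sub = np.linspace(left, right, k + 1)
        for a, b in zip(sub[:-1], sub[1:]):
            nodes.append(a + (b - a) * _GL_X)
            weights.append((b - a) * _GL_W)
    return np.concatenate(nodes), np.concatenate(weights)


def _phi(x: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


def _sf(x) -> np.ndarray:
    return ndtr(-np.asarray(x, dtype=float))


def _range(lo_bound: float) -> tuple[float, float]:
    lo = max(lo_bound, -CLIP)
    hi = max(lo_bound + TAIL_SPAN, CLIP)
    return lo, hi


def _bvn_upper(a, b, r: float):
    """Pr(X > a, Y > b) for standard bivariate normal with correlation r.

    Vectorised over broadcastable arrays ``a``, ``b``; ``r`` is scalar.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if abs(r) < 1e-14:
        return _sf(a) * _sf(b)
    if r >= 1.0 - 1e-14:
        return _sf(np.maximum(a, b))
    if r <= -1.0 + 1e-14:
        return np.maximum(0.0, ndtr(-b) - ndtr(a))
    if abs(r) > 0.925:
        return _bvn_upper_high_corr(a, b, r)

    s = np.sqrt(1.0 - r * r)
    scalar = a.ndim == 0 and b.ndim == 0
    a2, b2 = np.atleast_1d(a), np.atleast_1d(b)
    a2, b2 = np.broadcast_arrays(a2, b2)
    out = np.empty(a2.shape, dtype=float)
    # Integrate over the X coordinate; per-element limits, shared unit rule.
    lo = np.maximum(a2, -CLIP)
    hi = np.maximum(a2 + TAIL_SPAN, CLIP)
    t, w = _unit_rule()
    u = lo[..., None] + (hi - lo)[..., None] * t          # (..., n)
    integrand = _phi(u) * _sf((b2[..., None] - r * u) / s)
    out = np.einsum("...n,n->...", integrand, w) * (hi - lo)
    return float(out[(0,) * out.ndim]) if scalar else out.reshape(np.broadcast(a, b).shape)


_PLACKETT_X, _PLACKETT_W = np.polynomial.legendre.leggauss(48)


def _bvn_upper_high_corr(a, b, r: float):
    """Upper bivariate tail for |r| near 1 via Plackett's identity.

    dP/dr equals the bivariate density at (a, b), so P(r) is the value at the
    perfectly (anti)correlated limit plus an integral of the density over the
    correlation parameter.  Substituting t = sin(theta) removes the
    1/sqrt(1-t^2) endpoint singularity, leaving an analytic integrand that a
    single Gauss-Legendre rule integrates to machine precision — accurate
    where the conditional-CDF quadrature would face an arbitrarily steep step.
    """
    a2, b2 = np.broadcast_arrays(np.atleast_1d(a), np.atleast_1d(b))
    if r > 0:
        limit = _sf(np.maximum(a2, b2))
        th_lo, th_hi = np.arcsin(r), np.pi / 2.0
        sign = -1.0
    else:
        limit = np.maximum(0.0, ndtr(-b2) - ndtr(a2))
        th_lo, th_hi = -np.pi / 2.0, np.arcsin(r)
        sign = 1.0
    theta = th_lo + (th_hi - th_lo) * (_PLACKETT_X + 1.0) / 2.0
    w = _PLACKETT_W * (th_hi - th_lo) / 2.0
    sin_t = np.sin(theta)
    cos2 = np.cos(theta) ** 2
    expo = -(
        a2[..., None] ** 2 - 2.0 * a2[..., None] * b2[..., None] * sin_t + b2[..., None] ** 2
    ) / (2.0 * cos2)
    integral = np.einsum("...n,n->...", np.exp(expo), w) / (2.0 * np.pi)
    out = limit + sign * integral
    out = np.clip(out, 0.0, 1.0)
    shape = np.broadcast(a, b).shape
    return float(out.reshape(-1)[0]) if shape == () else out.reshape(shape)


_UNIT_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _unit_rule(n_panels: int = _N_PANELS) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre rule on [0, 1]."""
    if n_panels not in _UNIT_CACHE:
        edges = np.linspace(0.0, 1.0, n_panels + 1)
        nodes = (edges[:-1, None] + np.diff(edges)[:, None] * _GL_X).ravel()
        weights = (np.diff(edges)[:, None] * _GL_W).ravel()
        _UNIT_CACHE[n_panels] = (nodes, weights)
    return _UNIT_CACHE[n_panels]


def _validate_corr(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1] or sigma.shape[0] not in (2, 3):
        raise ValueError(f"sigma must be 2x2 or 3x3, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0, atol=1e-10):
        raise ValueError("sigma must have unit diagonal")
    if np.linalg.eigvalsh(sigma)[0] < -1e-8:
        raise ValueError("sigma is not positive semi-definite")
    return sigma


def _tail3_fullrank(sigma: np.ndarray, l: np.ndarray) -> float:
    r12, r13, r23 = sigma[0, 1], sigma[0, 2], sigma[1, 2]
    s2 = np.sqrt(1.0 - r12 * r12)
    s3 = np.sqrt(1.0 - r13 * r13)
    rc = (r23 - r12 * r13) / (s2 * s3)   # conditional correlation given Z1
    lo, hi = _range(l[0])
    # where the two conditional bounds cross the integrand loses smoothness
    # as rc -> 1 (inner tail ~ Phi-bar of the max); make it a panel edge
    breaks = []
    denom = r12 * s3 - r13 * s2
    if abs(denom) > 1e-14:
        breaks.append((l[1] * s3 - l[2] * s2) / denom)
    x, w = _panels(lo, hi, breaks=breaks)
    a2 = (l[1] - r12 * x) / s2
    a3 = (l[2] - r13 * x) / s3
    vals = _phi(x) * _bvn_upper(a2, a3, rc)
    return float(np.dot(vals, w))


def _tail_rank2(rho12: float, a: float, b: float, l: np.ndarray) -> float:
    """Pr(Z1 > l1, Z2 > l2, a*Z1 + b*Z2 > l3), (Z1,Z2) std bivariate corr rho12."""
    l1, l2, l3 = l
    if abs(b) < 1e-12:
        # Constraint involves Z1 only.
        if abs(a) < 1e-12:
            if l3 >= 0:
                return 0.0
            return float(_bvn_upper(l1, l2, rho12))
        if a > 0:
            l1 = max(l1, l3 / a)
            return float(_bvn_upper(l1, l2, rho12))
        # a < 0: Z1 < l3/a upper bound -> Pr(l1 < Z1 < l3/a, Z2 > l2)
        up = l3 / a
        if up <= l1:
            return 0.0
        return float(_bvn_upper(l1, l2, rho12) - _bvn_upper(up, l2, rho12))

    s = np.sqrt(max(1.0 - rho12 * rho12, 0.0))
    if s < 1e-12:
        raise ValueError("degenerate bivariate margin in rank-2 reduction")
    lo, hi = _range(l1 if np.isfinite(l1) else -np.inf)
    if not np.isfinite(l1):
        lo, hi = -CLIP, CLIP
    # Kink where the half-plane constraint crosses the Z2 bound.
    breaks = []
    if abs(a) > 1e-12:
        breaks.append((l3 - b * l2) / a)
    x, w = _panels(lo, hi, breaks=breaks)
    cond_mean = rho12 * x
    if b > 0:
        low2 = np.maximum(l2, (l3 - a * x) / b)
        probs = _sf((low2 - cond_mean) / s)
    else:
        up2 = (l3 - a * x) / b
        probs = np.maximum(0.0, ndtr((up2 - cond_mean) / s) - ndtr((l2 - cond_mean) / s))
    vals = _phi(x) * probs
    return float(np.dot(vals, w))


def tail_probability(sigma: np.ndarray, region: TailRegion) -> float:
    """Pr(Z_i > lower_bound_i - shift_i for all i), Z ~ N(0, sigma).

    ``sigma`` may be 2x2, full-rank 3x3, or rank-2 3x3 (handled through the
    exact linear dependence of the third coordinate on the first two).
    Bounds of ``-inf`` drop their dimension.  Deterministic; no Monte-Carlo.
    """
    sigma = _validate_corr(sigma)
    l = region.effective_bounds()
    if np.any(np.isnan(l)):
        raise ValueError("NaN bound in tail region")
    if l.shape[0] != sigma.shape[0]:
        raise ValueError("region dimension does not match sigma")

    active = np.isfinite(l)
    if not np.any(active):
        return 1.0

    if sigma.shape[0] == 2:
        if active.sum() == 1:
            return float(_sf(l[active][0]))
        return float(_bvn_upper(l[0], l[1], sigma[0, 1]))

    # 3-D case: drop -inf dimensions first.
    if active.sum() == 1:
        return float(_sf(l[active][0]))
    if active.sum() == 2:
        idx = np.flatnonzero(active)
        # The rank-2 linear dependence, if any, only ties all three coords;
        # with one constraint dropped the remaining pair is a plain bivariate
        # (possibly perfectly correlated) tail.
        return float(_bvn_upper(l[idx[0]], l[idx[1]], sigma[idx[0], idx[1]]))

    coeffs = reduce_singular(sigma)
    if coeffs is None:
        return _tail3_fullrank(sigma, l)
    a, b = coeffs
    return _tail_rank2(sigma[0, 1], a, b, l)
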