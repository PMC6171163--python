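"""Null correlation structure of the five association Z-statistics.

A two-stage case-control study has four cohorts: discovery controls ``C0``
(size ``n0``) and cases ``C1`` (``n1``), and replication controls ``C0'``
(``n0p``) and cases ``C1'`` (``n1p``).  Five signed allelic Z-statistics are
in play:

====  ==============================================
z_d   discovery:      C1    vs C0
z_r   replication:    C1'   vs C0'
z_s   shared-control: C1'   vs C0 ∪ C0'
z_c   pooled-control: C1    vs C0 ∪ C0'
z_m   meta-analytic:  C1∪C1' vs C0 ∪ C0'
====  ==============================================

Under the global null (all four population minor-allele frequencies equal)
the statistics are jointly Gaussian with unit variance, and every pair that
shares a cohort is correlated.  Each Z is the difference of two cohort
allele-frequency estimators divided by its null standard error; with
``var(m_i) = mu(1-mu)/(2 n_i)`` and pooled frequencies taken as count-weighted
means, the correlation of two Z's is the covariance contributed by the shared
cohorts over the product of the standard errors.  The common ``mu(1-mu)``
factor cancels, so correlations are functions of the four cohort sizes only.

The per-method 3x3 covariance (= correlation) matrices are

    Sigma_A = corr(z_d, z_r, z_m)   (independent controls)
    Sigma_B = corr(z_d, z_s, z_m)   (shared replication controls)
    Sigma_C = corr(z_c, z_s, z_m)   (controls pooled at both stages)

``Sigma_C`` is singular for every design (z_m is an exact linear combination
of z_c and z_s); ``Sigma_A`` and ``Sigma_B`` are singular exactly when
``n0/n1 == n0p/n1p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StudyDesign",
    "CorrelationStructure",
    "derive_correlations",
    "reduce_singular",
]

# Relative eigenvalue below which a correlation matrix is treated as singular,
# and condition number above which the rank-2 integration path is preferred.
SINGULARITY_EIGVAL_RTOL = 1e-9
NEAR_SINGULAR_COND = 1e8

# Eigenvalues below -NEGATIVE_EIGVAL_TOL mark an invalid correlation matrix.
NEGATIVE_EIGVAL_TOL = 1e-8


@dataclass(frozen=True)
class StudyDesign:
    """Cohort sizes (individuals) of a two-stage case-control study.

    Attributes
    ----------
    n0, n1 : int
        Discovery controls and cases.
    n0p, n1p : int
        Replication controls and cases.

    Allele-level computations use ``2 n`` chromosomes per cohort (diploid,
    Hardy-Weinberg).
    """

    n0: int
    n1: int
    n0p: int
    n1p: int

    def __post_init__(self) -> None:
        for name in ("n0", "n1", "n0p", "n1p"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n0p + self.n1p

    def with_extra_replication_controls(self, extra: int) -> "StudyDesign":
        return StudyDesign(self.n0, self.n1, self.n0p + extra, self.n1p)


@dataclass(frozen=True)
class CorrelationStructure:
    """Pairwise null correlations and the per-method covariance matrices."""

    rho_dr: float
    rho_dm: float
    rho_rm: float
    rho_ds: float
    rho_sm: float
    rho_cs: float
    rho_cm: float
    sigma_A: np.ndarray = field(repr=False)
    sigma_B: np.ndarray = field(repr=False)
    sigma_C: np.ndarray = field(repr=False)

    def sigma(self, method: str) -> np.ndarray:
        try:
            return {"A": self.sigma_A, "B": self.sigma_B, "C": self.sigma_C}[method]
        except KeyError:
            raise ValueError(f"method must be 'A', 'B' or 'C', got {method!r}") from None

    def rho_discovery_replication(self, method: str) -> float:
        """Correlation between the method's discovery and replication Z."""
        return {"A": self.rho_dr, "B": self.rho_ds, "C": self.rho_cs}[method]


def _corr_matrix(r12: float, r13: float, r23: float) -> np.ndarray:
    return np.array(
        [[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]], dtype=float
    )


def derive_correlations(design: StudyDesign) -> CorrelationStructure:
    """Compute the seven pairwise null correlations from the cohort sizes.

    Each Z-statistic is modelled as a difference of cohort allele-frequency
    estimators over its null standard error.  Writing ``u_X = 1/n_X`` for the
    (relative) variance of a cohort estimator and ``u_00 = 1/(n0+n0p)``,
    ``u_11 = 1/(n1+n1p)`` for the pooled estimators, shared-cohort covariances
    give closed forms, e.g.::

        rho_ds = u_00 / sqrt((u_1 + u_0) (u_1p + u_00))

    which coincides with the classical published closed form
    ``sqrt(n0 n1 n1p / ((n0+n0p)(n0+n1)(n0+n0p+n1p)))``.

    All correlations are invariant under scaling the four counts by a common
    factor, and ``rho_dr == 0`` exactly (disjoint cohorts).
    """
    d = design
    u0, u1 = 1.0 / d.n0, 1.0 / d.n1
    u0p, u1p = 1.0 / d.n0p, 1.0 / d.n1p
    u00 = 1.0 / (d.n0 + d.n0p)  # pooled controls C0 ∪ C0'
    u11 = 1.0 / (d.n1 + d.n1p)  # pooled cases    C1 ∪ C1'

    sd_d = np.sqrt(u1 + u0)
    sd_r = np.sqrt(u1p + u0p)
    sd_s = np.sqrt(u1p + u00)
    sd_c = np.sqrt(u1 + u00)
    sd_m = np.sqrt(u11 + u00)

    # Covariances from shared cohorts.  cov(pooled, member) = var(pooled).
    rho_dr = 0.0
    rho_dm = (u11 + u00) / (sd_d * sd_m)  # = sd_m / sd_d
    rho_rm = (u11 + u00) / (sd_r * sd_m)
    rho_ds = u00 / (sd_d * sd_s)
    rho_sm = (u11 + u00) / (sd_s * sd_m)
    rho_cs = u00 / (sd_c * sd_s)
    rho_cm = (u11 + u00) / (sd_c * sd_m)

    return CorrelationStructure(
        rho_dr=rho_dr,
        rho_dm=rho_dm,
        rho_rm=rho_rm,
        rho_ds=rho_ds,
        rho_sm=rho_sm,
        rho_cs=rho_cs,
        rho_cm=rho_cm,
        sigma_A=_corr_matrix(rho_dr, rho_dm, rho_rm),
        sigma_B=_corr_matrix(rho_ds, rho_dm, rho_sm),
        sigma_C=_corr_matrix(rho_cs, rho_cm, rho_sm),
    )


def reduce_singular(sigma: np.ndarray):
    """Detect (near-)singularity of a 3x3 correlation matrix.

    Returns ``None`` for a full-rank matrix, otherwise the pair ``(a, b)``
    such that ``z3 = a*z1 + b*z2`` holds exactly under the null.  The
    coefficients are the regression of the third coordinate on the first two::

        a = (rho13 - rho12*rho23) / (1 - rho12**2)
        b = (rho23 - rho12*rho13) / (1 - rho12**2)

    which for the always-singular method-C matrix reproduces the classical
    reduction of the 3-D integral to two dimensions.

    Raises
    ------
    ValueError
        If ``sigma`` is not a valid (symmetric, unit-diagonal, PSD)
        correlation matrix, or the first two coordinates are themselves
        colinear so no unique reduction exists.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise ValueError("sigma must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0, atol=1e-12):
        raise ValueError("sigma must have unit diagonal")
    eigvals = np.linalg.eigvalsh(sigma)
    if eigvals[0] < -NEGATIVE_EIGVAL_TOL:
        raise ValueError(f"sigma is not PSD (min eigenvalue {eigvals[0]:.3g})")

    singular = eigvals[0] < SINGULARITY_EIGVAL_RTOL * eigvals[-1]
    near_singular = eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > NEAR_SINGULAR_COND
    if not (singular or near_singular):
        return None

    r12, r13, r23 = sigma[0, 1], sigma[0, 2], sigma[1, 2]
    denom = 1.0 - r12 * r12
    if denom < 1e-12:
        raise ValueError("first two coordinates are colinear; cannot reduce")
    a = (r13 - r12 * r23) / denom
    b = (r23 - r12 * r13) / denom
    return (a, b)
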