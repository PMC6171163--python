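"""Monte-Carlo generator and empirical oracle for the two-stage design.

Each replicate draws one variant's minor-allele counts independently for the
four cohorts, ``count_X ~ Binomial(2 n_X, mu_X)`` (diploid, Hardy-Weinberg,
allele-level sampling) — the minimal model whose estimator variances
``mu(1-mu)/(2n)`` match the analytic calculus.  From the counts, the five
signed Z-statistics are computed as score-type two-proportion tests
(difference of allele-frequency estimates over the pooled-frequency null
standard error; asymptotically equivalent to the Wald log-odds-ratio form
and stable at extreme counts):

    d: C1 vs C0;  r: C1' vs C0';  s: C1' vs C0∪C0';
    c: C1 vs C0∪C0';  m: C1∪C1' vs C0∪C0'.

Replicates in which a compared pair has pooled frequency exactly 0 or 1 are
flagged and excluded (their Z is undefined); the exclusion count is kept.

On top of the per-replicate statistics sit empirical estimators of every
analytic quantity in the package: null correlations, noncentralities, hit
rates / power / error rates under each method's full hit rule (thresholds
plus sign agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlations import StudyDesign
from .effects import FrequencySpec
from .thresholds import AdjustedThresholds, ThresholdSet, z_from_p

__all__ = [
    "SimulatedStudy",
    "simulate_counts",
    "statistics_from_counts",
    "empirical_correlations",
    "empirical_zeta",
    "empirical_rates",
]

STATS = ("d", "r", "s", "c", "m")


@dataclass(frozen=True)
class SimulatedStudy:
    """Per-replicate minor-allele counts with their generating parameters."""

    design: StudyDesign
    spec: FrequencySpec
    seed: int
    counts: np.ndarray = field(repr=False)  # (replicates, 4) in cohort order

    @property
    def replicates(self) -> int:
        return self.counts.shape[0]


def simulate_counts(
    design: StudyDesign, spec: FrequencySpec, replicates: int, seed: int
) -> SimulatedStudy:
    """Draw per-cohort binomial allele counts for ``replicates`` variants."""
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    sizes = 2 * np.array([design.n0, design.n1, design.n0p, design.n1p])
    mus = spec.as_array()
    counts = rng.binomial(sizes[None, :], mus[None, :], size=(replicates, 4))
    return SimulatedStudy(design=design, spec=spec, seed=seed, counts=counts)


def _two_prop_z(c_case, n_case, c_ctrl, n_ctrl):
    """Score-type two-proportion Z with pooled null SE; n's are allele counts."""
    m_case = c_case / n_case
    m_ctrl = c_ctrl / n_ctrl
    pooled = (c_case + c_ctrl) / (n_case + n_ctrl)
    var = pooled * (1.0 - pooled) * (1.0 / n_case + 1.0 / n_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m_case - m_ctrl) / np.sqrt(var)
    return z


def statistics_from_counts(study: SimulatedStudy) -> dict:
    """Per-replicate Z-statistics (z_d, z_r, z_s, z_c, z_m).

    Returns a dict with a ``(kept, 5)`` array ``z`` (columns in STATS order),
    the boolean keep mask over the original replicates, and the number
    excluded as degenerate (some compared pair entirely 0 or entirely 2n).
    """
    d = study.design
    n = 2.0 * np.array([d.n0, d.n1, d.n0p, d.n1p], dtype=float)
    c0, c1, c0p, c1p = (study.counts[:, j].astype(float) for j in range(4))

    z_d = _two_prop_z(c1, n[1], c0, n[0])
    z_r = _two_prop_z(c1p, n[3], c0p, n[2])
    z_s = _two_prop_z(c1p, n[3], c0 + c0p, n[0] + n[2])
    z_c = _two_prop_z(c1, n[1], c0 + c0p, n[0] + n[2])
    z_m = _two_prop_z(c1 + c1p, n[1] + n[3], c0 + c0p, n[0] + n[2])

    z = np.column_stack([z_d, z_r, z_s, z_c, z_m])
    keep = np.all(np.isfinite(z), axis=1)
    return {"z": z[keep], "keep": keep, "n_excluded": int((~keep).sum())}


def empirical_correlations(study: SimulatedStudy = None, z: np.ndarray = None, names=STATS) -> dict:
    """Sample correlations between null Z-scores, with Monte-Carlo SEs.

    Accepts either a simulated null study or a user-supplied Z table
    (``z`` with one column per statistic in ``names``).  Refuses fewer than
    100 replicates, and columns with zero variance.
    """
    if z is None:
        if study is None:
            raise ValueError("provide a SimulatedStudy or a Z table")
        z = statistics_from_counts(study)["z"]
        names = STATS
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != len(names):
        raise ValueError("z must be 2-D with one column per named statistic")
    n = z.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 replicates for a stable estimate, got {n}")
    sd = z.std(axis=0)
    if np.any(sd == 0.0):
        bad = [names[i] for i in np.flatnonzero(sd == 0.0)]
        raise ValueError(f"zero-variance Z column(s): {bad}")
    corr = np.corrcoef(z, rowvar=False)
    out = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(corr[i, j])
            out[f"rho_{names[i]}{names[j]}"] = {
                "estimate": r,
                "se": (1.0 - r * r) / np.sqrt(n),
            }
    return out


def empirical_zeta(study: SimulatedStudy) -> dict:
    """Mean Z per statistic with Monte-Carlo SEs (estimates the zeta vector)."""
    z = statistics_from_counts(study)["z"]
    n = z.shape[0]
    return {
        f"zeta_{s}": {"estimate": float(z[:, j].mean()), "se": float(z[:, j].std(ddof=1) / np.sqrt(n))}
        for j, s in enumerate(STATS)
    }


def _hits(z: np.ndarray, method: str, thresholds: ThresholdSet, z_rep: float) -> np.ndarray:
    """Apply a method's full hit rule (thresholds + sign agreement)."""
    cols = {"A": (0, 1, 4), "B": (0, 2, 4), "C": (3, 2, 4)}[method]
    zd, zr, zm = (z[:, c] for c in cols)
    bounds = (thresholds.z_alpha, z_rep, thresholds.z_gamma)
    pass_thresh = (
        (np.abs(zd) > bounds[0]) & (np.abs(zr) > bounds[1]) & (np.abs(zm) > bounds[2])
    )
    same_sign = (np.sign(zd) == np.sign(zr)) & (np.sign(zd) == np.sign(zm))
    return pass_thresh & same_sign


def empirical_rates(
    design: StudyDesign,
    thresholds: ThresholdSet,
    adjusted: AdjustedThresholds,
    spec: FrequencySpec,
    methods=("A", "B", "C"),
    replicates: int = 100_000,
    seed: int = 0,
) -> dict:
    """Empirical hit rate of each method (power, or a type-1 error rate).

    Returns per-method ``{"rate", "se", "hits", "n"}`` with the binomial
    Monte-Carlo standard error, plus the replicate-exclusion count.
    """
    study = simulate_counts(design, spec, replicates, seed)
    stats = statistics_from_counts(study)
    z = stats["z"]
    n = z.shape[0]
    z_reps = {
        "A": thresholds.z_beta,
        "B": z_from_p(adjusted.beta_star),
        "C": z_from_p(adjusted.beta_perp),
    }
    out = {"n_excluded": stats["n_excluded"]}
    for m in methods:
        h = int(_hits(z, m, thresholds, z_reps[m]).sum())
        rate = h / n
        out[m] = {
            "rate": rate,
            "se": float(np.sqrt(max(rate * (1.0 - rate), 1.0 / n) / n)),
            "hits": h,
            "n": n,
        }
    return out
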