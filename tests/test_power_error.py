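"""Rejection probabilities, power comparisons and aberrance error profiles."""

import numpy as np
import pytest

from ctrlshare import (
    FrequencySpec,
    NoncentralityVector,
    StudyDesign,
    ThresholdSet,
    aberrance_pattern,
    average_power_difference,
    controls_needed_for_parity,
    max_power_difference,
    noncentralities,
    power_at_log_or,
    rb_ra_bound,
    rejection_probability,
    solve_adjusted,
    type1_profile,
)

MODERATE = ThresholdSet(1e-4, 1e-3, 1e-6)


def test_zero_noncentrality_recovers_null_hit_rate(ftd_design, gwas_thresholds):
    adj = solve_adjusted(ftd_design, gwas_thresholds)
    zero = NoncentralityVector(0.0, 0.0, 0.0, 0.0, 0.0)
    for m in ("A", "B", "C"):
        p = rejection_probability(m, ftd_design, gwas_thresholds, zero, adj)
        assert p == pytest.approx(adj.p0, rel=1e-9)


def test_overwhelming_effect_has_power_one(k15_design, gwas_thresholds):
    adj = solve_adjusted(k15_design, gwas_thresholds)
    big = NoncentralityVector(40.0, 40.0, 40.0, 40.0, 40.0)
    for m in ("A", "B", "C"):
        assert rejection_probability(m, k15_design, gwas_thresholds, big, adj) > 1 - 1e-9


def test_average_difference_of_identical_methods_is_zero(k15_design, gwas_thresholds):
    res = average_power_difference("B", "B", k15_design, gwas_thresholds, 0.1)
    assert res["integral"] == 0.0
    res = max_power_difference("A", "A", k15_design, gwas_thresholds, 0.1)
    assert res["max_difference"] == 0.0


def test_average_difference_grid_convergence(k15_design, gwas_thresholds):
    """The quadrature is converged: halving the grid changes nothing material."""
    adj = solve_adjusted(k15_design, gwas_thresholds)
    a = average_power_difference("B", "A", k15_design, gwas_thresholds, 0.1, adj, n_grid=121)
    b = average_power_difference("B", "A", k15_design, gwas_thresholds, 0.1, adj, n_grid=241)
    assert a["integral"] == pytest.approx(b["integral"], rel=1e-4)
    assert b["integral"] > 0.0


def test_shared_controls_help_most_with_control_rich_discovery(gwas_thresholds):
    """The B-over-A advantage grows with the discovery control:case ratio."""
    gains = []
    for n0 in (5000, 10000, 15000):
        d = StudyDesign(n0, 5000, 5000, 5000)
        m = max_power_difference("B", "A", d, gwas_thresholds, 0.1)
        gains.append(m["max_difference"])
    assert gains == sorted(gains)
    assert gains[-1] > 0.05


def test_parity_contract(k15_design, gwas_thresholds):
    adj = solve_adjusted(k15_design, gwas_thresholds)
    res = controls_needed_for_parity(k15_design, gwas_thresholds, 0.1, -0.208, adj)
    x = res["extra_controls"]
    assert x > 0 and not res["capped"]

    def power_a(extra):
        d = k15_design.with_extra_replication_controls(extra)
        return power_at_log_or(
            "A", d, gwas_thresholds, -0.208, 0.1, design_for_effect=k15_design
        )

    assert power_a(x - 1) < res["power_b"] <= power_a(x)


def test_parity_zero_when_already_matched(balanced_design):
    """With essentially no sharing benefit at a saturated effect, no controls are needed."""
    th = ThresholdSet(1e-2, 1e-2, 1e-2)
    adj = solve_adjusted(balanced_design, th)
    res = controls_needed_for_parity(balanced_design, th, 0.1, 1.5, adj)
    assert res["extra_controls"] == 0


class TestTypeOneProfiles:
    def test_rates_equal_p0_at_zero_aberrance(self, ftd_design):
        adj = solve_adjusted(ftd_design, MODERATE)
        prof = type1_profile(("A", "B", "C"), ftd_design, MODERATE, "C1", [0.0], adj)
        for m in ("A", "B", "C"):
            assert prof.rates[m][0] == pytest.approx(adj.p0, rel=1e-9)

    def test_discovery_case_aberrance_limits(self, ftd_design):
        """zeta_d -> inf: R_A -> beta/2, R_B -> beta*/2, R_C -> beta_perp/2."""
        adj = solve_adjusted(ftd_design, MODERATE)
        prof = type1_profile(("A", "B", "C"), ftd_design, MODERATE, "C1", [20.0], adj)
        assert prof.rates["A"][0] == pytest.approx(MODERATE.beta / 2, rel=1e-3)
        assert prof.rates["B"][0] == pytest.approx(adj.beta_star / 2, rel=1e-3)
        assert prof.rates["C"][0] == pytest.approx(adj.beta_perp / 2, rel=1e-3)

    def test_replication_case_aberrance_limits(self, ftd_design):
        """zeta_r -> +-inf with aberrant C1': every method's rate -> alpha/2."""
        adj = solve_adjusted(ftd_design, MODERATE)
        prof = type1_profile(("A", "B", "C"), ftd_design, MODERATE, "C1p", [-20.0, 20.0], adj)
        for m in ("A", "B", "C"):
            for v in prof.rates[m]:
                assert v == pytest.approx(MODERATE.alpha / 2, rel=1e-3)

    def test_upper_bounds_by_cohort(self, ftd_design):
        """Each method's rate never exceeds its worst-case bound for any aberrance size."""
        adj = solve_adjusted(ftd_design, MODERATE)
        bounds = {
            "A": {"C0": MODERATE.beta, "C0p": MODERATE.alpha, "C1": MODERATE.beta, "C1p": MODERATE.alpha},
            "B": {"C0": 1.0, "C0p": MODERATE.alpha, "C1": adj.beta_star, "C1p": MODERATE.alpha},
            "C": {"C0": 1.0, "C0p": 1.0, "C1": adj.beta_perp, "C1p": MODERATE.alpha},
        }
        grid = np.linspace(-12.0, 12.0, 13)
        for scenario in ("C0", "C1", "C0p", "C1p"):
            prof = type1_profile(("A", "B", "C"), ftd_design, MODERATE, scenario, grid, adj)
            for m in ("A", "B", "C"):
                assert prof.rates[m].max() <= bounds[m][scenario] + 1e-9, (m, scenario)

    def test_shared_controls_repair_replication_control_aberrance(self, ftd_design):
        """Aberrance in C0' is partly corrected by the pooled controls: R_B <= R_A."""
        adj = solve_adjusted(ftd_design, MODERATE)
        grid = np.linspace(-8.0, 8.0, 17)
        prof = type1_profile(("A", "B"), ftd_design, MODERATE, "C0p", grid, adj)
        assert np.all(prof.rates["B"] <= prof.rates["A"] + 1e-12)

    def test_discovery_case_aberrance_favours_sharing_without_meta(self, ftd_design):
        """With gamma = 1, R_A >= R_B pointwise under C1 aberrance."""
        th = ThresholdSet(1e-4, 1e-3, 1.0)
        adj = solve_adjusted(ftd_design, th)
        grid = np.linspace(-8.0, 8.0, 17)
        prof = type1_profile(("A", "B"), ftd_design, th, "C1", grid, adj)
        assert np.all(prof.rates["A"] >= prof.rates["B"] - 1e-12)

    def test_opposed_aberrance_suppresses_errors(self, ftd_design):
        """Opposite-direction aberrance in C1 and C1' rejects less than either alone."""
        adj = solve_adjusted(ftd_design, MODERATE)
        base = FrequencySpec(0.1, 0.1, 0.1, 0.1)
        single = noncentralities(ftd_design, aberrance_pattern(["C1"], 0.02, base))
        opposed = noncentralities(
            ftd_design, aberrance_pattern(["C1", "C1p"], [0.02, -0.02], base)
        )
        for m in ("A", "B"):
            r1 = rejection_probability(m, ftd_design, MODERATE, single, adj)
            r2 = rejection_probability(m, ftd_design, MODERATE, opposed, adj)
            assert r2 < r1


class TestLargeAberranceBound:
    def test_bound_is_far_below_alpha_over_two(self, ra_design, gwas_thresholds):
        # the excess error from replication-case aberrance is a small
        # fraction of the worst case; the control-side counterpart (an
        # improvement, negative) merely stays within it
        assert abs(rb_ra_bound(ra_design, gwas_thresholds, "C1p")) < 0.5 * gwas_thresholds.alpha / 2
        assert abs(rb_ra_bound(ra_design, gwas_thresholds, "C0p")) < gwas_thresholds.alpha / 2

    def test_bound_positive_for_case_negative_for_control_aberrance(self, k15_design):
        th = ThresholdSet(1e-4, 1e-3, 1.0)
        assert rb_ra_bound(k15_design, th, "C1p") > 0
        assert rb_ra_bound(k15_design, th, "C0p") < 0


def test_typical_power_ordering_across_design_grid(gwas_thresholds):
    """Power_C >= Power_B >= Power_A is the typical (not universal) ordering.

    On a grid of 20000-sample designs with equal replication arms, evaluated
    at each design's mid-power effect: sharing controls always helps when the
    discovery cohort is control-rich (n0 >= 2 n1), and the fully-pooled design
    is the most powerful for the clear majority of the grid.
    """
    th = gwas_thresholds
    n_total, n_b_wins, n_c_wins = 0, 0, 0
    for n1 in (2000, 3000, 4000, 5000, 6000):
        for n1p in (1000, 1500, 2000, 2500):
            n0 = 20000 - n1 - 2 * n1p
            d = StudyDesign(n0, n1, n1p, n1p)
            adj = solve_adjusted(d, th)
            # log-OR putting the discovery statistic just past its threshold
            x = (th.z_alpha + 0.6) / np.sqrt(2 * d.n0 * d.n1 / (d.n0 + d.n1)) / 0.3
            pa, pb, pc = (power_at_log_or(m, d, th, x, 0.1, adj) for m in ("A", "B", "C"))
            n_total += 1
            n_b_wins += pb >= pa - 1e-9
            n_c_wins += pc >= pb - 1e-9
            if d.n0 >= 2 * d.n1:
                assert pb >= pa - 1e-9, d
    assert n_total >= 20
    assert n_b_wins >= 0.9 * n_total
    assert n_c_wins >= 0.6 * n_total
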