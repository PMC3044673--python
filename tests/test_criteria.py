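import numpy as np
import pytest
from scipy import stats

from bimodalgene import (
    CriteriaConfig,
    assign_components,
    classify_gene,
    component_intersections,
    gender_association_p,
    lower_mode_percentile,
    lrt_pvalue,
    misclassification_area,
)
from bimodalgene.exceptions import ConfigurationError, DataError, DegenerateDataError
from bimodalgene.mixture import BimodalFit

from conftest import mixture_draw


def _fit(mu1, s1, mu2, s2, p1):
    return BimodalFit(mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2, p1=p1, loglik=0.0)


class TestLrt:
    def test_null_case(self):
        stat, p = lrt_pvalue(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail(self):
        stat, p = lrt_pvalue(0.0, 22.4577 / 2, df=6)
        assert p == pytest.approx(0.00100, abs=5e-6)

    def test_monotone_in_statistic(self):
        ps = [lrt_pvalue(0.0, s / 2, df=6)[1] for s in np.linspace(0, 50, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestIntersections:
    def test_symmetric_midpoint(self):
        res = component_intersections(_fit(0, 1, 4, 1, 0.5))
        assert res.points == [pytest.approx(2.0)]
        assert res.chosen_threshold == pytest.approx(2.0)

    def test_unbalanced_closed_form(self):
        # equal variances: x* = (mu1+mu2)/2 + sigma^2 ln(p1/(1-p1)) / (mu2-mu1)
        res = component_intersections(_fit(0, 1, 4, 1, 0.8))
        assert res.points[0] == pytest.approx(2 + np.log(4) / 4)

    def test_roots_satisfy_density_equality(self):
        """Quadratic roots really are crossings of the weighted densities."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            mu1 = rng.normal(0, 1)
            mu2 = mu1 + rng.uniform(1, 6)
            s1, s2 = rng.uniform(0.5, 2, 2)
            if abs(s1 - s2) < 1e-3:
                continue
            p1 = rng.uniform(0.15, 0.85)
            fit = _fit(mu1, s1, mu2, s2, p1)
            for x in component_intersections(fit).points:
                d1 = p1 * stats.norm.pdf(x, mu1, s1)
                d2 = (1 - p1) * stats.norm.pdf(x, mu2, s2)
                assert abs(d1 - d2) <= 1e-8 * max(d1, d2, 1e-300)

    def test_degenerate_components(self):
        with pytest.raises(DegenerateDataError):
            component_intersections(_fit(1, 1, 1, 1, 0.5))


class TestMisclassificationArea:
    def test_normal_cdf_arithmetic(self):
        fit = _fit(0, 1, 6, 1, 0.5)
        area, t = misclassification_area(fit, component_intersections(fit))
        assert t == pytest.approx(3.0)
        assert area == pytest.approx(0.5 * stats.norm.cdf(-3), rel=1e-9)

    def test_vanishing_overlap(self):
        fit = _fit(0, 1, 10, 1, 0.5)
        area, _ = misclassification_area(fit, component_intersections(fit))
        assert area < 1e-6

    def test_monotone_in_separation(self):
        areas = []
        for delta in np.linspace(2, 8, 13):
            fit = _fit(0, 1, delta, 1.4, 0.35)
            areas.append(misclassification_area(fit, component_intersections(fit))[0])
        assert all(a >= b - 1e-12 for a, b in zip(areas, areas[1:]))


class TestAssignComponents:
    def test_boundary_and_counting(self):
        labels, frac_low, frac_high = assign_components([1, 2, 3, 4], 0.5)
        assert frac_low == 0.0
        labels, frac_low, _ = assign_components([1, 2, 3, 4], 2.5)
        assert frac_low == 0.5
        # values exactly at the threshold go to the high component
        labels, frac_low, _ = assign_components([1.0, 2.0, 3.0], 2.0)
        assert list(labels) == ["low", "high", "high"]

    def test_outlier_guard_scenario(self):
        """2 of 100 points below threshold: 10% criterion must fail."""
        x = np.r_[np.full(98, 5.0) + np.arange(98) * 1e-3, [0.0, 0.1]]
        _, frac_low, _ = assign_components(x, 2.0)
        assert frac_low == pytest.approx(0.02)
        assert frac_low < CriteriaConfig().min_component_frac


class TestGenderAssociation:
    def test_no_effect(self):
        x = np.r_[np.ones(10), np.ones(10)]
        assert gender_association_p(x, ["M"] * 10 + ["F"] * 10) == 1.0

    def test_matches_pooled_t_test(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(5, 30, 2)
            x = rng.normal(0, 1, n1 + n2)
            g = ["M"] * n1 + ["F"] * n2
            p = gender_association_p(x, g)
            oracle = stats.ttest_ind(x[:n1], x[n1:], equal_var=True).pvalue
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_power_on_strong_shift(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(3, 1, 30)]
        assert gender_association_p(x, ["M"] * 30 + ["F"] * 30) < 1e-6

    def test_single_gender_returns_one(self):
        assert gender_association_p(np.arange(10.0), ["M"] * 10) == 1.0


class TestClassifyGene:
    def test_planted_bimodal_called(self, fast_config):
        rng = np.random.default_rng(21)
        x, _ = mixture_draw(rng, 120, 0.4, 4.0)
        g = rng.choice(["M", "F"], 120)
        # avoid a chance gender association confounding the planted signal
        while gender_association_p(x, g) < 0.1:
            g = rng.choice(["M", "F"], 120)
        v = classify_gene(x, g, fast_config)
        assert v.final_call
        assert v.frac_low + v.frac_high == pytest.approx(1.0)

    def test_unimodal_not_called(self, fast_config):
        rng = np.random.default_rng(22)
        calls = 0
        for _ in range(40):
            x = rng.normal(8, 0.6, 120)
            calls += classify_gene(x, rng.choice(["M", "F"], 120), fast_config).final_call
        assert calls == 0

    def test_outliers_fail_component_floor(self, fast_config):
        """Two extreme outliers can win the LRT but not the 10% rule."""
        rng = np.random.default_rng(23)
        x = np.r_[rng.normal(8, 0.3, 98), [2.0, 2.1]]
        v = classify_gene(x, rng.choice(["M", "F"], 100), fast_config)
        assert not v.final_call
        if v.passes["lrt"]:
            assert not v.passes["min_component"]

    def test_gender_dichotomy_filtered(self, fast_config):
        """A pure male/female mean shift is excluded by the gender filter."""
        rng = np.random.default_rng(24)
        g = np.r_[["M"] * 70, ["F"] * 50]
        x = np.where(g == "M", rng.normal(10, 0.5, 120), rng.normal(6, 0.5, 120))
        v = classify_gene(x, g, fast_config)
        assert not v.passes["gender"]
        assert not v.final_call

    def test_compounding_monotonicity(self, fast_config, small_study):
        """Cumulative criterion counts are non-increasing in Table-2 order."""
        _, (expr, meta, _, _) = small_study
        verdicts = [
            classify_gene(expr.gene(gid), meta.gender(), fast_config)
            for gid in expr.gene_ids[:30]
        ]
        from bimodalgene import compounding_counts
        counts = compounding_counts(verdicts).to_numpy()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_not_assessable_on_constant_gene(self, fast_config):
        v = classify_gene(np.full(50, 2.0), ["M", "F"] * 25, fast_config)
        assert not v.assessable and not v.final_call


class TestLowerModePercentile:
    def test_floor_and_hand_counting(self):
        fit = _fit(0, 1, 5, 1, 0.5)
        values = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        labels = np.array(["low"] * 3 + ["high"] * 3)
        # lower-mode median 0.1; below every reference median -> 0
        assert lower_mode_percentile(fit, labels, values, [1, 2, 3, 4]) == 0.0
        # ranked 3rd of 4 others (two below) -> 50.0
        assert lower_mode_percentile(fit, labels, values, [-1.0, 0.0, 0.5, 2.0]) == 50.0

    def test_empty_mode_errors(self):
        fit = _fit(0, 1, 5, 1, 0.5)
        with pytest.raises(DataError):
            lower_mode_percentile(fit, ["high"] * 4, np.arange(4.0), [1.0])


def test_config_validation():
    with pytest.raises(ConfigurationError):
        CriteriaConfig(p_threshold=1.1)
    with pytest.raises(ConfigurationError):
        CriteriaConfig(trim_frac=0.7)
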