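"""Compound model-selection rule deciding whether one gene is bimodal.

A gene is called bimodal only when all four criteria hold simultaneously:

1. likelihood-ratio test p < 0.001 against chi-square with six degrees of
   freedom (deliberately more stringent than the nominal three extra
   parameters);
2. misclassification area at the best between-component threshold < 0.1;
3. at least 10% of the data points on each side of that threshold, which
   guards against a handful of outliers masquerading as a second mode;
4. no association of expression with gender at the 0.05 level, so that
   male/female mean differences are not reported as bimodality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError, DataError, DegenerateDataError
from .mixture import BimodalFit, fit_bimodal, fit_unimodal
from .transform import TransformResult, select_lambda


@dataclass
class CriteriaConfig:
    """Thresholds of the compound bimodality rule."""

    lrt_df: int = 6
    p_threshold: float = 0.001
    misclass_threshold: float = 0.1
    min_component_frac: float = 0.10
    gender_alpha: float = 0.05
    trim_frac: float = 0.05
    mixture_budget: int = 200_000

    def __post_init__(self):
        if self.lrt_df < 1:
            raise ConfigurationError("lrt_df must be a positive integer")
        for name in ("p_threshold", "misclass_threshold", "min_component_frac",
                     "gender_alpha"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if not (0.0 <= self.trim_frac < 0.5):
            raise ConfigurationError("trim_frac must lie in [0, 0.5)")
        if self.mixture_budget < 100:
            raise ConfigurationError("mixture_budget must be >= 100")


@dataclass
class IntersectionResult:
    """Crossing points of the two weighted component densities."""

    points: list  # 0-2 real crossings, ascending
    chosen_threshold: float
    fallback_used: bool = False


@dataclass
class BimodalityVerdict:
    """Everything the compound rule measured for one gene."""

    gene_id: str | None
    transform: TransformResult | None
    fit_uni: object
    fit_bi: BimodalFit | None
    lrt_stat: float
    p_bimodal: float
    misclass_area: float
    threshold: float
    frac_low: float
    frac_high: float
    gender_p: float
    passes: dict = field(default_factory=dict)
    final_call: bool = False
    assessable: bool = True
    assignments: np.ndarray | None = field(default=None, repr=False)


def lrt_pvalue(ll_uni: float, ll_bi: float, df: int = 6):
    """Likelihood-ratio statistic and chi-square upper-tail p-value.

    The statistic ``2 (ll_bi - ll_uni)`` is clamped at 0 against floating-
    point jitter; the reference distribution is chi-square with ``df``
    degrees of freedom (default 6 rather than the naive 3, a deliberately
    conservative choice for this non-regular nested comparison).
    """
    stat = max(0.0, 2.0 * (ll_bi - ll_uni))
    return stat, float(stats.chi2.sf(stat, df))


def _weighted_logdens(fit: BimodalFit, x, component: int):
    if component == 1:
        w, mu, s = fit.p1, fit.mu1, fit.sigma1
    else:
        w, mu, s = 1.0 - fit.p1, fit.mu2, fit.sigma2
    return math.log(w) - math.log(s) - 0.5 * math.log(2 * math.pi) - 0.5 * ((x - mu) / s) ** 2


def _misclass_at(fit: BimodalFit, t: float) -> float:
    # component 1 is the lower mode (canonical order): mass of the lower
    # component above t vs mass of the upper component below t.
    a1 = fit.p1 * stats.norm.sf(t, fit.mu1, fit.sigma1)
    a2 = (1.0 - fit.p1) * stats.norm.cdf(t, fit.mu2, fit.sigma2)
    return float(min(a1, a2))


def component_intersections(fit: BimodalFit) -> IntersectionResult:
    """Solve for the crossings of the two weighted component densities.

    With unequal variances the log-density difference is quadratic in x,
    giving 0, 1, or 2 real crossings; with equal variances it is linear
    with a single closed-form root.  When no real crossing exists the two
    component means serve as fallback candidate thresholds.  Of the
    candidates, the one minimising the misclassification area is recorded
    as ``chosen_threshold``.
    """
    mu1, s1, mu2, s2, p1 = fit.params
    if mu1 == mu2 and s1 == s2:
        raise DegenerateDataError("identical components: intersection undefined")

    # p1 N(mu1,s1) = (1-p1) N(mu2,s2)  <=>  a x^2 + b x + c = 0
    a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = (
        0.5 * (mu2**2 / s2**2 - mu1**2 / s1**2)
        + math.log(p1 / (1.0 - p1))
        + math.log(s2 / s1)
    )
    roots: list[float] = []
    if abs(a) < 1e-14:  # equal variances: linear
        if abs(b) > 1e-300:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc > 0:
            sq = math.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
            if abs(roots[1] - roots[0]) < 1e-12:
                roots = roots[:1]
        elif disc == 0:
            roots = [-b / (2 * a)]
    roots = [float(r) for r in roots if np.isfinite(r)]

    candidates, fallback = _candidate_thresholds(fit, roots)
    chosen = min(candidates, key=lambda t: _misclass_at(fit, t))
    return IntersectionResult(points=roots, chosen_threshold=float(chosen),
                              fallback_used=fallback)


def _candidate_thresholds(fit: BimodalFit, roots):
    """Dichotomising threshold candidates from the density crossings.

    Only crossings lying between the component means can split the two
    modes; with unequal variances the densities cross a second time far
    out in a tail, where the misclassification area is vacuously tiny but
    the threshold would put (almost) all data on one side.  When no
    crossing lies within [mu1, mu2] the component means serve as the
    fallback candidates.
    """
    inner = [r for r in roots if fit.mu1 <= r <= fit.mu2]
    if inner:
        return inner, False
    return [fit.mu1, fit.mu2], True


def misclassification_area(fit: BimodalFit, inter: IntersectionResult):
    """Minimum mixture-weighted tail mass on the wrong side of a threshold.

    Each candidate threshold t scores ``min(p1 P(X1 > t), (1-p1) P(X2 < t))``
    with X1 the lower and X2 the upper component; the candidate with the
    smallest area wins.  Small areas mean well-separated modes.
    """
    candidates, _ = _candidate_thresholds(fit, inter.points)
    areas = [(_misclass_at(fit, t), t) for t in candidates]
    area, t = min(areas, key=lambda at: at[0])
    return float(area), float(t)


def assign_components(values, threshold: float):
    """Split samples at the threshold: strictly below -> "low", else "high"."""
    x = np.asarray(values, dtype=float)
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    labels = np.where(x < threshold, "low", "high")
    frac_low = float(np.mean(x < threshold))
    return labels, frac_low, 1.0 - frac_low


def gender_association_p(values, gender) -> float:
    """Two-sided p for a gender effect on (untransformed) expression.

    Ordinary least squares of expression on a gender indicator — the same
    test as a pooled-variance two-sample t-test.  Run on the raw normalised
    intensities, before any power transform.  Degenerate inputs (a single
    gender present, or no variation) return p = 1.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(gender)
    levels = np.unique(g)
    if levels.size < 2:
        return 1.0
    if levels.size > 2:
        raise DataError(f"expected 2 gender levels, got {levels.size}")
    ind = (g == levels[1]).astype(float)
    if min(ind.sum(), (1 - ind).sum()) < 2:
        return 1.0
    if np.ptp(x) == 0:
        return 1.0
    X = sm.add_constant(ind)
    res = sm.OLS(x, X).fit()
    p = float(res.pvalues[1])
    return 1.0 if not np.isfinite(p) else p


def classify_gene(values, gender, config: CriteriaConfig | None = None,
                  gene_id: str | None = None) -> BimodalityVerdict:
    """Run the full per-gene pipeline and apply the compound rule.

    Box-Cox exponent selection, unimodal and bimodal maximum-likelihood
    fits, the four criteria in order (LRT, misclassification area,
    10%-per-component, gender), with every intermediate recorded.  Genes
    whose data are degenerate come back flagged not assessable rather than
    raising.
    """
    config = config or CriteriaConfig()
    x = np.asarray(values, dtype=float)
    g = np.asarray(gender)
    if x.size < 10:
        raise DataError(f"need >= 10 values, got {x.size}")

    try:
        tr = select_lambda(x)
        y = tr.transformed_values
        uni = fit_unimodal(y)
        bi = fit_bimodal(y, budget=config.mixture_budget)
        stat, p = lrt_pvalue(uni.loglik, bi.loglik, df=config.lrt_df)
        inter = component_intersections(bi)
        area, threshold = misclassification_area(bi, inter)
        labels, frac_low, frac_high = assign_components(y, threshold)
    except DegenerateDataError:
        return BimodalityVerdict(
            gene_id=gene_id, transform=None, fit_uni=None, fit_bi=None,
            lrt_stat=float("nan"), p_bimodal=1.0, misclass_area=float("nan"),
            threshold=float("nan"), frac_low=float("nan"),
            frac_high=float("nan"), gender_p=1.0, passes={},
            final_call=False, assessable=False,
        )

    gender_p = gender_association_p(x, g)  # pre-transform values

    passes = {
        "lrt": p < config.p_threshold,
        "misclass": area < config.misclass_threshold,
        "min_component": min(frac_low, frac_high) >= config.min_component_frac,
        "gender": gender_p >= config.gender_alpha,
    }
    return BimodalityVerdict(
        gene_id=gene_id, transform=tr, fit_uni=uni, fit_bi=bi,
        lrt_stat=stat, p_bimodal=p, misclass_area=area, threshold=threshold,
        frac_low=frac_low, frac_high=frac_high, gender_p=gender_p,
        passes=passes, final_call=all(passes.values()), assessable=True,
        assignments=labels,
    )


def lower_mode_percentile(gene_fit: BimodalFit, assignments, gene_values,
                          all_gene_medians) -> float:
    """Percentile rank of the lower mode's median among other genes' medians.

    Used to judge whether the lower mode sits at background (no
    expression) level — a lower-mode median at or below the 25th
    percentile of all gene medians — or represents a second genuine
    abundance level.
    """
    labels = np.asarray(assignments)
    x = np.asarray(gene_values, dtype=float)
    meds = np.asarray(all_gene_medians, dtype=float)
    low = x[labels == "low"]
    if low.size == 0 or low.size == x.size:
        raise DataError("both modes must be non-empty")
    if meds.size == 0:
        raise DataError("no reference medians")
    low_med = float(np.median(low))
    return float(np.mean(meds < low_med) * 100.0)
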