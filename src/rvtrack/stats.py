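"""Agreement and diagnostic-performance statistics.

Implements the evaluation battery used to validate automated displacement
indices against reference measurements:

* Bland-Altman agreement (mean difference and mean +/- 1.96 SD limits of
  agreement, sample SD), with Pearson correlation and a least-squares
  regression line;
* intra-class correlation, two-way random effects, absolute agreement,
  single measurement — ICC(2,1) — with the F-based 95% confidence
  interval of McGraw & Wong;
* ROC analysis with the Mann-Whitney rank formulation of the AUC, a
  DeLong confidence interval, and an operating point chosen to maximize
  specificity subject to a sensitivity floor (sens > 80% by default);
* unpaired t tests and tertile trend analysis (one-way ANOVA across
  empirical tertiles of a stratifying variable).

Orientation convention: displacement indices fall with worsening RV
function, so by default LOWER scores indicate the positive (dysfunction)
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


# --------------------------------------------------------------------------
# agreement
# --------------------------------------------------------------------------

@dataclass
class AgreementReport:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pearson_r: float
    slope: float
    intercept: float
    n: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement between paired measurements ``a`` and ``b``.

    Differences are ``a - b``; limits of agreement are mean +/- 1.96 times
    the sample standard deviation (n-1 denominator).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D and paired")
    if len(a) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = a - b
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        r = np.nan
        slope, intercept = np.nan, np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
        res = sps.linregress(b, a)
        slope, intercept = float(res.slope), float(res.intercept)
    return AgreementReport(
        mean_diff=md,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        sd_diff=sd,
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        n=len(a),
    )


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int
    defined: bool = True


def icc(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_cases, k_raters) matrix. The confidence interval
    is the F-based interval of McGraw & Wong. With zero between-case
    variance the coefficient is undefined and flagged as such rather than
    reported as a number.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be an (n_cases, k_raters) matrix")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 raters and >= 3 cases")
    if np.all(x == x[:, [0]]):
        # raters agree exactly on every case: perfect absolute agreement
        # (undefined if the cases do not vary at all)
        if np.all(x == x.flat[0]):
            return ICCResult(np.nan, np.nan, np.nan, n, k, defined=False)
        return ICCResult(1.0, 1.0, 1.0, n, k)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(msr, 0.0) and np.isclose(denom, 0.0):
        return ICCResult(np.nan, np.nan, np.nan, n, k, defined=False)
    est = (msr - mse) / denom

    if np.isclose(mse, 0.0) and np.isclose(msc, 0.0):
        # identical raters on varying cases: exact agreement, degenerate CI
        return ICCResult(float(est), float(est), float(est), n, k)

    fj = msc / mse if mse > 0 else np.inf
    vn = (k - 1) * (n - 1) * (k * est * fj + n * (1 + (k - 1) * est) - k * est) ** 2
    vd = (n - 1) * k ** 2 * est ** 2 * fj ** 2 + (n * (1 + (k - 1) * est) - k * est) ** 2
    v = vn / vd
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return ICCResult(float(est), float(lower), float(upper), n, k)


# --------------------------------------------------------------------------
# diagnostic performance
# --------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    units: str = ""
    sensitivity_floor_met: bool = True

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _oriented(scores, labels, lower_is_positive):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D and aligned")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    risk = -scores if lower_is_positive else scores
    return risk, labels


def roc_auc(scores, labels, lower_is_positive: bool = True,
            alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC by the Mann-Whitney rank formulation, with a DeLong 95% CI.

    ``lower_is_positive=True`` encodes that a LOWER index indicates
    dysfunction (the positive class).
    """
    risk, labels = _oriented(scores, labels, lower_is_positive)
    pos, neg = risk[labels], risk[~labels]
    m, n = len(pos), len(neg)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components via midranks
    v10 = (sps.rankdata(np.concatenate([pos, neg]))[:m] - sps.rankdata(pos)) / n
    v01 = 1.0 - (sps.rankdata(np.concatenate([neg, pos]))[:n] - sps.rankdata(neg)) / m
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def _confusion_at(risk, labels, cut):
    pred = risk >= cut
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    return tp, fp, tn, fn


def operating_point(scores, labels, sensitivity_floor: float = 0.80,
                    lower_is_positive: bool = True, units: str = "") -> DiagnosticReport:
    """Cutoff maximizing specificity subject to sensitivity > floor.

    Candidate cutoffs are the midpoints between sorted unique scores (an
    invariant choice under monotone within-gap score perturbations). Among
    candidates with sensitivity strictly above the floor the one with
    maximal specificity wins; ties break toward higher sensitivity, then
    toward the less aggressive cutoff. If no candidate attains the floor,
    the maximum-sensitivity candidate is reported and flagged.
    """
    if not 0.0 < sensitivity_floor < 1.0 and sensitivity_floor != 0.0:
        raise ValueError("sensitivity_floor must lie in [0, 1)")
    risk, lab = _oriented(scores, labels, lower_is_positive)
    uniq = np.unique(risk)
    if len(uniq) < 2:
        raise ValueError("scores are constant; no operating point exists")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0

    best = None  # (spec, sens, -cut_in_risk_units, cut)
    fallback = None  # (sens, spec, cut)
    for cut in cuts:
        tp, fp, tn, fn = _confusion_at(risk, lab, cut)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if fallback is None or (sens, spec) > fallback[:2]:
            fallback = (sens, spec, cut)
        if sens > sensitivity_floor:
            key = (spec, sens, -cut)
            if best is None or key > best[0]:
                best = (key, cut)
    met = best is not None
    cut = best[1] if met else fallback[2]
    tp, fp, tn, fn = _confusion_at(risk, lab, cut)
    auc, (lo, hi) = roc_auc(scores, labels, lower_is_positive)
    total = tp + fp + tn + fn
    return DiagnosticReport(
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
        cutoff=float(-cut) if lower_is_positive else float(cut),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / total,
        ppv=tp / (tp + fp) if tp + fp else np.nan,
        npv=tn / (tn + fn) if tn + fn else np.nan,
        units=units,
        sensitivity_floor_met=met,
    )


def roc_curve_points(scores, labels, lower_is_positive: bool = True) -> np.ndarray:
    """(1 - specificity, sensitivity) pairs over all candidate cutoffs."""
    risk, lab = _oriented(scores, labels, lower_is_positive)
    thresholds = np.concatenate([[np.inf], np.unique(risk)[::-1], [-np.inf]])
    pts = []
    for cut in thresholds:
        tp, fp, tn, fn = _confusion_at(risk, lab, cut)
        pts.append((fp / (fp + tn), tp / (tp + fn)))
    return np.array(pts)


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def group_compare(values, group_labels, equal_var: bool = True):
    """Two-sided unpaired Student's t test between two groups.

    Returns ``(t, p, (mean0, sd0), (mean1, sd1))``; ``equal_var=False``
    switches to the Welch variant.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    g0 = values[groups == uniq[0]]
    g1 = values[groups == uniq[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("empty group")
    t, p = sps.ttest_ind(g0, g1, equal_var=equal_var)
    return (float(t), float(p),
            (float(g0.mean()), float(g0.std(ddof=1))),
            (float(g1.mean()), float(g1.std(ddof=1))))


def tertile_trend(values, stratifier):
    """Per-tertile means of ``values`` across tertiles of ``stratifier``.

    Tertiles split at the empirical 33.3rd/66.7th percentiles of the
    stratifying variable; the trend p value is a one-way ANOVA across the
    three strata. Returns ``(tertile_means, anova_p, tertile_assignment)``.
    """
    values = np.asarray(values, dtype=float)
    strat = np.asarray(stratifier, dtype=float)
    if values.shape != strat.shape:
        raise ValueError("values and stratifier must align")
    q1, q2 = np.percentile(strat, [100 / 3, 200 / 3])
    assign = np.where(strat <= q1, 0, np.where(strat <= q2, 1, 2))
    groups = [values[assign == t] for t in range(3)]
    if any(len(g) < 3 for g in groups):
        raise ValueError("each tertile needs >= 3 cases")
    means = [float(g.mean()) for g in groups]
    _, p = sps.f_oneway(*groups)
    return means, float(p), assign
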