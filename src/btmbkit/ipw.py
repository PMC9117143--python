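"""Propensity-score / inverse-probability-weighting adjustment.

Compares the low-ctDNA (MSAF < 1%) and adequate-ctDNA (MSAF >= 1%)
subgroups after reweighting for baseline imbalances: baseline factors are
screened at p < 0.15 (rank test for continuous factors, chi-square — Fisher
exact for sparse 2x2 tables — for categorical), the screened factors enter
a logistic propensity model for MSAF-group membership, and patients are
weighted by the inverse probability of their observed group. Adjusted
response rates, a weighted odds ratio with a linearized (sandwich-style)
interval, weighted Kaplan–Meier PFS medians and a weighted Cox hazard ratio
are reported, along with standardized mean differences before and after
weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import PatientRecord
from .survival import CoxResult, MedianCI, cox_hr, km_fit, km_median_ci

CONTINUOUS_FACTORS = ("age", "sld_mm", "n_target_lesions")
CATEGORICAL_FACTORS = ("smoking", "pdl1_status", "histology", "sex")
ALL_FACTORS = CONTINUOUS_FACTORS + CATEGORICAL_FACTORS

MSAF_THRESHOLD = 0.01


class SeparationError(RuntimeError):
    """The propensity model separated; remove a factor and refit."""


@dataclass(frozen=True)
class IPWResult:
    selected_factors: list          # (factor, screening p-value)
    propensity: np.ndarray          # P(MSAF < 1% | covariates)
    weights: np.ndarray
    n_truncated: int
    orr_low_msaf: float             # adjusted ORR, MSAF < 1% group
    orr_high_msaf: float            # adjusted ORR, MSAF >= 1% group
    odds_ratio: float
    or_ci: tuple
    or_p: float
    unadjusted_odds_ratio: float
    pfs_hr: Optional[CoxResult]
    pfs_median_low_msaf: Optional[MedianCI]
    pfs_median_high_msaf: Optional[MedianCI]
    balance: pd.DataFrame = field(default_factory=pd.DataFrame)


def msaf_group_indicator(patients: Sequence[PatientRecord]) -> np.ndarray:
    """1 for the MSAF < 1% (low-ctDNA) group, 0 for MSAF >= 1%."""
    vals = []
    for p in patients:
        if p.msaf is None:
            raise ValueError(f"patient {p.id} has no MSAF")
        vals.append(p.msaf < MSAF_THRESHOLD)
    return np.asarray(vals, dtype=int)


def _factor_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "age": [p.age for p in patients],
        "sld_mm": [p.sld_mm for p in patients],
        "n_target_lesions": [p.n_target_lesions for p in patients],
        "smoking": [p.smoking for p in patients],
        "pdl1_status": [p.pdl1_status for p in patients],
        "histology": [p.histology for p in patients],
        "sex": [p.sex for p in patients],
    })


def screen_factors(patients: Sequence[PatientRecord],
                   group: Optional[np.ndarray] = None,
                   alpha: float = 0.15,
                   factors: Sequence[str] = ALL_FACTORS,
                   ) -> list[tuple[str, float]]:
    """Baseline factors with a notable between-group difference (p < alpha).

    Continuous factors use the two-sample Wilcoxon rank-sum test;
    categorical factors use the chi-square test without continuity
    correction, falling back to Fisher's exact test for sparse 2x2 tables.
    Constant factors are skipped with a warning.
    """
    if group is None:
        group = msaf_group_indicator(patients)
    group = np.asarray(group, dtype=int)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise ValueError("need at least 2 patients per group")
    df = _factor_frame(patients)
    selected = []
    for factor in factors:
        col = df[factor]
        if col.nunique() < 2:
            warnings.warn(f"factor {factor!r} is constant; skipped")
            continue
        if factor in CONTINUOUS_FACTORS:
            _, p = sps.mannwhitneyu(col[group == 1], col[group == 0],
                                    alternative="two-sided")
            if p < alpha:
                selected.append((factor, float(p)))
            continue
        # categorical factors are screened level by level as binary
        # indicators (the trial convention: "current smokers",
        # "PD-L1-positive"); the strongest level is selected
        best_level, best_p = None, np.inf
        for level in sorted(col.unique()):
            tab = pd.crosstab(col == level, group).to_numpy()
            if tab.shape != (2, 2):
                continue
            if (sps.contingency.expected_freq(tab) < 5).any():
                _, p = sps.fisher_exact(tab)
            else:
                _, p, _, _ = sps.chi2_contingency(tab, correction=False)
            if p < best_p:
                best_level, best_p = level, float(p)
        if best_p < alpha:
            selected.append((f"{factor}={best_level}", best_p))
    return selected


def _design_matrix(patients, factor_names) -> pd.DataFrame:
    """Columns for the propensity model.

    Accepts continuous factor names, plain categorical names (expanded to
    dummies) and ``factor=level`` indicator names from the screen.
    """
    df = _factor_frame(patients)
    cols = {}
    plain_cat = []
    for name in factor_names:
        if "=" in name:
            factor, level = name.split("=", 1)
            cols[name] = (df[factor] == level).astype(float)
        elif name in CATEGORICAL_FACTORS:
            plain_cat.append(name)
        else:
            cols[name] = df[name].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if plain_cat:
        dummies = pd.get_dummies(df[plain_cat], columns=plain_cat,
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_propensity(patients: Sequence[PatientRecord],
                   selected_factors: Sequence,
                   group: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-patient probability of MSAF < 1% membership.

    Logistic regression (IRLS) of the group indicator on the screened
    factors; with no factors the propensity is the group prevalence.
    Missing categorical levels enter as their own category.
    """
    if group is None:
        group = msaf_group_indicator(patients)
    group = np.asarray(group, dtype=float)
    names = [f[0] if isinstance(f, (tuple, list)) else f
             for f in selected_factors]
    if not names:
        return np.full(len(patients), group.mean())
    X = _design_matrix(patients, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(group, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-10)
        except Exception as exc:  # perfect separation raises in statsmodels
            raise SeparationError(
                f"propensity model failed ({exc}); remove a factor") from exc
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    if (np.abs(fit.params.to_numpy()).max() > 15
            or np.any(fitted <= 1e-9) or np.any(fitted >= 1 - 1e-9)):
        raise SeparationError(
            "propensity model separated (diverging coefficient / "
            "degenerate fitted probability); remove a factor")
    return fitted


def _weighted_prop(y, w):
    return float(np.sum(w * y) / np.sum(w))


def _logit_var(y, w, p):
    # linearized (Horvitz–Thompson) variance of logit(weighted proportion)
    if p <= 0 or p >= 1:
        return np.inf
    var_p = np.sum(w ** 2 * (y - p) ** 2) / np.sum(w) ** 2
    return var_p / (p * (1 - p)) ** 2


def standardized_mean_difference(values, group, weights=None) -> float:
    """SMD of one factor between groups; categorical factors report the
    largest per-level SMD. Pooled SD is always the unweighted one, so the
    before/after comparison shares a scale."""
    g = np.asarray(group, dtype=bool)
    w = np.ones(g.size) if weights is None else np.asarray(weights, float)
    vals = pd.Series(values)
    if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
        smds = []
        for level in vals.unique():
            smds.append(standardized_mean_difference(
                (vals == level).astype(float).to_numpy(), g, w))
        return max(smds)
    x = vals.to_numpy(dtype=float)
    m1 = np.average(x[g], weights=w[g])
    m0 = np.average(x[~g], weights=w[~g])
    s1, s0 = x[g].std(ddof=1), x[~g].std(ddof=1)
    pooled = np.sqrt((s1 ** 2 + s0 ** 2) / 2)
    return float(abs(m1 - m0) / pooled) if pooled > 0 else 0.0


def ipw_estimate(patients: Sequence[PatientRecord],
                 propensity: np.ndarray,
                 group: Optional[np.ndarray] = None,
                 selected_factors: Sequence = (),
                 conf: float = 0.95,
                 truncate_pct: tuple = (1.0, 99.0),
                 stabilized: bool = False) -> IPWResult:
    """Inverse-probability-weighted comparison of the MSAF groups.

    Weights are 1/p for the MSAF < 1% group and 1/(1-p) otherwise
    (multiplied by the group prevalence when ``stabilized``), truncated at
    the given weight percentiles within each group — pooling the two
    groups' very different weight scales before truncating would clip
    exactly the most informative low-propensity patients and bias the
    estimate. The weighted odds-ratio interval uses a linearized variance
    for the weighted log-odds.
    """
    if group is None:
        group = msaf_group_indicator(patients)
    group = np.asarray(group, dtype=int)
    p = np.asarray(propensity, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("propensity must be strictly inside (0, 1)")
    w = np.where(group == 1, 1.0 / p, 1.0 / (1.0 - p))
    if stabilized:
        prev = group.mean()
        w *= np.where(group == 1, prev, 1 - prev)
    n_trunc = 0
    for mask in (group == 1, group == 0):
        if mask.sum() == 0:
            continue
        lo, hi = np.percentile(w[mask], truncate_pct)
        n_trunc += int(np.sum((w[mask] < lo) | (w[mask] > hi)))
        w[mask] = np.clip(w[mask], lo, hi)

    y = np.array([pt.confirmed_responder for pt in patients], dtype=float)
    g1, g0 = group == 1, group == 0
    p1, p0 = _weighted_prop(y[g1], w[g1]), _weighted_prop(y[g0], w[g0])

    def _odds(pr):
        return pr / (1 - pr)

    # unadjusted OR with Haldane correction if needed
    a, b = y[g1].sum(), (1 - y[g1]).sum()
    c, d = y[g0].sum(), (1 - y[g0]).sum()
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    unadj_or = float((a * d) / (b * c))

    if 0 < p1 < 1 and 0 < p0 < 1:
        log_or = np.log(_odds(p1) / _odds(p0))
        se = np.sqrt(_logit_var(y[g1], w[g1], p1)
                     + _logit_var(y[g0], w[g0], p0))
        z = sps.norm.ppf(0.5 + conf / 2)
        or_ci = (float(np.exp(log_or - z * se)),
                 float(np.exp(log_or + z * se)))
        or_p = float(2 * sps.norm.sf(abs(log_or) / se)) if se > 0 else 1.0
        or_est = float(np.exp(log_or))
    else:
        or_est, or_ci, or_p = float("nan"), (0.0, np.inf), 1.0

    times = np.array([pt.pfs_time for pt in patients])
    events = np.array([pt.pfs_event for pt in patients])
    pfs_hr = None
    med1 = med0 = None
    if events[g1].any() and events[g0].any():
        pfs_hr = cox_hr(times, events, group.astype(float), conf=conf,
                        weights=w)
        med1 = km_median_ci(km_fit(times[g1], events[g1], weights=w[g1]))
        med0 = km_median_ci(km_fit(times[g0], events[g0], weights=w[g0]))

    df = _factor_frame(patients)
    names = [f[0] if isinstance(f, (tuple, list)) else f
             for f in selected_factors]

    def _values(name):
        if "=" in name:
            factor, level = name.split("=", 1)
            return (df[factor] == level).astype(float)
        return df[name]

    balance = pd.DataFrame([
        {"factor": name,
         "smd_before": standardized_mean_difference(_values(name), group),
         "smd_after": standardized_mean_difference(_values(name), group, w)}
        for name in names])

    return IPWResult(
        selected_factors=list(selected_factors), propensity=p, weights=w,
        n_truncated=n_trunc, orr_low_msaf=p1, orr_high_msaf=p0,
        odds_ratio=or_est, or_ci=or_ci, or_p=or_p,
        unadjusted_odds_ratio=unadj_or, pfs_hr=pfs_hr,
        pfs_median_low_msaf=med1, pfs_median_high_msaf=med0,
        balance=balance)


def ipw_analysis(patients: Sequence[PatientRecord], alpha: float = 0.15,
                 conf: float = 0.95, stabilized: bool = False) -> IPWResult:
    """Full chain: screen factors, fit the propensity model, weight.

    If the propensity model separates, the screened factor with the
    weakest evidence (largest screening p-value) is dropped and the model
    refitted, repeating until the fit is regular.
    """
    group = msaf_group_indicator(patients)
    selected = sorted(screen_factors(patients, group, alpha=alpha),
                      key=lambda fp: fp[1])
    current = list(selected)
    while True:
        try:
            propensity = fit_propensity(patients, current, group)
            break
        except SeparationError:
            if not current:
                raise
            dropped = current.pop()
            warnings.warn(f"propensity model separated; dropping factor "
                          f"{dropped[0]!r} and refitting")
    propensity = np.clip(propensity, 1e-6, 1 - 1e-6)
    return ipw_estimate(patients, propensity, group,
                        selected_factors=current, conf=conf,
                        stabilized=stabilized)
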