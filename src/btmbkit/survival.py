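"""Right-censored survival primitives.

Kaplan–Meier product-limit estimation with Greenwood variance,
Brookmeyer–Crowley confidence intervals for the median, log-rank
comparison, Cox proportional-hazards estimation for a binary covariate
(Newton's method with Efron tie handling), and Schoenfeld's approximation
for log-rank power.

All estimators are written from first principles over explicit risk sets;
they are the reporting conventions of a biomarker-stratified trial:
survival times in months, hazard ratios oriented so that values below 1
favor the first-listed group, Wald intervals on the log-hazard scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier estimate over the distinct event times.

    ``greenwood_var`` is the variance of S(t) itself (plain scale):
    S(t)^2 * sum d_j / (n_j (n_j - d_j)). ``max_follow_up`` is the largest
    observed time (event or censoring).
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    max_follow_up: float
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])


class MedianCI(NamedTuple):
    median: Optional[float]   # None = not estimable
    ci_low: Optional[float]
    ci_high: Optional[float]


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    conf: float
    converged: bool
    monotone: bool = False    # no events in a group: likelihood unbounded
    n_iter: int = 0


def _as_arrays(times, events, weights=None):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d and equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    w = (np.ones_like(t) if weights is None
         else np.asarray(weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return t, e, w


def km_fit(times, events, weights=None) -> SurvivalCurve:
    """Product-limit estimator.

    Censored observations at an event time leave the risk set after the
    events at that time (standard convention). With case weights the risk
    set and event counts are weighted sums and the Greenwood accumulation
    uses the weighted counts (an approximation whose variance is exact in
    the unweighted case).
    """
    t, e, w = _as_arrays(times, events, weights)
    order = np.argsort(t, kind="stable")
    t, e, w = t[order], e[order], w[order]
    total_w = w.sum()
    distinct = np.unique(t[e])
    surv = 1.0
    gw_acc = 0.0
    out_t, out_n, out_d, out_s, out_v = [], [], [], [], []
    for tt in distinct:
        at_risk = w[t >= tt].sum()
        d = w[(t == tt) & e].sum()
        if at_risk <= 0:
            continue
        surv *= 1.0 - d / at_risk
        if at_risk > d:
            gw_acc += d / (at_risk * (at_risk - d))
        else:
            gw_acc = np.inf
        out_t.append(tt)
        out_n.append(at_risk)
        out_d.append(d)
        out_s.append(surv)
        out_v.append(surv * surv * gw_acc if np.isfinite(gw_acc) else 0.0)
    return SurvivalCurve(
        event_times=np.array(out_t), n_at_risk=np.array(out_n),
        n_events=np.array(out_d), survival=np.array(out_s),
        greenwood_var=np.array(out_v), max_follow_up=float(t.max()),
        n_total=int(t.size))


def km_median_ci(curve: SurvivalCurve, conf: float = 0.95) -> MedianCI:
    """Median survival with a Brookmeyer–Crowley confidence interval.

    The median is the first event time where S(t) <= 0.5. The interval is
    the hull of event times t where (S(t) - 0.5)^2 / Var[S(t)] does not
    exceed the chi-square(1) critical value; a side with no bounding event
    time within follow-up is reported as not estimable (None).
    """
    if curve.event_times.size == 0:
        return MedianCI(None, None, None)
    below = np.nonzero(curve.survival <= 0.5)[0]
    median = float(curve.event_times[below[0]]) if below.size else None
    crit = sps.chi2.ppf(conf, df=1)
    s, v = curve.survival, curve.greenwood_var
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(v > 0, (s - 0.5) ** 2 / np.where(v > 0, v, 1.0),
                        np.where(s == 0.5, 0.0, np.inf))
    ok = np.nonzero(stat <= crit)[0]
    if ok.size == 0:
        return MedianCI(median, None, None)
    lo = float(curve.event_times[ok[0]])
    # upper bound: first event time after the acceptance run where the
    # curve has fallen below 0.5; if the run reaches the last event time,
    # the bound is beyond follow-up
    hi: Optional[float] = None
    if ok[-1] < curve.event_times.size - 1:
        hi = float(curve.event_times[ok[-1] + 1])
    return MedianCI(median, lo, hi)


def greenwood_landmark_ci(curve: SurvivalCurve, landmark: float,
                          conf: float = 0.95,
                          transform: str = "plain") -> ProportionPair:
    """Confidence interval for S(landmark) from the Greenwood variance.

    ``transform='plain'`` uses the normal interval on the survival scale,
    clipped to [0, 1]; ``'loglog'`` uses the complementary log-log scale
    (never escapes [0, 1], preferable near the boundaries).
    """
    if landmark < 0:
        raise ValueError("landmark must be non-negative")
    if landmark > curve.max_follow_up:
        raise ValueError(
            f"landmark {landmark} beyond last follow-up "
            f"{curve.max_follow_up}")
    s = curve.survival_at(landmark)
    v = curve.variance_at(landmark)
    z = sps.norm.ppf(0.5 + conf / 2)
    if v <= 0:
        return ProportionPair(s, s, s)
    if transform == "plain":
        half = z * np.sqrt(v)
        return ProportionPair(s, max(0.0, s - half), min(1.0, s + half))
    if transform == "loglog":
        if s <= 0 or s >= 1:
            return ProportionPair(s, s, s)
        se_ll = np.sqrt(v) / (s * abs(np.log(s)))
        lo = s ** np.exp(z * se_ll)
        hi = s ** np.exp(-z * se_ll)
        return ProportionPair(s, float(lo), float(hi))
    raise ValueError(f"unknown transform {transform!r}")


class ProportionPair(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


def logrank_test(times1, events1, times2, events2) -> tuple[float, float]:
    """Unweighted two-group log-rank test.

    Returns the chi-square statistic (1 df) and two-sided p-value.
    """
    t1, e1, _ = _as_arrays(times1, events1)
    t2, e2, _ = _as_arrays(times2, events2)
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(t1.size, bool), np.ones(t2.size, bool)])
    if not e.any():
        warnings.warn("no events in either group; log-rank undefined")
        return 0.0, 1.0
    obs_minus_exp = 0.0
    var = 0.0
    for tt in np.unique(t[e]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & ~g).sum()
        d = (e & (t == tt)).sum()
        d1 = (e & (t == tt) & ~g).sum()
        if n <= 1:
            continue
        obs_minus_exp += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    stat = obs_minus_exp ** 2 / var
    return float(stat), float(sps.chi2.sf(stat, df=1))


def _cox_loglik_derivs(beta: float, t, e, x, w, ties: str):
    """Log partial likelihood with first and second derivatives.

    Efron tie handling on unweighted data; case weights use the Breslow
    form (the convention for inverse-probability-weighted fits).
    """
    eta = beta * x
    r = w * np.exp(eta)
    loglik = dU = dI = 0.0
    for tt in np.unique(t[e]):
        fail = e & (t == tt)
        at_risk = t >= tt
        d = int(fail.sum())
        s0_r = r[at_risk].sum()
        s1_r = (r[at_risk] * x[at_risk]).sum()
        s2_r = (r[at_risk] * x[at_risk] ** 2).sum()
        if ties == "efron" and d > 1:
            s0_d = r[fail].sum()
            s1_d = (r[fail] * x[fail]).sum()
            s2_d = (r[fail] * x[fail] ** 2).sum()
            loglik += (w[fail] * eta[fail]).sum()
            for l in range(d):
                f = l / d
                s0 = s0_r - f * s0_d
                s1 = s1_r - f * s1_d
                s2 = s2_r - f * s2_d
                loglik -= np.log(s0)
                dU -= s1 / s0
                dI += s2 / s0 - (s1 / s0) ** 2
            dU += (w[fail] * x[fail]).sum()
        else:  # Breslow (also the single-event case, where both agree)
            loglik += (w[fail] * eta[fail]).sum() - w[fail].sum() * np.log(s0_r)
            dU += (w[fail] * x[fail]).sum() - w[fail].sum() * s1_r / s0_r
            dI += w[fail].sum() * (s2_r / s0_r - (s1_r / s0_r) ** 2)
    return loglik, dU, dI


def cox_hr(times, events, group, conf: float = 0.90,
           ties: str = "efron", weights=None, max_iter: int = 60,
           tol: float = 1e-10) -> CoxResult:
    """Hazard ratio for a binary group indicator from the Cox partial
    likelihood, maximized by Newton's method.

    ``group`` = 1 is the first-listed (e.g. biomarker-high) group, so the
    returned hazard ratio is high-versus-low and values below 1 favor the
    high group. The Wald interval is on the log scale at level ``conf``
    (trial convention: 90%). A group with no events gives a monotone
    likelihood; the fit is flagged and the interval unbounded.
    """
    t, e, w = _as_arrays(times, events, weights)
    x = np.asarray(group, dtype=float)
    if x.shape != t.shape:
        raise ValueError("group must match times in length")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")
    if weights is not None:
        ties = "breslow"  # weighted fits use the Breslow form
    events_high = e[x == 1].sum()
    events_low = e[x == 0].sum()
    monotone = (e.sum() > 0) and (events_high == 0 or events_low == 0)

    beta = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, u, i_info = _cox_loglik_derivs(beta, t, e, x, w, ties)
        if i_info <= 0:
            break
        step = u / i_info
        step = np.clip(step, -2.0, 2.0)  # damp early oversized steps
        beta += step
        if abs(step) < tol or abs(u) < 1e-12:
            converged = True
            break
        if abs(beta) > 20:  # drifting to +-inf: monotone likelihood
            monotone = True
            break
    if monotone:
        warnings.warn("monotone partial likelihood (no events in a group); "
                      "hazard ratio unbounded")
        hr = float(np.exp(np.clip(beta, -20, 20)))
        return CoxResult(hr, 0.0, np.inf, 1.0, beta, np.inf, conf,
                         converged=False, monotone=True, n_iter=it)
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last beta={beta:.4g})")
    _, _, i_info = _cox_loglik_derivs(beta, t, e, x, w, ties)
    se = float(1.0 / np.sqrt(i_info))
    z = sps.norm.ppf(0.5 + conf / 2)
    p = float(2 * sps.norm.sf(abs(beta) / se))
    return CoxResult(float(np.exp(beta)), float(np.exp(beta - z * se)),
                     float(np.exp(beta + z * se)), p, float(beta), se,
                     conf, converged=True, n_iter=it)


def logrank_power(n: int, prevalence_high: float, hr: float,
                  alpha_two_sided: float = 0.10,
                  event_fraction: float = 0.87) -> float:
    """Power of the two-group log-rank test by Schoenfeld's formula.

    With d = n * event_fraction expected events and group prevalence p,
    power = Phi(sqrt(d p (1-p)) |log hr| - z_{1-alpha/2}).
    """
    if not 0 < prevalence_high < 1:
        raise ValueError("prevalence_high must be in (0, 1)")
    if hr <= 0:
        raise ValueError("hr must be positive")
    d = n * event_fraction
    z = sps.norm.ppf(1 - alpha_two_sided / 2)
    return float(sps.norm.cdf(
        np.sqrt(d * prevalence_high * (1 - prevalence_high))
        * abs(np.log(hr)) - z))
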