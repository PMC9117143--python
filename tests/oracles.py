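"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or naive
definition-level arithmetic, deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_btmb(variants, af_min=0.005, msaf_threshold=0.01,
                     band=0.05):
    """Definition-level burden scoring: returns (msaf, score or None).

    A variant is germline if flagged in a population DB or its AF is
    within ``band`` of 0.5 or 1.0; MSAF is the max AF over somatic SNVs
    below 0.20; the score counts distinct somatic non-driver SNV keys with
    AF >= af_min, masked when MSAF < threshold.
    """
    def is_germline(v):
        return (v.in_population_db
                or abs(v.allele_frequency - 0.5) <= band
                or abs(v.allele_frequency - 1.0) <= band)

    somatic = [v for v in variants if not is_germline(v)]
    msaf_afs = [v.allele_frequency for v in somatic
                if v.variant_class == "SNV" and v.allele_frequency < 0.20]
    msaf = max(msaf_afs) if msaf_afs else 0.0
    keys = {(v.position, v.ref, v.alt) for v in somatic
            if v.variant_class == "SNV" and not v.is_known_driver
            and v.allele_frequency >= af_min}
    if msaf < msaf_threshold:
        return msaf, None
    return msaf, len(keys)


def brute_force_km(times, events):
    """Product-limit estimate by direct risk-set enumeration.

    Returns (event_times, survival) over distinct event times.
    """
    times = list(map(float, times))
    events = list(map(bool, events))
    distinct = sorted({t for t, e in zip(times, events) if e})
    surv = 1.0
    out_t, out_s = [], []
    for tt in distinct:
        n_risk = sum(1 for t in times if t >= tt)
        d = sum(1 for t, e in zip(times, events) if e and t == tt)
        surv *= (n_risk - d) / n_risk
        out_t.append(tt)
        out_s.append(surv)
    return out_t, out_s


def logrank_chi2_stat(times, events, labels):
    """Standardized log-rank statistic by direct risk-set enumeration."""
    o_minus_e = 0.0
    var = 0.0
    for tt in sorted({t for t, e in zip(times, events) if e}):
        n = sum(1 for t in times if t >= tt)
        n1 = sum(1 for t, g in zip(times, labels) if t >= tt and g == 1)
        d = sum(1 for t, e in zip(times, events) if e and t == tt)
        d1 = sum(1 for t, e, g in zip(times, events, labels)
                 if e and t == tt and g == 1)
        if n <= 1:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var if var > 0 else 0.0


def permutation_logrank_p(times1, events1, times2, events2,
                          statistic=None):
    """Exact permutation p-value for the log-rank comparison.

    Enumerates every assignment of group labels of the observed sizes to
    the pooled observations; p is the fraction of assignments whose
    statistic is at least the observed one. ``statistic`` defaults to the
    enumeration-based standardized statistic.
    """
    if statistic is None:
        statistic = logrank_chi2_stat
    times = list(times1) + list(times2)
    events = list(events1) + list(events2)
    n1 = len(times1)
    n = len(times)
    obs = statistic(times, events, [1] * n1 + [0] * (n - n1))
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        labels = [0] * n
        for i in idx:
            labels[i] = 1
        total += 1
        if statistic(times, events, labels) >= obs - 1e-12:
            count += 1
    return count / total


def grid_cox_loglik(beta, times, events, group):
    """Breslow/Efron-free partial log-likelihood for untied data."""
    ll = 0.0
    for tt in sorted({t for t, e in zip(times, events) if e}):
        xi = [g for t, e, g in zip(times, events, group) if e and t == tt]
        assert len(xi) == 1, "oracle requires untied event times"
        risk = [g for t, g in zip(times, group) if t >= tt]
        ll += beta * xi[0] - math.log(sum(math.exp(beta * g) for g in risk))
    return ll


def golden_section_cox(times, events, group, lo=-5.0, hi=5.0, tol=1e-10):
    """Maximize the untied Cox partial likelihood by golden-section search."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc = grid_cox_loglik(c, times, events, group)
    fd = grid_cox_loglik(d, times, events, group)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = grid_cox_loglik(c, times, events, group)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = grid_cox_loglik(d, times, events, group)
    return (a + b) / 2


def bh_step_up(p_values):
    """Benjamini–Hochberg adjusted p-values by the direct step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def fisher_two_sided_p(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric point-mass enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))
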