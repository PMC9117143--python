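"""Biomarker cutoff sweep.

Re-computes the per-cutoff efficacy comparison (group sizes, response
rates, PFS/OS hazard ratios and log-rank p-values, medians) over a grid of
burden-score cutoffs. Hazard ratios are oriented high-versus-low: values
below 1 favor the high-burden group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import PatientRecord
from .stats import ProportionCI, blaker_ci
from .survival import CoxResult, MedianCI, cox_hr, km_fit, km_median_ci, logrank_test

DEFAULT_CUTOFFS = (10, 12, 14, 16, 18, 20)


@dataclass(frozen=True)
class CutoffSweepRow:
    cutoff: int
    n_high: int
    n_low: int
    orr_high: Optional[ProportionCI]
    orr_low: Optional[ProportionCI]
    pfs_hr: Optional[CoxResult]
    pfs_logrank_p: Optional[float]
    os_hr: Optional[CoxResult]
    os_logrank_p: Optional[float]
    median_pfs_high: Optional[MedianCI]
    median_pfs_low: Optional[MedianCI]
    median_os_high: Optional[MedianCI]
    median_os_low: Optional[MedianCI]
    estimable: bool = True


def _endpoint(patients, attr_time, attr_event, high_mask, conf):
    times = np.array([getattr(p, attr_time) for p in patients])
    events = np.array([getattr(p, attr_event) for p in patients])
    hr = cox_hr(times, events, high_mask.astype(float), conf=conf)
    _, p = logrank_test(times[high_mask], events[high_mask],
                        times[~high_mask], events[~high_mask])
    med_hi = km_median_ci(km_fit(times[high_mask], events[high_mask]))
    med_lo = km_median_ci(km_fit(times[~high_mask], events[~high_mask]))
    return hr, p, med_hi, med_lo


def sweep(patients: Sequence[PatientRecord],
          cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
          conf_surv: float = 0.90,
          conf_orr: float = 0.95) -> list[CutoffSweepRow]:
    """One row of stratified efficacy statistics per cutoff.

    Non-evaluable patients (no reportable score) are excluded from every
    row. A cutoff that leaves one group empty is flagged not estimable.
    """
    evaluable = [p for p in patients if p.btmb_score is not None]
    rows = []
    for cutoff in cutoffs:
        high = np.array([p.btmb_score >= cutoff for p in evaluable])
        n_high, n_low = int(high.sum()), int((~high).sum())
        if n_high == 0 or n_low == 0:
            rows.append(CutoffSweepRow(
                cutoff=cutoff, n_high=n_high, n_low=n_low, orr_high=None,
                orr_low=None, pfs_hr=None, pfs_logrank_p=None, os_hr=None,
                os_logrank_p=None, median_pfs_high=None, median_pfs_low=None,
                median_os_high=None, median_os_low=None, estimable=False))
            continue
        resp = np.array([p.confirmed_responder for p in evaluable])
        orr_high = blaker_ci(int(resp[high].sum()), n_high, conf_orr)
        orr_low = blaker_ci(int(resp[~high].sum()), n_low, conf_orr)
        pfs_hr, pfs_p, mph, mpl = _endpoint(
            evaluable, "pfs_time", "pfs_event", high, conf_surv)
        os_hr, os_p, moh, mol = _endpoint(
            evaluable, "os_time", "os_event", high, conf_surv)
        rows.append(CutoffSweepRow(
            cutoff=cutoff, n_high=n_high, n_low=n_low,
            orr_high=orr_high, orr_low=orr_low,
            pfs_hr=pfs_hr, pfs_logrank_p=pfs_p,
            os_hr=os_hr, os_logrank_p=os_p,
            median_pfs_high=mph, median_pfs_low=mpl,
            median_os_high=moh, median_os_low=mol))
    return rows


def sweep_table(rows: Sequence[CutoffSweepRow]) -> pd.DataFrame:
    """Flatten sweep rows for TSV export."""
    out = []
    for r in rows:
        rec = {"cutoff": r.cutoff, "n_high": r.n_high, "n_low": r.n_low}
        if r.estimable:
            rec.update({
                "orr_high_pct": 100 * r.orr_high.estimate,
                "orr_low_pct": 100 * r.orr_low.estimate,
                "pfs_hr": r.pfs_hr.hazard_ratio,
                "pfs_hr_lo": r.pfs_hr.ci_low, "pfs_hr_hi": r.pfs_hr.ci_high,
                "pfs_logrank_p": r.pfs_logrank_p,
                "os_hr": r.os_hr.hazard_ratio,
                "os_hr_lo": r.os_hr.ci_low, "os_hr_hi": r.os_hr.ci_high,
                "os_logrank_p": r.os_logrank_p,
                "median_pfs_high": r.median_pfs_high.median,
                "median_pfs_low": r.median_pfs_low.median,
                "median_os_high": r.median_os_high.median,
                "median_os_low": r.median_os_low.median,
            })
        out.append(rec)
    return pd.DataFrame(out)
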