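"""Synthetic trial generator.

Generates complete single-arm cohorts — baseline covariates, ctDNA variant
profiles over the capture panel, and burden-dependent outcomes — standing
in for access-controlled patient-level trial data. The defaults emulate a
~152-patient first-line NSCLC immunotherapy cohort: ~78% of samples have
adequate ctDNA (MSAF >= 1%), ~24% of evaluable samples have a burden score
>= 16, response probability and PFS/OS hazards depend on the burden group,
and the MSAF subgroups differ in baseline prognostics (age, smoking, PD-L1,
lesion count, tumor size).

The burden-score distribution is log-normal, discretized to integers, with
its location set by quantile matching so that the configured high-score
fraction lands at the >= 16 cutoff. Survival is exponential (constant
hazard) by default for analytic tractability of parameter-recovery tests;
Weibull shapes are available. Administrative censoring reflects uniform
accrual followed by a fixed data cut.

A second generator plants pure confounding: MSAF-group membership and
outcomes both depend on baseline covariates, while MSAF itself has no
effect — the dataset on which a correct IPW analysis must drive the
adjusted group effect toward null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as sps

from .io import PatientRecord, VariantCall, write_clinical_table, write_variant_table
from .panel import PanelDefinition, default_panel

_BASES = "ACGT"
_LOGIT = sps.logistic.ppf
_INVLOGIT = sps.logistic.cdf


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Anchors: evaluability 0.78, high-score fraction 0.24 at cutoff 16,
    response rates 35.7% / 5.5% / 37.9% (high / low / non-evaluable),
    PFS median 3.5 months in the low group with hazard ratio 0.80 for the
    high group and 0.62 for the non-evaluable (low-ctDNA) group, OS median
    13.4 months with hazard ratio 0.66, uniform 18-month accrual with a
    data cut at 36.5 months, and 36% missing PD-L1.
    """

    n_patients: int = 152
    prob_evaluable: float = 0.78
    prob_high_given_evaluable: float = 0.24
    outcome_cutoff: int = 16
    btmb_sigma: float = 0.9          # log-scale spread of the score

    # response model (per realized burden group)
    orr_high: float = 0.357
    orr_low: float = 0.055
    orr_non_evaluable: float = 0.379

    # survival models: exponential baseline (weibull_shape = 1)
    pfs_median_low: float = 3.5
    pfs_hr_high: float = 0.80
    pfs_hr_non_evaluable: float = 0.62
    pfs_score_log_hr: Optional[float] = None   # per-score-unit log-HR mode
    os_median_low: float = 13.4
    os_hr_high: float = 0.66
    os_hr_non_evaluable: float = 0.80
    weibull_shape: float = 1.0
    accrual_months: float = 18.0
    max_follow_up: float = 36.5
    dropout_hazard: float = 0.005    # per month, non-administrative censoring

    # covariate models (MSAF < 1% group vs MSAF >= 1% group)
    age_mean: tuple = (65.0, 70.0)
    age_sd: float = 9.0
    smoking_current: tuple = (0.14, 0.25)
    smoking_never: tuple = (0.12, 0.06)
    pdl1_positive: tuple = (0.52, 0.38)
    pdl1_missing: float = 0.36
    lesions_mean: tuple = (1.8, 2.4)
    sld_median: tuple = (42.4, 70.0)
    sld_sigma: float = 0.55
    squamous_by_group: dict = field(default_factory=lambda: {
        "high": 0.46, "low": 0.24, "non_evaluable": 0.28})
    prob_male: float = 0.60

    # ctDNA variant model
    af_min: float = 0.005
    msaf_log_mean: float = -3.2      # evaluable MSAF ~ lognormal, clipped
    msaf_log_sd: float = 0.8
    germline_count_mean: float = 30.0
    germline_db_frac: float = 0.90
    germline_hom_frac: float = 0.10
    driver_prob: float = 0.50
    indel_frac: float = 0.10
    prob_zero_somatic: float = 0.15  # non-evaluable samples with no ctDNA
    enriched_gene_probs: dict = field(default_factory=lambda: {
        "TP53": (0.80, 0.40), "LRP1B": (0.45, 0.25), "CDKN2A": (0.30, 0.15)})

    # confounded-MSAF generator
    confounding_strength: float = 1.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        probs = [self.prob_evaluable, self.prob_high_given_evaluable,
                 self.orr_high, self.orr_low, self.orr_non_evaluable,
                 self.pdl1_missing, self.prob_male]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.prob_evaluable == 0 and self.prob_high_given_evaluable > 0:
            raise ValueError(
                "prob_evaluable = 0 is inconsistent with a positive "
                "high-score target")
        if min(self.pfs_median_low, self.os_median_low) <= 0:
            raise ValueError("survival medians must be positive")
        if min(self.pfs_hr_high, self.os_hr_high,
               self.pfs_hr_non_evaluable, self.os_hr_non_evaluable) <= 0:
            raise ValueError("hazard ratios must be positive")


def btmb_lognormal_params(config: SimulationConfig) -> tuple[float, float]:
    """Quantile-match the score distribution to the high-score anchor.

    Scores are round(lognormal), so P(score >= c) = P(X >= c - 0.5); the
    log-mean is set so that this equals ``prob_high_given_evaluable`` at
    the outcome cutoff.
    """
    z = sps.norm.ppf(1 - config.prob_high_given_evaluable)
    mu = np.log(config.outcome_cutoff - 0.5) - z * config.btmb_sigma
    return mu, config.btmb_sigma


def _draw_scores(rng, config, size):
    mu, sigma = btmb_lognormal_params(config)
    return np.maximum(np.round(rng.lognormal(mu, sigma, size)), 0).astype(int)


def _survival_time(rng, median_ref, multiplier, shape):
    # scale chosen so the reference (multiplier = 1) median is median_ref
    scale = median_ref / np.log(2) ** (1 / shape)
    u = rng.uniform()
    # inverse CDF of Weibull with hazard multiplied by `multiplier`
    return scale * (-np.log(u) / multiplier) ** (1 / shape)


def _censoring(rng, config):
    admin = config.max_follow_up - rng.uniform(0, config.accrual_months)
    if config.dropout_hazard > 0:
        return min(admin, rng.exponential(1 / config.dropout_hazard))
    return admin


def _covariates(rng, config, low_msaf: bool, btmb_group: str):
    gi = 0 if low_msaf else 1
    age = float(np.clip(rng.normal(config.age_mean[gi], config.age_sd),
                        30, 92))
    u = rng.uniform()
    if u < config.smoking_current[gi]:
        smoking = "current"
    elif u < config.smoking_current[gi] + config.smoking_never[gi]:
        smoking = "never"
    else:
        smoking = "former"
    if rng.uniform() < config.pdl1_missing:
        pdl1 = "missing"
    else:
        p_pos = config.pdl1_positive[gi] / (1 - config.pdl1_missing)
        pdl1 = "positive" if rng.uniform() < min(p_pos, 1.0) else "negative"
    lesions = 1 + rng.poisson(max(config.lesions_mean[gi] - 1, 0.0))
    sld = float(rng.lognormal(np.log(config.sld_median[gi]),
                              config.sld_sigma))
    squamous = rng.uniform() < config.squamous_by_group[btmb_group]
    sex = "male" if rng.uniform() < config.prob_male else "female"
    return dict(age=age, sex=sex, smoking=smoking,
                histology="squamous" if squamous else "non-squamous",
                pdl1_status=pdl1, sld_mm=sld, n_target_lesions=int(lesions))


def _outcomes(rng, config, btmb_group: str, score: Optional[int]):
    if btmb_group == "high":
        p_resp, pfs_mult, os_mult = (config.orr_high, config.pfs_hr_high,
                                     config.os_hr_high)
    elif btmb_group == "low":
        p_resp, pfs_mult, os_mult = config.orr_low, 1.0, 1.0
    else:
        p_resp = config.orr_non_evaluable
        pfs_mult = config.pfs_hr_non_evaluable
        os_mult = config.os_hr_non_evaluable
    if config.pfs_score_log_hr is not None and score is not None:
        ref = np.exp(btmb_lognormal_params(config)[0])  # median score
        pfs_mult = float(np.exp(config.pfs_score_log_hr * (score - ref)))
    responder = rng.uniform() < p_resp
    t_pfs = _survival_time(rng, config.pfs_median_low, pfs_mult,
                           config.weibull_shape)
    t_os = _survival_time(rng, config.os_median_low, os_mult,
                          config.weibull_shape)
    c = _censoring(rng, config)
    return dict(
        confirmed_responder=bool(responder),
        pfs_time=float(min(t_pfs, c)), pfs_event=bool(t_pfs <= c),
        os_time=float(min(t_os, c)), os_event=bool(t_os <= c))


def _sample_variants(rng, config, panel: PanelDefinition, sample_id: str,
                     msaf: float, n_somatic: int, btmb_group: str,
                     evaluable: bool) -> list[VariantCall]:
    genes = sorted(panel.genes)
    drivers = sorted(panel.driver_set)
    calls: list[VariantCall] = []
    pos_counter = iter(range(1_000_000, 9_000_000))

    def _snv_bases():
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        return ref, alt

    def _add(gene, af, vclass="SNV", driver=False, in_db=False):
        pos = next(pos_counter)
        if vclass == "SNV":
            ref, alt = _snv_bases()
        elif vclass == "insertion":
            ref, alt = "A", "AT"
        else:
            ref, alt = "AT", "A"
        calls.append(VariantCall(
            sample_id=sample_id, gene=gene, position=pos, ref=ref, alt=alt,
            variant_class=vclass, allele_frequency=float(af),
            in_population_db=in_db, is_known_driver=driver))

    # somatic passengers: one anchor at the MSAF, the rest below it
    if msaf > 0 and n_somatic > 0:
        lo = config.af_min if evaluable else 0.2 * msaf
        lo = min(lo, msaf)
        afs = [msaf] + list(rng.uniform(lo, msaf, n_somatic - 1))
        gene_idx = rng.integers(0, len(genes), n_somatic)
        passengers = list(zip(gene_idx, afs))
        # plant gene-level enrichment by relabelling passenger genes
        planted = []
        for gene, (p_high, p_low) in config.enriched_gene_probs.items():
            prob = p_high if btmb_group == "high" else p_low
            if rng.uniform() < prob:
                planted.append(gene)
        for j, (gi, af) in enumerate(passengers):
            gene = planted[j] if j < len(planted) else genes[int(gi)]
            _add(gene, af)
        # known drivers: counted for MSAF, excluded from the score
        if drivers and msaf >= config.af_min and (
                rng.uniform() < config.driver_prob):
            dg, _ = drivers[rng.integers(len(drivers))]
            _add(dg, rng.uniform(config.af_min, msaf), driver=True)
        # indels: never counted
        for _ in range(rng.poisson(config.indel_frac * n_somatic)):
            vclass = "insertion" if rng.uniform() < 0.5 else "deletion"
            _add(genes[rng.integers(len(genes))],
                 rng.uniform(lo, msaf), vclass=vclass)
    # germline background near heterozygous/homozygous fractions
    for _ in range(rng.poisson(config.germline_count_mean)):
        if rng.uniform() < config.germline_hom_frac:
            af = float(np.clip(rng.normal(0.98, 0.01), 0.955, 1.0))
        else:
            af = float(np.clip(rng.normal(0.5, 0.02), 0.46, 0.54))
        _add(genes[rng.integers(len(genes))], af,
             in_db=bool(rng.uniform() < config.germline_db_frac))
    return calls


def simulate_cohort(config: SimulationConfig = SimulationConfig(),
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    panel: Optional[PanelDefinition] = None,
                    include_variants: bool = True,
                    ) -> tuple[list[PatientRecord], list[VariantCall]]:
    """Draw one complete synthetic cohort.

    Returns patient records (with realized MSAF and, for evaluable
    samples, the intended burden score) and, unless ``include_variants``
    is False, the per-sample variant calls whose scoring reproduces those
    intended values.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    if panel is None:
        panel = default_panel()
    records: list[PatientRecord] = []
    variants: list[VariantCall] = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        evaluable = rng.uniform() < config.prob_evaluable
        score = int(_draw_scores(rng, config, 1)[0])
        if evaluable:
            msaf = float(np.clip(
                np.exp(rng.normal(config.msaf_log_mean, config.msaf_log_sd)),
                0.010, 0.199))
            n_somatic = score
            group = ("high" if score >= config.outcome_cutoff else "low")
        else:
            if rng.uniform() < config.prob_zero_somatic:
                msaf, n_somatic = 0.0, 0
            else:
                msaf = float(rng.uniform(0.001, 0.0095))
                n_somatic = 1 + int(rng.poisson(2))
            group = "non_evaluable"
        cov = _covariates(rng, config, low_msaf=not evaluable,
                          btmb_group=group)
        out = _outcomes(rng, config, group,
                        score if evaluable else None)
        records.append(PatientRecord(
            id=pid, msaf=msaf,
            btmb_score=score if evaluable else None, **cov, **out))
        if include_variants:
            variants.extend(_sample_variants(
                rng, config, panel, pid, msaf, n_somatic, group, evaluable))
    return records, variants


def simulate_confounded_msaf(config: SimulationConfig = SimulationConfig(),
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None,
                             ) -> list[PatientRecord]:
    """Cohort with planted confounding and no MSAF effect.

    Baseline prognostics (younger age, smaller tumor burden, fewer
    lesions, non-smoking, PD-L1 positivity) drive both the probability of
    being in the MSAF < 1% group and the outcomes; MSAF itself has no
    effect. With ``confounding_strength`` = 0 there is no signal at all.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    s = config.confounding_strength
    n = config.n_patients
    age = np.clip(rng.normal(68, 9, n), 30, 92)
    sld = rng.lognormal(np.log(57.0), 0.6, n)
    lesions = 1 + rng.poisson(1.2, n)
    current = rng.uniform(size=n) < 0.22
    never = ~current & (rng.uniform(size=n) < 0.10)
    pdl1_u = rng.uniform(size=n)
    pdl1 = np.where(pdl1_u < config.pdl1_missing, "missing",
                    np.where(pdl1_u < config.pdl1_missing + 0.42 * (
                        1 - config.pdl1_missing), "positive", "negative"))
    squamous = rng.uniform(size=n) < 0.28
    male = rng.uniform(size=n) < config.prob_male

    # standardized on the raw measurement scales (the scales on which a
    # propensity model would enter these factors)
    z_age = (age - 68) / 9
    z_sld = (sld - 68.0) / 45.0
    z_les = (lesions - 2.2) / 1.1
    prognosis = (-0.35 * z_age - 0.45 * z_sld - 0.35 * z_les
                 - 0.30 * current + 0.30 * (pdl1 == "positive"))

    p_low_msaf = _INVLOGIT(_LOGIT(0.13) + 2.2 * s * prognosis)
    low_msaf = rng.uniform(size=n) < p_low_msaf
    p_resp = _INVLOGIT(_LOGIT(0.15) + 2.0 * s * prognosis)
    responder = rng.uniform(size=n) < p_resp

    records = []
    for i in range(n):
        msaf = (float(rng.uniform(0.0005, 0.0095)) if low_msaf[i]
                else float(rng.uniform(0.011, 0.19)))
        score = (None if low_msaf[i]
                 else int(_draw_scores(rng, config, 1)[0]))
        pfs_mult = float(np.exp(-0.5 * s * prognosis[i]))
        os_mult = float(np.exp(-0.4 * s * prognosis[i]))
        t_pfs = _survival_time(rng, 4.0, pfs_mult, 1.0)
        t_os = _survival_time(rng, 14.0, os_mult, 1.0)
        c = _censoring(rng, config)
        smoking = ("current" if current[i]
                   else "never" if never[i] else "former")
        records.append(PatientRecord(
            id=f"P{i + 1:04d}", age=float(age[i]),
            sex="male" if male[i] else "female", smoking=smoking,
            histology="squamous" if squamous[i] else "non-squamous",
            pdl1_status=str(pdl1[i]), sld_mm=float(sld[i]),
            n_target_lesions=int(lesions[i]),
            confirmed_responder=bool(responder[i]),
            pfs_time=float(min(t_pfs, c)), pfs_event=bool(t_pfs <= c),
            os_time=float(min(t_os, c)), os_event=bool(t_os <= c),
            msaf=msaf, btmb_score=score))
    return records


def write_cohort(records, variants, outdir) -> tuple[Path, Path]:
    """Write the clinical CSV and variant TSV consumed by the CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clinical = outdir / "clinical.csv"
    table = outdir / "variants.tsv"
    write_clinical_table(records, clinical)
    write_variant_table(variants, table)
    return clinical, table
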