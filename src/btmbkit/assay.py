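"""Blood tumor mutational burden (bTMB) scoring.

The score for one plasma sample is the number of distinct somatic
single-nucleotide substitutions on the panel at allele frequency >= 0.5%,
after germline filtering and removal of known driver alterations. Tumor
content is summarized by the maximum somatic allele frequency (MSAF): the
highest allele fraction among somatic base substitutions below 20%,
regardless of driver status. Samples with MSAF below 1% are not evaluable
— the assay's sensitivity is inadequate at that ctDNA fraction — and their
score is masked.

Germline status is assigned by a surrogate rule (population-database
membership, or allele frequency within a configurable band of 0.5 or 1.0)
standing in for a full somatic-germline-zygosity classifier, which requires
read-level data this package does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .io import VariantCall
from .panel import PanelDefinition

DEFAULT_AF_MIN = 0.005       # validated lower AF bound for counted SNVs
DEFAULT_MSAF_THRESHOLD = 0.01
DEFAULT_MSAF_CAP = 0.20      # substitutions at or above this AF never set MSAF
DEFAULT_GERMLINE_BAND = 0.05
DEFAULT_CUTOFF = 16


@dataclass(frozen=True)
class BtmbResult:
    """Per-sample burden result.

    ``btmb_score`` is None (not reportable) when the sample is not
    evaluable; ``counted_variant_keys`` lists the distinct
    (position, ref, alt) substitutions that contributed.
    """

    sample_id: str
    msaf: float
    evaluable: bool
    btmb_score: Optional[int]
    mut_per_mb: Optional[float]
    counted_variant_keys: tuple = ()


def classify_germline(variants: Iterable[VariantCall],
                      panel: Optional[PanelDefinition] = None,
                      af_germline_band: float = DEFAULT_GERMLINE_BAND,
                      ) -> list[VariantCall]:
    """Assign ``germline_flag`` to every call.

    A call is germline if it is in a population database (its own flag, or
    key membership in the panel's SNP set), or if its allele frequency lies
    within ``af_germline_band`` of 0.5 or 1.0 — heterozygous and homozygous
    germline fractions in cfDNA, the surrogate zygosity rule. Everything
    else is somatic.
    """
    out = []
    snps = panel.population_snp_set if panel is not None else frozenset()
    for v in variants:
        in_db = v.in_population_db or v.key in snps
        near_het = abs(v.allele_frequency - 0.5) <= af_germline_band
        near_hom = abs(v.allele_frequency - 1.0) <= af_germline_band
        flag = "germline" if (in_db or near_het or near_hom) else "somatic"
        out.append(replace(v, germline_flag=flag))
    return out


def compute_msaf(variants: Iterable[VariantCall],
                 af_cap: float = DEFAULT_MSAF_CAP) -> float:
    """Maximum somatic allele frequency.

    The highest allele fraction over somatic-flagged single-nucleotide
    substitutions strictly below ``af_cap`` (calls at or above the cap are
    assumed clonal-hematopoiesis/germline-like and excluded). Driver status
    does not exclude a call. Returns 0 when no qualifying call exists.
    """
    afs = [v.allele_frequency for v in variants
           if v.germline_flag == "somatic" and v.variant_class == "SNV"
           and v.allele_frequency < af_cap]
    return max(afs, default=0.0)


def compute_btmb(variants: Iterable[VariantCall],
                 panel: PanelDefinition,
                 af_min: float = DEFAULT_AF_MIN,
                 msaf_threshold: float = DEFAULT_MSAF_THRESHOLD,
                 sample_id: Optional[str] = None) -> BtmbResult:
    """Score one sample's variant list.

    Counts distinct (position, ref, alt) keys over somatic SNVs with
    AF >= ``af_min`` that are not known drivers. Indels are never counted.
    If MSAF < ``msaf_threshold`` the sample is non-evaluable and the score
    is masked (None).
    """
    if panel.total_mb <= 0:
        raise ValueError("panel total_mb must be positive")
    variants = list(variants)
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else "sample"
    msaf = compute_msaf(variants)
    keys = sorted({
        v.key for v in variants
        if v.variant_class == "SNV"
        and v.germline_flag == "somatic"
        and v.allele_frequency >= af_min
        and not v.is_known_driver
    })
    if msaf < msaf_threshold:
        return BtmbResult(sample_id=sample_id, msaf=msaf, evaluable=False,
                          btmb_score=None, mut_per_mb=None,
                          counted_variant_keys=tuple(keys))
    score = len(keys)
    return BtmbResult(sample_id=sample_id, msaf=msaf, evaluable=True,
                      btmb_score=score, mut_per_mb=score / panel.total_mb,
                      counted_variant_keys=tuple(keys))


def classify_btmb_group(result: BtmbResult, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Assign 'high', 'low' or 'non_evaluable' at a score cutoff (>= is high)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not result.evaluable or result.btmb_score is None:
        return "non_evaluable"
    return "high" if result.btmb_score >= cutoff else "low"


def score_samples(variants: Iterable[VariantCall],
                  panel: PanelDefinition,
                  af_min: float = DEFAULT_AF_MIN,
                  msaf_threshold: float = DEFAULT_MSAF_THRESHOLD,
                  af_germline_band: float = DEFAULT_GERMLINE_BAND,
                  ) -> list[BtmbResult]:
    """Germline-classify and score every sample present in a variant list."""
    by_sample: dict[str, list[VariantCall]] = {}
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
    results = []
    for sid in sorted(by_sample):
        flagged = classify_germline(by_sample[sid], panel, af_germline_band)
        results.append(compute_btmb(flagged, panel, af_min=af_min,
                                    msaf_threshold=msaf_threshold,
                                    sample_id=sid))
    return results
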