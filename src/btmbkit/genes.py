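"""Gene-level alteration prevalence and association with burden status.

A sample's gene is "altered" if the sample carries at least one
non-synonymous SNV or indel passing read-time filters; germline and driver
filtering is deliberately NOT applied at this stage, mirroring the
exploratory molecularly-evaluable-population (MEP) convention. Genes
mutated in at least ``min_prevalence`` of the MEP are tested for
association with high-burden status (two-sided Fisher exact), with
Benjamini–Hochberg false-discovery-rate adjustment across the retained
genes. No gene-size normalization is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import VariantCall


@dataclass(frozen=True)
class GenePrevalenceRow:
    gene: str
    prevalence_mep: float
    prevalence_high: float
    prevalence_low: float
    p_raw: float
    p_adjusted: float


def altered_gene_sets(variants: Iterable[VariantCall]) -> dict[str, set]:
    """Per-sample set of altered genes (any SNV or indel call)."""
    sets: dict[str, set] = {}
    for v in variants:
        sets.setdefault(v.sample_id, set()).add(v.gene)
    return sets


def prevalence_table(samples: Mapping[str, set],
                     groups: Mapping[str, str],
                     min_prevalence: float = 0.02,
                     ) -> list[GenePrevalenceRow]:
    """Per-gene prevalence in the MEP and Fisher/BH association test.

    ``samples`` maps sample id -> altered gene set; ``groups`` maps sample
    id -> {'high', 'low', 'non_evaluable'}. Non-evaluable samples count in
    the MEP prevalence denominator but are excluded from the high/low
    comparison.
    """
    if not samples:
        raise ValueError("empty sample set")
    ids = sorted(samples)
    bad = {groups[i] for i in ids} - {"high", "low", "non_evaluable"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    high_ids = [i for i in ids if groups[i] == "high"]
    low_ids = [i for i in ids if groups[i] == "low"]
    n_mep, n_high, n_low = len(ids), len(high_ids), len(low_ids)
    all_genes = sorted(set().union(*(samples[i] for i in ids)))

    kept = []
    for gene in all_genes:
        k_mep = sum(gene in samples[i] for i in ids)
        if k_mep / n_mep < min_prevalence:
            continue
        k_high = sum(gene in samples[i] for i in high_ids)
        k_low = sum(gene in samples[i] for i in low_ids)
        _, p = fisher_exact(
            [[k_high, n_high - k_high], [k_low, n_low - k_low]],
            alternative="two-sided")
        kept.append((gene, k_mep / n_mep,
                     k_high / n_high if n_high else float("nan"),
                     k_low / n_low if n_low else float("nan"), float(p)))
    if not kept:
        return []
    _, p_adj, _, _ = multipletests([k[4] for k in kept], method="fdr_bh")
    return [GenePrevalenceRow(g, pm, ph, pl, p, float(pa))
            for (g, pm, ph, pl, p), pa in zip(kept, p_adj)]


def prevalence_frame(rows: Iterable[GenePrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
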