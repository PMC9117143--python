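"""Assay panel definitions.

A hybrid-capture ctDNA panel is described by its gene set, the coding
footprint it captures (in megabases), a list of known driver alterations
(excluded from the mutational-burden count to avoid capture bias), and a set
of population-database SNP keys used for germline filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

# Cancer-panel genes commonly captured by large NSCLC ctDNA assays; used to
# seed the default panel, padded with synthetic placeholder symbols.
_CORE_GENES = [
    "TP53", "KRAS", "EGFR", "ALK", "LRP1B", "CDKN2A", "CDKN2B", "STK11",
    "KEAP1", "BRAF", "MET", "ERBB2", "PIK3CA", "PTEN", "RB1", "NF1",
    "ARID1A", "ARID2", "SMARCA4", "ATM", "BRCA1", "BRCA2", "NOTCH1",
    "FAT1", "FGFR1", "FGFR2", "FGFR3", "NTRK1", "ROS1", "RET", "MYC",
    "MDM2", "CCND1", "CDK4", "CDK6", "APC", "CTNNB1", "SMAD4", "NRAS",
    "HRAS", "IDH1", "IDH2", "KIT", "PDGFRA", "VHL", "MLH1", "MSH2",
    "MSH6", "PMS2", "POLE", "TERT", "STAG2", "SETD2", "KMT2D", "KMT2C",
    "CREBBP", "EP300", "SPTA1", "ZFHX3", "GRIN2A", "RBM10",
]

_DEFAULT_DRIVERS = [
    ("EGFR", "L858R"), ("EGFR", "T790M"), ("EGFR", "E746_A750del"),
    ("KRAS", "G12C"), ("KRAS", "G12D"), ("KRAS", "G12V"),
    ("BRAF", "V600E"), ("PIK3CA", "E545K"), ("PIK3CA", "H1047R"),
    ("MET", "D1228N"), ("ERBB2", "Y772_A775dup"), ("NRAS", "Q61K"),
    ("IDH1", "R132H"), ("CTNNB1", "S45F"), ("TERT", "promoter-124"),
]


@dataclass(frozen=True)
class PanelDefinition:
    """Gene set and coding footprint of a capture panel.

    Attributes
    ----------
    genes : frozenset of str
        Gene symbols captured by the panel.
    total_mb : float
        Coding footprint in megabases; must be positive.
    driver_set : frozenset of (gene, change)
        Known driver alterations, removed from the burden count.
    population_snp_set : frozenset of (position, ref, alt)
        Keys present in population variant databases (dbSNP/ExAC-style
        membership), treated as germline.
    """

    genes: frozenset = field(default_factory=frozenset)
    total_mb: float = 1.1
    driver_set: frozenset = field(default_factory=frozenset)
    population_snp_set: frozenset = field(default_factory=frozenset)
    name: str = "panel"

    def __post_init__(self):
        if self.total_mb <= 0:
            raise ValueError(f"total_mb must be positive, got {self.total_mb}")
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "driver_set",
                           frozenset(tuple(k) for k in self.driver_set))
        object.__setattr__(self, "population_snp_set",
                           frozenset(tuple(k) for k in self.population_snp_set))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def default_panel(n_genes: int = 394, total_mb: float = 1.1) -> PanelDefinition:
    """Build the default 394-gene / 1.1 Mb panel.

    The gene list is synthetic: a core of real cancer-panel symbols padded
    with placeholder symbols (``PNL###``) up to ``n_genes``, since the
    proprietary bait set is not public.
    """
    genes = list(_CORE_GENES[:n_genes])
    i = 1
    while len(genes) < n_genes:
        genes.append(f"PNL{i:03d}")
        i += 1
    return PanelDefinition(
        genes=frozenset(genes),
        total_mb=total_mb,
        driver_set=frozenset(_DEFAULT_DRIVERS),
        name=f"default-{n_genes}gene",
    )


def load_panel(path) -> PanelDefinition:
    """Read a panel definition from a YAML config.

    Expected keys: ``genes`` (list), ``total_mb`` (float), optional
    ``drivers`` (list of "GENE:change"), ``population_snps`` (list of
    "pos:ref:alt"), ``name``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    drivers = frozenset(
        tuple(item.split(":", 1)) for item in cfg.get("drivers", []))
    snps = frozenset()
    if cfg.get("population_snps"):
        parts = [item.split(":") for item in cfg["population_snps"]]
        snps = frozenset((int(p), r, a) for p, r, a in parts)
    return PanelDefinition(
        genes=frozenset(cfg["genes"]),
        total_mb=float(cfg["total_mb"]),
        driver_set=drivers,
        population_snp_set=snps,
        name=cfg.get("name", "panel"),
    )


def save_panel(panel: PanelDefinition, path) -> None:
    cfg = {
        "name": panel.name,
        "total_mb": panel.total_mb,
        "genes": sorted(panel.genes),
        "drivers": sorted(f"{g}:{c}" for g, c in panel.driver_set),
        "population_snps": sorted(
            f"{p}:{r}:{a}" for p, r, a in panel.population_snp_set),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
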