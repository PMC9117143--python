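"""Readers and writers for variant tables, clinical tables and result tables.

Two variant dialects are supported:

* a 9-column TSV (``sample_id gene position ref alt variant_class
  allele_frequency in_population_db is_known_driver``), the package's
  interchange format;
* a VCF v4.x subset: CHROM/POS/REF/ALT plus a configurable INFO key for the
  allele fraction (default ``AF``), ``GENE`` for the gene symbol, the
  standard ``DB`` flag for population-database membership and a ``DRIVER``
  flag for known drivers.

Coordinates are 1-based, fully closed (VCF convention). Allele fractions may
be given as a fraction or with a ``%`` suffix; they are stored as fractions.
"""

from __future__ import annotations

import csv
import warnings

import numpy as np
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .panel import PanelDefinition

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
GERMLINE_FLAGS = ("somatic", "germline", "unknown")

CLINICAL_COLUMNS = [
    "id", "age", "sex", "smoking", "histology", "pdl1_status", "sld_mm",
    "n_target_lesions", "confirmed_response", "pfs_time", "pfs_event",
    "os_time", "os_event",
]


class FormatError(ValueError):
    """A record could not be parsed into the expected schema."""


@dataclass(frozen=True)
class VariantCall:
    """One called alteration in a ctDNA sample."""

    sample_id: str
    gene: str
    position: int
    ref: str
    alt: str
    variant_class: str
    allele_frequency: float
    in_population_db: bool = False
    is_known_driver: bool = False
    germline_flag: str = "unknown"

    def __post_init__(self):
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(
                f"allele_frequency {self.allele_frequency} outside [0, 1] "
                f"for {self.sample_id} {self.gene}:{self.position}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_class == "SNV" and (
                len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError(
                f"SNV at {self.position} must have single-base ref/alt, "
                f"got {self.ref}>{self.alt}")
        if self.germline_flag not in GERMLINE_FLAGS:
            raise ValueError(f"unknown germline_flag {self.germline_flag!r}")

    @property
    def key(self):
        """Distinct-substitution key used for counting."""
        return (self.position, self.ref, self.alt)


@dataclass(frozen=True)
class PatientRecord:
    """Baseline covariates and efficacy outcomes for one patient.

    Times are in months; ``confirmed_responder`` means confirmed complete or
    partial response. ``btmb_score`` is None when the sample was not
    biomarker-evaluable (MSAF below threshold).
    """

    id: str
    age: float
    sex: str
    smoking: str
    histology: str
    pdl1_status: str
    sld_mm: float
    n_target_lesions: int
    confirmed_responder: bool
    pfs_time: float
    pfs_event: bool
    os_time: float
    os_event: bool
    msaf: Optional[float] = None
    btmb_score: Optional[int] = None

    def __post_init__(self):
        if self.pfs_time < 0 or self.os_time < 0:
            raise ValueError(
                f"patient {self.id}: negative survival time "
                f"(pfs={self.pfs_time}, os={self.os_time})")


def _parse_af(text: str) -> float:
    text = str(text).strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def _parse_flag(text) -> bool:
    return str(text).strip().lower() in ("1", "true", "yes", "t")


def _infer_class(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


def _check_gene(call: VariantCall, panel: Optional[PanelDefinition],
                drop_unknown_genes: bool) -> bool:
    """True if the call should be kept."""
    if panel is None or call.gene in panel:
        return True
    if drop_unknown_genes:
        warnings.warn(
            f"dropping {call.gene}:{call.position} — gene not on panel")
        return False
    raise FormatError(
        f"gene {call.gene!r} (sample {call.sample_id}, position "
        f"{call.position}) is not on the panel")


def read_variant_table(path, dialect: str = "tsv", *,
                       panel: Optional[PanelDefinition] = None,
                       af_key: str = "AF",
                       drop_unknown_genes: bool = False) -> list[VariantCall]:
    """Read a variant table in the TSV or VCF dialect.

    When a ``panel`` is given, calls in genes not on the panel raise
    ``FormatError`` (or are dropped with a warning when
    ``drop_unknown_genes`` is set), since the burden score is defined only
    over the panel footprint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        calls = _read_tsv(path)
    elif dialect == "vcf":
        calls = _read_vcf(path, af_key=af_key)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return [c for c in calls if _check_gene(c, panel, drop_unknown_genes)]


def _read_tsv(path: Path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "gene", "position", "ref", "alt",
                    "variant_class", "allele_frequency"}
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header line")
        missing = required - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            if row["allele_frequency"] in (None, ""):
                raise FormatError(f"{path} line {i}: missing allele frequency")
            calls.append(VariantCall(
                sample_id=row["sample_id"],
                gene=row["gene"],
                position=int(row["position"]),
                ref=row["ref"],
                alt=row["alt"],
                variant_class=row["variant_class"],
                allele_frequency=_parse_af(row["allele_frequency"]),
                in_population_db=_parse_flag(row.get("in_population_db", "0")),
                is_known_driver=_parse_flag(row.get("is_known_driver", "0")),
                germline_flag=row.get("germline_flag") or "unknown",
            ))
    return calls


def _read_vcf(path: Path, af_key: str = "AF") -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            gene = info.get("GENE")
            if gene is None:
                raise FormatError(
                    f"{path} position {rec.pos}: missing GENE INFO field")
            alts = rec.alts or ()
            afs = info.get(af_key)
            if afs is None:
                raise FormatError(
                    f"{path} position {rec.pos}: missing {af_key} INFO field")
            if not isinstance(afs, tuple):
                afs = (afs,)
            if len(afs) != len(alts):
                raise FormatError(
                    f"{path} position {rec.pos}: {len(afs)} {af_key} values "
                    f"for {len(alts)} ALT alleles")
            sample_id = sample_names[0] if sample_names else path.stem
            for alt, af in zip(alts, afs):
                # pysam reports INFO floats in single precision; recover the
                # decimal the file carried via the shortest float32 repr
                af64 = float(np.format_float_positional(
                    np.float32(af), unique=True))
                calls.append(VariantCall(
                    sample_id=sample_id,
                    gene=str(gene),
                    position=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    variant_class=_infer_class(rec.ref, alt),
                    allele_frequency=af64,
                    in_population_db=bool(info.get("DB", False)),
                    is_known_driver=bool(info.get("DRIVER", False)),
                ))
    return calls


def write_variant_table(calls: Iterable[VariantCall], path) -> None:
    """Write calls in the 9(+1)-column TSV dialect."""
    cols = ["sample_id", "gene", "position", "ref", "alt", "variant_class",
            "allele_frequency", "in_population_db", "is_known_driver",
            "germline_flag"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for c in calls:
            writer.writerow([
                c.sample_id, c.gene, c.position, c.ref, c.alt,
                c.variant_class, repr(c.allele_frequency),
                int(c.in_population_db), int(c.is_known_driver),
                c.germline_flag,
            ])


def read_clinical_table(path) -> list[PatientRecord]:
    """Read the patient-level clinical CSV.

    Missing PD-L1 results are kept as an explicit ``missing`` level.
    Negative times or non-binary event flags raise ``FormatError`` listing
    the offending rows.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["pfs_time"] < 0) | (df["os_time"] < 0)].tolist()
    bad += df.index[~df["pfs_event"].isin([0, 1])
                    | ~df["os_event"].isin([0, 1])].tolist()
    if bad:
        raise FormatError(
            f"{path}: invalid times/event flags in rows {sorted(set(bad))}")
    records = []
    for _, row in df.iterrows():
        pdl1 = row["pdl1_status"]
        if pd.isna(pdl1) or str(pdl1).strip() == "":
            pdl1 = "missing"
        score = row.get("btmb_score")
        msaf = row.get("msaf")
        records.append(PatientRecord(
            id=str(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            smoking=str(row["smoking"]),
            histology=str(row["histology"]),
            pdl1_status=str(pdl1),
            sld_mm=float(row["sld_mm"]),
            n_target_lesions=int(row["n_target_lesions"]),
            confirmed_responder=bool(int(row["confirmed_response"])),
            pfs_time=float(row["pfs_time"]),
            pfs_event=bool(int(row["pfs_event"])),
            os_time=float(row["os_time"]),
            os_event=bool(int(row["os_event"])),
            msaf=None if pd.isna(msaf) else float(msaf),
            btmb_score=None if score is None or pd.isna(score) else int(score),
        ))
    return records


def write_clinical_table(records: Iterable[PatientRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "age": r.age, "sex": r.sex, "smoking": r.smoking,
            "histology": r.histology, "pdl1_status": r.pdl1_status,
            "sld_mm": r.sld_mm, "n_target_lesions": r.n_target_lesions,
            "confirmed_response": int(r.confirmed_responder),
            "pfs_time": r.pfs_time, "pfs_event": int(r.pfs_event),
            "os_time": r.os_time, "os_event": int(r.os_event),
            "msaf": "" if r.msaf is None else r.msaf,
            "btmb_score": "" if r.btmb_score is None else r.btmb_score,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def with_scores(records: Iterable[PatientRecord], results) -> list[PatientRecord]:
    """Attach per-sample burden results (by sample/patient id) to records."""
    by_id = {res.sample_id: res for res in results}
    out = []
    for r in records:
        res = by_id.get(r.id)
        if res is None:
            out.append(r)
        else:
            out.append(replace(
                r, msaf=res.msaf,
                btmb_score=res.btmb_score if res.evaluable else None))
    return out
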