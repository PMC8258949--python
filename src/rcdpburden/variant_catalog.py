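"""Variant ingestion and pathogenicity filtering.

Reads per-variant annotation/frequency records (TSV, or minimal VCF with
gnomAD-style ``AC``/``AN`` INFO fields plus a sidecar annotation table)
and applies the inclusion rules for disease-contributing alleles:

1. variants outside a configured per-gene genomic interval are excluded
   (used to restrict *PEX5* to the PTS2-domain encoding region);
2. clinically reported benign variants are excluded, regardless of
   in-silico predictions;
3. clinically reported pathogenic variants are included;
4. predicted loss-of-function consequences (stop gained, frameshift,
   canonical splice donor/acceptor, start lost) are included;
5. missense variants are included only when SIFT calls them deleterious
   AND PolyPhen-2 calls them (possibly/probably) damaging;
6. everything else is excluded, with the reason recorded.

Non-canonical splice-region variants are deliberately not auto-included:
cryptic-splicing outcomes are hard to predict and are treated as inputs
(clinical evidence) rather than predictions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_REGION = "splice_region"
    INFRAME_INDEL = "inframe_indel"
    START_LOST = "start_lost"
    OTHER = "other"


#: consequence classes treated as predicted loss of function
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.STOP_GAINED,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_DONOR,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.START_LOST,
    }
)


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PolyphenCall(str, enum.Enum):
    DAMAGING = "damaging_or_probably_damaging"
    BENIGN = "benign"
    UNKNOWN = "unknown"


class ClinicalStatus(str, enum.Enum):
    PATHOGENIC = "reported_pathogenic"
    UNCERTAIN = "reported_uncertain"
    BENIGN = "reported_benign"
    UNREPORTED = "unreported"


class Rule(str, enum.Enum):
    """Which filter rule decided a variant's fate."""

    CLINICAL = "clinical"
    PREDICTED_LOF = "predicted_lof"
    MISSENSE_CONCORDANT = "missense_concordant"
    EXCLUDED_BENIGN = "excluded_benign"
    EXCLUDED_DISCORDANT = "excluded_discordant"
    EXCLUDED_REGION = "excluded_region"
    EXCLUDED_OTHER = "excluded_other"


INCLUSION_RULES = frozenset({Rule.CLINICAL, Rule.PREDICTED_LOF, Rule.MISSENSE_CONCORDANT})


@dataclass(frozen=True)
class GenomicInterval:
    """1-based closed interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class VariantRecord:
    """One variant observed in one dataset (multi-allelic sites: one record per alt)."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    sift_call: SiftCall
    polyphen_call: PolyphenCall
    clinical_status: ClinicalStatus
    allele_count: int
    allele_number: int
    dataset: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if self.allele_number <= 0:
            raise ValueError(f"{self.variant_id}: allele_number must be positive")
        if not (0 <= self.allele_count <= self.allele_number):
            raise ValueError(
                f"{self.variant_id}: AC={self.allele_count} outside [0, AN={self.allele_number}]"
            )

    @property
    def allele_frequency(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class PathogenicityCall:
    variant_id: str
    included: bool
    rule_fired: Rule

    def __post_init__(self) -> None:
        if self.included != (self.rule_fired in INCLUSION_RULES):
            raise ValueError(
                f"{self.variant_id}: included={self.included} inconsistent with rule {self.rule_fired}"
            )


class VariantFormatError(ValueError):
    """Malformed input table (missing columns, unparsable fields)."""


TSV_COLUMNS = [
    "variant_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
    "sift", "polyphen", "clinical", "AC", "AN", "dataset",
]

# raw annotation strings accepted in input tables, mapped onto the enums
_SIFT_ALIASES = {
    "deleterious": SiftCall.DELETERIOUS,
    "deleterious_low_confidence": SiftCall.DELETERIOUS,
    "tolerated": SiftCall.TOLERATED,
    "tolerated_low_confidence": SiftCall.TOLERATED,
    "unknown": SiftCall.UNKNOWN,
    "": SiftCall.UNKNOWN,
    ".": SiftCall.UNKNOWN,
}

_CLINICAL_ALIASES = {
    "reported_pathogenic": ClinicalStatus.PATHOGENIC,
    "pathogenic": ClinicalStatus.PATHOGENIC,
    "likely_pathogenic": ClinicalStatus.PATHOGENIC,
    "reported_uncertain": ClinicalStatus.UNCERTAIN,
    "uncertain_significance": ClinicalStatus.UNCERTAIN,
    "vus": ClinicalStatus.UNCERTAIN,
    "reported_benign": ClinicalStatus.BENIGN,
    "benign": ClinicalStatus.BENIGN,
    "likely_benign": ClinicalStatus.BENIGN,
    "unreported": ClinicalStatus.UNREPORTED,
    "": ClinicalStatus.UNREPORTED,
    ".": ClinicalStatus.UNREPORTED,
}


def parse_polyphen(raw: str, possibly_damaging_is_damaging: bool = True) -> PolyphenCall:
    """Map a raw PolyPhen-2 grade onto the binary damaging/benign call.

    "possibly damaging" counts as damaging by default (the permissive
    reading of the two-tool concordance rule); set the flag False to
    require "probably damaging".
    """
    s = raw.strip().lower()
    if s in ("probably_damaging", "damaging", "damaging_or_probably_damaging"):
        return PolyphenCall.DAMAGING
    if s == "possibly_damaging":
        return PolyphenCall.DAMAGING if possibly_damaging_is_damaging else PolyphenCall.BENIGN
    if s == "benign":
        return PolyphenCall.BENIGN
    if s in ("unknown", "", "."):
        return PolyphenCall.UNKNOWN
    raise VariantFormatError(f"unrecognised PolyPhen call: {raw!r}")


def _parse_sift(raw: str) -> SiftCall:
    try:
        return _SIFT_ALIASES[raw.strip().lower()]
    except KeyError:
        raise VariantFormatError(f"unrecognised SIFT call: {raw!r}") from None


def _parse_clinical(raw: str) -> ClinicalStatus:
    try:
        return _CLINICAL_ALIASES[raw.strip().lower()]
    except KeyError:
        raise VariantFormatError(f"unrecognised clinical status: {raw!r}") from None


def _record_from_row(row: Mapping[str, object], row_no: int,
                     possibly_damaging_is_damaging: bool) -> VariantRecord:
    try:
        return VariantRecord(
            variant_id=str(row["variant_id"]),
            gene=str(row["gene"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            consequence=Consequence(str(row["consequence"]).strip().lower()),
            sift_call=_parse_sift(str(row["sift"])),
            polyphen_call=parse_polyphen(str(row["polyphen"]), possibly_damaging_is_damaging),
            clinical_status=_parse_clinical(str(row["clinical"])),
            allele_count=int(row["AC"]),
            allele_number=int(row["AN"]),
            dataset=str(row["dataset"]),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, KeyError):
            raise VariantFormatError(f"row {row_no}: missing column {exc}") from None
        raise ValueError(f"row {row_no}: {exc}") from None


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    annotations: Optional[str | Path] = None,
    possibly_damaging_is_damaging: bool = True,
) -> list[VariantRecord]:
    """Read variant records from a TSV table or a minimal VCF.

    The TSV dialect is tab-separated with a header row and the columns
    ``variant_id gene chrom pos ref alt consequence sift polyphen
    clinical AC AN dataset``.

    The VCF dialect extracts ``AC``/``AN`` from INFO (one record per alt
    allele) and joins gene/consequence/prediction annotations from a
    sidecar TSV keyed by ``variant_id`` = ``chrom-pos-ref-alt`` (the
    sidecar uses the same columns as the TSV dialect minus AC/AN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"variant table not found: {path}")
    if dialect == "tsv":
        return _read_tsv(path, possibly_damaging_is_damaging)
    if dialect == "vcf":
        if annotations is None:
            raise VariantFormatError("VCF dialect requires a sidecar annotation table")
        return _read_vcf(path, Path(annotations), possibly_damaging_is_damaging)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_tsv(path: Path, possibly_damaging_is_damaging: bool) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VariantFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        records.append(_record_from_row(row, i, possibly_damaging_is_damaging))
    return records


def _read_vcf(path: Path, annotations: Path, possibly_damaging_is_damaging: bool) -> list[VariantRecord]:
    import pysam

    anno = pd.read_csv(annotations, sep="\t", dtype=str, keep_default_na=False)
    required = ["variant_id", "gene", "consequence", "sift", "polyphen", "clinical", "dataset"]
    missing = [c for c in required if c not in anno.columns]
    if missing:
        raise VariantFormatError(
            f"{annotations}: missing mandatory column(s): {', '.join(missing)}"
        )
    anno_by_key = {r["variant_id"]: r for r in anno.to_dict("records")}

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            acs = rec.info.get("AC")
            an = rec.info.get("AN")
            if acs is None or an is None:
                raise VariantFormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks AC/AN INFO fields"
                )
            if not isinstance(acs, (tuple, list)):
                acs = (acs,)
            for alt, ac in zip(rec.alts or (), acs):
                key = f"{rec.chrom}-{rec.pos}-{rec.ref}-{alt}"
                side = anno_by_key.get(key)
                if side is None:
                    continue  # unannotated allele: not part of the configured catalogue
                records.append(
                    VariantRecord(
                        variant_id=key,
                        gene=str(side["gene"]),
                        chrom=str(rec.chrom),
                        pos=int(rec.pos),
                        ref=str(rec.ref),
                        alt=str(alt),
                        consequence=Consequence(str(side["consequence"]).strip().lower()),
                        sift_call=_parse_sift(str(side["sift"])),
                        polyphen_call=parse_polyphen(
                            str(side["polyphen"]), possibly_damaging_is_damaging
                        ),
                        clinical_status=_parse_clinical(str(side["clinical"])),
                        allele_count=int(ac),
                        allele_number=int(an),
                        dataset=str(side["dataset"]),
                    )
                )
    return records


def classify_variant(
    v: VariantRecord,
    region_restriction: Optional[GenomicInterval] = None,
) -> PathogenicityCall:
    """Apply the inclusion decision procedure to one validated record.

    Precedence: region restriction, then clinical benign, then clinical
    pathogenic, then predicted LoF, then SIFT/PolyPhen-concordant
    missense.  Clinical evidence overrides in-silico predictions in both
    directions.
    """
    if region_restriction is not None and not region_restriction.contains(v.chrom, v.pos):
        return PathogenicityCall(v.variant_id, False, Rule.EXCLUDED_REGION)
    if v.clinical_status is ClinicalStatus.BENIGN:
        return PathogenicityCall(v.variant_id, False, Rule.EXCLUDED_BENIGN)
    if v.clinical_status is ClinicalStatus.PATHOGENIC:
        return PathogenicityCall(v.variant_id, True, Rule.CLINICAL)
    if v.consequence in LOF_CONSEQUENCES:
        return PathogenicityCall(v.variant_id, True, Rule.PREDICTED_LOF)
    if v.consequence is Consequence.MISSENSE:
        if v.sift_call is SiftCall.DELETERIOUS and v.polyphen_call is PolyphenCall.DAMAGING:
            return PathogenicityCall(v.variant_id, True, Rule.MISSENSE_CONCORDANT)
        return PathogenicityCall(v.variant_id, False, Rule.EXCLUDED_DISCORDANT)
    return PathogenicityCall(v.variant_id, False, Rule.EXCLUDED_OTHER)


def classify_all(
    variants: Sequence[VariantRecord],
    region_restrictions: Optional[Mapping[str, GenomicInterval]] = None,
) -> list[PathogenicityCall]:
    """Classify every record, applying any per-gene interval restriction."""
    restrictions = region_restrictions or {}
    return [classify_variant(v, restrictions.get(v.gene)) for v in variants]


def consequence_class_summary(
    variants: Sequence[VariantRecord],
    calls: Sequence[PathogenicityCall],
) -> pd.DataFrame:
    """Aggregate allele frequency of included variants per (gene, dataset, consequence).

    The per-class sums partition each gene's total pathogenic frequency,
    mirroring a mutational-landscape overview clustered by molecular
    consequence.
    """
    if len(variants) != len(calls):
        raise ValueError("variants and calls must be parallel sequences")
    rows = [
        {
            "gene": v.gene,
            "dataset": v.dataset,
            "consequence": v.consequence.value,
            "allele_frequency": v.allele_frequency,
        }
        for v, c in zip(variants, calls)
        if c.included
    ]
    if not rows:
        return pd.DataFrame(columns=["gene", "dataset", "consequence", "aggregate_af"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "dataset", "consequence"], as_index=False)["allele_frequency"]
        .sum()
        .rename(columns={"allele_frequency": "aggregate_af"})
        .sort_values(["gene", "dataset", "consequence"], ignore_index=True)
    )
    return out
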