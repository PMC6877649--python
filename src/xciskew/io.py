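"""Readers and writers for the pipeline's tabular and VCF inputs.

Phased genotypes come from VCF 4.x (cyvcf2); allelic read counts from
GATK-ASEReadCounter-style tab-separated tables; sample metadata and all
result tables are plain TSV with documented headers.  Only biallelic,
heterozygous, phased SNVs ever leave the VCF reader — everything else is
skipped and counted in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .config import GenomicInterval, PAR1_GRCH37, PAR2_GRCH37, XIST_GRCH37

logger = logging.getLogger(__name__)

__all__ = [
    "PhasedGenotype",
    "AllelicSite",
    "SampleMetadata",
    "VcfParseError",
    "SchemaError",
    "read_phased_vcf",
    "read_allelic_counts",
    "read_metadata",
    "write_metadata",
    "write_skew_table",
    "read_skew_table",
    "SKEW_TABLE_COLUMNS",
    "METADATA_COLUMNS",
]

_NUCLEOTIDES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; names the offending file/record."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns."""


@dataclass(frozen=True)
class PhasedGenotype:
    """One heterozygous, phased, biallelic SNV for one sample.

    ``hap1_allele`` is the base carried on haplotype 1 and equals either
    ``ref_allele`` or ``alt_allele``.
    """

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    hap1_allele: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or a.upper() not in _NUCLEOTIDES:
                raise ValueError(f"not a single-nucleotide allele: {a!r}")
        if self.hap1_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError("hap1_allele must be the ref or the alt allele")

    @property
    def hap1_is_ref(self) -> bool:
        return self.hap1_allele == self.ref_allele


@dataclass(frozen=True)
class AllelicSite:
    """Allelic read counts at one heterozygous X-linked SNV in one sample."""

    contig: str
    position: int
    ref_count: int
    alt_count: int
    sample_id: str
    in_xist: bool = False
    in_par: bool = False

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total_count(self) -> int:
        # other-base reads are excluded upstream; depth is ref + alt by definition
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    individual_id: str
    family_id: str
    zygosity: str  # MZ | DZ | singleton
    age: float
    tissue: str
    smoking: str = "unknown"  # never | current | unknown
    disease: str = "none"  # none | RA | unknown
    time_point: int = 1

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ", "singleton"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.age < 0:
            raise ValueError("age must be non-negative")


def read_phased_vcf(
    path: str | Path,
    region: Optional[GenomicInterval] = None,
    samples: Optional[Sequence[str]] = None,
) -> list[PhasedGenotype]:
    """Read phased heterozygous biallelic SNVs from a VCF.

    Multi-allelic records, indels, homozygous and unphased genotypes are
    skipped (counts logged).  ``region`` filters by 1-based inclusive
    coordinates; a region with no records yields an empty list.
    """
    path = str(path)
    skipped = {"multiallelic_or_indel": 0, "homozygous_or_missing": 0, "unphased": 0}
    out: list[PhasedGenotype] = []
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises on unreadable/headerless files
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    vcf_samples = list(vcf.samples)
    wanted = set(samples) if samples is not None else None
    try:
        for variant in vcf:
            if region is not None and not region.contains(variant.CHROM, variant.POS):
                continue
            if len(variant.ALT) != 1 or not variant.is_snp:
                skipped["multiallelic_or_indel"] += 1
                continue
            ref, alt = variant.REF, variant.ALT[0]
            for i, sample in enumerate(vcf_samples):
                if wanted is not None and sample not in wanted:
                    continue
                a, b, *rest = variant.genotypes[i]
                phased = bool(rest[-1]) if rest else False
                if a < 0 or b < 0 or a == b:
                    skipped["homozygous_or_missing"] += 1
                    continue
                if not phased:
                    skipped["unphased"] += 1
                    continue
                out.append(
                    PhasedGenotype(
                        contig=variant.CHROM,
                        position=variant.POS,
                        ref_allele=ref,
                        alt_allele=alt,
                        hap1_allele=ref if a == 0 else alt,
                        sample_id=sample,
                    )
                )
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(f"malformed VCF record in {path}: {exc}") from exc
    if any(skipped.values()):
        logger.info("read_phased_vcf(%s): skipped %s", path, skipped)
    return out


_REQUIRED_COUNT_COLUMNS = [
    "contig", "position", "refAllele", "altAllele", "refCount", "altCount", "totalCount",
]


def read_allelic_counts(
    path: str | Path,
    sample_id: Optional[str] = None,
    xist_interval: GenomicInterval = XIST_GRCH37,
    par_intervals: Sequence[GenomicInterval] = (PAR1_GRCH37, PAR2_GRCH37),
) -> list[AllelicSite]:
    """Read an ASEReadCounter-style allelic count table.

    ``in_xist`` / ``in_par`` flags are set from the configured intervals.
    A row whose printed totalCount differs from refCount + altCount has its
    total recomputed as ref + alt (the discrepancy is logged): reads carrying
    neither allele do not count toward allelic depth.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if ((df["refCount"] < 0) | (df["altCount"] < 0)).any():
        raise ValueError(f"{path}: negative allelic counts")
    sid = sample_id if sample_id is not None else path.stem
    n_mismatch = int((df["totalCount"] != df["refCount"] + df["altCount"]).sum())
    if n_mismatch:
        logger.info(
            "%s: %d rows with totalCount != refCount + altCount; total recomputed",
            path, n_mismatch,
        )
    sites = []
    for row in df.itertuples(index=False):
        contig, pos = str(row.contig), int(row.position)
        sites.append(
            AllelicSite(
                contig=contig,
                position=pos,
                ref_count=int(row.refCount),
                alt_count=int(row.altCount),
                sample_id=sid,
                in_xist=xist_interval.contains(contig, pos),
                in_par=any(iv.contains(contig, pos) for iv in par_intervals),
            )
        )
    return sites


METADATA_COLUMNS = [
    "sample_id", "individual_id", "family_id", "zygosity", "age",
    "tissue", "smoking", "disease", "time_point",
]


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str, "family_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {missing}")
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS, float_format="%.10g")


SKEW_TABLE_COLUMNS = ["sample_id", "tissue", "n_snps", "xist_ase", "ds", "classification"]


def write_skew_table(calls: Iterable, path: str | Path) -> None:
    """Write per-sample skew calls as TSV in a fixed column order.

    Accepts a sequence of SkewCall-like objects or a DataFrame; round-trips
    losslessly (floats to 10 significant digits) through read_skew_table.
    """
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "tissue": c.tissue,
                    "n_snps": c.n_snps,
                    "xist_ase": c.xist_ase,
                    "ds": c.ds,
                    "classification": c.classification,
                }
                for c in calls
            ],
            columns=SKEW_TABLE_COLUMNS,
        )
    df.to_csv(path, sep="\t", index=False, columns=SKEW_TABLE_COLUMNS, float_format="%.12g")


def read_skew_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    missing = [c for c in SKEW_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: skew table missing columns {missing}")
    return df
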