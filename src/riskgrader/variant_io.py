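"""Read and validate annotated multi-sample VCFs and phenotype tables.

The pipeline's in-memory model is deliberately small: a dense dosage matrix
(samples x biallelic variants, alternate-allele counts with ``MISSING`` for
no-calls), one annotation record per variant, and a per-sample phenotype
table with the overall severity grade plus the four clinical sub-phenotype
grades (non-verbal IQ, memory, attention, verbal ability), each dichotomised
severe vs mild.

Coordinates are VCF-native: 1-based, inclusive. Only biallelic SNV-style
records are accepted; multi-allelic records must be decomposed upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import PhenotypeError, VcfFormatError

#: Sentinel for a missing (uncalled or half-called) genotype in the dosage matrix.
MISSING: int = -1

SUBPHENOTYPES: tuple[str, ...] = ("iq", "memory", "attention", "verbal")
SEVERITY_FIELDS: tuple[str, ...] = ("severity",) + SUBPHENOTYPES

#: Default mapping from annotation concepts to INFO keys; a caller may rename
#: keys for VCFs produced by other annotation stacks.
DEFAULT_INFO_KEYS: Mapping[str, str] = {
    "gene": "GENE",
    "sift": "SIFT",
    "polyphen": "POLYPHEN",
    "aaf_1kg": "AAF_1KG",
}


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of alternate-allele dosages.

    ``dosage`` entries are 0, 1, 2 or :data:`MISSING`.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise VcfFormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise VcfFormatError("duplicate sample IDs")
        if len(set(self.variant_ids)) != m:
            raise VcfFormatError("duplicate variant IDs")
        valid = (self.dosage == MISSING) | ((self.dosage >= 0) & (self.dosage <= 2))
        if not valid.all():
            raise VcfFormatError("dosage entries must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variant_ids)}


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant metadata carried alongside a dosage column."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    sift: str | None = None
    polyphen: str | None = None
    aaf_1kg: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfFormatError(f"{self.variant_id}: pos must be >= 1")
        if self.ref == self.alt:
            raise VcfFormatError(f"{self.variant_id}: ref equals alt")


@dataclass
class PhenotypeTable:
    """Binary severity grades per sample: overall plus four sub-phenotypes.

    Backed by a DataFrame indexed by sample ID with columns
    ``severity, iq, memory, attention, verbal``; every value is the token
    ``"severe"`` or ``"mild"``.
    """

    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing_cols = [c for c in SEVERITY_FIELDS if c not in self.records.columns]
        if missing_cols:
            raise PhenotypeError(f"phenotype table lacks columns: {missing_cols}")
        self.records = self.records[list(SEVERITY_FIELDS)].copy()
        bad = ~self.records.isin(["severe", "mild"]).all(axis=1)
        if bad.any():
            raise PhenotypeError(
                f"non-binary severity values for samples: {list(self.records.index[bad])}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)

    def severe_mask(self, phenotype: str = "severity") -> np.ndarray:
        """Boolean array (in table order) marking samples graded severe."""
        if phenotype not in SEVERITY_FIELDS:
            raise PhenotypeError(f"unknown phenotype field {phenotype!r}")
        return (self.records[phenotype] == "severe").to_numpy()

    def group_members(self, phenotype: str, side: str) -> list[str]:
        """Sample IDs in one sub-phenotype x severity group."""
        if side not in ("severe", "mild"):
            raise PhenotypeError(f"unknown severity side {side!r}")
        mask = self.severe_mask(phenotype)
        if side == "mild":
            mask = ~mask
        return [s for s, m in zip(self.sample_ids, mask) if m]


def read_vcf(
    path: str | Path,
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
) -> tuple[GenotypeMatrix, list[VariantAnnotation]]:
    """Load a multi-sample VCF into a dosage matrix plus annotations.

    Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and ./. -> missing;
    half-calls are treated as missing. Multi-allelic records are rejected
    with an instruction to decompose upstream. Variant order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids: list[str] = []
    annotations: list[VariantAnnotation] = []
    rows: list[np.ndarray] = []
    for idx, record in enumerate(vcf):
        if len(record.ALT) != 1:
            raise VcfFormatError(
                f"multi-allelic record at {record.CHROM}:{record.POS} "
                f"(ALT={','.join(record.ALT) or '.'}); decompose the VCF upstream "
                "(e.g. bcftools norm -m-) before loading"
            )
        vid = record.ID or f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        dosages = np.empty(len(sample_ids), dtype=np.int16)
        for j, gt in enumerate(record.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                dosages[j] = MISSING
            elif all(a in (0, 1) for a in alleles):
                dosages[j] = alleles[0] + alleles[1]
            else:
                raise VcfFormatError(
                    f"malformed GT for sample {sample_ids[j]} at record {idx + 1} "
                    f"({record.CHROM}:{record.POS}): alleles {alleles}"
                )
        aaf = record.INFO.get(info_keys["aaf_1kg"])
        annotations.append(
            VariantAnnotation(
                variant_id=vid,
                chrom=record.CHROM,
                pos=record.POS,
                ref=record.REF,
                alt=record.ALT[0],
                gene=record.INFO.get(info_keys["gene"]),
                sift=record.INFO.get(info_keys["sift"]),
                polyphen=record.INFO.get(info_keys["polyphen"]),
                # INFO floats surface as 32-bit; round to the dialect's precision
                aaf_1kg=None if aaf is None else round(float(aaf), 6),
            )
        )
        variant_ids.append(vid)
        rows.append(dosages)
    dosage = (
        np.stack(rows, axis=1) if rows else np.empty((len(sample_ids), 0), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, variant_ids, dosage), annotations


def read_phenotypes(path: str | Path, samples: Sequence[str]) -> PhenotypeTable:
    """Read the TSV phenotype table and align it to the genotype sample order.

    Severity tokens are case-folded. Every genotyped sample must appear
    exactly once.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sample_id" not in df.columns:
        raise PhenotypeError(f"{path}: missing 'sample_id' column")
    missing_cols = [c for c in SEVERITY_FIELDS if c not in df.columns]
    if missing_cols:
        raise PhenotypeError(f"{path}: missing columns {missing_cols}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise PhenotypeError(f"duplicate sample(s) in phenotype table: {sorted(set(dup))}")
    df = df.set_index("sample_id")
    absent = [s for s in samples if s not in df.index]
    if absent:
        raise PhenotypeError(f"sample(s) missing from phenotype table: {absent}")
    df = df.loc[list(samples), list(SEVERITY_FIELDS)]
    for col in SEVERITY_FIELDS:
        df[col] = df[col].str.strip().str.lower()
        bad = sorted(set(df[col]) - {"severe", "mild"})
        if bad:
            raise PhenotypeError(f"unknown severity token(s) in column {col!r}: {bad}")
    return PhenotypeTable(df)


def write_gene_list(genes: Sequence[str], path: str | Path, header: str | None = None) -> None:
    """Write a newline-delimited gene symbol list."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")
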