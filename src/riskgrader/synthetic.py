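"""Seeded synthetic exome cohorts with planted case-control structure.

The generator emulates the data both pipeline arms consume: a small
two-group cohort (default 15 severe / 18 mild, the usual size of a deeply
phenotyped clinical series), biallelic exome variants drawn per sample under
Hardy-Weinberg equilibrium, SIFT/PolyPhen labels, and four sub-phenotype
grades (non-verbal IQ, memory, attention, verbal) correlated with overall
severity. Two kinds of signal can be planted:

* risk variants — alternate-allele frequency raised by ``risk_delta`` in the
  severe group, the signal the association/risk-model arm must recover;
* "important genes" — genes given one homozygous-alternate, doubly damaging
  variant in (all but at most one of) the members of a chosen sub-phenotype
  group, the signal the rule-based gene arm must recover.

One seed yields one cohort, bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import SpecValidationError
from .variant_io import (
    MISSING,
    SUBPHENOTYPES,
    GenotypeMatrix,
    PhenotypeTable,
    VariantAnnotation,
    read_phenotypes,
    read_vcf,
)

import pandas as pd

#: SIFT / PolyPhen tokens that satisfy the deleteriousness rule downstream.
QUALIFYING_SIFT: tuple[str, ...] = ("deleterious", "deleterious_low_confidence")
QUALIFYING_POLYPHEN: tuple[str, ...] = ("probably_damaging", "possibly_damaging")

#: Severe/mild marginal counts per sub-phenotype for the default 33-sample
#: cohort (overall severity is the non-verbal IQ grouping).
DEFAULT_SUBPHENOTYPE_SPLITS: Mapping[str, tuple[int, int]] = {
    "iq": (15, 18),
    "memory": (15, 18),
    "attention": (24, 9),
    "verbal": (14, 19),
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PlantedGene:
    """A gene planted as 'important' for one sub-phenotype group."""

    gene_index: int
    subphenotype: str
    side: str  # "severe" or "mild"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort; see :func:`simulate_cohort`.

    ``aaf_range``, when set, draws each variant's background alternate-allele
    frequency from Uniform(low, high) instead of the constant
    ``background_aaf`` — exome sites span a wide frequency spectrum, and the
    heterogeneity also removes the p-value lattice a single shared frequency
    imposes on small-cohort 2x2 tests.
    """

    n_severe: int = 15
    n_mild: int = 18
    n_variants: int = 2000
    n_genes: int = 400
    background_aaf: float = 0.2
    aaf_range: tuple[float, float] | None = None
    planted_risk_variants: int = 20
    risk_delta: float = 0.35
    planted_ig_genes: tuple[PlantedGene, ...] = ()
    deleterious_rate_background: float = 0.05
    missing_rate: float = 0.02
    subphenotype_splits: Mapping[str, tuple[int, int]] | None = None
    discordance: float = 0.1
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_severe + self.n_mild

    def resolved_splits(self) -> dict[str, tuple[int, int]]:
        """Severe/mild counts per sub-phenotype, defaulted for this cohort size."""
        if self.subphenotype_splits is not None:
            return {k: tuple(v) for k, v in self.subphenotype_splits.items()}
        if (self.n_severe, self.n_mild) == (15, 18):
            return dict(DEFAULT_SUBPHENOTYPE_SPLITS)
        return {s: (self.n_severe, self.n_mild) for s in SUBPHENOTYPES}

    def validate(self) -> None:
        if self.n_severe < 1 or self.n_mild < 1:
            raise SpecValidationError("n_severe and n_mild must be positive")
        if self.n_variants < 1 or self.n_genes < 1:
            raise SpecValidationError("n_variants and n_genes must be positive")
        for name in ("background_aaf",):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SpecValidationError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.risk_delta < 1.0:
            raise SpecValidationError(f"risk_delta must lie in [0, 1), got {self.risk_delta}")
        if self.background_aaf + self.risk_delta > 1.0:
            raise SpecValidationError(
                "background_aaf + risk_delta must not exceed 1 "
                f"({self.background_aaf} + {self.risk_delta})"
            )
        if self.aaf_range is not None:
            lo, hi = self.aaf_range
            if not (0.0 < lo <= hi < 1.0) or hi + self.risk_delta > 1.0:
                raise SpecValidationError(f"aaf_range {self.aaf_range} incompatible with risk_delta")
        if not 0.0 <= self.deleterious_rate_background <= 1.0:
            raise SpecValidationError("deleterious_rate_background must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SpecValidationError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if not 0.0 <= self.discordance <= 0.5:
            raise SpecValidationError("discordance must lie in [0, 0.5]")
        if not 0 <= self.planted_risk_variants <= self.n_variants:
            raise SpecValidationError(
                f"planted_risk_variants ({self.planted_risk_variants}) exceeds n_variants"
            )
        if self.planted_risk_variants + len(self.planted_ig_genes) > self.n_variants:
            raise SpecValidationError("not enough variants for all planted signals")
        splits = self.resolved_splits()
        for sub in SUBPHENOTYPES:
            if sub not in splits:
                raise SpecValidationError(f"subphenotype_splits missing {sub!r}")
            k_sev, k_mild = splits[sub]
            if k_sev + k_mild != self.n_samples or min(k_sev, k_mild) < 0:
                raise SpecValidationError(
                    f"subphenotype_splits[{sub!r}] = {splits[sub]} does not sum to "
                    f"{self.n_samples} samples"
                )
        for pg in self.planted_ig_genes:
            if not 0 <= pg.gene_index < self.n_genes:
                raise SpecValidationError(f"planted gene index {pg.gene_index} >= n_genes")
            if pg.subphenotype not in SUBPHENOTYPES or pg.side not in ("severe", "mild"):
                raise SpecValidationError(
                    f"planted gene target ({pg.subphenotype!r}, {pg.side!r}) is not a valid group"
                )


@dataclass(frozen=True)
class PlantedGeneTruth:
    gene: str
    subphenotype: str
    side: str
    variant_id: str


@dataclass
class CohortTruth:
    """Ground truth of the planted signals, for recovery checks."""

    risk_variant_ids: list[str]
    ig_genes: list[PlantedGeneTruth]


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    annotations: list[VariantAnnotation]
    phenotypes: PhenotypeTable
    truth: CohortTruth


def _gene_symbol(i: int) -> str:
    return f"GENE{i + 1:04d}"


def _assign_subphenotype(
    rng: np.random.Generator,
    overall_severe: np.ndarray,
    k_severe: int,
    discordance: float,
) -> np.ndarray:
    """Draw one sub-phenotype label vector with the requested severe count.

    Starts from the assignment maximally concordant with overall severity,
    then swaps label pairs (preserving the marginal) until about
    ``discordance`` x n samples disagree with that concordant baseline.
    """
    n = overall_severe.size
    severe_idx = np.flatnonzero(overall_severe)
    mild_idx = np.flatnonzero(~overall_severe)
    label = np.zeros(n, dtype=bool)
    if k_severe >= severe_idx.size:
        label[severe_idx] = True
        extra = rng.choice(mild_idx, size=k_severe - severe_idx.size, replace=False)
        label[extra] = True
    else:
        keep = rng.choice(severe_idx, size=k_severe, replace=False)
        label[keep] = True
    n_swaps = int(round(discordance * n / 2))
    for _ in range(n_swaps):
        sev_concordant = np.flatnonzero(label & overall_severe)
        mild_concordant = np.flatnonzero(~label & ~overall_severe)
        if sev_concordant.size == 0 or mild_concordant.size == 0:
            break
        i = rng.choice(sev_concordant)
        j = rng.choice(mild_concordant)
        label[i], label[j] = False, True
    return label


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one seeded cohort with the planted structure of ``spec``.

    Genotypes are Binomial(2, f) per sample and variant; planted risk
    variants use f + risk_delta in the severe group. Planted important genes
    receive a dedicated hom-alt, SIFT+PolyPhen-damaging variant in all but at
    most one member of their target sub-phenotype group (never fewer than
    group size - 2), and those cells are shielded from missingness so the
    planted signal is never eroded below the calling threshold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    overall = np.zeros(n, dtype=bool)
    overall[: spec.n_severe] = True

    # per-variant background alternate-allele frequency
    if spec.aaf_range is None:
        freq = np.full(m, spec.background_aaf)
    else:
        freq = rng.uniform(spec.aaf_range[0], spec.aaf_range[1], size=m)

    planted_risk = np.sort(rng.choice(m, size=spec.planted_risk_variants, replace=False))
    fmat = np.tile(freq, (n, 1))
    fmat[np.ix_(overall, planted_risk)] += spec.risk_delta
    dosage = rng.binomial(2, fmat).astype(np.int16)

    gene_of = rng.integers(0, spec.n_genes, size=m)
    damaging = rng.random(m) < spec.deleterious_rate_background

    # sub-phenotype grades
    splits = spec.resolved_splits()
    labels = {}
    for sub in SUBPHENOTYPES:
        if sub == "iq" and splits[sub] == (spec.n_severe, spec.n_mild):
            # overall severity is defined from non-verbal IQ
            labels[sub] = overall.copy()
        else:
            labels[sub] = _assign_subphenotype(rng, overall, splits[sub][0], spec.discordance)

    # plant important genes on dedicated variants
    reserved = set(planted_risk.tolist())
    protected = np.zeros((n, m), dtype=bool)
    ig_truth: list[PlantedGeneTruth] = []
    free = [i for i in range(m) if i not in reserved]
    chosen = rng.choice(len(free), size=len(spec.planted_ig_genes), replace=False) if spec.planted_ig_genes else []
    for pg, pick in zip(spec.planted_ig_genes, np.atleast_1d(chosen)):
        v = free[int(pick)]
        side_mask = labels[pg.subphenotype] if pg.side == "severe" else ~labels[pg.subphenotype]
        members = np.flatnonzero(side_mask)
        if members.size < 3:
            raise SpecValidationError(
                f"group ({pg.subphenotype}, {pg.side}) has fewer than 3 members; "
                "the n-2 rule is undefined"
            )
        carriers = members
        if members.size > 3 and rng.random() < 0.5:
            # leave one member uncovered to exercise the >= n-2 tolerance
            carriers = np.delete(members, rng.integers(members.size))
        gene_of[v] = pg.gene_index
        damaging[v] = True
        dosage[carriers, v] = 2
        protected[carriers, v] = True
        ig_truth.append(
            PlantedGeneTruth(_gene_symbol(pg.gene_index), pg.subphenotype, pg.side, f"v{v + 1:05d}")
        )

    # SIFT / PolyPhen tokens
    sift = np.where(damaging, rng.choice(QUALIFYING_SIFT, size=m), "tolerated")
    polyphen = np.where(damaging, rng.choice(QUALIFYING_POLYPHEN, size=m), "benign")

    # missingness, uniform at random, shielding planted-gene carrier cells
    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        miss &= ~protected
        dosage[miss] = MISSING

    # loci: contiguous chromosome blocks, increasing positions
    chroms = [str(i * 22 // m + 1) for i in range(m)]
    pos_step = rng.integers(100, 5000, size=m)
    annotations: list[VariantAnnotation] = []
    pos = 0
    prev_chrom = None
    for i in range(m):
        if chroms[i] != prev_chrom:
            pos = 10_000
            prev_chrom = chroms[i]
        pos += int(pos_step[i])
        ref, alt = rng.choice(4, size=2, replace=False)
        annotations.append(
            VariantAnnotation(
                variant_id=f"v{i + 1:05d}",
                chrom=chroms[i],
                pos=pos,
                ref=_BASES[ref],
                alt=_BASES[alt],
                gene=_gene_symbol(int(gene_of[i])),
                sift=str(sift[i]),
                polyphen=str(polyphen[i]),
                aaf_1kg=round(float(freq[i]), 4),
            )
        )

    pheno = pd.DataFrame(
        {
            "severity": np.where(overall, "severe", "mild"),
            **{sub: np.where(labels[sub], "severe", "mild") for sub in SUBPHENOTYPES},
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    genotypes = GenotypeMatrix(sample_ids, [a.variant_id for a in annotations], dosage)
    truth = CohortTruth([f"v{i + 1:05d}" for i in planted_risk], ig_truth)
    return SyntheticCohort(genotypes, annotations, PhenotypeTable(pheno), truth)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + TSVs; round-trips through :mod:`variant_io`.

    Returns a map of logical name -> path for the VCF, phenotype table and
    the two truth files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "cohort.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "truth_variants": directory / "truth_risk_variants.tsv",
        "truth_genes": directory / "truth_ig_genes.tsv",
    }

    g = cohort.genotypes
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=riskgrader-synthetic\n")
        for chrom in dict.fromkeys(a.chrom for a in cohort.annotations):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT label">\n')
        fh.write('##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen label">\n')
        fh.write(
            '##INFO=<ID=AAF_1KG,Number=1,Type=Float,Description="Population alternate allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, ann in enumerate(cohort.annotations):
            info = (
                f"GENE={ann.gene};SIFT={ann.sift};POLYPHEN={ann.polyphen};"
                f"AAF_1KG={ann.aaf_1kg:.4f}"
            )
            gts = "\t".join(_GT_STRINGS[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{ann.chrom}\t{ann.pos}\t{ann.variant_id}\t{ann.ref}\t{ann.alt}"
                f"\t.\tPASS\t{info}\tGT\t{gts}\n"
            )

    cohort.phenotypes.records.to_csv(paths["phenotypes"], sep="\t")

    with open(paths["truth_variants"], "w") as fh:
        fh.write("variant_id\n")
        for vid in cohort.truth.risk_variant_ids:
            fh.write(f"{vid}\n")
    with open(paths["truth_genes"], "w") as fh:
        fh.write("gene\tsubphenotype\tside\tvariant_id\n")
        for t in cohort.truth.ig_genes:
            fh.write(f"{t.gene}\t{t.subphenotype}\t{t.side}\t{t.variant_id}\n")
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    genotypes, annotations = read_vcf(directory / "cohort.vcf")
    phenotypes = read_phenotypes(directory / "phenotypes.tsv", genotypes.sample_ids)
    truth_v = pd.read_csv(directory / "truth_risk_variants.tsv", sep="\t")
    truth_g = pd.read_csv(directory / "truth_ig_genes.tsv", sep="\t")
    truth = CohortTruth(
        list(truth_v["variant_id"]),
        [PlantedGeneTruth(*row) for row in truth_g.itertuples(index=False)],
    )
    return SyntheticCohort(genotypes, annotations, phenotypes, truth)
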