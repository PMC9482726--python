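"""Rule-based "important gene" (IG) discovery from damaging hom-alt variants.

A variant qualifies for a sample when the sample is homozygous for the
alternate allele AND the variant is flagged damaging by both predictors:
SIFT in {deleterious, deleterious_low_confidence} and PolyPhen in
{possibly_damaging, probably_damaging} (token match is case-insensitive;
an absent label disqualifies). Each sample's gene set is the distinct
symbols of its qualifying variants. A gene is an IG of a sub-phenotype x
severity group of n samples when it appears in at least n - 2 member sets.
The eight group IG sets are then partitioned by exact membership pattern
(the Venn regions); the region common to all groups is the
severity-independent gene signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .variant_io import (
    SUBPHENOTYPES,
    GenotypeMatrix,
    PhenotypeTable,
    VariantAnnotation,
)

QUALIFYING_SIFT = frozenset({"deleterious", "deleterious_low_confidence"})
QUALIFYING_POLYPHEN = frozenset({"possibly_damaging", "probably_damaging"})

#: All eight sub-phenotype x severity groups, in report order.
ALL_GROUPS: tuple[tuple[str, str], ...] = tuple(
    (sub, side) for sub in SUBPHENOTYPES for side in ("severe", "mild")
)


@dataclass
class SampleGeneSet:
    sample_id: str
    genes: set[str]


@dataclass
class GroupIGSet:
    group: tuple[str, str]
    n: int
    threshold: int
    genes: set[str]
    member_counts: dict[str, int] = field(repr=False, default_factory=dict)


@dataclass
class VennPartition:
    set_names: list[str]
    regions: dict[frozenset[str], set[str]]

    def region(self, *names: str) -> set[str]:
        return self.regions.get(frozenset(names), set())


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    fold: float | None
    p_value: float
    n_draws: int


def variant_is_damaging(ann: VariantAnnotation) -> bool:
    """True when both predictor labels are in their qualifying token sets."""
    if ann.sift is None or ann.polyphen is None:
        return False
    return (
        ann.sift.strip().lower() in QUALIFYING_SIFT
        and ann.polyphen.strip().lower() in QUALIFYING_POLYPHEN
    )


def qualifying_variants(
    genotypes: GenotypeMatrix, annotations: Sequence[VariantAnnotation]
) -> dict[str, set[str]]:
    """Per sample, the variant IDs that are hom-alt and doubly damaging."""
    if len(annotations) != genotypes.n_variants:
        raise ValidationError("annotation list does not match variant count")
    damaging = np.array([variant_is_damaging(a) for a in annotations])
    hom = genotypes.dosage == 2
    out: dict[str, set[str]] = {}
    vids = np.asarray(genotypes.variant_ids)
    for i, sid in enumerate(genotypes.sample_ids):
        out[sid] = set(vids[hom[i] & damaging])
    return out


def sample_gene_sets(
    qualifying: Mapping[str, set[str]],
    annotations: Sequence[VariantAnnotation],
) -> list[SampleGeneSet]:
    """Collapse qualifying variants to distinct gene symbols per sample.

    Variants without a gene symbol are dropped (their count is reported via
    the returned objects' total, logged by the CLI layer).
    """
    gene_of = {a.variant_id: a.gene for a in annotations}
    out = []
    for sid, vids in qualifying.items():
        genes = {gene_of[v] for v in vids if gene_of.get(v)}
        out.append(SampleGeneSet(sample_id=sid, genes=genes))
    return out


def group_ig_set(
    gene_sets: Sequence[SampleGeneSet],
    members: Sequence[str],
    group: tuple[str, str] = ("severity", "severe"),
    threshold: int | None = None,
) -> GroupIGSet:
    """Genes present in at least n - 2 of the group's n member sets."""
    n = len(members)
    if n < 3:
        raise ValidationError(
            f"group {group} has n={n} < 3 members; the n-2 rule is undefined"
        )
    if threshold is None:
        threshold = n - 2
    by_sample = {g.sample_id: g.genes for g in gene_sets}
    absent = [m for m in members if m not in by_sample]
    if absent:
        raise ValidationError(f"no gene set for member(s): {absent}")
    counts: dict[str, int] = {}
    for m in members:
        for g in by_sample[m]:
            counts[g] = counts.get(g, 0) + 1
    genes = {g for g, c in counts.items() if c >= threshold}
    return GroupIGSet(
        group=group,
        n=n,
        threshold=threshold,
        genes=genes,
        member_counts={g: counts[g] for g in genes},
    )


def venn_partition(named_sets: Mapping[str, set[str]]) -> VennPartition:
    """Partition the union of 2-8 named sets by exact membership pattern."""
    names = list(named_sets)
    if not 2 <= len(names) <= 8:
        raise ValidationError(f"venn_partition supports 2-8 sets, got {len(names)}")
    regions: dict[frozenset[str], set[str]] = {}
    universe = set().union(*named_sets.values())
    for gene in universe:
        key = frozenset(n for n in names if gene in named_sets[n])
        regions.setdefault(key, set()).add(gene)
    return VennPartition(set_names=names, regions=regions)


def intersection_enrichment(
    named_sets: Mapping[str, set[str]],
    universe_size: int,
    n_draws: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """All-set overlap vs the independence expectation, with a Monte-Carlo p.

    Expected overlap under independent uniform draws is
    U * prod(|s_i| / U); the p-value is the continuity-corrected fraction of
    seeded same-size random draws whose all-set overlap reaches the observed
    one.
    """
    sets = list(named_sets.values())
    if len(sets) < 2:
        raise ValidationError("need at least two sets")
    sizes = [len(s) for s in sets]
    if max(sizes, default=0) > universe_size:
        raise ValidationError("a set exceeds the stated universe")
    observed = len(set.intersection(*sets))
    expected = universe_size * float(np.prod([s / universe_size for s in sizes]))
    fold = None if expected == 0 else observed / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        draws = [
            frozenset(rng.choice(universe_size, size=sz, replace=False)) for sz in sizes
        ]
        inter = set(draws[0])
        for d in draws[1:]:
            inter &= d
        if len(inter) >= observed:
            hits += 1
    p = (hits + 1) / (n_draws + 1)
    return EnrichmentResult(observed, expected, fold, p, n_draws)


@dataclass
class IGReport:
    sample_gene_sets: list[SampleGeneSet]
    group_sets: dict[tuple[str, str], GroupIGSet]
    venn: VennPartition
    severity_independent: set[str]
    severity_pooled: dict[str, set[str]]  # "severe", "mild", "common"
    all_ig_genes: set[str]


def ig_report(
    genotypes: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    phenotypes: PhenotypeTable,
) -> IGReport:
    """Run the full rule-based arm: per-sample sets, 8 group IG sets, the
    Venn partition across groups, and the severity-pooled comparison."""
    qual = qualifying_variants(genotypes, annotations)
    gsets = sample_gene_sets(qual, annotations)
    group_sets: dict[tuple[str, str], GroupIGSet] = {}
    for sub, side in ALL_GROUPS:
        members = phenotypes.group_members(sub, side)
        group_sets[(sub, side)] = group_ig_set(gsets, members, group=(sub, side))
    venn = venn_partition({f"{sub}_{side}": s.genes for (sub, side), s in group_sets.items()})
    severity_independent = venn.region(*venn.set_names)
    by_sample = {g.sample_id: g.genes for g in gsets}
    pooled = {}
    for side in ("severe", "mild"):
        members = phenotypes.group_members("severity", side)
        pooled[side] = set().union(*(by_sample[m] for m in members)) if members else set()
    pooled["common"] = pooled["severe"] & pooled["mild"]
    return IGReport(
        sample_gene_sets=gsets,
        group_sets=group_sets,
        venn=venn,
        severity_independent=severity_independent,
        severity_pooled=pooled,
        all_ig_genes=set().union(*(g.genes for g in gsets)) if gsets else set(),
    )
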