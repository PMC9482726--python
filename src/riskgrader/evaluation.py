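"""Leave-one-out cross-validation with fold-nested feature selection.

For every held-out sample the allelic association ranking and top-k
selection are recomputed on the remaining samples only, the Cauchy-prior
risk model is refitted on them, and the held-out sample is scored
out-of-fold — so no sample ever influences its own feature selection or
training (the severe class is positive throughout). On top of the per-fold
machinery this module provides the saturation scan over k, the confusion
metrics (accuracy, sensitivity, specificity, MCC), rank-based ROC AUC,
reclassification measures (NRI, IDI), and the UPGMA clustering of risk
scores into molecular subtypes with the list of samples whose molecular
grade disagrees with the clinical one.

AUC is computed on the pooled out-of-fold risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from . import association
from .errors import ValidationError
from .risk_model import fit_risk_model, mean_impute, predict_risk
from .variant_io import MISSING, GenotypeMatrix, PhenotypeTable, VariantAnnotation


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    mcc: float


@dataclass
class FoldOutcome:
    risk: float
    predicted: str
    true: str
    fold_variants: list[str]


@dataclass
class LoocvResult:
    k: int
    per_sample: dict[str, FoldOutcome]
    confusion: tuple[int, int, int, int]  # tp, fp, fn, tn (severe = positive)
    metrics: Metrics
    auc: float
    pooled_variants: list[str]
    selection_counts: dict[str, int]


@dataclass
class SaturationScan:
    grid: list[int]
    accuracy_by_k: dict[int, float]
    chosen_k: int
    results: dict[int, LoocvResult] = field(repr=False, default_factory=dict)


@dataclass
class ReclassificationComparison:
    categories: list[float]
    table_events: np.ndarray
    table_nonevents: np.ndarray
    nri: float
    idi: float


@dataclass
class ClusterResult:
    linkage: np.ndarray
    cluster_of: dict[str, int]  # sample -> cluster index, 0 = highest mean risk
    severe_like: set[str]
    discordant: list[str]  # sorted by descending risk
    order: list[str]  # all samples sorted by descending risk


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Accuracy, sensitivity, specificity and MCC from a confusion matrix.

    MCC is 0 by convention when any factor of its denominator vanishes;
    sensitivity/specificity are absent (None) when their denominator is 0.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValidationError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / math.sqrt(den)
    return Metrics(accuracy, sensitivity, specificity, mcc)


def roc_auc(risks: Sequence[float], truths: Sequence[str]) -> float:
    """AUC as the Mann-Whitney probability P(risk_severe > risk_mild) + tie/2."""
    risks = np.asarray(risks, dtype=float)
    severe = np.asarray([t == "severe" for t in truths])
    n_s, n_m = int(severe.sum()), int((~severe).sum())
    if n_s == 0 or n_m == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = rankdata(risks)
    return float((ranks[severe].sum() - n_s * (n_s + 1) / 2) / (n_s * n_m))


def run_loocv(
    genotypes: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    phenotypes: PhenotypeTable,
    k: int,
    threshold: float = 0.5,
    prior_scale_coef: float = 2.5,
    prior_scale_intercept: float = 10.0,
    severe_mask: np.ndarray | None = None,
) -> LoocvResult:
    """One full LOOCV pass at a fixed number of selected variants ``k``.

    ``severe_mask`` overrides the phenotype table's severity column (used by
    the permutation null); everything else is recomputed per fold.
    """
    if severe_mask is None:
        severe_mask = phenotypes.severe_mask()
    severe_mask = np.asarray(severe_mask, dtype=bool)
    n = genotypes.n_samples
    if severe_mask.size != n:
        raise ValidationError("severity mask length does not match cohort size")
    if min(severe_mask.sum(), (~severe_mask).sum()) < 2:
        raise ValidationError("need at least 2 samples per class for LOOCV")
    if not 1 <= k <= genotypes.n_variants:
        raise ValidationError(f"k={k} out of range [1, {genotypes.n_variants}]")

    D = genotypes.dosage
    vindex = genotypes.variant_index()
    per_sample: dict[str, FoldOutcome] = {}
    counts: dict[str, int] = {}
    best_rank: dict[str, int] = {}
    for i, sid in enumerate(genotypes.sample_ids):
        train = np.ones(n, dtype=bool)
        train[i] = False
        results = association.associate_dosage(D[train], severe_mask[train], annotations)
        ranked = association.rank_variants(results)
        selected = association.select_top_k(ranked, k)
        cols = [vindex[v] for v in selected]
        Xtr = D[train][:, cols].astype(float)
        Xtr[Xtr == MISSING] = np.nan
        Xtr, means = mean_impute(Xtr)
        model = fit_risk_model(
            Xtr,
            severe_mask[train].astype(float),
            selected,
            prior_scale_coef=prior_scale_coef,
            prior_scale_intercept=prior_scale_intercept,
        )
        xte = D[i, cols].astype(float)
        xte[xte == MISSING] = np.nan
        xte, _ = mean_impute(xte[None, :], means)
        pred = predict_risk(model, xte, selected, [sid], threshold)[0]
        per_sample[sid] = FoldOutcome(
            risk=pred.risk,
            predicted=pred.predicted_class,
            true="severe" if severe_mask[i] else "mild",
            fold_variants=selected,
        )
        for rank_pos, v in enumerate(selected):
            counts[v] = counts.get(v, 0) + 1
            best_rank[v] = min(best_rank.get(v, rank_pos), rank_pos)

    tp = sum(1 for o in per_sample.values() if o.true == "severe" and o.predicted == "severe")
    fn = sum(1 for o in per_sample.values() if o.true == "severe" and o.predicted == "mild")
    fp = sum(1 for o in per_sample.values() if o.true == "mild" and o.predicted == "severe")
    tn = sum(1 for o in per_sample.values() if o.true == "mild" and o.predicted == "mild")
    metrics = confusion_metrics(tp, fp, fn, tn)
    auc = roc_auc(
        [o.risk for o in per_sample.values()], [o.true for o in per_sample.values()]
    )
    pooled = sorted(counts, key=lambda v: (-counts[v], best_rank[v], v))
    return LoocvResult(
        k=k,
        per_sample=per_sample,
        confusion=(tp, fp, fn, tn),
        metrics=metrics,
        auc=auc,
        pooled_variants=pooled,
        selection_counts=counts,
    )


def _scan(
    accuracy_fn: Callable[[int], float],
    k_start: int,
    k_step: int,
    patience: int,
    k_max: int,
) -> tuple[list[int], dict[int, float], int]:
    """Walk the k grid until `patience` consecutive values stay strictly
    below the running maximum accuracy (a tie with the maximum resets the
    counter), or the grid is exhausted."""
    if k_start < 1:
        raise ValidationError("k_start must be >= 1")
    if k_max < k_start:
        raise ValidationError(f"k_max ({k_max}) < k_start ({k_start})")
    if k_step < 1 or patience < 1:
        raise ValidationError("k_step and patience must be >= 1")
    grid: list[int] = []
    acc: dict[int, float] = {}
    best = -np.inf
    stale = 0
    for k in range(k_start, k_max + 1, k_step):
        grid.append(k)
        acc[k] = accuracy_fn(k)
        if acc[k] >= best:
            best = max(best, acc[k])
            stale = 0
        else:
            stale += 1
        if stale >= patience:
            break
    chosen = min(k for k in grid if acc[k] == max(acc.values()))
    return grid, acc, chosen


def saturation_scan(
    genotypes: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    phenotypes: PhenotypeTable,
    k_start: int = 6,
    k_step: int = 2,
    patience: int = 3,
    k_max: int | None = None,
    **loocv_kwargs,
) -> SaturationScan:
    """Scan LOOCV accuracy over increasing k and pick the saturation point.

    ``chosen_k`` is the smallest k attaining the maximum accuracy seen.
    """
    if k_max is None:
        k_max = min(genotypes.n_variants, 60)
    results: dict[int, LoocvResult] = {}

    def acc(k: int) -> float:
        results[k] = run_loocv(genotypes, annotations, phenotypes, k, **loocv_kwargs)
        return results[k].metrics.accuracy

    grid, accuracy_by_k, chosen = _scan(acc, k_start, k_step, patience, k_max)
    return SaturationScan(grid, accuracy_by_k, chosen, results)


def reclassification(
    risks_old: Sequence[float],
    risks_new: Sequence[float],
    truths: Sequence[str],
    cutpoints: Sequence[float] = (0.0, 0.5, 1.0),
) -> ReclassificationComparison:
    """Risk reclassification between two models: NRI and IDI.

    Categories are the half-open intervals [c_i, c_{i+1}) with the last
    interval closed. NRI = [P(up|severe) - P(down|severe)] -
    [P(up|mild) - P(down|mild)]; IDI is the between-class difference of the
    mean risk change.
    """
    old = np.asarray(risks_old, dtype=float)
    new = np.asarray(risks_new, dtype=float)
    severe = np.asarray([t == "severe" for t in truths])
    if not (old.size == new.size == severe.size):
        raise ValidationError("risk vectors and truths must have equal length")
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.size < 2 or np.any(np.diff(cuts) <= 0) or cuts[0] != 0.0 or cuts[-1] != 1.0:
        raise ValidationError("cutpoints must strictly increase from 0 to 1")
    if severe.all() or not severe.any():
        raise ValidationError("both classes must be present")

    def categorize(r: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(cuts, r, side="right") - 1, 0, cuts.size - 2)

    cat_old, cat_new = categorize(old), categorize(new)
    n_cat = cuts.size - 1
    tables = {}
    for label, mask in (("events", severe), ("nonevents", ~severe)):
        t = np.zeros((n_cat, n_cat), dtype=int)
        np.add.at(t, (cat_old[mask], cat_new[mask]), 1)
        tables[label] = t

    def net_up(mask: np.ndarray) -> float:
        up = float(np.mean(cat_new[mask] > cat_old[mask]))
        down = float(np.mean(cat_new[mask] < cat_old[mask]))
        return up - down

    nri = net_up(severe) - net_up(~severe)
    idi = float((new - old)[severe].mean() - (new - old)[~severe].mean())
    return ReclassificationComparison(list(cuts), tables["events"], tables["nonevents"], nri, idi)


def cluster_risk_scores(
    sample_ids: Sequence[str],
    risks: Sequence[float],
    clinical: Sequence[str],
    n_clusters: int = 2,
) -> ClusterResult:
    """UPGMA clustering of scalar risk scores into molecular subtypes.

    Average-linkage agglomeration with Euclidean distance on the 1-D risks;
    the tree is cut to ``n_clusters`` and clusters are indexed by descending
    mean risk, so cluster 0 is the "high-risk / severe-like" subtype.
    Discordant samples are those whose membership in cluster 0 disagrees
    with their clinical severity, reported sorted by descending risk.
    """
    risks = np.asarray(risks, dtype=float)
    if risks.size < n_clusters:
        raise ValidationError("fewer samples than requested clusters")
    if risks.size != len(sample_ids) or risks.size != len(clinical):
        raise ValidationError("sample_ids, risks and clinical must align")
    Z = hierarchy.linkage(risks[:, None], method="average", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    means = {c: risks[raw == c].mean() for c in np.unique(raw)}
    order_clusters = sorted(means, key=lambda c: -means[c])
    relabel = {c: i for i, c in enumerate(order_clusters)}
    cluster_of = {sid: relabel[c] for sid, c in zip(sample_ids, raw)}
    severe_like = {sid for sid in sample_ids if cluster_of[sid] == 0}
    clinical_of = dict(zip(sample_ids, clinical))
    discordant = [
        sid for sid in sample_ids if (sid in severe_like) != (clinical_of[sid] == "severe")
    ]
    by_risk = {sid: r for sid, r in zip(sample_ids, risks)}
    discordant.sort(key=lambda s: -by_risk[s])
    order = sorted(sample_ids, key=lambda s: -by_risk[s])
    return ClusterResult(Z, cluster_of, severe_like, discordant, order)


def permutation_null_accuracies(
    genotypes: GenotypeMatrix,
    annotations: Sequence[VariantAnnotation],
    phenotypes: PhenotypeTable,
    k: int,
    n_permutations: int,
    seed: int,
    **loocv_kwargs,
) -> np.ndarray:
    """LOOCV accuracies under seeded random permutations of the severity labels."""
    rng = np.random.default_rng(seed)
    base = phenotypes.severe_mask()
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(base)
        out[b] = run_loocv(
            genotypes, annotations, phenotypes, k, severe_mask=perm, **loocv_kwargs
        ).metrics.accuracy
    return out


def per_sample_table(result: LoocvResult, clusters: ClusterResult | None = None) -> pd.DataFrame:
    """Per-sample report: truth, out-of-fold risk, prediction, cluster."""
    rows = []
    for sid, o in result.per_sample.items():
        row = {
            "sample_id": sid,
            "true": o.true,
            "risk": o.risk,
            "predicted": o.predicted,
        }
        if clusters is not None:
            row["cluster"] = clusters.cluster_of[sid]
            row["discordant"] = sid in clusters.discordant
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("risk", ascending=False).reset_index(drop=True)
    return df
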