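import itertools

import numpy as np
import pytest

from riskgrader import evaluation
from riskgrader.errors import ValidationError
from riskgrader.evaluation import (
    _scan,
    cluster_risk_scores,
    confusion_metrics,
    reclassification,
    roc_auc,
    run_loocv,
)
from riskgrader.synthetic import CohortSpec, simulate_cohort


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(5, 0, 0, 5)
        assert (m.accuracy, m.sensitivity, m.specificity, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_constant_prediction_has_zero_mcc(self):
        m = confusion_metrics(0, 0, 4, 6)
        assert m.mcc == 0.0
        assert m.sensitivity == 0.0
        assert m.accuracy == 0.6

    def test_undefined_sensitivity_is_absent(self):
        m = confusion_metrics(0, 3, 0, 7)  # no true severe samples at all
        assert m.sensitivity is None

    def test_negative_counts_error(self):
        with pytest.raises(ValidationError):
            confusion_metrics(-1, 0, 0, 1)

    def test_mcc_is_plus_one_only_without_errors(self):
        assert confusion_metrics(3, 1, 0, 4).mcc < 1.0
        assert confusion_metrics(3, 0, 0, 4).mcc == 1.0


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], ["severe", "severe", "mild", "mild"]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.4] * 6, ["severe"] * 3 + ["mild"] * 3) == 0.5

    def test_matches_exhaustive_pair_oracle(self, rng):
        risks = rng.random(12)
        truths = ["severe" if rng.random() < 0.5 else "mild" for _ in range(12)]
        if "severe" not in truths:
            truths[0] = "severe"
        if "mild" not in truths:
            truths[-1] = "mild"
        sev = [r for r, t in zip(risks, truths) if t == "severe"]
        mld = [r for r, t in zip(risks, truths) if t == "mild"]
        oracle = np.mean(
            [1.0 if s > m else 0.5 if s == m else 0.0 for s, m in itertools.product(sev, mld)]
        )
        assert roc_auc(risks, truths) == pytest.approx(oracle)

    def test_invariant_under_monotone_transform(self, rng):
        risks = rng.random(20)
        truths = ["severe"] * 9 + ["mild"] * 11
        assert roc_auc(risks, truths) == pytest.approx(
            roc_auc(1 / (1 + np.exp(-7 * risks)), truths)
        )

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc([0.5, 0.6], ["severe", "severe"])


class TestReclassification:
    def test_identity_comparison_is_zero(self, rng):
        r = rng.random(10)
        t = ["severe"] * 4 + ["mild"] * 6
        cmp = reclassification(r, r, t)
        assert cmp.nri == 0.0 and cmp.idi == 0.0

    def test_single_upward_move_of_one_severe_sample(self):
        old = [0.4, 0.3, 0.7, 0.2, 0.6]
        new = [0.6, 0.3, 0.7, 0.2, 0.6]
        t = ["severe", "severe", "severe", "mild", "mild"]
        cmp = reclassification(old, new, t)
        assert cmp.nri == pytest.approx(1 / 3)
        assert cmp.table_events[0, 1] == 1

    def test_matches_direct_count_oracle(self, rng):
        n = 30
        old, new = rng.random(n), rng.random(n)
        t = ["severe" if x < 0.5 else "mild" for x in rng.random(n)]
        t[0], t[1] = "severe", "mild"
        cmp = reclassification(old, new, t, cutpoints=(0, 0.25, 0.5, 0.75, 1.0))

        def cat(r):
            for i, c in enumerate((0.25, 0.5, 0.75, 1.0)):
                if r < c or c == 1.0:
                    return i
        up_e = down_e = up_n = down_n = n_e = n_n = 0
        ids_e = ids_n = 0.0
        for o, nw, tt in zip(old, new, t):
            if tt == "severe":
                n_e += 1
                up_e += cat(nw) > cat(o)
                down_e += cat(nw) < cat(o)
                ids_e += nw - o
            else:
                n_n += 1
                up_n += cat(nw) > cat(o)
                down_n += cat(nw) < cat(o)
                ids_n += nw - o
        oracle_nri = (up_e - down_e) / n_e - (up_n - down_n) / n_n
        oracle_idi = ids_e / n_e - ids_n / n_n
        assert cmp.nri == pytest.approx(oracle_nri)
        assert cmp.idi == pytest.approx(oracle_idi)

    def test_antisymmetry_under_model_swap(self, rng):
        old, new = rng.random(15), rng.random(15)
        t = ["severe"] * 7 + ["mild"] * 8
        fwd = reclassification(old, new, t)
        rev = reclassification(new, old, t)
        assert fwd.nri == pytest.approx(-rev.nri)
        assert fwd.idi == pytest.approx(-rev.idi)

    def test_invalid_cutpoints_error(self):
        with pytest.raises(ValidationError):
            reclassification([0.1], [0.2], ["severe"], cutpoints=(0, 0.7, 0.5, 1))


def brute_force_upgma(points):
    """Independent O(n^3) average-linkage clustering of scalar points."""
    clusters = {i: [i] for i in range(len(points))}
    sizes = {i: 1 for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [abs(points[p] - points[q]) for p in clusters[i] for q in clusters[j]]
            )
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        d, i, j = best
        merges.append(d)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestClustering:
    def test_merge_heights_match_brute_force_upgma(self, rng):
        points = rng.random(20)
        Z = cluster_risk_scores(
            [f"s{i}" for i in range(20)], points, ["severe"] * 10 + ["mild"] * 10
        ).linkage
        assert np.allclose(sorted(Z[:, 2]), sorted(brute_force_upgma(points)), atol=1e-10)

    def test_clean_separation_has_no_discordance(self):
        res = cluster_risk_scores(
            ["a", "b", "c", "d"],
            [0.9, 0.85, 0.1, 0.12],
            ["severe", "severe", "mild", "mild"],
        )
        assert res.discordant == []
        assert res.severe_like == {"a", "b"}

    def test_fully_swapped_labels_are_all_discordant(self):
        res = cluster_risk_scores(["a", "b"], [0.9, 0.2], ["mild", "severe"])
        assert set(res.discordant) == {"a", "b"}
        assert res.discordant[0] == "a"  # sorted by descending risk

    def test_too_few_samples_error(self):
        with pytest.raises(ValidationError):
            cluster_risk_scores(["a"], [0.5], ["mild"], n_clusters=2)


class TestSaturationRule:
    def test_walkthrough_with_plateau(self):
        accs = {6: 0.7, 8: 0.8, 10: 0.8, 12: 0.75, 14: 0.75, 16: 0.75, 18: 0.9}
        grid, by_k, chosen = _scan(lambda k: accs[k], 6, 2, 3, 40)
        # ties with the running max reset patience; three strict drops stop the scan
        assert grid == [6, 8, 10, 12, 14, 16]
        assert chosen == 8

    def test_monotone_decreasing_chooses_k_start(self):
        grid, by_k, chosen = _scan(lambda k: 1.0 / k, 6, 2, 3, 30)
        assert chosen == 6

    def test_k_max_bounds_the_grid(self):
        grid, _, _ = _scan(lambda k: 0.5, 6, 2, 3, 10)
        assert grid == [6, 8, 10]

    def test_bad_grid_errors(self):
        with pytest.raises(ValidationError):
            _scan(lambda k: 0.5, 6, 2, 3, 4)


@pytest.fixture(scope="module")
def separable_cohort():
    return simulate_cohort(
        CohortSpec(seed=21, n_variants=300, planted_risk_variants=5,
                   background_aaf=0.05, risk_delta=0.9, missing_rate=0.0)
    )


class TestLoocv:
    def test_fold_structure(self, small_cohort):
        res = run_loocv(small_cohort.genotypes, small_cohort.annotations,
                        small_cohort.phenotypes, k=5)
        assert len(res.per_sample) == 12
        tp, fp, fn, tn = res.confusion
        assert tp + fn == 5 and tn + fp == 7
        assert all(len(o.fold_variants) == 5 for o in res.per_sample.values())

    def test_near_separable_cohort_classifies_almost_perfectly(self, separable_cohort):
        c = separable_cohort
        res = run_loocv(c.genotypes, c.annotations, c.phenotypes, k=5)
        assert res.metrics.accuracy >= 0.9
        planted = set(c.truth.risk_variant_ids)
        assert planted & set(res.pooled_variants)
        # the strongest planted variants are selected in every fold
        top = res.pooled_variants[0]
        assert res.selection_counts[top] == 33 and top in planted

    def test_no_leakage_from_the_held_out_sample(self, small_cohort):
        """Perturbing the held-out sample's dosages cannot change that fold's
        selected variant list."""
        c = small_cohort
        res = run_loocv(c.genotypes, c.annotations, c.phenotypes, k=5)
        sid = c.genotypes.sample_ids[0]
        perturbed = c.genotypes.dosage.copy()
        perturbed[0] = (perturbed[0] + 1) % 3
        from riskgrader.variant_io import GenotypeMatrix

        g2 = GenotypeMatrix(c.genotypes.sample_ids, c.genotypes.variant_ids, perturbed)
        res2 = run_loocv(g2, c.annotations, c.phenotypes, k=5)
        assert res.per_sample[sid].fold_variants == res2.per_sample[sid].fold_variants

    def test_permutation_null_no_better_than_majority(self):
        """LOOCV accuracy under label permutation does not beat the
        majority-class rate (it is typically below it)."""
        c = simulate_cohort(
            CohortSpec(seed=3, n_severe=9, n_mild=11, n_variants=300,
                       planted_risk_variants=0, risk_delta=0.0)
        )
        null = evaluation.permutation_null_accuracies(
            c.genotypes, c.annotations, c.phenotypes, k=6,
            n_permutations=100, seed=5,
        )
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert null.mean() <= 11 / 20 + 3 * se
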