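"""Evaluation metrics against closed forms and brute-force sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disograph.io import LabelMatrix, PropensityProfile
from disograph.metrics import (
    ConfusionCounts,
    auc,
    aupr_aps,
    compare_predictors,
    confusion,
    evaluate,
    fmax,
    mcc_bacc,
    mf_residue_eval,
)


def mann_whitney_auc(scores, labels):
    """Oracle: explicit pairwise count with ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exhaustive_fmax(scores, labels):
    best = 0.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        if tp:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_pairwise_count(self):
        assert auc([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            assert auc(scores, labels) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(np.linspace(0.01, 0.99, 20))  # tie-free
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestPRMetrics:
    def test_perfect_ranking(self):
        aupr, aps = aupr_aps([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == pytest.approx(1.0)
        assert aps == pytest.approx(1.0)

    def test_single_positive_ranked_last(self):
        _, aps = aupr_aps([0.9, 0.8, 0.7, 0.1], [0, 0, 0, 1])
        assert aps == pytest.approx(0.25)

    def test_aps_step_sum_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0] = 1
        order = np.argsort(-scores)
        y = labels[order]
        tp = np.cumsum(y)
        prec = tp / np.arange(1, 31)
        rec = tp / y.sum()
        aps_oracle = np.sum(np.diff(np.concatenate([[0], rec])) * prec)
        _, aps = aupr_aps(scores, labels)
        assert aps == pytest.approx(aps_oracle, abs=1e-12)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            aupr_aps([0.5, 0.1], [0, 0])


class TestFmax:
    def test_perfect(self):
        f, _ = fmax([0.9, 0.8, 0.2], [1, 1, 0])
        assert f == 1.0

    def test_worked_sweep(self):
        # thresholds 0.1 -> F1 = 2*2/(2*2+1+0) = 0.8; 0.8 -> 2/(2+1+1) = 0.5;
        # 0.9 -> 2/(2+0+1) = 2/3; maximum is 0.8 at threshold 0.1
        f, thr = fmax([0.9, 0.8, 0.1], [1, 0, 1])
        assert f == pytest.approx(0.8)
        assert thr == pytest.approx(0.1)

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(3, 25))
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = np.round(rng.random(n), 2)
            f, thr = fmax(scores, labels)
            assert f == pytest.approx(exhaustive_fmax(scores, labels), abs=1e-12)

    def test_fmax_bounds_fixed_threshold_f1(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1
        f, _ = fmax(scores, labels)
        for t in (0.2, 0.5, 0.8):
            pred = scores >= t
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            fn = int((~pred & (labels == 1)).sum())
            f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            assert f >= f1 - 1e-12

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        f1, _ = fmax(scores, labels)
        f2, _ = fmax(1 / (1 + np.exp(-5 * scores)), labels)
        assert f1 == pytest.approx(f2)
        assert auc(scores, labels) == pytest.approx(
            auc(scores ** 3, labels))


class TestMccBacc:
    @pytest.mark.parametrize("counts,mcc,bacc", [
        (ConfusionCounts(1, 1, 1, 1), 0.0, 0.5),
        (ConfusionCounts(2, 0, 2, 0), 1.0, 1.0),
        (ConfusionCounts(3, 1, 4, 2), 10 / np.sqrt(600), 0.7),
    ])
    def test_closed_forms(self, counts, mcc, bacc):
        m, b = mcc_bacc(counts)
        assert m == pytest.approx(mcc, abs=1e-4)
        assert b == pytest.approx(bacc, abs=1e-12)

    def test_degenerate_denominator_is_zero(self):
        m, _ = mcc_bacc(ConfusionCounts(0, 0, 5, 5))
        assert m == 0.0

    def test_sign_flip_on_complement(self):
        m1, _ = mcc_bacc(ConfusionCounts(4, 1, 4, 1))
        m2, _ = mcc_bacc(ConfusionCounts(1, 4, 1, 4))
        assert m1 == pytest.approx(-m2)


def _profile_pair(rng, n_prot=3, L=30):
    profs, labs = [], []
    for i in range(n_prot):
        scores = rng.random((L, 7))
        labels = rng.integers(0, 2, (L, 7))
        labels[0] = 1
        labels[1] = 0
        profs.append(PropensityProfile(f"P{i}", scores))
        labs.append(LabelMatrix(f"P{i}", labels))
    return profs, labs


class TestEvaluate:
    def test_pooled_equals_concatenated_auc(self):
        rng = np.random.default_rng(6)
        profs, labs = _profile_pair(rng)
        report = evaluate(profs, labs, np.full(7, 0.5))
        S = np.concatenate([p.scores for p in profs])
        Y = np.concatenate([l.labels for l in labs])
        for h, head in enumerate(report.per_head):
            assert report.per_head[head]["auc"] == pytest.approx(
                auc(S[:, h], Y[:, h]))

    def test_duplication_invariance(self):
        rng = np.random.default_rng(7)
        profs, labs = _profile_pair(rng, n_prot=1)
        r1 = evaluate(profs, labs, np.full(7, 0.5))
        profs2 = profs + [PropensityProfile("Q0", profs[0].scores)]
        labs2 = labs + [LabelMatrix("Q0", labs[0].labels)]
        r2 = evaluate(profs2, labs2, np.full(7, 0.5))
        for head in r1.per_head:
            assert r1.per_head[head]["auc"] == pytest.approx(
                r2.per_head[head]["auc"])

    def test_per_protein_single_equals_pooled(self):
        rng = np.random.default_rng(8)
        profs, labs = _profile_pair(rng, n_prot=1)
        report = evaluate(profs, labs, np.full(7, 0.5), per_protein=True)
        table = report.per_protein["P0"]
        for head in table:
            assert table[head]["auc"] == pytest.approx(
                report.per_head[head]["auc"])

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        profs, labs = _profile_pair(rng, n_prot=2)
        with pytest.raises(ValueError):
            evaluate(profs[:1], labs[1:], np.full(7, 0.5))


class TestMFResidues:
    def _toy(self):
        """6 residues, two MF types, hand-enumerated below."""
        # functions: protein_binding (col 1) and lipid_binding (col 5),
        # dna_binding (col 2) + rna_binding (col 3)
        labels = np.zeros((6, 7), int)
        labels[0, [1, 5]] = 1          # type A
        labels[1, [1, 5]] = 1          # type A
        labels[2, [2, 3]] = 1          # type B
        labels[3, 1] = 1               # single-function residue
        # residues 4, 5 unannotated
        scores = np.full((6, 7), 0.1)
        scores[0, [1, 5]] = 0.9        # type-A residue, both heads high
        scores[1, 1] = 0.9             # type-A residue, lipid head low
        scores[1, 5] = 0.2
        scores[2, [2, 3]] = 0.8        # type-B residue, both high
        scores[3, [1, 5]] = 0.7        # false positive for type A
        return ([PropensityProfile("P0", scores)],
                [LabelMatrix("P0", labels)])

    def test_hand_enumerated_fmax(self):
        profs, labs = self._toy()
        table = mf_residue_eval(profs, labs, np.full(7, 0.5))
        a = table[("protein_binding", "lipid_binding")]
        b = table[("dna_binding", "rna_binding")]
        # type A: min-scores are [0.9, 0.2, 0.1, 0.7, 0.1, 0.1], pos = r0, r1.
        # thr 0.9: P=1, R=1/2 -> F1 = 2/3; thr 0.7: 1 TP 1 FP 1 FN -> 1/2;
        # thr 0.2: 2 TP 1 FP -> 4/5; thr 0.1: 2 TP 4 FP -> 1/2. Fmax = 0.8.
        assert a["fmax"] == pytest.approx(0.8)
        assert a["n_residues"] == 2
        # type B: min-scores [0.1, 0.1, 0.8, 0.1, 0.1, 0.1], single positive
        # perfectly separated -> Fmax = 1.
        assert b["fmax"] == pytest.approx(1.0)

    def test_joint_correctness_rule(self):
        profs, labs = self._toy()
        table = mf_residue_eval(profs, labs, np.full(7, 0.5))
        a = table[("protein_binding", "lipid_binding")]
        # at 0.5 thresholds: r0 correct, r1 not (lipid head below), r3 FP
        assert a["mcc"] == pytest.approx(mcc_bacc(
            ConfusionCounts(tp=1, fp=1, tn=3, fn=1))[0])

    def test_no_mf_residues_warns_empty(self, caplog):
        labels = np.zeros((3, 7), int)
        labels[0, 1] = 1
        out = mf_residue_eval([PropensityProfile("P", np.full((3, 7), 0.2))],
                              [LabelMatrix("P", labels)], np.full(7, 0.5))
        assert out == {}


class TestComparePredictors:
    def test_identical_predictors_null_p(self):
        rng = np.random.default_rng(10)
        profs, labs = _profile_pair(rng, n_prot=4)
        pvals = compare_predictors(profs, profs, labs, n_resamples=200, seed=1)
        assert all(p > 0.5 for p in pvals.values())

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        profs, labs = _profile_pair(rng, n_prot=4)
        other = [PropensityProfile(p.protein_id, np.clip(
            p.scores + 0.05, 0, 1)) for p in profs]
        p1 = compare_predictors(profs, other, labs, n_resamples=100, seed=3)
        p2 = compare_predictors(profs, other, labs, n_resamples=100, seed=3)
        assert p1 == p2

    def test_converges_to_reference(self):
        """Resampled p-values converge to a large-resample reference."""
        rng = np.random.default_rng(12)
        profs, labs = _profile_pair(rng, n_prot=5, L=20)
        noisy = [PropensityProfile(p.protein_id, np.clip(
            p.scores + rng.normal(0, 0.3, p.scores.shape), 0, 1))
            for p in profs]
        ref = compare_predictors(profs, noisy, labs, n_resamples=50_000, seed=0)
        est = compare_predictors(profs, noisy, labs, n_resamples=5000, seed=99)
        for head in ref:
            assert est[head] == pytest.approx(ref[head], abs=0.05)

    def test_rank_auc_matches_public_auc(self):
        from disograph.metrics import _rank_auc
        rng = np.random.default_rng(14)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)
            assert _rank_auc(scores, labels) == pytest.approx(
                auc(scores, labels), abs=1e-12)

    def test_too_few_proteins_rejected(self):
        rng = np.random.default_rng(13)
        profs, labs = _profile_pair(rng, n_prot=1)
        with pytest.raises(ValueError):
            compare_predictors(profs, profs, labs)
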