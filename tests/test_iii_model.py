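import random

import numpy as np
import pytest

from iiinet.data_io import Isoform, IsoformCatalog
from iiinet.errors import ContractViolation
from iiinet.features import PairFeatureVector
from iiinet.iii_model import (
    CoefficientVector,
    evaluate_on_test,
    fit_logistic,
    logit_score,
    precision_recall_curve,
    predict,
    score_many,
    standard_errors,
    threshold_for_operating_point,
)
from iiinet.synthetic_data import sample_model_pairs


def fv(ddi, corr, a="I1", b="I2"):
    return PairFeatureVector(a, b, ddi=ddi, corr=tuple(corr))


class TestLogitScore:
    def test_all_zero_coefficients(self):
        coeffs = CoefficientVector(0.0, (0.0, 0.0), 0.0)
        vec = fv(2, (0.5, 0.9))
        assert logit_score(coeffs, vec) == 0.0

    def test_intercept_only(self):
        coeffs = CoefficientVector(1.0, (0.0,), 0.0)
        assert logit_score(coeffs, fv(0, (0.0,))) == pytest.approx(1.0)

    def test_probability_is_inverse_logit(self):
        from iiinet.iii_model import IIIPrediction

        p = IIIPrediction(("I1", "I2"), ("G1", "G2"), 0.0, "low", fv(0, ()))
        assert p.probability == pytest.approx(0.5)

    def test_random_against_dot_product(self):
        rng = random.Random(5)
        for _ in range(50):
            k = rng.randint(1, 6)
            coeffs = CoefficientVector(
                rng.uniform(-2, 2),
                tuple(rng.uniform(-2, 2) for _ in range(k)),
                rng.uniform(-2, 2),
            )
            corr = [rng.uniform(0, 1) for _ in range(k)]
            ddi = rng.randint(0, 3)
            expected = (
                coeffs.alpha0
                + sum(a * c for a, c in zip(coeffs.alpha_corr, corr))
                + coeffs.alpha_ddi * ddi
            )
            assert logit_score(coeffs, fv(ddi, corr)) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        coeffs = CoefficientVector(0.0, (1.0, 1.0), 0.0)
        with pytest.raises(ContractViolation):
            logit_score(coeffs, fv(0, (0.5,)))


class TestFitLogistic:
    def test_separable_data_converges_with_ridge(self):
        feats = [fv(0, (0.1,)), fv(0, (0.2,)), fv(0, (0.8,)), fv(0, (0.9,))]
        labels = [0, 0, 1, 1]
        coeffs = fit_logistic(feats, labels, ridge=0.1)
        scores = score_many(coeffs, feats)
        assert ((scores > 0).astype(int) == np.array(labels)).all()
        assert np.isfinite(coeffs.as_array()).all()

    def test_single_class_rejected(self):
        with pytest.raises(ContractViolation):
            fit_logistic([fv(0, (0.1,)), fv(0, (0.2,))], [1, 1])

    def test_permuted_labels_large_ridge_kills_slopes(self):
        rng = np.random.default_rng(0)
        feats, labels = sample_model_pairs(
            400, CoefficientVector(-1.0, (2.0,), 0.5), seed=3
        )
        permuted = rng.permutation(labels).tolist()
        if len(set(permuted)) < 2:  # pragma: no cover
            permuted[0] = 1 - permuted[0]
        coeffs = fit_logistic(feats, permuted, ridge=1e6)
        assert abs(coeffs.alpha_corr[0]) < 1e-2
        assert abs(coeffs.alpha_ddi) < 1e-2

    def test_parameter_recovery_within_three_se(self):
        truth = CoefficientVector(-3.0, (2.0, 2.0), 0.8)
        feats, labels = sample_model_pairs(5000, truth, seed=17)
        coeffs = fit_logistic(feats, labels)
        se = standard_errors(coeffs, feats)
        est = coeffs.as_array()
        for e, t, s in zip(est, truth.as_array(), se):
            assert abs(e - t) < 3 * s, (e, t, s)

    def test_estimates_tighten_with_sample_size(self):
        truth = CoefficientVector(-2.0, (1.5,), 0.6)
        errs = []
        for n in (500, 20000):
            feats, labels = sample_model_pairs(n, truth, seed=29)
            coeffs = fit_logistic(feats, labels)
            errs.append(
                float(np.linalg.norm(coeffs.as_array() - truth.as_array()))
            )
        assert errs[1] < errs[0]


def pr_oracle(scores, labels, t):
    """Brute-force confusion matrix at one threshold (strict >)."""
    tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
    pos = sum(labels)
    precision = tp / (tp + fp) if tp + fp else 1.0
    return precision, tp / pos


class TestPRCurve:
    def test_simple_curve(self):
        curve = precision_recall_curve([3, 2, 1], [1, 1, 0])
        # threshold 1: items {3,2} called -> precision 1.0, recall 1.0
        idx = curve.thresholds.index(1.0)
        assert curve.precision[idx] == 1.0
        assert curve.recall[idx] == 1.0

    def test_all_positive_labels(self):
        curve = precision_recall_curve([0.2, 0.5, 0.9], [1, 1, 1])
        assert all(p == 1.0 for p in curve.precision)

    def test_no_positives_rejected(self):
        with pytest.raises(ContractViolation):
            precision_recall_curve([1.0, 2.0], [0, 0])

    def test_randomized_against_confusion_matrix(self):
        rng = random.Random(31)
        for _ in range(100):
            n = rng.randint(5, 40)
            scores = [rng.choice([0.1, 0.4, 0.5, 0.9, 1.3]) for _ in range(n)]
            labels = [rng.randint(0, 1) for _ in range(n)]
            if sum(labels) == 0:
                labels[0] = 1
            curve = precision_recall_curve(scores, labels)
            assert list(curve.thresholds) == sorted(set(scores))
            for t, p, r in curve:
                ep, er = pr_oracle(scores, labels, t)
                assert p == pytest.approx(ep)
                assert r == pytest.approx(er)

    def test_recall_non_increasing(self):
        rng = random.Random(37)
        scores = [rng.uniform(0, 1) for _ in range(200)]
        labels = [rng.randint(0, 1) for _ in range(200)]
        labels[0] = 1
        curve = precision_recall_curve(scores, labels)
        assert all(
            a >= b for a, b in zip(curve.recall, curve.recall[1:])
        )
        assert all(
            a < b for a, b in zip(curve.thresholds, curve.thresholds[1:])
        )


class TestOperatingPoint:
    def test_target_zero_gives_minimum_threshold(self):
        curve = precision_recall_curve([1, 2, 3], [0, 1, 1])
        assert threshold_for_operating_point(curve, 0.0) == min(curve.thresholds)

    def test_unachievable_target_names_maximum(self):
        curve = precision_recall_curve([1, 2, 3], [1, 0, 0])
        with pytest.raises(ContractViolation, match="maximum"):
            threshold_for_operating_point(curve, 0.99)

    def test_randomized_against_full_scan(self):
        rng = random.Random(41)
        for _ in range(100):
            n = rng.randint(5, 30)
            scores = [rng.uniform(0, 1) for _ in range(n)]
            labels = [rng.randint(0, 1) for _ in range(n)]
            if sum(labels) == 0:
                labels[0] = 1
            curve = precision_recall_curve(scores, labels)
            target = rng.uniform(0, 1)
            eligible = [
                t
                for (t, p, _r), c in zip(curve, curve.n_called)
                if c > 0 and p >= target
            ]
            if not eligible:
                with pytest.raises(ContractViolation):
                    threshold_for_operating_point(curve, target)
            else:
                assert threshold_for_operating_point(curve, target) == min(
                    eligible
                )


def two_gene_catalog():
    return IsoformCatalog(
        [
            Isoform("A1", "GA", frozenset()),
            Isoform("A2", "GA", frozenset()),
            Isoform("B1", "GB", frozenset()),
        ]
    )


class TestPredict:
    def make_features(self, corr_by_pair):
        return [
            PairFeatureVector(a, b, ddi=0, corr=(c,))
            for (a, b), c in sorted(corr_by_pair.items())
        ]

    def test_tier_assignment_and_rescue(self):
        catalog = two_gene_catalog()
        # score = 10 * corr  (alpha0 = 0)
        coeffs = CoefficientVector(0.0, (10.0,), 0.0)
        feats = self.make_features(
            {("A1", "B1"): 0.30, ("A2", "B1"): 0.04}
        )
        preds = predict(
            feats, coeffs, [("GA", "GB")], catalog,
            high_threshold=2.575, low_threshold=1.692,
        )
        by_pair = {p.pair: p for p in preds}
        assert by_pair[("A1", "B1")].tier == "high"  # 3.0 > 2.575
        assert ("A2", "B1") not in by_pair  # 0.4, not best of PPI

    def test_rescue_when_all_below_low(self):
        catalog = two_gene_catalog()
        coeffs = CoefficientVector(0.0, (1.0,), 0.0)
        feats = self.make_features({("A1", "B1"): 0.4, ("A2", "B1"): 0.2})
        preds = predict(feats, coeffs, [("GA", "GB")], catalog)
        assert len(preds) == 1
        assert preds[0].pair == ("A1", "B1")
        assert preds[0].tier == "rescued"

    def test_strict_threshold_boundaries(self):
        catalog = two_gene_catalog()
        coeffs = CoefficientVector(0.0, (1.0,), 0.0)
        # scores exactly at the thresholds are NOT above them
        feats = [
            PairFeatureVector("A1", "B1", ddi=0, corr=(0.9,)),
        ]
        preds = predict(
            feats, coeffs, [("GA", "GB")], catalog,
            high_threshold=0.9, low_threshold=0.9,
        )
        assert preds[0].tier == "rescued"

    def test_pair_without_ppi_rejected(self):
        catalog = two_gene_catalog()
        coeffs = CoefficientVector(0.0, (1.0,), 0.0)
        feats = self.make_features({("A1", "B1"): 0.5})
        with pytest.raises(ContractViolation):
            predict(feats, coeffs, [], catalog)

    def test_randomized_against_rule_oracle(self):
        rng = random.Random(43)
        for trial in range(30):
            n_genes = rng.randint(2, 6)
            isoforms = []
            by_gene = {}
            serial = 0
            for g in range(n_genes):
                gene = f"G{g}"
                by_gene[gene] = []
                for _ in range(rng.randint(1, 3)):
                    serial += 1
                    iso = f"I{serial:02d}"
                    isoforms.append(Isoform(iso, gene, frozenset()))
                    by_gene[gene].append(iso)
            catalog = IsoformCatalog(isoforms)
            genes = sorted(by_gene)
            ppis = set()
            for _ in range(rng.randint(1, 4)):
                ppis.add(tuple(sorted(rng.sample(genes, 2))))
            feats = []
            for ga, gb in sorted(ppis):
                for ia in by_gene[ga]:
                    for ib in by_gene[gb]:
                        a, b = sorted((ia, ib))
                        feats.append(
                            PairFeatureVector(
                                a, b, ddi=0, corr=(rng.uniform(0, 1),)
                            )
                        )
            coeffs = CoefficientVector(rng.uniform(-2, 2), (4.0,), 0.0)
            hi = rng.uniform(0.5, 2.5)
            lo = rng.uniform(-1.0, hi)
            preds = predict(
                feats, coeffs, sorted(ppis), catalog,
                high_threshold=hi, low_threshold=lo,
            )

            # oracle: apply the three tier rules pair by pair
            scores = {f.pair: logit_score(coeffs, f) for f in feats}
            gene_of = {i.isoform_id: i.gene_id for i in isoforms}
            best = {}
            for f in feats:
                gp = tuple(sorted((gene_of[f.pair[0]], gene_of[f.pair[1]])))
                cur = best.get(gp)
                cand = (-scores[f.pair], f.pair)
                if cur is None or cand < cur:
                    best[gp] = cand
            expected = {}
            for f in feats:
                s = scores[f.pair]
                gp = tuple(sorted((gene_of[f.pair[0]], gene_of[f.pair[1]])))
                if s > hi:
                    expected[f.pair] = "high"
                elif s > lo:
                    expected[f.pair] = "low"
                elif best[gp][1] == f.pair:
                    expected[f.pair] = "rescued"
            assert {p.pair: p.tier for p in preds} == expected
            # rescue guarantee: every PPI with candidates has >= 1 prediction
            covered = {
                tuple(sorted((gene_of[p.pair[0]], gene_of[p.pair[1]])))
                for p in preds
            }
            assert covered == set(best)

    def test_enumeration_order_invariance(self):
        catalog = two_gene_catalog()
        coeffs = CoefficientVector(0.0, (3.0,), 0.0)
        feats = self.make_features({("A1", "B1"): 0.3, ("A2", "B1"): 0.6})
        fwd = predict(feats, coeffs, [("GA", "GB")], catalog)
        rev = predict(list(reversed(feats)), coeffs, [("GA", "GB")], catalog)
        assert fwd == rev


class TestEvaluateOnTest:
    def test_requires_both_classes(self):
        coeffs = CoefficientVector(0.0, (1.0,), 0.0)
        with pytest.raises(ContractViolation):
            evaluate_on_test(coeffs, [fv(0, (0.5,))], [1])

    def test_high_recall_never_exceeds_low_recall(self):
        truth = CoefficientVector(-2.0, (4.0,), 1.0)
        feats, labels = sample_model_pairs(800, truth, seed=51)
        coeffs = fit_logistic(feats, labels)
        ev = evaluate_on_test(coeffs, feats, labels)
        assert ev.low_recall >= ev.high_recall

    def test_null_world_precision_matches_prevalence(self):
        rng = np.random.default_rng(53)
        n = 4000
        feats = [
            fv(int(rng.integers(0, 4)), (float(rng.uniform(0, 1)),),
               a=f"A{i}", b=f"B{i}")
            for i in range(n)
        ]
        prevalence = 0.3
        labels = (rng.random(n) < prevalence).astype(int).tolist()
        coeffs = CoefficientVector(0.0, (1.0,), 0.25)  # arbitrary scorer
        ev = evaluate_on_test(
            coeffs, feats, labels, high_threshold=1.0, low_threshold=0.5
        )
        # with labels independent of scores, precision ~ prevalence
        for precision in (ev.high_precision, ev.low_precision):
            assert abs(precision - prevalence) < 3 * np.sqrt(
                prevalence * (1 - prevalence) / 500
            )
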