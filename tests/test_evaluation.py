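import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from speechmark.evaluation import (
    ProtocolConfig,
    auc_roc,
    delong_test,
    early_fusion,
    make_split,
    regression_metrics,
    run_protocol,
    zscore_fit_transform,
)
from speechmark.io_preprocess import CohortManifest, ParticipantRecord


def manifest_of(n_patient, n_control, mmse=None):
    parts = []
    for i in range(n_patient):
        parts.append(ParticipantRecord(id=f"p{i}", group="patient",
                                       mmse=mmse[i] if mmse else 20))
    for i in range(n_control):
        parts.append(ParticipantRecord(id=f"c{i}", group="control", mmse=29))
    return CohortManifest(parts)


class TestMakeSplit:
    def test_ten_plus_ten(self):
        plan = make_split(manifest_of(10, 10), 0.8, seed=0)
        train_p = [i for i in plan.train_ids if i.startswith("p")]
        test_p = [i for i in plan.test_ids if i.startswith("p")]
        assert (len(train_p), len(test_p)) == (8, 2)
        train_c = [i for i in plan.train_ids if i.startswith("c")]
        assert len(train_c) == 8

    def test_same_seed_identical(self):
        m = manifest_of(12, 9)
        assert make_split(m, seed=3) == make_split(m, seed=3)

    def test_all_seeds_disjoint_and_exhaustive(self):
        m = manifest_of(7, 11)
        all_ids = {p.id for p in m.participants}
        for seed in range(100):
            plan = make_split(m, seed=seed)
            train, test = set(plan.train_ids), set(plan.test_ids)
            assert train & test == set()
            assert train | test == all_ids

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="stratify"):
            make_split(manifest_of(1, 10))


class TestZScore:
    def test_train_columns_standardized(self, rng):
        train = pd.DataFrame(rng.normal(3, 2, (50, 4)), columns=list("abcd"))
        test = pd.DataFrame(rng.normal(3, 2, (20, 4)), columns=list("abcd"))
        train_z, test_z, mean, sd = zscore_fit_transform(train, test)
        np.testing.assert_allclose(train_z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(train_z.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_test_uses_train_parameters(self, rng):
        train = pd.DataFrame(rng.normal(0, 1, (50, 2)), columns=["a", "b"])
        test = pd.DataFrame(rng.normal(5, 1, (20, 2)), columns=["a", "b"])
        _, test_z, mean, sd = zscore_fit_transform(train, test)
        # test mean stays far from 0 because train parameters were applied
        assert test_z["a"].mean() > 2.0
        np.testing.assert_allclose(test_z["a"], (test["a"] - mean["a"]) / sd["a"])

    def test_constant_train_feature_dropped(self, rng):
        train = pd.DataFrame({"a": np.ones(30), "b": rng.normal(size=30)})
        test = pd.DataFrame({"a": np.ones(5), "b": rng.normal(size=5)})
        train_z, test_z, _, _ = zscore_fit_transform(train, test)
        assert list(train_z.columns) == ["b"]
        assert list(test_z.columns) == ["b"]


class TestEarlyFusion:
    def test_shapes_concatenate(self, rng):
        a = pd.DataFrame(rng.normal(size=(5, 3)),
                         columns=[f"timing__{i}" for i in range(3)],
                         index=list("abcde"))
        b = pd.DataFrame(rng.normal(size=(5, 2)),
                         columns=[f"lexsem__{i}" for i in range(2)],
                         index=list("abcde"))
        fused = early_fusion(a, b)
        assert fused.shape == (5, 5)

    def test_row_alignment_by_id(self, rng):
        idx = list("abcde")
        a = pd.DataFrame(rng.normal(size=(5, 2)),
                         columns=["timing__x", "timing__y"], index=idx)
        b = pd.DataFrame(rng.normal(size=(5, 2)),
                         columns=["lexsem__x", "lexsem__y"], index=idx[::-1])
        fused = early_fusion(a, b)
        assert fused.loc["a", "lexsem__x"] == b.loc["a", "lexsem__x"]

    def test_disjoint_ids_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(2, 1)), columns=["timing__x"], index=["a", "b"])
        b = pd.DataFrame(rng.normal(size=(2, 1)), columns=["lexsem__x"], index=["c", "d"])
        with pytest.raises(ValueError, match="id sets"):
            early_fusion(a, b)


class TestAUC:
    def test_perfect_separation(self):
        auc, _ = auc_roc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        auc, _ = auc_roc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_equals_rank_sum_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = auc_roc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            )
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_roc_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        auc, roc = auc_roc(scores, labels)
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)
        fpr = [p[0] for p in roc]
        tpr = [p[1] for p in roc]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_auc_equals_own_trapezoid(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        auc, roc = auc_roc(scores, labels)
        trap = sum((x1 - x0) * (y0 + y1) / 2
                   for (x0, y0), (x1, y1) in zip(roc, roc[1:]))
        assert auc == pytest.approx(trap, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            auc_roc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_self_comparison_degenerate(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        delta, p, degenerate = delong_test(scores, scores, labels)
        assert delta == 0.0
        assert p == 1.0
        assert degenerate

    def test_placements_match_bruteforce(self, rng):
        from speechmark.evaluation import _placements

        scores = rng.normal(size=12)
        labels = np.array([1, 0] * 6)
        v10, v01 = _placements(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for i, sp in enumerate(pos):
            expect = np.mean([1.0 if sp > sn else 0.5 if sp == sn else 0.0
                              for sn in neg])
            assert v10[i] == pytest.approx(expect, abs=1e-12)
        for j, sn in enumerate(neg):
            expect = np.mean([1.0 if sn < sp else 0.5 if sp == sn else 0.0
                              for sp in pos])
            assert v01[j] == pytest.approx(1 - (1 - expect), abs=1e-12)

    def test_detects_large_difference(self, rng):
        n = 200
        labels = np.array([1] * 100 + [0] * 100)
        good = labels * 2.0 + rng.normal(0, 0.5, n)
        bad = rng.normal(0, 1, n)
        _, p, degenerate = delong_test(good, bad, labels)
        assert not degenerate
        assert p < 0.001

    def test_mean_auc_difference_sign(self, rng):
        labels = np.array([1] * 50 + [0] * 50)
        good = labels + rng.normal(0, 0.8, 100)
        bad = rng.normal(size=100)
        delta, _, _ = delong_test(good, bad, labels)
        assert delta > 0


class TestRegressionMetrics:
    def test_identical_vectors(self):
        rho, rmse = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rho == pytest.approx(1.0)
        assert rmse == 0.0

    def test_reversed_ranks(self):
        rho, _ = regression_metrics([1.0, 2.0, 3.0, 4.0], [9.0, 7.0, 5.0, 1.0])
        assert rho == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        pred = rng.normal(20, 4, 15)
        true = rng.normal(20, 4, 15)
        rho, rmse = regression_metrics(pred, true)
        rp, rt = rankdata(pred), rankdata(true)
        rho_oracle = (np.mean(rp * rt) - np.mean(rp) * np.mean(rt)) / (
            np.std(rp) * np.std(rt)
        )
        rmse_oracle = math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, true)) / 15)
        assert rho == pytest.approx(rho_oracle, abs=1e-9)
        assert rmse == pytest.approx(rmse_oracle, abs=1e-9)

    def test_constant_vector_flagged_nan(self):
        rho, rmse = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho)
        assert rmse >= 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def cohort_and_features():
    from speechmark.pipeline import extract_cohort_features
    from speechmark.synthetic_data import CohortConfig, generate_cohort

    cohort = generate_cohort(CohortConfig(n_per_group=20, seed=9))
    return cohort, extract_cohort_features(cohort)


class TestProtocol:
    def test_within_mode_rejects_target(self, cohort_and_features):
        cohort, feats = cohort_and_features
        with pytest.raises(ValueError, match="target"):
            run_protocol(cohort.manifest(), feats, "timing",
                         target=cohort.manifest(), setting="within")

    def test_within_mode_strong_effect(self, cohort_and_features):
        cohort, feats = cohort_and_features
        rep = run_protocol(cohort.manifest(), feats, "timing",
                           config=ProtocolConfig(n_bootstrap=2, seed=0))
        assert np.mean(rep.bootstrap_aucs) >= 0.9

    def test_between_mode_requires_target(self, cohort_and_features):
        cohort, feats = cohort_and_features
        with pytest.raises(ValueError, match="target"):
            run_protocol(cohort.manifest(), feats, "timing", setting="between")

    def test_between_mode_model_independent_of_target(self):
        """Leakage audit: swapping the target cohort leaves the trained
        model bit-identical (0-shot guarantee)."""
        from speechmark.evaluation import _fit_and_score, _labels_for, select_modality
        from speechmark.pipeline import extract_cohort_features
        from speechmark.synthetic_data import CohortConfig, generate_cohort

        src = generate_cohort(CohortConfig(n_per_group=15, seed=1))
        tgt_a = generate_cohort(CohortConfig(n_per_group=10, seed=2))
        tgt_b = generate_cohort(CohortConfig(n_per_group=12, seed=3))
        fs = select_modality(extract_cohort_features(src), "timing")
        fa = select_modality(extract_cohort_features(tgt_a), "timing")
        fb = select_modality(extract_cohort_features(tgt_b), "timing")
        sids = [p.id for p in src.participants]
        y = _labels_for(src.manifest(), sids)
        config = ProtocolConfig(seed=0)
        model_a, _, _ = _fit_and_score(fs.loc[sids], fa, y, config, 0)
        model_b, _, _ = _fit_and_score(fs.loc[sids], fb, y, config, 0)
        assert model_a.W1.tobytes() == model_b.W1.tobytes()
        assert model_a.W2.tobytes() == model_b.W2.tobytes()
        assert model_a.b1.tobytes() == model_b.b1.tobytes()
        assert model_a.b2 == model_b.b2

    def test_report_serializes(self, cohort_and_features):
        cohort, feats = cohort_and_features
        rep = run_protocol(cohort.manifest(), feats, "lexsem",
                           config=ProtocolConfig(n_bootstrap=1, seed=4))
        d = rep.to_dict()
        assert d["modality"] == "lexsem"
        assert 0.0 <= d["auc"] <= 1.0
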