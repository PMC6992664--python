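import numpy as np
import pytest

from ctseg import (
    BinaryMask,
    auroc,
    bootstrap_ci,
    build_features,
    compare_auroc,
    cv_train_eval,
    dichotomize,
)
from ctseg.lesion_mask import LesionResult
from ctseg.outcome_model import ClinicalRecord, FeatureSpec, MissingField, ModelEval
from ctseg.zeta import ZetaMap


def record(**kw):
    base = dict(age=70.0, sex=1)
    base.update(kw)
    return ClinicalRecord(**base)


def lesion_result(rng, shape=(3, 3, 3), volume_ml=5.0):
    mask = BinaryMask(rng.uniform(size=shape) < 0.3, (4.0, 4.0, 4.0))
    zeta = ZetaMap(rng.normal(size=shape), (4.0, 4.0, 4.0))
    return LesionResult(mask=mask, mask_mni4=mask, zeta_mni4=zeta, volume_ml=volume_ml)


class TestDichotomize:
    @pytest.mark.parametrize(
        "outcome,kw,expected",
        [
            ("pre_mrs", dict(pre_mrs=2), 0),   # mRS 0-2 = independent
            ("pre_mrs", dict(pre_mrs=3), 1),
            ("dis_mrs", dict(dis_mrs=3), 1),   # mRS 3-6 = dependent
            ("dis_mrs", dict(dis_mrs=0), 0),
            ("nihss_deterioration", dict(nihss_admit=10, nihss_24h=13), 1),  # delta 3 > 2
            ("nihss_deterioration", dict(nihss_admit=10, nihss_24h=12), 0),
            ("sex", dict(sex=0), 0),
        ],
    )
    def test_rules(self, outcome, kw, expected):
        kw.setdefault("sex", 1)
        assert dichotomize(record(**kw), outcome) == expected

    def test_missing_field_excludes_record_with_reason(self):
        with pytest.raises(MissingField, match="dis_mrs"):
            dichotomize(record(), "dis_mrs")

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            record(pre_mrs=6)


class TestBuildFeatures:
    def test_age_tier_is_length_one(self):
        assert build_features(record(), spec=FeatureSpec("age")).shape == (1,)

    def test_voxel_mask_tier_length(self, rng):
        les = lesion_result(rng)
        v = build_features(record(), les, FeatureSpec("+voxel_mask"))
        assert v.shape == (5 + 27,)

    def test_combined_tier_concatenates_mask_and_zeta(self, rng):
        les = lesion_result(rng)
        v = build_features(record(), les, FeatureSpec("+voxel_mask_zeta"))
        assert v.shape == (5 + 27 + 27,)

    def test_volume_tier_appends_single_scalar(self, rng):
        les = lesion_result(rng, volume_ml=7.5)
        v = build_features(record(), les, FeatureSpec("+lesion_volume"))
        assert v.shape == (6,)
        assert v[-1] == 7.5

    def test_voxel_ordering_consistent_across_subjects(self, rng):
        les1 = lesion_result(rng)
        les2 = lesion_result(rng)
        v1 = build_features(record(), les1, FeatureSpec("+voxel_mask"))
        v2 = build_features(record(), les2, FeatureSpec("+voxel_mask"))
        # voxel j must mean the same location: flip one voxel, only that
        # feature may change
        data = les1.mask_mni4.data.copy()
        data[1, 2, 0] ^= True
        les1b = lesion_result(rng)
        les1b.mask_mni4 = BinaryMask(data, les1.mask_mni4.spacing)
        v1b = build_features(record(), les1b, FeatureSpec("+voxel_mask"))
        changed = np.flatnonzero(v1 != v1b)
        assert changed.size == 1
        assert changed[0] == 5 + np.ravel_multi_index((1, 2, 0), (3, 3, 3))
        assert v1.shape == v2.shape

    def test_imaging_tier_without_lesion_rejected(self):
        with pytest.raises(ValueError, match="lesion"):
            build_features(record(), None, FeatureSpec("+voxel_mask"))


class TestAuroc:
    def test_hand_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_concordant_pair_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 101))
            scores = rng.choice(np.linspace(0, 1, 20), size=n)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert auroc(scores, labels) == pytest.approx(wins / (pos.size * neg.size))

    def test_antisymmetry_for_tie_free_scores(self, rng):
        scores = rng.permutation(100) / 100.0
        labels = rng.integers(0, 2, 100)
        if labels.sum() in (0, 100):
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2, 3], [1, 1, 1])


class TestBootstrapCI:
    def test_perfect_separation_gives_degenerate_ci(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert bootstrap_ci(scores, labels, n_boot=200, seed=4) == (1.0, 1.0)

    def test_fixed_seed_reproducible(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        a = bootstrap_ci(scores, labels, n_boot=300, seed=9)
        b = bootstrap_ci(scores, labels, n_boot=300, seed=9)
        assert a == b

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(3)

        def width(n):
            scores = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
            labels = np.r_[np.zeros(n, int), np.ones(n, int)]
            lo, hi = bootstrap_ci(scores, labels, n_boot=400, seed=5)
            return hi - lo

        assert width(500) < width(50)


class TestCompareAuroc:
    def _eval(self, scores, labels):
        return ModelEval(
            fold_aurocs=[], mean_auroc=0.5, scores=np.asarray(scores, float),
            labels=np.asarray(labels, int), ci_low=0, ci_high=1,
        )

    def test_model_compared_with_itself_gives_p_one(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        e = self._eval(scores, labels)
        assert compare_auroc(e, e) == 1.0

    def test_unpaired_inputs_rejected(self, rng):
        e1 = self._eval(rng.normal(size=30), np.r_[np.zeros(15, int), np.ones(15, int)])
        e2 = self._eval(rng.normal(size=30), np.r_[np.ones(15, int), np.zeros(15, int)])
        with pytest.raises(ValueError, match="paired"):
            compare_auroc(e1, e2)

    def test_strong_vs_null_feature_detected(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        strong = labels + rng.normal(0, 0.5, n)
        null = rng.normal(size=n)
        p = compare_auroc(self._eval(strong, labels), self._eval(null, labels))
        assert p < 0.001


class TestCvTrainEval:
    def test_perfectly_separable_data_scores_one(self, rng):
        X = np.r_[rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        ev = cv_train_eval(X, y, grid={"C": [1.0], "gamma": ["scale"]}, k=5, seed=1, n_boot=50)
        assert ev.mean_auroc == pytest.approx(1.0)

    def test_permuted_labels_score_near_chance(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        y = rng.integers(0, 2, n)  # independent of X
        ev = cv_train_eval(X, y, grid={"C": [1.0], "gamma": ["scale"]}, k=10, seed=2, n_boot=50)
        # 3 SE of the null AUROC at this n is well under 0.15
        assert abs(ev.mean_auroc - 0.5) < 0.15

    def test_planted_volume_signal_beats_age(self, rng):
        from ctseg.phantom import make_outcome_table

        table = make_outcome_table(150, volume_effect=0.6, seed=3, age_effect=0.0)
        y = table["outcome"].to_numpy()
        grid = {"C": [1.0, 10.0], "gamma": ["scale"]}
        ev_vol = cv_train_eval(table[["lesion_volume_ml"]].to_numpy(), y, grid=grid, k=5, seed=4, n_boot=50)
        ev_age = cv_train_eval(table[["age"]].to_numpy(), y, grid=grid, k=5, seed=4, n_boot=50)
        assert ev_vol.mean_auroc > ev_age.mean_auroc

    def test_fixed_seed_fully_reproducible(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        a = cv_train_eval(X, y, grid={"C": [1.0, 4.0], "gamma": [0.1]}, k=5, seed=8, n_boot=100)
        b = cv_train_eval(X, y, grid={"C": [1.0, 4.0], "gamma": [0.1]}, k=5, seed=8, n_boot=100)
        assert a.to_dict() == b.to_dict()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cv_train_eval(np.zeros((10, 1)), np.ones(10, int))
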