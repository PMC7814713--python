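import numpy as np
import pytest

import segpipe as sp
from segpipe.errors import ValidationError
from segpipe.evaluation import OVERLAY_ALPHA, OVERLAY_PALETTE
from segpipe.metrics import classwise_dice
from segpipe.model import ConstantModel
from segpipe.preprocessing import one_hot_encode


def ids(n):
    return [f"s{i:03d}" for i in range(n)]


class TestMakeSplit:
    def test_kfold_120_by_3_gives_80_40(self):
        plan = sp.make_split(ids(120), "kfold", k=3, seed=0)
        assert len(plan.folds) == 3
        for train, test in plan.folds:
            assert len(train) == 80 and len(test) == 40
        tests = [set(t) for _, t in plan.folds]
        assert set().union(*tests) == set(ids(120))

    def test_kfold_remainder_distribution(self):
        plan = sp.make_split(ids(10), "kfold", k=3, seed=1)
        sizes = sorted(len(t) for _, t in plan.folds)
        assert sizes == [3, 3, 4]
        assert set().union(*[set(t) for _, t in plan.folds]) == set(ids(10))
        for train, test in plan.folds:
            assert not set(train) & set(test)

    def test_loo(self):
        plan = sp.make_split(ids(5), "loo")
        assert len(plan.folds) == 5
        assert all(len(t) == 1 for _, t in plan.folds)
        assert {t[0] for _, t in plan.folds} == set(ids(5))

    @pytest.mark.parametrize("mode", ["percentage", "holdout"])
    def test_percentage_and_holdout(self, mode):
        plan = sp.make_split(ids(10), mode, fraction=0.8, seed=2)
        (train, test), = plan.folds
        assert len(train) == 8 and len(test) == 2
        assert not set(train) & set(test)

    def test_detailed_copies_lists_verbatim(self):
        folds = [(("s000", "s001"), ("s002",))]
        plan = sp.make_split(ids(3), "detailed", folds=folds)
        assert plan.folds == [(("s000", "s001"), ("s002",))]

    def test_detailed_overlap_rejected(self):
        with pytest.raises(ValidationError):
            sp.make_split(ids(3), "detailed",
                          folds=[(("s000", "s001"), ("s001",))])

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            sp.make_split(ids(5), "kfold", k=10)

    def test_invariants_over_random_draws(self, rng):
        for _ in range(100):
            n = int(rng.choice([5, 10, 120]))
            mode = str(rng.choice(["kfold", "loo", "percentage", "holdout"]))
            seed = int(rng.integers(0, 2 ** 31))
            if mode == "kfold":
                k = int(rng.choice([2, 3, 5]))
                plan = sp.make_split(ids(n), mode, k=k, seed=seed)
                tests = [set(t) for _, t in plan.folds]
                assert set().union(*tests) == set(ids(n))
                sizes = [len(t) for t in tests]
                assert max(sizes) - min(sizes) <= 1
            elif mode == "loo":
                plan = sp.make_split(ids(n), mode)
                assert len(plan.folds) == n
            else:
                plan = sp.make_split(ids(n), mode,
                                     fraction=float(rng.uniform(0.2, 0.9)),
                                     seed=seed)
            for train, test in plan.folds:
                assert not set(train) & set(test)
                assert len(test) >= 1

    def test_seed_reproducibility_and_variability(self):
        a = sp.make_split(ids(20), "kfold", k=4, seed=3)
        b = sp.make_split(ids(20), "kfold", k=4, seed=3)
        assert a.folds == b.folds
        distinct = sum(
            sp.make_split(ids(20), "kfold", k=4, seed=s).folds
            != sp.make_split(ids(20), "kfold", k=4, seed=s + 1).folds
            for s in range(50)
        )
        assert distinct > 45


@pytest.fixture
def cv_setup():
    samples = {
        s.id: s for s in sp.generate_phantom_samples(6, sp.PhantomConfig(), seed=8)
    }
    preproc = sp.PreprocSpec(normalization="zscore", n_classes=3)
    patchcfg = sp.PatchConfig((16, 16, 16), (8, 8, 8))
    return samples, preproc, patchcfg


class TestCrossValidation:
    def test_ground_truth_stub_scores_perfectly(self, cv_setup, tmp_path):
        samples, preproc, patchcfg = cv_setup
        plan = sp.make_split(sorted(samples), "kfold", k=3, seed=0)
        tables = sp.run_cross_validation(
            samples, plan, lambda f: None, preproc, patchcfg,
            sp.AugmentSpec.disabled(), sp.BatchPlan(), sp.TrainSpec(),
            eval_metrics=("dice_soft", "dice_classwise"),
            predictor=lambda m, s: s.segmentation.copy(), n_classes=3,
            out_dir=str(tmp_path))
        assert np.allclose(tables["per_sample"].value, 1.0, atol=1e-4)
        agg = tables["aggregate"]
        # 3 fold rows + 1 mean row per metric
        assert len(agg) == 4 * 2
        assert (tmp_path / "report.tsv").exists()
        assert (tmp_path / "aggregate.tsv").exists()

    def test_constant_background_matches_direct_metric_calls(self, cv_setup):
        samples, preproc, patchcfg = cv_setup
        plan = sp.make_split(sorted(samples), "holdout", fraction=0.5, seed=1)
        stub = ConstantModel(3, label=0)
        tables = sp.run_cross_validation(
            samples, plan, lambda f: stub, preproc, patchcfg,
            sp.AugmentSpec.disabled(), sp.BatchPlan(), sp.TrainSpec(),
            eval_metrics=("dice_classwise",), n_classes=3)
        for _, row in tables["per_sample"].iterrows():
            s = samples[row.sample_id]
            truth = one_hot_encode(s.segmentation, 3)
            pred = one_hot_encode(np.zeros_like(s.segmentation), 3)
            _, expected = classwise_dice(truth, pred)
            assert row.value == pytest.approx(expected, abs=1e-9)
            assert row.value < 0.75  # foreground classes missed

    def test_missing_ground_truth_on_test_id_rejected(self, cv_setup):
        samples, preproc, patchcfg = cv_setup
        sid = sorted(samples)[0]
        samples[sid] = sp.Sample(id=sid, image=samples[sid].image,
                                 spacing=samples[sid].spacing)
        plan = sp.make_split(sorted(samples), "loo")
        with pytest.raises(ValidationError):
            sp.run_cross_validation(samples, plan, lambda f: None, preproc,
                                    patchcfg, sp.AugmentSpec.disabled(),
                                    sp.BatchPlan(), sp.TrainSpec(),
                                    predictor=lambda m, s: s.segmentation,
                                    n_classes=3)


class TestDatasetStatistics:
    def test_all_background_fraction_one(self):
        s = sp.Sample(id="bg", image=np.zeros((4, 4, 4, 1), np.float32),
                      segmentation=np.zeros((4, 4, 4), np.int32),
                      spacing=(1, 1, 1))
        stats = sp.dataset_statistics([s], n_classes=2)
        assert stats[stats["class"] == 0].fraction.iloc[0] == 1.0
        assert stats[stats["class"] == 1].voxel_count.iloc[0] == 0

    def test_counts_match_generator_bookkeeping(self, phantom3):
        stats = sp.dataset_statistics([phantom3], n_classes=3)
        for c, count in phantom3.meta["class_counts"].items():
            assert stats[stats["class"] == c].voxel_count.iloc[0] == count
        assert stats.groupby("sample_id").fraction.sum().iloc[0] == pytest.approx(
            1.0, abs=1e-9)

    def test_clipped_dataset_range(self, phantom3):
        clipped = sp.clip_intensities(phantom3.image, 0.1, 0.9)
        s = sp.Sample(id="c", image=clipped, segmentation=phantom3.segmentation,
                      spacing=phantom3.spacing)
        stats = sp.dataset_statistics([s], n_classes=3)
        assert stats.image_min.iloc[0] >= 0.1 and stats.image_max.iloc[0] <= 0.9


class TestOverlay:
    def test_background_mask_is_plain_grayscale(self, tmp_path, phantom3):
        import matplotlib.image as mpimg
        mask = np.zeros_like(phantom3.segmentation)
        (path,) = sp.render_overlay(phantom3, mask, slice_index=10,
                                    out_dir=str(tmp_path))
        rgba = mpimg.imread(path)
        assert np.allclose(rgba[..., 0], rgba[..., 1])  # gray: R == G == B
        assert np.allclose(rgba[..., 1], rgba[..., 2])

    def test_single_voxel_paints_one_pixel(self, tmp_path):
        import matplotlib.image as mpimg
        img = np.zeros((1, 8, 8, 1), np.float32)
        mask = np.zeros((1, 8, 8), np.int32)
        mask[0, 3, 5] = 1
        s = sp.Sample(id="v", image=img, segmentation=mask, spacing=(1, 1, 1))
        (path,) = sp.render_overlay(s, mask, slice_index=0, out_dir=str(tmp_path))
        rgba = mpimg.imread(path)
        colored = ~np.isclose(rgba[..., 0], rgba[..., 2])
        assert colored.sum() == 1 and colored[3, 5]
        expected_red = OVERLAY_ALPHA * OVERLAY_PALETTE[1][0]
        assert rgba[3, 5, 0] == pytest.approx(expected_red, abs=2 / 255)

    def test_out_of_range_slice_rejected(self, phantom3):
        with pytest.raises(ValidationError):
            sp.render_overlay(phantom3, phantom3.segmentation, slice_index=99,
                              out_dir=".")
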