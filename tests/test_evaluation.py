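import numpy as np
import pytest

from perirec.evaluation import (METRIC_NAMES, aggregate_cohort, sector_labels,
                                sector_metrics, sector_partition, voxel_metrics)
from perirec.io import MaskVolume
from perirec.labeling import OUTSIDE, LabelVolume
from perirec.postprocess import probability_map_from_scores


def _shell_masks(shape=(40, 40, 40), r_cav=5.0, r_out=15.0):
    c = (np.asarray(shape) - 1) / 2.0
    coords = np.stack(np.meshgrid(*map(np.arange, shape), indexing="ij"), -1)
    r = np.linalg.norm(coords - c, axis=-1)
    cavity = MaskVolume(data=(r <= r_cav).astype(np.uint8))
    shell = MaskVolume(data=((r > r_cav) & (r <= r_out)).astype(np.uint8))
    return cavity, shell


class TestVoxelMetrics:
    def _label_volume(self, y, shape=(10, 10, 10)):
        data = np.full(shape, OUTSIDE, dtype=np.uint8)
        flat = data.reshape(-1)
        flat[:len(y)] = y
        return LabelVolume(data=flat.reshape(shape), affine=np.eye(4))

    def _pred_mask(self, y, shape=(10, 10, 10)):
        data = np.zeros(shape, dtype=np.uint8)
        flat = data.reshape(-1)
        flat[:len(y)] = y
        return MaskVolume(data=flat.reshape(shape))

    def test_perfect_prediction(self):
        y = np.r_[np.ones(40, int), np.zeros(60, int)]
        truth = self._label_volume(y)
        pred = self._pred_mask(y)
        m = voxel_metrics(y.astype(float), pred, truth)
        assert m["auc"] == 1.0 and m["accuracy"] == 1.0 and m["kappa"] == 1.0

    def test_hand_computed_confusion(self):
        """TP=40, FN=10, FP=20, TN=30: accuracy 0.7, kappa (0.7-0.5)/0.5 = 0.4."""
        y_true = np.r_[np.ones(50, int), np.zeros(50, int)]
        y_pred = np.r_[np.ones(40, int), np.zeros(10, int),
                       np.ones(20, int), np.zeros(30, int)]
        truth = self._label_volume(y_true)
        pred = self._pred_mask(y_pred)
        m = voxel_metrics(y_pred.astype(float), pred, truth)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["kappa"] == pytest.approx(0.4)
        assert m["precision"] == pytest.approx(40 / 60)
        assert m["recall"] == pytest.approx(0.8)

    def test_null_scores_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 10_000)
            scores = rng.random(10_000)
            truth = self._label_volume(y, shape=(22, 22, 22))
            pred = self._pred_mask((scores > 0.5).astype(int), shape=(22, 22, 22))
            aucs.append(voxel_metrics(scores, pred, truth)["auc"])
        assert 0.45 < np.mean(aucs) < 0.55

    def test_single_class_truth_reports_missing_auc(self):
        y = np.zeros(100, int)
        truth = self._label_volume(y)
        pred = self._pred_mask(y)
        m = voxel_metrics(np.zeros(100), pred, truth)
        assert m["auc"] is None
        assert "single-class" in m["auc_missing_reason"]


class TestSectorPartition:
    def test_pure_axis_displacement_is_face_sector(self):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        # voxel straight along +x from the centroid (RAS affine: +x = right)
        sid = part.sector_ids[33, 19, 19]
        assert part.names[int(sid)] == "right"

    def test_diagonal_displacement_is_corner_sector(self):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        sid = part.sector_ids[27, 27, 27]
        assert part.names[int(sid)] == "right-anterior-superior"

    def test_full_shell_populates_26_sectors(self):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        assert len(part.present_ids) == 26

    @pytest.mark.parametrize("seed", range(5))
    def test_disjoint_cover_on_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        shape = (32, 32, 32)
        center = 16 + rng.uniform(-4, 4, 3)
        coords = np.stack(np.meshgrid(*map(np.arange, shape), indexing="ij"), -1)
        r = np.linalg.norm(coords - center, axis=-1)
        r_cav = rng.uniform(2, 5)
        cavity = MaskVolume(data=(r <= r_cav).astype(np.uint8))
        shell = MaskVolume(data=((r > r_cav) & (r <= r_cav + rng.uniform(4, 8))
                                 ).astype(np.uint8))
        part = sector_partition(shell, cavity)
        inside = part.sector_ids[shell.data > 0]
        assert np.all(inside >= 0)                       # full cover
        assert np.all(part.sector_ids[shell.data == 0] == -1)  # nothing outside

    def test_empty_mask_rejected(self):
        cavity, shell = _shell_masks()
        with pytest.raises(ValueError):
            sector_partition(shell, MaskVolume(data=np.zeros((40, 40, 40), np.uint8)))


class TestSectorLabels:
    def test_activation_threshold_arithmetic(self):
        """5 of 1000 voxels at fraction 0.01 -> negative; 10 -> positive."""
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        sid = int(part.present_ids[0])
        sel = np.argwhere(part.sector_ids == sid)
        size = len(sel)
        k_neg = int(np.floor(0.01 * size)) - 1
        k_pos = int(np.ceil(0.01 * size))
        for k, expected in ((k_neg, False), (k_pos, True)):
            mask = np.zeros((40, 40, 40), dtype=np.uint8)
            mask[tuple(sel[:k].T)] = 1
            labs = sector_labels(part, MaskVolume(data=mask),
                                 activation_fraction=0.01)
            assert labs[sid] is expected

    def test_full_sector_positive_any_fraction(self):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        labs = sector_labels(part, shell, activation_fraction=1.0)
        assert all(labs.values())

    def test_empty_mask_all_negative(self):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        empty = MaskVolume(data=np.zeros((40, 40, 40), dtype=np.uint8))
        assert not any(sector_labels(part, empty).values())


class TestSectorMetrics:
    def test_exact_match_perfect_metrics(self, rng):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        mask = np.zeros((40, 40, 40), dtype=np.uint8)
        mask[part.sector_ids == int(part.present_ids[0])] = 1
        mask[part.sector_ids == int(part.present_ids[5])] = 1
        truth_mask = MaskVolume(data=mask)
        scores = rng.random(shell.n_voxels) * 0.2
        pmap = probability_map_from_scores(scores, shell, stage="corrected")
        m = sector_metrics(part, truth_mask, truth_mask, pmap)
        assert m["accuracy"] == 1.0 and m["kappa"] == 1.0 and m["recall"] == 1.0

    def test_complement_prediction_zero_recall(self, rng):
        cavity, shell = _shell_masks()
        part = sector_partition(shell, cavity)
        truth = np.isin(part.sector_ids, part.present_ids[:4]) & (shell.data > 0)
        pred = (~truth) & (shell.data > 0)
        pmap = probability_map_from_scores(rng.random(shell.n_voxels) * 0.1,
                                           shell, stage="corrected")
        m = sector_metrics(part, MaskVolume(data=truth.astype(np.uint8)),
                           MaskVolume(data=pred.astype(np.uint8)), pmap)
        assert m["recall"] == 0.0


class TestAggregate:
    def test_identical_cases_zero_sd(self):
        case = {m: 0.5 for m in METRIC_NAMES}
        df = aggregate_cohort([case, dict(case)])
        assert (df["sd"] == 0).all()

    def test_two_case_mean_sd(self):
        cases = [{m: 0.7 for m in METRIC_NAMES}, {m: 0.9 for m in METRIC_NAMES}]
        df = aggregate_cohort(cases).set_index("metric")
        assert df.loc["auc", "mean"] == pytest.approx(0.8)
        assert df.loc["auc", "sd"] == pytest.approx(0.1)  # population convention

    def test_missing_auc_excluded_with_count(self):
        a = {m: 0.8 for m in METRIC_NAMES}
        b = {m: 0.6 for m in METRIC_NAMES}
        b["auc"] = None
        df = aggregate_cohort([a, b]).set_index("metric")
        assert df.loc["auc", "mean"] == pytest.approx(0.8)
        assert df.loc["auc", "n_cases"] == 1
        assert df.loc["accuracy", "n_cases"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cohort([])


class TestROCPoints:
    def test_curve_endpoints_and_monotone(self, rng):
        from perirec.evaluation import roc_points
        from perirec.labeling import OUTSIDE, LabelVolume

        y = rng.integers(0, 2, 200)
        data = np.full((6, 6, 6), OUTSIDE, dtype=np.uint8)
        data.reshape(-1)[:200] = y
        truth = LabelVolume(data=data, affine=np.eye(4))
        pts = roc_points(rng.random(200), truth)
        assert pts["fpr"].iloc[0] == 0.0 and pts["fpr"].iloc[-1] == 1.0
        assert pts["tpr"].iloc[-1] == 1.0
        assert (pts["fpr"].diff().dropna() >= 0).all()
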