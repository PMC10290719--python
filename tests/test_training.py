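import math

import numpy as np
import pytest

from kinoprof.features import FeatureBundle
from kinoprof.models import Predictor
from kinoprof.training import (
    ConsensusPredictor,
    TrainConfig,
    compute_metrics,
    consensus_predict,
    kfold_cv,
    per_entity_pcc,
    train,
)

from conftest import tiny_config
from _oracles import closed_form_metrics

rng = np.random.default_rng(3)


def synth_bundle(n=80, n_kin=4, width=30, noise=0.0, seed=5):
    """Tiny bundle with a linear signal in the PCPP block."""
    r = np.random.default_rng(seed)
    kin = np.eye(21, dtype=np.float32)[r.integers(0, 21, (n_kin, width))]
    idx = r.integers(0, n_kin, n)
    blocks = {
        "PCPP": r.normal(size=(n, 208)).astype(np.float32),
        "MCFP": r.integers(0, 2, (n, 167)).astype(np.float32),
        "MGFP": r.integers(0, 2, (n, 1792)).astype(np.float32),
    }
    y = blocks["PCPP"][:, 0] * 1.5 - blocks["PCPP"][:, 3] + noise * r.normal(size=n)
    return FeatureBundle(kin, idx, blocks, y.astype(np.float64), ["k"] * n, ["s"] * n)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert m.pcc == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == 0.0 and m.mae == 0.0

    def test_anticorrelated(self):
        m = compute_metrics([0.0, 1.0, 2.0], [2.0, 1.0, 0.0])
        assert m.pcc == pytest.approx(-1.0)

    def test_rmse_dominates_mae(self):
        m = compute_metrics([0.0, 0.0, 3.0, 3.0], [1.0, 1.0, 1.0, 1.0])
        assert m.rmse >= m.mae >= 0
        assert m.rmse == pytest.approx(math.sqrt((1 + 1 + 4 + 4) / 4))
        assert m.mae == pytest.approx(1.5)

    def test_matches_closed_forms(self):
        y = [0.3, -1.2, 2.4, 0.9, -0.5]
        p = [0.1, -0.8, 2.0, 1.4, -0.2]
        m = compute_metrics(y, p)
        pcc, r2, rmse, mae = closed_form_metrics(y, p)
        assert m.pcc == pytest.approx(pcc)
        assert m.r2 == pytest.approx(r2)
        assert m.rmse == pytest.approx(rmse)
        assert m.mae == pytest.approx(mae)

    def test_constant_truth_flagged(self):
        m = compute_metrics([1.0, 1.0, 1.0], [0.5, 1.0, 1.5])
        assert m.undefined
        assert math.isnan(m.pcc) and math.isnan(m.r2)
        assert m.rmse > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0])


class TestTrain:
    def test_learns_linear_signal(self):
        bundle = synth_bundle()
        tr, va = bundle.subset(np.arange(60)), bundle.subset(np.arange(60, 80))
        pred = Predictor(tiny_config("3-1", kinase_length=30))
        hist = train(pred, tr, va, TrainConfig(max_epochs=60, patience=59, batch_size=20, lr=3e-3, seed=0))
        assert min(hist.val_loss) < hist.val_loss[0]

    def test_early_stop_on_noise(self):
        bundle = synth_bundle(seed=9)
        bundle.y = np.random.default_rng(1).normal(size=len(bundle))
        tr, va = bundle.subset(np.arange(60)), bundle.subset(np.arange(60, 80))
        pred = Predictor(tiny_config("3-1", kinase_length=30))
        hist = train(pred, tr, va, TrainConfig(max_epochs=500, patience=1, batch_size=20, lr=1e-3, seed=0))
        assert hist.n_epochs < 500

    def test_best_epoch_contract(self):
        bundle = synth_bundle()
        tr, va = bundle.subset(np.arange(60)), bundle.subset(np.arange(60, 80))
        pred = Predictor(tiny_config("3-1", kinase_length=30))
        hist = train(pred, tr, va, TrainConfig(max_epochs=30, patience=5, batch_size=20, lr=3e-3, seed=0))
        # restored weights achieve the minimum recorded validation loss
        from kinoprof.training import _eval_loss

        assert _eval_loss(pred, va) == pytest.approx(min(hist.val_loss), rel=1e-5)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_deterministic_history(self):
        bundle = synth_bundle()
        tr, va = bundle.subset(np.arange(60)), bundle.subset(np.arange(60, 80))
        hists = []
        for _ in range(2):
            pred = Predictor(tiny_config("3-1", kinase_length=30))
            hists.append(
                train(pred, tr, va, TrainConfig(max_epochs=5, patience=4, batch_size=20, seed=0))
            )
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss

    def test_empty_sets_rejected(self):
        bundle = synth_bundle()
        pred = Predictor(tiny_config("3-1", kinase_length=30))
        with pytest.raises(ValueError):
            train(pred, bundle.subset([]), bundle, TrainConfig(max_epochs=2, patience=1))


class TestKFold:
    def test_partition_disjoint_and_covering(self):
        bundle = synth_bundle(n=100)
        cv = kfold_cv(
            bundle,
            tiny_config("3-1", kinase_length=30),
            TrainConfig(max_epochs=3, patience=2, batch_size=32, seed=0),
            k=5,
        )
        all_idx = np.concatenate([f.val_indices for f in cv.folds])
        assert sorted(all_idx.tolist()) == list(range(100))
        assert len(set(all_idx.tolist())) == 100
        assert all(len(f.val_indices) == 20 for f in cv.folds)

    def test_same_seed_same_folds(self):
        bundle = synth_bundle(n=50)
        cfg = tiny_config("3-1", kinase_length=30)
        tc = TrainConfig(max_epochs=2, patience=1, batch_size=32, seed=4)
        a = kfold_cv(bundle, cfg, tc, k=5)
        b = kfold_cv(bundle, cfg, tc, k=5)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.val_indices, fb.val_indices)

    def test_summary_matches_per_fold_values(self):
        bundle = synth_bundle(n=60)
        cv = kfold_cv(
            bundle,
            tiny_config("3-1", kinase_length=30),
            TrainConfig(max_epochs=2, patience=1, batch_size=32, seed=0),
            k=3,
        )
        pccs = [f.metrics.pcc for f in cv.folds]
        assert cv.metrics_mean["pcc"] == pytest.approx(np.mean(pccs))
        assert cv.metrics_std["pcc"] == pytest.approx(np.std(pccs))

    def test_k_below_two_rejected(self):
        bundle = synth_bundle(n=20)
        with pytest.raises(ValueError):
            kfold_cv(bundle, tiny_config("3-1", kinase_length=30), TrainConfig(max_epochs=2, patience=1), k=1)


class _ConstantMember:
    """Stub predictor returning a constant; mimics the Predictor interface."""

    def __init__(self, value, variant_id="3-1"):
        self.value = value
        from conftest import tiny_config as tc

        self.config = tc(variant_id, kinase_length=30)

    def predict(self, kinase_inputs, kinase_index, blocks):
        return np.full(len(kinase_index), self.value, dtype=float)


class TestConsensus:
    def test_mean_of_members(self):
        members = [_ConstantMember(v) for v in (1, 2, 3, 4, 5)]
        cons = ConsensusPredictor(members=members)
        bundle = synth_bundle(n=4)
        np.testing.assert_allclose(consensus_predict(cons, bundle), 3.0)

    def test_single_member_identity(self):
        cons = ConsensusPredictor(members=[_ConstantMember(2.5)])
        bundle = synth_bundle(n=4)
        np.testing.assert_allclose(consensus_predict(cons, bundle), 2.5)

    def test_bounded_by_member_extremes(self):
        bundle = synth_bundle(n=30)
        members = [Predictor(tiny_config("3-1", kinase_length=30, seed=s)) for s in range(3)]
        preds = np.stack(
            [m.predict(bundle.kinase_inputs, bundle.kinase_index, bundle.blocks) for m in members]
        )
        cons = ConsensusPredictor(members=members).predict(bundle)
        assert np.all(cons >= preds.min(axis=0) - 1e-9)
        assert np.all(cons <= preds.max(axis=0) + 1e-9)

    def test_mixed_variants_rejected(self):
        with pytest.raises(ValueError):
            ConsensusPredictor(members=[_ConstantMember(1, "3-1"), _ConstantMember(2, "2-1")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ConsensusPredictor(members=[])


class TestPerEntityPcc:
    def test_strictly_more_than_min_n(self):
        kin = ["A"] * 11 + ["B"] * 10
        smi = ["s"] * 21
        y = np.arange(21, dtype=float)
        table = per_entity_pcc(kin, smi, y, y, group_by="kinase", min_n=10)
        assert table.entity.tolist() == ["A"]
        assert table.n.tolist() == [11]
        assert table.pcc.iloc[0] == pytest.approx(1.0)

    def test_fraction_above_threshold_downstream(self):
        kin = ["A"] * 12 + ["B"] * 12
        smi = ["s"] * 24
        y = np.arange(24, dtype=float)
        p = y.copy()
        p[12:] = -y[12:]  # entity B anticorrelated
        table = per_entity_pcc(kin, smi, y, p, group_by="kinase", min_n=10)
        frac = (table.pcc > 0.7).mean()
        assert frac == pytest.approx(0.5)

    def test_compound_grouping(self):
        kin = ["k"] * 22
        smi = ["X"] * 11 + ["Y"] * 11
        y = np.arange(22, dtype=float)
        table = per_entity_pcc(kin, smi, y, y, group_by="compound", min_n=10)
        assert sorted(table.entity) == ["X", "Y"]
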