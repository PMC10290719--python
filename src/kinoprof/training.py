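"""Training loop, five-fold cross-validation, consensus prediction and
regression metrics.

Training minimises mean squared error with Adam, stopping early when the
validation loss has not improved for ``patience`` consecutive epochs and
restoring the weights of the best validation epoch.  Cross-validation
partitions records (kinase-compound pairs) into k seeded folds; the model of
fold i trains on the other folds and validates on fold i, and the consensus
predictor averages the k member predictions.  All metrics are computed on the
log10(nM) bioactivity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold

from . import nn
from .features import FeatureBundle, FeatureScaler
from .models import Predictor, PredictorConfig


@dataclass
class TrainConfig:
    max_epochs: int = 3000
    patience: int = 100
    batch_size: int = 512
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingHistory:
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int  # 0-based index into the loss lists

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class MetricsReport:
    """Regression metrics on the log10(nM) scale."""

    pcc: float
    r2: float
    rmse: float
    mae: float
    n: int
    undefined: bool = False  # PCC/R2 undefined (constant truth)

    def as_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "n": self.n,
            "undefined": self.undefined,
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """PCC, R^2, RMSE and MAE of predictions against observations.

    A constant truth vector leaves PCC and R^2 undefined; they are reported
    as NaN with the ``undefined`` flag set, while RMSE/MAE are still computed.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("metrics need at least two observations")
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        return MetricsReport(math.nan, math.nan, rmse, mae, y_true.size, undefined=True)
    r2 = float(r2_score(y_true, y_pred))
    if np.ptp(y_pred) == 0:  # correlation against a constant is undefined
        return MetricsReport(math.nan, r2, rmse, mae, y_true.size, undefined=True)
    pcc = float(_sps.pearsonr(y_true, y_pred).statistic)
    return MetricsReport(pcc, r2, rmse, mae, y_true.size)


def _eval_loss(predictor: Predictor, bundle: FeatureBundle) -> float:
    pred = predictor.predict(bundle.kinase_inputs, bundle.kinase_index, bundle.blocks)
    return float(np.mean((pred - bundle.y) ** 2))


def train(
    predictor: Predictor,
    train_bundle: FeatureBundle,
    val_bundle: FeatureBundle,
    config: TrainConfig,
) -> TrainingHistory:
    """Fit a predictor by minibatch MSE descent with early stopping.

    Returns the per-epoch loss history; on return the predictor carries the
    weights of the best validation epoch.
    """
    if len(train_bundle) == 0 or len(val_bundle) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(predictor.parameters(), lr=config.lr, betas=config.betas)
    history = TrainingHistory(train_loss=[], val_loss=[], best_epoch=0)
    best_val = math.inf
    best_state = predictor.state_dict()
    n = len(train_bundle)
    y = train_bundle.y
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            blocks = {k: v[idx] for k, v in train_bundle.blocks.items()}
            out = predictor.forward(
                train_bundle.kinase_inputs, train_bundle.kinase_index[idx], blocks
            )
            loss = nn.mse_loss(out, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / n)
        val_loss = _eval_loss(predictor, val_bundle)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = predictor.state_dict()
            history.best_epoch = epoch
        elif epoch - history.best_epoch >= config.patience:
            break
    predictor.load_state_dict(best_state)
    return history


@dataclass
class FoldResult:
    predictor: Predictor
    scaler: FeatureScaler
    metrics: MetricsReport
    history: TrainingHistory
    val_indices: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    metrics_mean: dict[str, float]
    metrics_std: dict[str, float]

    @property
    def consensus(self) -> "ConsensusPredictor":
        return ConsensusPredictor(
            members=[f.predictor for f in self.folds],
            scalers=[f.scaler for f in self.folds],
        )


def kfold_cv(
    bundle: FeatureBundle,
    predictor_config: PredictorConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int | None = None,
) -> CVResult:
    """Seeded k-fold cross-validation over records.

    Folds partition the records disjointly; fold i's model trains on the
    remaining folds (with a scaler fitted on those rows only) and is evaluated
    on fold i.  Per-fold metrics are summarised by their mean and standard
    deviation.
    """
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    if len(bundle) < k:
        raise ValueError("fewer records than folds")
    seed = train_config.seed if seed is None else seed
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) & 0x7FFFFFFF)
    folds: list[FoldResult] = []
    for i, (tr_idx, va_idx) in enumerate(kf.split(np.arange(len(bundle)))):
        scaler = FeatureScaler().fit(bundle, tr_idx)
        scaled = scaler.transform(bundle)
        tr, va = scaled.subset(tr_idx), scaled.subset(va_idx)
        cfg_i = PredictorConfig(**{**predictor_config.to_manifest(), "seed": predictor_config.seed + i})
        pred = Predictor(cfg_i)
        tc_i = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + i})
        history = train(pred, tr, va, tc_i)
        y_hat = pred.predict(va.kinase_inputs, va.kinase_index, va.blocks)
        folds.append(
            FoldResult(
                predictor=pred,
                scaler=scaler,
                metrics=compute_metrics(va.y, y_hat),
                history=history,
                val_indices=va_idx,
            )
        )
    keys = ("pcc", "r2", "rmse", "mae")
    vals = {k_: [getattr(f.metrics, k_) for f in folds] for k_ in keys}
    return CVResult(
        folds=folds,
        metrics_mean={k_: float(np.mean(v)) for k_, v in vals.items()},
        metrics_std={k_: float(np.std(v)) for k_, v in vals.items()},
    )


@dataclass
class ConsensusPredictor:
    """Arithmetic-mean ensemble of fold-trained predictors."""

    members: list[Predictor]
    scalers: list[FeatureScaler] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("consensus needs at least one member")
        v0 = self.members[0].config.variant.variant_id
        if any(m.config.variant.variant_id != v0 for m in self.members):
            raise ValueError("consensus members must share a variant")
        if self.scalers is not None and len(self.scalers) != len(self.members):
            raise ValueError("one scaler per member required")

    def predict(self, bundle: FeatureBundle) -> np.ndarray:
        preds = []
        for i, m in enumerate(self.members):
            b = self.scalers[i].transform(bundle) if self.scalers else bundle
            preds.append(m.predict(b.kinase_inputs, b.kinase_index, b.blocks))
        return np.mean(preds, axis=0)


def consensus_predict(consensus: ConsensusPredictor, bundle: FeatureBundle) -> np.ndarray:
    """Element-wise mean of the member predictions."""
    return consensus.predict(bundle)


def per_entity_pcc(
    kinase_ids: Sequence[str],
    smiles: Sequence[str],
    y_true,
    y_pred,
    group_by: str = "kinase",
    min_n: int = 10,
):
    """Within-entity PCC for entities with strictly more than ``min_n`` records.

    Returns a DataFrame with columns (entity, n, pcc), sorted by entity.
    """
    import pandas as pd

    if group_by not in ("kinase", "compound"):
        raise ValueError("group_by must be 'kinase' or 'compound'")
    df = pd.DataFrame(
        {
            "entity": kinase_ids if group_by == "kinase" else smiles,
            "y": np.asarray(y_true, dtype=np.float64),
            "p": np.asarray(y_pred, dtype=np.float64),
        }
    )
    rows = []
    for entity, grp in df.groupby("entity", sort=True):
        if len(grp) <= min_n:
            continue
        if grp.y.nunique() < 2:
            continue
        rows.append(
            {
                "entity": entity,
                "n": len(grp),
                "pcc": float(_sps.pearsonr(grp.y, grp.p).statistic),
            }
        )
    return pd.DataFrame(rows, columns=["entity", "n", "pcc"])
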