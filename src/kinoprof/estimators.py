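"""Scikit-learn style estimators wrapping the affinity regressor.

:class:`KinaseLigandRegressor` fits a single model with an internal
validation split for early stopping; :class:`ConsensusKinaseLigandRegressor`
runs seeded k-fold cross-validation and predicts with the arithmetic mean of
the fold models.  ``X`` may be a prebuilt :class:`~kinoprof.features.FeatureBundle`
(fast path), a list of :class:`~kinoprof.curation.ActivityRecord`, or a
DataFrame with ``kinase_id`` and ``smiles`` columns (featurized on the fly;
``y`` then supplies the bioactivities).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split

from .curation import ActivityRecord
from .features import FeatureBundle, FeatureScaler, featurize_records
from .kinases import ActiveSiteMap, KinaseCatalog
from .models import Predictor, PredictorConfig, VariantSpec
from .training import (
    ConsensusPredictor,
    CVResult,
    TrainConfig,
    kfold_cv,
    train,
)


class _RegressorBase(BaseEstimator, RegressorMixin):
    def __init__(
        self,
        catalog: KinaseCatalog | None = None,
        site_map: ActiveSiteMap | None = None,
        variant: str = "3-2",
        ced_dim: int = 3348,
        conv_channels: int = 64,
        kernel_sizes: tuple[int, ...] = (3, 5, 7),
        attention_heads: int = 4,
        embed_dim: int = 128,
        head_dims: tuple[int, ...] = (256, 64),
        max_epochs: int = 3000,
        patience: int = 100,
        batch_size: int = 512,
        lr: float = 1e-3,
        max_conformers: int = 16,
        seed: int = 0,
    ):
        self.catalog = catalog
        self.site_map = site_map
        self.variant = variant
        self.ced_dim = ced_dim
        self.conv_channels = conv_channels
        self.kernel_sizes = kernel_sizes
        self.attention_heads = attention_heads
        self.embed_dim = embed_dim
        self.head_dims = head_dims
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.lr = lr
        self.max_conformers = max_conformers
        self.seed = seed

    # -- shared plumbing --------------------------------------------------------
    def _as_bundle(self, X, y=None) -> FeatureBundle:
        if isinstance(X, FeatureBundle):
            if y is not None:
                X = X.subset(np.arange(len(X)))
                X.y = np.asarray(y, dtype=np.float64)
            return X
        if isinstance(X, pd.DataFrame):
            bios = (
                np.asarray(y, dtype=np.float64)
                if y is not None
                else X["bioactivity"].to_numpy(dtype=np.float64)
                if "bioactivity" in X
                else np.zeros(len(X))
            )
            records = [
                ActivityRecord.from_bioactivity(
                    kinase_id=str(k), compound_smiles=str(s), bioactivity=float(b)
                )
                for k, s, b in zip(X["kinase_id"], X["smiles"], bios)
            ]
        elif X and isinstance(X[0], ActivityRecord):
            records = list(X)
        else:
            raise TypeError(
                "X must be a FeatureBundle, a DataFrame with kinase_id/smiles, "
                "or a list of ActivityRecord"
            )
        if self.catalog is None:
            raise ValueError("a KinaseCatalog is required to featurize records")
        bundle = featurize_records(
            records,
            self.catalog,
            self.variant,
            site_map=self.site_map,
            max_conformers=self.max_conformers,
            seed=self.seed + 7,
            compound_cache=getattr(self, "_compound_cache", None),
        )
        if y is not None:
            bundle.y = np.asarray(y, dtype=np.float64)
        return bundle

    def _predictor_config(self, bundle: FeatureBundle) -> PredictorConfig:
        n_kin, L, C = bundle.kinase_inputs.shape
        return PredictorConfig(
            variant=VariantSpec(self.variant),
            kinase_length=L,
            kinase_channels=C,
            ced_dim=self.ced_dim,
            conv_channels=self.conv_channels,
            kernel_sizes=tuple(self.kernel_sizes),
            attention_heads=self.attention_heads,
            embed_dim=self.embed_dim,
            head_dims=tuple(self.head_dims),
            seed=self.seed,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            batch_size=self.batch_size,
            lr=self.lr,
            seed=self.seed,
        )


class KinaseLigandRegressor(_RegressorBase):
    """Single attention-based affinity regressor with early stopping.

    Fitted attributes: ``predictor_`` (the trained model), ``scaler_``,
    ``history_`` (per-epoch losses), ``n_features_in_``.
    """

    def __init__(self, *, validation_fraction: float = 0.1, **kwargs):
        super().__init__(**kwargs)
        self.validation_fraction = validation_fraction

    # sklearn's get_params needs explicit kwargs; rebuild them from the base.
    @classmethod
    def _get_param_names(cls):
        base = _RegressorBase._get_param_names()
        return sorted(base + ["validation_fraction"])

    def fit(self, X, y=None):
        bundle = self._as_bundle(X, y)
        if bundle.y is None:
            raise ValueError("fit requires bioactivity targets")
        idx = np.arange(len(bundle))
        tr_idx, va_idx = train_test_split(
            idx, test_size=self.validation_fraction, random_state=self.seed & 0x7FFFFFFF
        )
        self.scaler_ = FeatureScaler().fit(bundle, tr_idx)
        scaled = self.scaler_.transform(bundle)
        self.predictor_ = Predictor(self._predictor_config(bundle))
        self.history_ = train(
            self.predictor_, scaled.subset(tr_idx), scaled.subset(va_idx), self._train_config()
        )
        self.n_features_in_ = sum(v.shape[1] for v in bundle.blocks.values())
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "predictor_"):
            raise RuntimeError("estimator is not fitted")
        bundle = self.scaler_.transform(self._as_bundle(X))
        return self.predictor_.predict(
            bundle.kinase_inputs, bundle.kinase_index, bundle.blocks
        )


class ConsensusKinaseLigandRegressor(_RegressorBase):
    """k-fold consensus: mean of the fold-trained models' predictions.

    Fitted attributes: ``cv_result_`` (per-fold models, metrics, histories),
    ``consensus_``, ``n_features_in_``.
    """

    def __init__(self, *, n_folds: int = 5, **kwargs):
        super().__init__(**kwargs)
        self.n_folds = n_folds

    @classmethod
    def _get_param_names(cls):
        base = _RegressorBase._get_param_names()
        return sorted(base + ["n_folds"])

    def fit(self, X, y=None):
        bundle = self._as_bundle(X, y)
        if bundle.y is None:
            raise ValueError("fit requires bioactivity targets")
        self.cv_result_: CVResult = kfold_cv(
            bundle,
            self._predictor_config(bundle),
            self._train_config(),
            k=self.n_folds,
            seed=self.seed,
        )
        self.consensus_: ConsensusPredictor = self.cv_result_.consensus
        self.n_features_in_ = sum(v.shape[1] for v in bundle.blocks.values())
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "consensus_"):
            raise RuntimeError("estimator is not fitted")
        return self.consensus_.predict(self._as_bundle(X))

    @property
    def fold_metrics_(self):
        return [f.metrics for f in self.cv_result_.folds]
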