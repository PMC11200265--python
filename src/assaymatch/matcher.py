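"""Gradient-boosted assay-molecule matcher.

A LightGBM binary classifier over fused (molecule, assay) embeddings that
predicts the probability that the pair is a "match", i.e. that the molecule
is active in the assay. The matcher is trained once on the pooled pair table
and reused, unchanged, for any new assay — that is what makes the pipeline
zero-shot. LightGBM is run single-threaded in deterministic mode so refits
with the same seed reproduce predictions exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np

from .exceptions import DegenerateLabelError, DimensionError


@dataclass(frozen=True)
class MatcherConfig:
    """Fixed, sane boosting defaults; tuning campaigns are out of scope."""

    n_estimators: int = 300
    learning_rate: float = 0.05
    max_leaves: int = 31
    min_child_samples: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class TrainedMatcher:
    booster: lgb.Booster
    feature_dim: int
    config: MatcherConfig


def _as_matrix(X) -> np.ndarray:
    if hasattr(X, "__len__") and len(X) and hasattr(X[0], "vector"):
        X = np.array([fe.vector for fe in X])
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X.reshape(0, 0) if X.size == 0 else X[None, :]
    return X


def train_matcher(X, y, config: MatcherConfig | None = None) -> TrainedMatcher:
    """Fit the gradient-boosted matcher on fused embeddings and 0/1 labels."""
    config = config or MatcherConfig()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] != y.shape[0]:
        raise DimensionError(f"|X|={X.shape[0]} != |y|={y.shape[0]}")
    if X.shape[0] < 10:
        raise DimensionError(f"need at least 10 training pairs, got {X.shape[0]}")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelError(
            f"training labels contain a single class ({classes.tolist()})"
        )
    params = {
        "objective": "binary",
        "learning_rate": config.learning_rate,
        "num_leaves": config.max_leaves,
        "min_child_samples": config.min_child_samples,
        "seed": config.seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "verbosity": -1,
    }
    train_set = lgb.Dataset(X, label=y, params={"verbosity": -1})
    booster = lgb.train(params, train_set, num_boost_round=config.n_estimators)
    return TrainedMatcher(booster=booster, feature_dim=X.shape[1], config=config)


def predict_proba(model: TrainedMatcher, X) -> np.ndarray:
    """Match probability for each row of X, each in [0, 1]."""
    X = _as_matrix(X)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.float64)
    if X.shape[1] != model.feature_dim:
        raise DimensionError(
            f"feature dim {X.shape[1]} != trained dim {model.feature_dim}"
        )
    return np.clip(model.booster.predict(X), 0.0, 1.0)


def save_matcher(model: TrainedMatcher, path: str | Path) -> None:
    path = Path(path)
    model.booster.save_model(str(path))
    meta = path.with_suffix(".meta.json")
    import json

    meta.write_text(
        json.dumps({"feature_dim": model.feature_dim, "config": asdict(model.config)})
    )


def load_matcher(path: str | Path) -> TrainedMatcher:
    import json

    path = Path(path)
    booster = lgb.Booster(model_file=str(path))
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return TrainedMatcher(
        booster=booster,
        feature_dim=meta["feature_dim"],
        config=MatcherConfig(**meta["config"]),
    )
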