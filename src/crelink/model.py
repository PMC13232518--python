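"""L2-regularized logistic classifier over assembled E-G pair features.

Features are z-scored with training-set means and scales before fitting so
the ridge penalty acts comparably across heterogeneously scaled inputs.
The fitted object stores feature names, standardization parameters,
coefficients (on the standardized scale) and the intercept, and serializes
to JSON so saved models can re-score feature tables from other cellular
contexts without retraining.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import FeatureMatrix

__all__ = ["TrainedModel", "train", "score"]

CONVERGENCE_TOL = 1e-8
MAX_ITER = 10_000


@dataclass
class TrainedModel:
    feature_names: list[str]
    coefficients: list[float]
    intercept: float
    reg_strength: float          # inverse penalty C (sklearn convention)
    means: list[float]
    scales: list[float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient/feature-name length mismatch")
        if any(s <= 0 for s in self.scales):
            raise ValueError("standardization scales must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        return cls(**json.loads(Path(path).read_text()))


def _as_xy(X: FeatureMatrix | pd.DataFrame, feature_names: Sequence[str] | None = None):
    df = X.data if isinstance(X, FeatureMatrix) else X
    if feature_names is None:
        feature_names = [c for c in df.columns if c not in ("cre_id", "gene_id")]
    missing = [c for c in feature_names if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return df, list(feature_names), df[list(feature_names)].to_numpy(dtype=float)


def train(
    X: FeatureMatrix | pd.DataFrame,
    y: Sequence[int],
    reg_strength: float = 1.0,
    seed: int = 0,
) -> TrainedModel:
    """Fit the L2-penalized logistic model.

    ``reg_strength`` is the inverse penalty (sklearn's C); larger means a
    weaker penalty. Requires both classes present and finite features.
    Deterministic given inputs (lbfgs, fixed tolerance).
    """
    df, names, mat = _as_xy(X)
    yarr = np.asarray(y, dtype=int)
    if len(yarr) != len(df):
        raise ValueError("label/feature row mismatch")
    if len(np.unique(yarr)) < 2:
        raise ValueError("training labels contain a single class")
    if not np.isfinite(mat).all():
        raise ValueError("non-finite feature values")

    means = mat.mean(axis=0)
    scales = mat.std(axis=0, ddof=0)
    scales[scales == 0] = 1.0
    z = (mat - means) / scales

    clf = LogisticRegression(
        C=reg_strength,  # default penalty is ridge (L2)
        solver="lbfgs",
        tol=CONVERGENCE_TOL,
        max_iter=MAX_ITER,
        random_state=seed,
    )
    clf.fit(z, yarr)
    return TrainedModel(
        feature_names=names,
        coefficients=[float(v) for v in clf.coef_[0]],
        intercept=float(clf.intercept_[0]),
        reg_strength=float(reg_strength),
        means=[float(v) for v in means],
        scales=[float(v) for v in scales],
        metadata={"seed": int(seed), "n_train": int(len(yarr)),
                  "n_pos": int(yarr.sum())},
    )


def score(model: TrainedModel, X: FeatureMatrix | pd.DataFrame) -> np.ndarray:
    """Predicted interaction probability per pair, inverse-logit of the
    standardized linear predictor. Raises if a model feature is absent."""
    _, names, mat = _as_xy(X, model.feature_names)
    z = (mat - np.asarray(model.means)) / np.asarray(model.scales)
    eta = model.intercept + z @ np.asarray(model.coefficients)
    return 1.0 / (1.0 + np.exp(-eta))
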