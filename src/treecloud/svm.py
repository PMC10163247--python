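"""RBF-kernel SVM baseline.

C-support vector classification with a radial basis kernel, the comparison
model for the cloud classifier.  Hyperparameters mirror the reference
configuration: degree 3, gamma 0.5, coef0 0.001, epsilon 0.001, C 1,
nu 0.5, shrinking on.  Under C-SVC with an RBF kernel only gamma, C and
shrinking are active; degree, coef0, nu and epsilon are carried in the
config for fidelity but are inert, as is the undefined parameter p.
Features are standardized (training mean/sd) before the kernel — gamma 0.5
is only meaningful on a standardized scale.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class SvmConfig:
    svm_type: str = "C-classification"
    kernel: str = "rbf"
    degree: int = 3
    gamma: float = 0.5
    coef0: float = 0.001
    epsilon: float = 0.001
    C: float = 1.0
    nu: float = 0.5
    shrinking: bool = True
    p: float = 1.0  # printed in the reference table; no C-SVC meaning

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be positive")


@dataclass
class SvmModel:
    pipeline: Pipeline
    feature_ids: tuple[str, ...]
    cfg: SvmConfig

    @property
    def config_record(self) -> dict:
        return asdict(self.cfg)


def _feature_array(samples: pd.DataFrame, feature_ids) -> np.ndarray:
    return samples[list(feature_ids)].to_numpy(dtype=float)


def fit_svm(
    train: pd.DataFrame,
    feature_ids,
    cfg: SvmConfig | None = None,
    labels=None,
) -> SvmModel:
    """Fit the standardize-then-RBF-SVC pipeline on finite training rows."""
    cfg = cfg or SvmConfig()
    feature_ids = tuple(feature_ids)
    X = _feature_array(train, feature_ids)
    y = np.asarray(train["label"] if labels is None else labels)
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} rows with missing features",
            stacklevel=2,
        )
        X, y = X[keep], y[keep]
    if np.unique(y).size < 2:
        raise ValueError("SVM training requires two classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel=cfg.kernel,
                    C=cfg.C,
                    gamma=cfg.gamma,
                    degree=cfg.degree,
                    coef0=cfg.coef0,
                    shrinking=cfg.shrinking,
                ),
            ),
        ]
    )
    pipe.fit(X, y)
    return SvmModel(pipe, feature_ids, cfg)


def predict_svm(model: SvmModel, samples: pd.DataFrame) -> np.ndarray:
    """Predict labels; applies the training standardization.

    Rows with missing features receive the empty label ''.
    """
    X = _feature_array(samples, model.feature_ids)
    out = np.empty(X.shape[0], dtype=object)
    keep = np.isfinite(X).all(axis=1)
    out[~keep] = ""
    if keep.any():
        out[keep] = model.pipeline.predict(X[keep])
    return out.astype(str)
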