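"""Development labels from angle thresholds, and the SVM classifier.

Threshold rules (strict inequalities, exactly as defined clinically):

* Tönnis: dysplasia iff angle > 10°;
* Sharp: dysplasia iff angle > 45°;
* CE: dysplasia iff angle < 20°, borderline for 20° <= angle <= 25°,
  normal above — only the CE rule produces the borderline class;
* dichotomized CE: borderline and dysplasia collapse to "abnormal"
  (equivalent to a single CE <= 25° cut).

The SVM mirrors the study configuration: a polynomial kernel of degree 2
with penalty C = 0.3, remaining parameters at scikit-learn defaults
(coef0 = 0, gamma = "scale" i.e. 1 / (n_features * Var(X))), fed the
three raw angles. Note that with coef0 = 0 the kernel is a homogeneous
quadratic, so mean-centering the features would make the decision surface
symmetric about the origin and destroy one-sided threshold boundaries;
features are therefore *not* centered by default (``SvmSpec(standardize=
True)`` restores a centered pipeline for experimentation). The evaluation
protocol is stratified 5-fold cross-validation with a fixed seed; the
model fitted on all data is also exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError

NORMAL = "normal"
BORDERLINE = "borderline"
DYSPLASIA = "dysplasia"
ABNORMAL = "abnormal"

THREE_CLASSES = (NORMAL, DYSPLASIA, BORDERLINE)
TWO_CLASSES = (NORMAL, ABNORMAL)

ANGLE_FEATURES = ("tonnis_deg", "sharp_deg", "ce_deg")

TONNIS_DYSPLASIA_DEG = 10.0
SHARP_DYSPLASIA_DEG = 45.0
CE_DYSPLASIA_DEG = 20.0
CE_BORDERLINE_UPPER_DEG = 25.0


def _check_finite(angle: float) -> float:
    angle = float(angle)
    if not math.isfinite(angle):
        raise ParameterError(f"angle must be finite, got {angle}")
    return angle


def classify_tonnis(angle: float) -> str:
    """Dysplasia iff Tönnis angle is strictly greater than 10 degrees."""
    return DYSPLASIA if _check_finite(angle) > TONNIS_DYSPLASIA_DEG else NORMAL


def classify_sharp(angle: float) -> str:
    """Dysplasia iff Sharp angle is strictly greater than 45 degrees."""
    return DYSPLASIA if _check_finite(angle) > SHARP_DYSPLASIA_DEG else NORMAL


def classify_ce(angle: float) -> str:
    """CE < 20 is dysplasia, 20 <= CE <= 25 borderline, else normal."""
    angle = _check_finite(angle)
    if angle < CE_DYSPLASIA_DEG:
        return DYSPLASIA
    if angle <= CE_BORDERLINE_UPPER_DEG:
        return BORDERLINE
    return NORMAL


def dichotomize_ce(label: str) -> str:
    """Collapse the three-class CE label to normal/abnormal."""
    if label == NORMAL:
        return NORMAL
    if label in (BORDERLINE, DYSPLASIA):
        return ABNORMAL
    raise ParameterError(f"unknown CE label {label!r}")


RULES = {
    "tonnis": ("tonnis_deg", classify_tonnis),
    "sharp": ("sharp_deg", classify_sharp),
    "ce": ("ce_deg", classify_ce),
}


def classify_angles(df: pd.DataFrame, rule: str) -> pd.Series:
    """Apply one threshold rule to a measurement table column-wise."""
    if rule not in RULES:
        raise ParameterError(f"unknown rule {rule!r}; expected one of {sorted(RULES)}")
    column, fn = RULES[rule]
    return df[column].map(fn)


@dataclass(frozen=True)
class SvmSpec:
    """Hyperparameters of the hip-development SVM."""

    degree: int = 2
    penalty_C: float = 0.3
    coef0: float = 0.0
    kernel_scale: str | float = "scale"  # 1 / (n_features * Var(X))
    standardize: bool = False
    seed: int = 0

    def make_pipeline(self) -> Pipeline:
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        return Pipeline(
            steps
            + [
                (
                    "svc",
                    SVC(
                        kernel="poly",
                        degree=self.degree,
                        C=self.penalty_C,
                        coef0=self.coef0,
                        gamma=self.kernel_scale,
                        random_state=self.seed,
                    ),
                ),
            ]
        )


def _as_features(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        features = features[list(ANGLE_FEATURES)]
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(ANGLE_FEATURES):
        raise ParameterError(
            f"expected an (n, {len(ANGLE_FEATURES)}) angle table, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ParameterError("angle features contain non-finite values")
    return X


def svm_fit(features, labels, spec: SvmSpec | None = None) -> Pipeline:
    """Fit the development SVM on an (n, 3) angle table.

    Deterministic for identical inputs. Raises :class:`ParameterError`
    when fewer than two classes are present.
    """
    spec = spec or SvmSpec()
    X = _as_features(features)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ParameterError("features and labels have different lengths")
    if np.unique(y).size < 2:
        raise ParameterError("SVM training needs at least two classes")
    model = spec.make_pipeline()
    model.fit(X, y)
    return model


def svm_predict(model: Pipeline, features) -> np.ndarray:
    """Predict one development label per angle-table row."""
    return model.predict(_as_features(features))


def svm_decision_values(model: Pipeline, features) -> np.ndarray:
    """Expose the SVM decision values (signed margins)."""
    return model.decision_function(_as_features(features))


def svm_cross_val_predict(
    features, labels, spec: SvmSpec | None = None, n_splits: int = 5
) -> np.ndarray:
    """Stratified k-fold out-of-fold predictions (default evaluation protocol)."""
    spec = spec or SvmSpec()
    X = _as_features(features)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    return cross_val_predict(spec.make_pipeline(), X, y, cv=cv)
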