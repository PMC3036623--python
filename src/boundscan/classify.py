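"""Two-stage margin classification of signal sites.

Stage 1 (task 1) separates false signals (from single-domain chains)
from near/away signals (from multi-domain chains); stage 2 (task 2),
trained only on multi-domain-chain signals, separates near from away.
Both stages are RBF-kernel support vector machines returning raw signed
margin distances, so a decision threshold in roughly [-1.5, 1.5] trades
precision against recall for the near class.

The central object is :class:`TwoStageBoundaryClassifier`, a
scikit-learn estimator (``fit`` / ``predict`` / ``decision_function``)
that composes with sklearn model selection; ``train_stage`` /
``predict_sites`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .types import ProteinClass, SiteLabel

MODEL_FORMAT_VERSION = 1

# integer codes used for y throughout
LABEL_CODES = {
    SiteLabel.FALSE_BOUNDARY: 0,
    SiteLabel.NEAR: 1,
    SiteLabel.AWAY: 2,
}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


def encode_labels(labels: list[SiteLabel]) -> np.ndarray:
    return np.array([LABEL_CODES[l] for l in labels], dtype=int)


@dataclass(frozen=True)
class ClassifierConfig:
    """Kernel and threshold settings shared by both stages."""

    gamma: float = 0.015
    regularization: float = 1.0
    decision_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")


@dataclass
class SitePrediction:
    """Classifier output for one site."""

    position: int
    stage1_score: float
    stage2_score: float | None
    call: SiteLabel


@dataclass
class ProteinCall:
    """Single/multi-domain call for one chain plus predicted boundaries."""

    chain_id: str
    call: ProteinClass
    predicted_boundaries: list[int] = field(default_factory=list)


class TwoStageBoundaryClassifier(ClassifierMixin, BaseEstimator):
    """Cascade of two RBF-SVMs over signal-site feature vectors.

    Parameters
    ----------
    gamma : float, default=0.015
        RBF kernel width for both stages.
    C : float, default=1.0
        Soft-margin regularization for both stages.
    decision_threshold : float, default=0.0
        Stage-2 margin above which a stage-1-positive site is called
        *near*; raising it trades recall for precision.

    Attributes
    ----------
    stage1_ : sklearn.svm.SVC
        False (0) vs near/away (1) classifier, fitted on all sites.
    stage2_ : sklearn.svm.SVC
        Away (0) vs near (1) classifier, fitted on multi-domain-chain
        sites only.
    classes_ : ndarray
        The three site-label codes (0 false, 1 near, 2 away).
    """

    def __init__(
        self,
        gamma: float = 0.015,
        C: float = 1.0,
        decision_threshold: float = 0.0,
    ):
        self.gamma = gamma
        self.C = C
        self.decision_threshold = decision_threshold

    def _make_svc(self) -> SVC:
        # cache capped so repeated CV fits stay within modest memory
        return SVC(kernel="rbf", gamma=self.gamma, C=self.C, cache_size=100)

    def fit(self, X, y):
        """Fit both stages.

        ``y`` holds integer site-label codes (0 false, 1 near, 2 away).
        Stage 2 sees only the near/away rows; each stage requires at
        least one example of each of its two classes.
        """
        X, y = validate_data(self, X, y)
        y = y.astype(int)
        self.classes_ = np.array([0, 1, 2])

        y1 = (y != 0).astype(int)
        for cls, name in ((0, "false"), (1, "near/away")):
            if not np.any(y1 == cls):
                raise ValueError(f"stage 1 training data has no {name} examples")
        self.stage1_ = self._make_svc().fit(X, y1)

        multi = y != 0
        y2 = (y[multi] == 1).astype(int)  # near = 1, away = 0
        for cls, name in ((0, "away"), (1, "near")):
            if not np.any(y2 == cls):
                raise ValueError(f"stage 2 training data has no {name} examples")
        self.stage2_ = self._make_svc().fit(X[multi], y2)
        return self

    def decision_function(self, X) -> np.ndarray:
        """(n, 2) raw margins: stage-1 score and stage-2 score.

        The stage-2 column is NaN for stage-1-negative rows — the
        cascade never scores them.
        """
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        s1 = self.stage1_.decision_function(X)
        s2 = np.full_like(s1, np.nan)
        pos = s1 > 0
        if np.any(pos):
            s2[pos] = self.stage2_.decision_function(X[pos])
        return np.column_stack([s1, s2])

    def predict(self, X) -> np.ndarray:
        """Site-label codes at the configured decision threshold."""
        scores = self.decision_function(X)
        out = np.zeros(len(scores), dtype=int)
        pos = scores[:, 0] > 0
        near = pos & (scores[:, 1] > self.decision_threshold)
        out[near] = 1
        out[pos & ~near] = 2
        return out


def train_stage(features, labels, config: ClassifierConfig = ClassifierConfig()) -> SVC:
    """Fit one binary RBF-SVM stage on 0/1 labels; raw-margin scoring."""
    labels = np.asarray(labels, dtype=int)
    present = np.unique(labels)
    for cls in (0, 1):
        if cls not in present:
            raise ValueError(f"training data has no class-{cls} examples")
    return SVC(
        kernel="rbf", gamma=config.gamma, C=config.regularization, cache_size=100
    ).fit(np.asarray(features), labels)


def fit_two_stage(
    X, y, config: ClassifierConfig = ClassifierConfig(), schema_hash: str = ""
) -> "TwoStageModel":
    clf = TwoStageBoundaryClassifier(
        gamma=config.gamma,
        C=config.regularization,
        decision_threshold=config.decision_threshold,
    ).fit(X, y)
    return TwoStageModel(clf, config, schema_hash)


@dataclass
class TwoStageModel:
    """A fitted cascade plus its config and the feature-schema hash."""

    classifier: TwoStageBoundaryClassifier
    config: ClassifierConfig
    feature_schema_hash: str

    def check_schema(self, schema_hash: str) -> None:
        if self.feature_schema_hash and schema_hash != self.feature_schema_hash:
            raise ValueError(
                "feature schema hash mismatch: model was trained on a "
                "different feature layout"
            )


def predict_sites(
    model: TwoStageModel,
    features,
    positions: list[int],
    threshold: float | None = None,
    schema_hash: str | None = None,
) -> list[SitePrediction]:
    """Score sites through the cascade and call each one.

    A site is false if its stage-1 margin is <= 0; otherwise near if
    its stage-2 margin exceeds the threshold, else away.
    """
    if schema_hash is not None:
        model.check_schema(schema_hash)
    thr = model.config.decision_threshold if threshold is None else threshold
    X = np.asarray(features)
    if len(X) == 0:
        return []
    scores = model.classifier.decision_function(X)
    preds = []
    for pos, (s1, s2) in zip(positions, scores):
        if s1 <= 0:
            preds.append(SitePrediction(pos, float(s1), None, SiteLabel.FALSE_BOUNDARY))
        else:
            call = SiteLabel.NEAR if s2 > thr else SiteLabel.AWAY
            preds.append(SitePrediction(pos, float(s1), float(s2), call))
    return preds


def call_protein(predictions: list[SitePrediction], chain_id: str) -> ProteinCall:
    """Chain-level call: multi-domain iff any site passed stage 1.

    Predicted boundaries are the positions of near calls; a chain with
    only away calls is still multi-domain, with no boundary placed.
    """
    if not any(p.stage1_score > 0 for p in predictions):
        return ProteinCall(chain_id, ProteinClass.SINGLE_DOMAIN)
    boundaries = sorted(p.position for p in predictions if p.call == SiteLabel.NEAR)
    return ProteinCall(chain_id, ProteinClass.MULTI_DOMAIN, boundaries)


def save_model(model: TwoStageModel, path) -> None:
    """Persist a fitted cascade (versioned joblib container)."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "config": model.config,
            "feature_schema_hash": model.feature_schema_hash,
            "classifier": model.classifier,
        },
        path,
    )


def load_model(path) -> TwoStageModel:
    """Load a saved cascade, rejecting unknown or corrupt containers."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path}: not a boundscan model container")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {payload['format_version']}"
        )
    return TwoStageModel(
        payload["classifier"], payload["config"], payload["feature_schema_hash"]
    )
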