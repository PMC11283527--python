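"""The six-classifier battery and confusion-matrix evaluation.

Families mirror the study's MATLAB-style presets:

========  ==================================================================
LSVM      support vector machine, polynomial kernel of degree 1
QSVM      support vector machine, polynomial kernel of degree 2
CSVM      support vector machine, polynomial kernel of degree 3
MNN       single-hidden-layer neural network, 25 units ("medium")
WNN       single-hidden-layer neural network, 100 units ("wide")
ESD       ensemble of linear discriminant learners on random feature
          subspaces (subspace discriminant)
========  ==================================================================

Every model is a sklearn pipeline with train-fitted z-scoring in front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import ConfusionMatrix
from .tables import LabeledFeatureTable

__all__ = [
    "CLASSIFIER_FAMILIES",
    "ClassifierSpec",
    "evaluate",
    "make_classifier",
    "train_and_evaluate",
]

CLASSIFIER_FAMILIES = ("LSVM", "QSVM", "CSVM", "MNN", "WNN", "ESD")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "LSVM": {"degree": 1, "C": 1.0},
    "QSVM": {"degree": 2, "C": 1.0},
    "CSVM": {"degree": 3, "C": 1.0},
    "MNN": {"hidden_width": 25, "max_iter": 500},
    "WNN": {"hidden_width": 100, "max_iter": 500},
    "ESD": {"n_learners": 30, "subspace_fraction": 0.5},
}


@dataclass
class ClassifierSpec:
    """One classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"expected one of {CLASSIFIER_FAMILIES}"
            )
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def make_classifier(spec: ClassifierSpec) -> Pipeline:
    """Build a fit/predict pipeline (z-scoring + estimator) for a spec."""
    hp = spec.hyperparameters
    if spec.family in ("LSVM", "QSVM", "CSVM"):
        est = SVC(
            kernel="poly",
            degree=hp["degree"],
            C=hp["C"],
            coef0=1.0,
            gamma="scale",
            random_state=spec.seed,
        )
    elif spec.family in ("MNN", "WNN"):
        est = MLPClassifier(
            hidden_layer_sizes=(hp["hidden_width"],),
            max_iter=hp["max_iter"],
            random_state=spec.seed,
        )
    else:  # ESD
        est = BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=hp["n_learners"],
            max_features=hp["subspace_fraction"],
            bootstrap=False,
            random_state=spec.seed,
        )
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def evaluate(
    model: Pipeline,
    train: LabeledFeatureTable,
    test: LabeledFeatureTable,
) -> ConfusionMatrix:
    """Tally (true, predicted) counts of a fitted model over the test rows.

    Class order is the sorted union of train and test labels; the model must
    have been fitted on ``train``'s feature set.
    """
    if train.feature_ids != test.feature_ids:
        raise ValueError("train and test tables must share feature_ids")
    predictions = np.asarray(model.predict(test.values), dtype=str)
    class_ids = sorted(set(train.class_ids) | set(test.class_ids))
    counts = _sk_confusion(test.labels, predictions, labels=class_ids)
    return ConfusionMatrix(counts=counts, class_ids=class_ids)


def train_and_evaluate(
    spec: ClassifierSpec,
    train: LabeledFeatureTable,
    test: LabeledFeatureTable,
) -> tuple[Pipeline, ConfusionMatrix]:
    """Fit a fresh classifier on train and tally its test confusion matrix."""
    model = make_classifier(spec)
    model.fit(train.values, train.labels)
    return model, evaluate(model, train, test)
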