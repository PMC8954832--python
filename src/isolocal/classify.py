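"""Uniform harness over the five classifier families.

The study compares linear discriminant analysis (LDA), random forests (RF),
a support-vector machine (SVM), a back-propagation neural network (BPNN) and
k-nearest neighbours (KNN) on identical standardized features, each trained
once (no internal tuning) and evaluated on a held-out test set with PGI as
the positive class.  Hyperparameters are conventional defaults, logged with
every fit so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aks import SelectionResult, aks_select
from .data import IsotopeLibrary, PGI
from .evaluate import ConfusionMatrix, confusion

__all__ = ["METHODS", "ClassifierSpec", "TrainedModel", "default_specs",
           "train", "predict", "run_global", "run_aks"]

logger = logging.getLogger("isolocal")

METHODS = ("LDA", "RF", "SVM", "BPNN", "KNN")


@dataclass
class ClassifierSpec:
    """One classifier family plus its (fully logged) hyperparameters."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")


def default_specs(seed: int = 0, methods: Sequence[str] = METHODS) -> list[ClassifierSpec]:
    """The five families at their documented defaults, sharing one seed."""
    return [ClassifierSpec(m, seed=seed) for m in methods]


def _build_backend(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.method == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if spec.method == "RF":
        hp.setdefault("n_estimators", 500)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.method == "SVM":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("C", 1.0)
        hp.setdefault("gamma", "scale")  # 1 / (p * var) on the scaled features
        return SVC(random_state=spec.seed, **hp)
    if spec.method == "BPNN":
        hp.setdefault("hidden_layer_sizes", (8,))
        hp.setdefault("activation", "logistic")
        hp.setdefault("solver", "lbfgs")
        hp.setdefault("max_iter", 2000)
        return MLPClassifier(random_state=spec.seed, **hp)
    if spec.method == "KNN":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    raise AssertionError(spec.method)


@dataclass
class TrainedModel:
    """A fitted back-end plus the training-set scaler and label inventory."""

    spec: ClassifierSpec
    scaler: StandardScaler | None
    backend: object | None
    classes: tuple[str, ...]
    degenerate: bool = False  # single training class: constant predictor

    @property
    def constant_label(self) -> str:
        if not self.degenerate:
            raise ValueError("model is not degenerate")
        return self.classes[0]


def train(spec: ClassifierSpec, library: IsotopeLibrary) -> TrainedModel:
    """Fit one classifier on a library.

    Features are standardized with the training statistics of *this*
    library, so local models are self-contained.  A single-class library
    yields a degenerate constant predictor (flagged and logged) rather than
    an error: local subsets can legitimately be one-class.
    """
    if len(library) < 2:
        raise ValueError("need at least two training samples")
    labels = library.groups
    classes = tuple(sorted(set(labels)))
    if len(classes) == 1:
        logger.warning(
            "single-class training library (%s, n=%d): %s degenerates to a "
            "constant predictor", classes[0], len(library), spec.method,
        )
        return TrainedModel(spec=spec, scaler=None, backend=None,
                            classes=classes, degenerate=True)
    if spec.method == "KNN":
        k = spec.hyperparameters.get("n_neighbors", 5)
        if k > len(library):
            raise ValueError(f"KNN k={k} exceeds training size {len(library)}")
    scaler = StandardScaler().fit(library.values)
    backend = _build_backend(spec)
    backend.fit(scaler.transform(library.values), labels)
    logger.info("fit %s on %r (n=%d, seed=%d)", spec.method, library.label,
                len(library), spec.seed)
    return TrainedModel(spec=spec, scaler=scaler, backend=backend, classes=classes)


def predict(model: TrainedModel, samples: IsotopeLibrary | np.ndarray) -> list[str]:
    """One PGI / nonPGI label per sample."""
    X = samples.values if isinstance(samples, IsotopeLibrary) else np.atleast_2d(samples)
    if X.shape[0] == 0:
        return []
    if model.degenerate:
        return [model.constant_label] * X.shape[0]
    return list(model.backend.predict(model.scaler.transform(X)))


def run_global(
    training: IsotopeLibrary,
    testing: IsotopeLibrary,
    specs: Sequence[ClassifierSpec],
) -> dict[str, ConfusionMatrix]:
    """Train each method on the full training library; score the test set."""
    if len(training) == 0 or len(testing) == 0:
        raise ValueError("training and testing libraries must be non-empty")
    actual = testing.groups
    out: dict[str, ConfusionMatrix] = {}
    for spec in specs:
        model = train(spec, training)
        out[spec.method] = confusion(actual, predict(model, testing), positive=PGI)
    return out


def run_aks(
    training: IsotopeLibrary,
    testing: IsotopeLibrary,
    specs: Sequence[ClassifierSpec],
    pc: int = 2,
    autoscale: bool = True,
    n_min: int | None = None,
) -> tuple[dict[str, ConfusionMatrix], SelectionResult]:
    """Adaptive Kennard-Stone subset first, then the global harness on it."""
    selection = aks_select(training, pc=pc, autoscale=autoscale, n_min=n_min)
    logger.info("AKS selected %d of %d training samples", selection.chosen_n,
                len(training))
    # The D-optimal optimum can be smaller than KNN's neighbourhood; shrink k
    # to the subset size (logged) rather than refusing the subset.
    adjusted = []
    for spec in specs:
        k = spec.hyperparameters.get("n_neighbors", 5)
        if spec.method == "KNN" and k > selection.chosen_n:
            logger.warning("KNN k=%d exceeds AKS subset size %d; clamping",
                           k, selection.chosen_n)
            spec = ClassifierSpec(
                "KNN",
                {**spec.hyperparameters, "n_neighbors": selection.chosen_n},
                seed=spec.seed,
            )
        adjusted.append(spec)
    return run_global(selection.subset, testing, adjusted), selection
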