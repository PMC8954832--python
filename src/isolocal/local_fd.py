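"""Per-test-sample local modeling on full-distance neighborhoods.

For each test sample, the training samples are ranked by how close their
full distance (FD) is to the test sample's FD, and the nearest window is
taken as that sample's one-time local training set.  The window size follows
the observed regimes: a small subset (around 27 samples) when the test
sample's FD sits far from the middle of the training FD distribution, a
medium subset (around 42) when it sits centrally — both inside the reported
20-47 range.  Each classifier is then trained on the subset and predicts
only that one test sample; accumulating the 23 single predictions yields one
confusion matrix per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import ClassifierSpec, predict, train
from .data import IsotopeLibrary, IsotopeRecord, PGI
from .ddsimca import DDSimcaModel, FDBand, fit_ddsimca, full_distances
from .evaluate import ConfusionMatrix, confusion

__all__ = ["LocalSubset", "size_rule", "fd_percentile", "nearest_fd_window",
           "fd_band_select", "run_local_fd"]

logger = logging.getLogger("isolocal")

SIZE_SMALL = 27   # midpoint of the small regime, 20 <= N < 35
SIZE_MEDIUM = 42  # midpoint of the medium regime, 35 <= N < 50
DEVIATION_THRESHOLD = 0.25  # quartiles split "central" from "deviated"


@dataclass
class LocalSubset:
    """One test sample's FD window and the training subset inside it."""

    test_sample_id: str
    band: FDBand
    subset: IsotopeLibrary
    target_size: int
    one_class: bool  # true when the window captured a single class


def size_rule(fd_percentile: float, deviation_threshold: float = DEVIATION_THRESHOLD) -> int:
    """Target subset size from the test FD's position in the training FDs.

    ``fd_percentile`` is the rank of the test sample's FD among the training
    FDs divided by n.  A percentile deviating from the median by more than
    the threshold selects the small regime; the boundary itself counts as
    central (medium).
    """
    if not 0 <= fd_percentile <= 1:
        raise ValueError("percentile must lie in [0, 1]")
    return SIZE_SMALL if abs(fd_percentile - 0.5) > deviation_threshold else SIZE_MEDIUM


def fd_percentile(model: DDSimcaModel, fd_test: float) -> float:
    """Rank of a test FD among the training FDs, as a fraction of n."""
    return float(np.sum(model.train_FD <= fd_test) / model.n_train)


def nearest_fd_window(fd_train: np.ndarray, fd_test: float, target: int) -> list[int]:
    """Indices of the ``target`` training FDs nearest ``fd_test``.

    Ties on equal |FD difference| break toward the lower index; the returned
    indices are sorted ascending.
    """
    fd_train = np.asarray(fd_train, dtype=float)
    if not 2 <= target <= fd_train.size:
        raise ValueError(
            f"target size must lie in [2, {fd_train.size}], got {target}"
        )
    order = np.argsort(np.abs(fd_train - fd_test), kind="stable")
    return sorted(int(i) for i in order[:target])


def fd_band_select(
    model: DDSimcaModel,
    training: IsotopeLibrary,
    test: IsotopeRecord,
    target_size: int | str = "auto",
) -> LocalSubset:
    """The ``target_size`` training samples whose FD is nearest the test FD.

    The training library is first put in canonical sample_id order, so the
    result is independent of input row order; ties on |FD difference| break
    toward the lower index in that canonical order.  The band records the
    (min, max) FD of the chosen window.
    """
    lib = training.sorted_by_id()
    fd_train = full_distances(model, lib.values)
    fd_test = full_distances(model, test.values)[0]
    if target_size == "auto":
        target = size_rule(fd_percentile(model, fd_test))
        target = min(target, len(lib))
    else:
        target = int(target_size)
    chosen = nearest_fd_window(fd_train, fd_test, target)
    subset = lib.subset(chosen, label=f"{training.label}-local-{test.sample_id}")
    fds = fd_train[chosen]
    lo, hi = float(fds.min()), float(fds.max())
    if lo == hi:  # all chosen FDs identical; widen infinitesimally for a valid band
        hi = lo + np.finfo(float).tiny
    one_class = len(set(subset.groups)) == 1
    if one_class:
        logger.warning(
            "local subset for %s contains a single class (%s)",
            test.sample_id, subset.groups[0],
        )
    return LocalSubset(
        test_sample_id=test.sample_id,
        band=FDBand(lo, hi),
        subset=subset,
        target_size=target,
        one_class=one_class,
    )


def run_local_fd(
    training: IsotopeLibrary,
    testing: IsotopeLibrary,
    specs: Sequence[ClassifierSpec],
    pc: int = 2,
    autoscale: bool = True,
    alpha: float = 0.05,
    gamma: float = 0.01,
    target_size: int | str = "auto",
) -> tuple[dict[str, ConfusionMatrix], list[LocalSubset]]:
    """One-time local model per test sample, accumulated per method.

    The distance model is fit once on the training library (the fit is
    deterministic, so refitting per test sample would be identical); each
    test sample then gets its own FD window and its own freshly trained
    classifiers, which predict only that sample.  One-class subsets fall
    back to a constant predictor for the affected sample and are logged.
    """
    if len(training) == 0 or len(testing) == 0:
        raise ValueError("training and testing libraries must be non-empty")
    model = fit_ddsimca(training, pc=pc, autoscale=autoscale, alpha=alpha, gamma=gamma)
    subsets: list[LocalSubset] = []
    predicted: dict[str, list[str]] = {s.method: [] for s in specs}
    for rec in testing:
        local = fd_band_select(model, training, rec, target_size=target_size)
        subsets.append(local)
        for spec in specs:
            clf = train(spec, local.subset)
            predicted[spec.method].append(predict(clf, rec.values)[0])
    actual = testing.groups
    matrices = {m: confusion(actual, preds, positive=PGI) for m, preds in predicted.items()}
    return matrices, subsets
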