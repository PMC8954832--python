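"""Adaptive Kennard-Stone subset selection.

Classic Kennard-Stone ordering spreads samples uniformly over the PCA score
space: start from the farthest-apart pair, then repeatedly add the sample
whose minimum distance to the already-selected set is largest.  The
*adaptive* part is the stopping rule: among all prefixes of the ordering,
keep the one maximizing the D-optimal information per sample,
``log Det(S^T S / N)``, where S is the principal-component score matrix of
the selected subset — i.e. the PCA is refit on each candidate prefix.  The
curve of this quantity against prefix length rises while new samples add
spread and falls once additions merely duplicate information, so its argmax
marks the most representative subset.  (Scoring prefixes inside the single
full-set model instead makes the per-sample information monotone decreasing
in the prefix length for elliptical data — the farthest-out points always
carry the most variance — which defeats the stopping rule; refitting is what
gives the curve its interior maximum.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import IsotopeLibrary
from .pca import PCAModel, fit_pca, project

__all__ = ["SelectionResult", "ks_order", "dopt_info", "prefix_info", "aks_select"]


@dataclass
class SelectionResult:
    """Kennard-Stone ordering, information curve and the chosen prefix."""

    ks_order: list[int]
    info_curve: list[tuple[int, float]]
    chosen_n: int
    subset: IsotopeLibrary
    pca: PCAModel


def ks_order(scores: np.ndarray) -> list[int]:
    """Kennard-Stone max-min ordering of score rows.

    The first two indices are the pair at maximal Euclidean distance; each
    subsequent index maximizes the minimum distance to all samples already
    selected.  All ties break toward the lowest original index, so the
    ordering is deterministic.  Duplicate points are allowed.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n == 0:
        raise ValueError("cannot order an empty score set")
    if n == 1:
        return [0]

    d = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=2)
    iu = np.triu_indices(n, k=1)
    flat = np.argmax(d[iu])  # argmax over i<j pairs; ties -> lexicographically first
    i, j = iu[0][flat], iu[1][flat]
    order = [int(i), int(j)]

    selected = np.zeros(n, dtype=bool)
    selected[[i, j]] = True
    min_dist = np.minimum(d[i], d[j])
    while len(order) < n:
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))  # np.argmax returns the first maximum
        order.append(nxt)
        selected[nxt] = True
        min_dist = np.minimum(min_dist, d[nxt])
    return order


def dopt_info(scores_subset: np.ndarray) -> float:
    """D-optimal information of a score subset: ``log Det(S^T S / N)``.

    Returns ``-inf`` when the Gram matrix is singular.  Requires at least as
    many rows as score dimensions, otherwise the matrix cannot be full rank
    by construction and the call is a contract violation.
    """
    S = np.atleast_2d(np.asarray(scores_subset, dtype=float))
    N, pc = S.shape
    if N < pc:
        raise ValueError(f"need at least pc={pc} rows, got {N}")
    M = S.T @ S / N
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    return float(logdet)


def prefix_info(X_subset: np.ndarray, pc: int, autoscale: bool = True) -> float:
    """D-optimal information of a candidate subset in its own PCA model.

    Refits the decomposition on the subset rows and returns
    :func:`dopt_info` of the resulting score matrix; ``-inf`` when the
    subset is too degenerate to fit (rank 0 or a constant column under
    autoscaling).
    """
    X_subset = np.atleast_2d(np.asarray(X_subset, dtype=float))
    try:
        model = fit_pca(X_subset, pc=pc, autoscale=autoscale)
    except ValueError:
        return -np.inf
    return dopt_info(project(model, X_subset))


def aks_select(
    training: IsotopeLibrary,
    pc: int = 2,
    autoscale: bool = True,
    n_min: int | None = None,
) -> SelectionResult:
    """Select the most representative training subset.

    Fits one PCA model on the whole training library, orders all samples by
    Kennard-Stone in score space, then for every prefix of length
    ``n_min .. N`` refits a PCA on the prefix alone and evaluates the
    D-optimal information of its score matrix; the argmax prefix wins (ties
    break toward the smallest prefix).  The library is first sorted by
    sample_id so the result does not depend on input row order.

    ``n_min`` defaults to ``pc + 2``: the Gram determinant is zero or
    numerically unstable below ``pc + 1`` samples.  A degenerate prefix that
    cannot be refit scores ``-inf``.
    """
    if n_min is None:
        n_min = pc + 2
    if n_min < pc + 1:
        raise ValueError(f"n_min must be at least pc + 1 = {pc + 1}")
    lib = training.sorted_by_id()
    n = len(lib)
    if n < n_min:
        raise ValueError(f"training library has {n} samples, need at least {n_min}")

    model = fit_pca(lib.values, pc=pc, autoscale=autoscale)
    scores = project(model, lib.values)
    order = ks_order(scores)

    curve: list[tuple[int, float]] = []
    best_n, best_info = n_min, -np.inf
    for m in range(n_min, n + 1):
        info = prefix_info(lib.values[order[:m]], pc=pc, autoscale=autoscale)
        curve.append((m, info))
        if info > best_info:  # strict: ties keep the smaller prefix
            best_n, best_info = m, info
    # Canonical (id-sorted) row order inside the subset: membership is what
    # matters, and row-order-sensitive back-ends (e.g. RF bootstrap) should
    # see a reproducible layout.
    subset = lib.subset(sorted(order[:best_n]), label=f"{training.label}-aks")
    return SelectionResult(
        ks_order=order, info_curve=curve, chosen_n=best_n, subset=subset, pca=model
    )
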