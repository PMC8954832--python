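"""Principal-component machinery shared by the two selection approaches.

Fits are mean-centred and, by default, autoscaled to unit variance: the four
isotopes live on very different per-mil scales (d2H spans tens of per mil,
d15N a few), so unscaled score-space distances would be dominated by
hydrogen.  Loadings carry a deterministic sign convention — the
largest-magnitude entry of each loading is positive — so orderings built on
scores are reproducible across linear-algebra back-ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "fit_pca", "project"]


@dataclass
class PCAModel:
    """Centering/scaling vectors plus an orthonormal loading basis.

    ``eigenvalues`` are the score variances (sample variance, n-1 in the
    denominator) of the retained components, in non-increasing order.
    """

    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # p x pc, orthonormal columns
    eigenvalues: np.ndarray
    pc: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.center.shape[0]:
            raise ValueError(
                f"expected {self.center.shape[0]} columns, got {X.shape[1]}"
            )
        return (X - self.center) / self.scale

    def to_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "pc": self.pc,
        }


def fit_pca(X: np.ndarray, pc: int = 2, autoscale: bool = True) -> PCAModel:
    """Fit a PCA model on an n x p matrix of delta values.

    Parameters
    ----------
    X:
        Data matrix, one row per sample.
    pc:
        Number of components to retain, ``1 <= pc <= min(n-1, p)``.
    autoscale:
        Divide each centred column by its standard deviation before the
        decomposition (default).  A constant column makes autoscaling
        impossible and raises.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples to fit a PCA model")
    if not 1 <= pc <= min(n - 1, p):
        raise ValueError(f"pc must be in [1, {min(n - 1, p)}], got {pc}")

    center = X.mean(axis=0)
    Xc = X - center
    if autoscale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [i for i, s in enumerate(sd) if s == 0]
            raise ValueError(f"constant column(s) {bad} cannot be autoscaled")
        scale = sd
    else:
        scale = np.ones(p)
    Z = Xc / scale

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s[0] > 0 else 0
    if rank == 0:
        raise ValueError("data matrix has rank 0 (all rows identical)")

    loadings = Vt[:pc].T
    # Sign convention: largest-magnitude entry of each loading positive.
    for a in range(pc):
        col = loadings[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, a] = -col
    eigenvalues = (s[:pc] ** 2) / (n - 1)
    return PCAModel(center=center, scale=scale, loadings=loadings,
                    eigenvalues=eigenvalues, pc=pc)


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Scores of new rows in the model's component basis (m x pc)."""
    return model.transform(X) @ model.loadings
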