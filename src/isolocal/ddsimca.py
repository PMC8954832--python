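"""Data-driven SIMCA distances, degrees of freedom and the full distance.

A fitted PCA model splits each sample into a projection onto the component
subspace and a residual.  Two squared distances characterize a sample's
position: the score distance SD (squared Mahalanobis distance of its scores
from the model centre) and the orthogonal distance OD (squared residual
norm).  Scaled by their training means SD0 and OD0 and by moment-estimated
degrees of freedom Nh and Nq, they combine into the full distance

    FD = Nh * SD / SD0 + Nq * OD / OD0,

which is approximately chi-squared with Nh + Nq degrees of freedom.  FD is
used both to delimit regular / extreme / outlier zones (acceptance plot) and
as a one-dimensional similarity coordinate for local sample selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import IsotopeLibrary
from .pca import PCAModel, fit_pca, project

__all__ = [
    "DDSimcaModel",
    "DistancePair",
    "FDBand",
    "dof_estimate",
    "fit_ddsimca",
    "distances",
    "full_distances",
    "acceptance_coordinates",
    "boundary_polyline",
]

ZONE_REGULAR = "regular"
ZONE_EXTREME = "extreme"
ZONE_OUTLIER = "outlier"

_DOF_MAX = 250


@dataclass
class DistancePair:
    """One sample's position relative to a fitted model."""

    SD: float
    OD: float
    FD: float
    zone: str


@dataclass
class FDBand:
    """An interval of full-distance values, FD1 < FD2."""

    FD1: float
    FD2: float

    def __post_init__(self) -> None:
        if not self.FD1 < self.FD2:
            raise ValueError(f"FD1 must be below FD2, got [{self.FD1}, {self.FD2}]")

    def contains(self, fd: float) -> bool:
        return self.FD1 <= fd <= self.FD2


@dataclass
class DDSimcaModel:
    pca: PCAModel
    SD0: float
    OD0: float
    Nh: int
    Nq: int
    alpha: float
    gamma: float
    n_train: int
    train_SD: np.ndarray
    train_OD: np.ndarray

    @property
    def fd_crit_regular(self) -> float:
        """Green-line limit: chi-squared quantile at 1 - alpha."""
        return float(stats.chi2.ppf(1 - self.alpha, self.Nh + self.Nq))

    @property
    def fd_crit_outlier(self) -> float:
        """Red-line limit with the per-sample (1 - gamma)^(1/n) correction."""
        q = (1 - self.gamma) ** (1 / self.n_train)
        return float(stats.chi2.ppf(q, self.Nh + self.Nq))

    @property
    def train_FD(self) -> np.ndarray:
        return self.Nh * self.train_SD / self.SD0 + self.Nq * self.train_OD / self.OD0


def dof_estimate(values: np.ndarray) -> int:
    """Method-of-moments degrees of freedom of a scaled chi-squared sample.

    If ``values ~ (c/k) * chi2(k)`` then ``2 * mean^2 / var = k``; the
    estimate is rounded and clamped to ``[1, 250]``.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    var = values.var(ddof=1)
    if var <= 0 or mean <= 0:
        raise ValueError("distance sample has zero mean or variance; cannot estimate DOF")
    k = int(round(2 * mean**2 / var))
    return int(np.clip(k, 1, _DOF_MAX))


def _raw_distances(pca: PCAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score distance and orthogonal distance for each row of X."""
    Z = pca.transform(X)
    T = Z @ pca.loadings
    lam = np.where(pca.eigenvalues > 0, pca.eigenvalues, np.inf)
    sd = np.sum(T**2 / lam, axis=1)
    resid = Z - T @ pca.loadings.T
    od = np.sum(resid**2, axis=1)
    return sd, od


def fit_ddsimca(
    training: IsotopeLibrary,
    pc: int = 2,
    autoscale: bool = True,
    alpha: float = 0.05,
    gamma: float = 0.01,
) -> DDSimcaModel:
    """Fit the distance model on a training library.

    By default the model is fit on all training samples regardless of class:
    here DD-SIMCA serves as a similarity engine over the whole library, not
    as a one-class classifier (pass a single-class library for that use).
    Test samples are later projected into this model, never refit.
    """
    if not 0 < alpha < 1 or not 0 < gamma < 1:
        raise ValueError("alpha and gamma must lie in (0, 1)")
    n = len(training)
    if n < pc + 2:
        raise ValueError(f"need at least pc + 2 = {pc + 2} training samples, got {n}")
    pca = fit_pca(training.values, pc=pc, autoscale=autoscale)
    sd, od = _raw_distances(pca, training.values)
    # Residuals of data lying exactly in the subspace are rounding noise, not
    # a usable OD distribution; compare against the overall scaled energy.
    tol = np.finfo(float).eps * np.mean(pca.transform(training.values) ** 2)
    if sd.mean() <= tol or od.mean() <= tol:
        raise ValueError(
            "degenerate training data: zero mean score or orthogonal distance"
        )
    return DDSimcaModel(
        pca=pca,
        SD0=float(sd.mean()),
        OD0=float(od.mean()),
        Nh=dof_estimate(sd),
        Nq=dof_estimate(od),
        alpha=alpha,
        gamma=gamma,
        n_train=n,
        train_SD=sd,
        train_OD=od,
    )


def _zone(model: DDSimcaModel, fd: float) -> str:
    if fd > model.fd_crit_outlier:
        return ZONE_OUTLIER
    if fd > model.fd_crit_regular:
        return ZONE_EXTREME
    return ZONE_REGULAR


def distances(model: DDSimcaModel, x: np.ndarray) -> DistancePair:
    """SD, OD, FD and acceptance zone for a single sample's delta 4-vector."""
    sd, od = _raw_distances(model.pca, np.atleast_2d(x))
    fd = model.Nh * sd[0] / model.SD0 + model.Nq * od[0] / model.OD0
    return DistancePair(SD=float(sd[0]), OD=float(od[0]), FD=float(fd), zone=_zone(model, fd))


def full_distances(model: DDSimcaModel, X: np.ndarray) -> np.ndarray:
    """Vector of FD values for many samples at once."""
    sd, od = _raw_distances(model.pca, X)
    return model.Nh * sd / model.SD0 + model.Nq * od / model.OD0


def acceptance_coordinates(model: DDSimcaModel, X: np.ndarray):
    """Acceptance-plot coordinates for a batch of samples.

    Returns a list of ``(u, v, zone)`` with ``u = ln(1 + Nh*SD/SD0)`` and
    ``v = ln(1 + Nq*OD/OD0)``; the log form keeps the extreme tail readable.
    Raw SD/OD are recoverable from the model's scaling constants.
    """
    sd, od = _raw_distances(model.pca, X)
    u = np.log1p(model.Nh * sd / model.SD0)
    v = np.log1p(model.Nq * od / model.OD0)
    fd = model.Nh * sd / model.SD0 + model.Nq * od / model.OD0
    return [(float(ui), float(vi), _zone(model, float(f))) for ui, vi, f in zip(u, v, fd)]


def boundary_polyline(fd_value: float, num: int = 200) -> np.ndarray:
    """Sampled iso-FD curve in acceptance-plot coordinates.

    All points on the returned polyline share the same full distance; the
    regular (green) and outlier (red) boundaries are the iso-FD curves at the
    model's two critical limits, and any other FD value gives an
    intermediate (yellow) line.
    """
    if fd_value <= 0:
        raise ValueError("iso-FD curves exist only for positive FD")
    u = np.linspace(0.0, np.log1p(fd_value), num)
    v = np.log1p(fd_value - np.expm1(u))
    return np.column_stack([u, v])
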