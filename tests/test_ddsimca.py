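"""DD-SIMCA distances, moment DOF estimation and acceptance zones."""

import numpy as np
import pytest
from scipy import stats

from isolocal import (
    IsotopeLibrary,
    IsotopeRecord,
    acceptance_coordinates,
    boundary_polyline,
    distances,
    dof_estimate,
    fit_ddsimca,
    full_distances,
)
from isolocal.ddsimca import DDSimcaModel
from isolocal.pca import PCAModel


def make_manual_model(Nh=1, Nq=2, SD0=2.0, OD0=4.0, n_train=50):
    """A hand-built model whose score space is the first two coordinates.

    With center 0 and unit scale/eigenvalues, a sample (a, b, c, d) has
    SD = a^2 + b^2 and OD = c^2 + d^2, so distances are controllable exactly.
    """
    pca = PCAModel(
        center=np.zeros(4),
        scale=np.ones(4),
        loadings=np.eye(4)[:, :2],
        eigenvalues=np.ones(2),
        pc=2,
    )
    return DDSimcaModel(
        pca=pca, SD0=SD0, OD0=OD0, Nh=Nh, Nq=Nq, alpha=0.05, gamma=0.01,
        n_train=n_train, train_SD=np.full(n_train, SD0), train_OD=np.full(n_train, OD0),
    )


class TestDofEstimate:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_recovers_scaled_chi_square_dof(self, k):
        rng = np.random.default_rng(100 + k)
        c = 2.7  # arbitrary positive scale
        sample = (c / k) * rng.chisquare(k, size=10_000)
        assert dof_estimate(sample) == k

    def test_gaussian_cloud_dof_near_pc(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        assert model.Nh in {1, 2, 3}

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            dof_estimate(np.ones(100))


class TestFitAndDistances:
    def test_center_sample_has_zero_distances(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        x = model.pca.center
        pair = distances(model, x)
        assert pair.SD == pytest.approx(0, abs=1e-20)
        assert pair.OD == pytest.approx(0, abs=1e-20)
        assert pair.FD == pytest.approx(0, abs=1e-20)
        assert pair.zone == "regular"

    def test_full_distance_formula_direct_substitution(self):
        model = make_manual_model(Nh=1, Nq=2, SD0=2.0, OD0=4.0)
        x = np.array([2.0, 0.0, np.sqrt(2.0), 0.0])  # SD = 4, OD = 2
        pair = distances(model, x)
        assert pair.SD == pytest.approx(4.0)
        assert pair.OD == pytest.approx(2.0)
        assert pair.FD == pytest.approx(1 * (4 / 2) + 2 * (2 / 4))

    def test_mean_training_fd_is_dof_sum(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        assert model.train_FD.mean() == pytest.approx(model.Nh + model.Nq, rel=1e-12)

    def test_data_in_subspace_is_degenerate(self):
        t = np.linspace(0, 1, 12)
        rows = np.column_stack([t, 2 * t, t - 1, 0.5 * t])  # rank 1: OD == 0 at pc=1
        recs = [
            IsotopeRecord(f"s{i}", "Abaga", *map(float, row))
            for i, row in enumerate(rows)
        ]
        with pytest.raises(ValueError, match="degenerate"):
            fit_ddsimca(IsotopeLibrary(recs), pc=1, autoscale=False)

    def test_training_rows_reproduce_stored_distances(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        for i in (0, 17, 92):
            pair = distances(model, training_library.values[i])
            assert pair.SD == pytest.approx(model.train_SD[i], rel=1e-12)
            assert pair.OD == pytest.approx(model.train_OD[i], rel=1e-12)

    def test_fd_invariant_to_training_row_order(self, training_library):
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(training_library))
        shuffled = training_library.subset(perm)
        a = fit_ddsimca(training_library, pc=2)
        b = fit_ddsimca(shuffled, pc=2)
        x = np.array([-20.0, 7.0, -110.0, 11.0])
        assert full_distances(a, x)[0] == pytest.approx(full_distances(b, x)[0], rel=1e-10)

    def test_regular_zone_calibration(self):
        """Chi-square limits hold approximately on multivariate-normal data."""
        rng = np.random.default_rng(12)
        rows = rng.normal(size=(500, 4))
        recs = [
            IsotopeRecord(f"s{i}", "Abaga", *map(float, row))
            for i, row in enumerate(rows)
        ]
        lib = IsotopeLibrary(recs)
        model = fit_ddsimca(lib, pc=2, alpha=0.05)
        fds = model.train_FD
        regular = np.mean(fds <= model.fd_crit_regular)
        assert regular >= 1 - model.alpha - 0.05

    def test_too_few_samples_rejected(self, toy_library):
        with pytest.raises(ValueError, match="pc \\+ 2"):
            fit_ddsimca(toy_library.subset([0, 1, 2]), pc=2)


class TestAcceptancePlot:
    def test_center_maps_to_origin(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        (u, v, zone), = acceptance_coordinates(model, model.pca.center[None, :])
        assert (u, v) == (pytest.approx(0, abs=1e-20), pytest.approx(0, abs=1e-20))
        assert zone == "regular"

    def test_zones_agree_with_distances(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        coords = acceptance_coordinates(model, training_library.values)
        for x, (_, _, zone) in zip(training_library.values, coords):
            assert distances(model, x).zone == zone

    def test_equal_fd_lies_on_same_iso_curve(self):
        model = make_manual_model(Nh=1, Nq=1, SD0=1.0, OD0=1.0)
        # two samples with FD = 5 split differently between SD and OD
        xa = np.array([2.0, 0.0, 1.0, 0.0])  # SD 4, OD 1
        xb = np.array([1.0, 0.0, 2.0, 0.0])  # SD 1, OD 4
        fa, fb = full_distances(model, np.vstack([xa, xb]))
        assert fa == pytest.approx(fb)
        curve = boundary_polyline(fa, num=5001)
        for x in (xa, xb):
            (u, v, _), = acceptance_coordinates(model, x[None, :])
            gap = np.min(np.hypot(curve[:, 0] - u, curve[:, 1] - v))
            assert gap < 2e-3

    def test_outlier_limit_exceeds_regular_limit(self, training_library):
        model = fit_ddsimca(training_library, pc=2)
        assert model.fd_crit_outlier > model.fd_crit_regular
        # red line is the chi-square quantile with the per-sample correction
        q = (1 - model.gamma) ** (1 / model.n_train)
        assert model.fd_crit_outlier == pytest.approx(
            stats.chi2.ppf(q, model.Nh + model.Nq)
        )
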