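import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from idpensemble import observables as ob
from idpensemble import synthetic_data as sd
from idpensemble.trajio import TOPOLOGY_COLUMNS, AnalysisError, Ensemble, ParameterError


def make_ensemble(coords, masses=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    masses = np.ones(n) if masses is None else np.asarray(masses, float)
    top = pd.DataFrame(
        {
            "name": ["CA"] * n,
            "element": ["C"] * n,
            "mass": masses,
            "resid": np.arange(1, n + 1),
            "resname": ["GLY"] * n,
        },
        columns=TOPOLOGY_COLUMNS,
    )
    return Ensemble(coords, top)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        ens = make_ensemble([[[1.0, 2.0, 3.0]]])
        assert ob.radius_of_gyration(ens).values[0] == 0.0

    def test_two_equal_masses(self):
        ens = make_ensemble([[[0, 0, 0], [0.4, 0, 0]]])
        assert ob.radius_of_gyration(ens).values[0] == pytest.approx(0.2, abs=1e-12)

    def test_pairwise_identity_oracle(self, ideal_chain_50):
        # Rg^2 = (1/2) sum_ij m_i m_j |r_i - r_j|^2 / (sum m)^2
        frame = ideal_chain_50.subset_frames([0])
        rg = ob.radius_of_gyration(frame).values[0]
        x = frame.coordinates[0]
        m = frame.masses
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
        rg2 = 0.5 * (m[:, None] * m[None, :] * d2).sum() / m.sum() ** 2
        assert rg**2 == pytest.approx(rg2, abs=1e-10)


class TestEndToEnd:
    def test_two_bead_chain(self):
        ens = sd.generate_ideal_chain(sd.ChainModelSpec(n_beads=2, bond_length=0.38, n_frames=5, seed=0))
        assert np.allclose(ob.end_to_end(ens, "caca").values, 0.38)

    def test_coincident_termini(self):
        ens = make_ensemble([[[0, 0, 0], [1, 0, 0], [0, 0, 0]]])
        assert ob.end_to_end(ens, "caca").values[0] == 0.0

    def test_ideal_chain_mean_square(self, ideal_chain_50):
        ree = ob.end_to_end(ideal_chain_50, "caca").values
        expected = 49 * 0.38**2
        se = (ree**2).std(ddof=1) / np.sqrt(len(ree))
        assert abs((ree**2).mean() - expected) < 3 * se

    def test_rigid_motion_invariance(self, ideal_chain_50):
        sub = ideal_chain_50.subset_frames(np.arange(50))
        rng = np.random.default_rng(5)
        R = Rotation.random(50, rng=rng).as_matrix()
        shift = rng.normal(size=(50, 1, 3))
        moved = Ensemble(np.einsum("fai,fij->faj", sub.coordinates, R) + shift, sub.topology)
        for fn in (ob.radius_of_gyration, lambda e: ob.end_to_end(e, "caca")):
            assert np.abs(fn(moved).values - fn(sub).values).max() < 1e-9


class TestBlockError:
    def test_iid_gaussian_plateau(self):
        rng = np.random.default_rng(11)
        est = ob.block_error(ob.ScalarSeries(rng.normal(0, 1, 4096)))
        assert abs(est.plateau - 1.0 / 64.0) / (1.0 / 64.0) < 0.20

    def test_constant_series_zero(self):
        est = ob.block_error(ob.ScalarSeries(np.full(256, 3.14)))
        assert np.all(est.errors == 0.0)
        assert est.plateau == 0.0

    def test_ar1_matches_effective_sample_size(self):
        rho, n = 0.9, 65536
        rng = np.random.default_rng(21)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        est = ob.block_error(ob.ScalarSeries(x))
        assert abs(est.plateau - expected) / expected < 0.25

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            ob.block_error(ob.ScalarSeries(np.arange(8.0)))


class TestAutocorrelation:
    def test_normalisation_and_white_noise(self):
        rng = np.random.default_rng(3)
        n = 4096
        acf, tau = ob.autocorrelation(ob.ScalarSeries(rng.normal(0, 1, n)))
        assert acf[0] == pytest.approx(1.0)
        assert np.abs(acf[1:50]).max() < 3.0 / np.sqrt(n)

    def test_ar1_decay_constant(self):
        rho, n = 0.8, 200000
        rng = np.random.default_rng(17)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        acf, _ = ob.autocorrelation(ob.ScalarSeries(x))
        lags = np.arange(1, 8)
        slope = np.polyfit(lags, np.log(acf[lags]), 1)[0]
        assert abs(-1.0 / slope - (-1.0 / np.log(rho))) / (-1.0 / np.log(rho)) < 0.10

    def test_zero_variance_rejected(self):
        with pytest.raises(AnalysisError):
            ob.autocorrelation(ob.ScalarSeries(np.ones(16)))


class TestHistogram:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        edges, density = ob.histogram(ob.ScalarSeries(rng.normal(0, 1, 5000)))
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_single_bin(self):
        edges, density = ob.histogram(ob.ScalarSeries(np.full(100, 2.0)))
        assert len(density) == 1
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_density_close_to_one(self):
        rng = np.random.default_rng(8)
        edges, density = ob.histogram(ob.ScalarSeries(rng.uniform(0, 1, 100000)))
        inner = (edges[:-1] > 0.01) & (edges[1:] < 0.99)
        assert np.abs(density[inner] - 1.0).max() < 0.05


class TestPercentDifference:
    # force-field comparison worked examples: printed means -> printed percentages
    @pytest.mark.parametrize("ref,other,expected", [
        (1.17, 1.12, 4), (3.44, 2.88, 16),   # Tau1 Rg / Ree
        (1.29, 1.06, 18), (3.27, 2.10, 36),  # Tau2
        (1.43, 1.08, 24), (3.09, 1.65, 47),  # bCPP
        (1.73, 1.41, 18), (4.05, 2.74, 32),  # Stath
    ])
    def test_force_field_table(self, ref, other, expected):
        assert ob.percent_difference(ref, other) == expected

    @pytest.mark.parametrize("sim,expected", [(1.73, 10), (1.41, 27)])
    def test_stath_vs_experimental_rg(self, sim, expected):
        assert ob.percent_difference(1.93, sim) == expected
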