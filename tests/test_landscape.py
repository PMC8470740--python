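import numpy as np
import pytest

from idpensemble import landscape as ls
from idpensemble import synthetic_data as sd
from idpensemble.trajio import AnalysisError, Ensemble, ParameterError


def two_gaussian_points(n=10000, weight=0.7, separation=3.0, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    n1 = int(round(weight * n))
    return np.vstack([
        rng.normal([0.0, 0.0], sigma, (n1, 2)),
        rng.normal([separation, 0.0], sigma, (n - n1, 2)),
    ])


@pytest.fixture(scope="module")
def chain_ensemble():
    return sd.generate_ideal_chain(sd.ChainModelSpec(n_beads=20, n_frames=400, seed=2))


class TestCentralStructure:
    def test_identical_frames_tie_break_first(self, chain_ensemble):
        coords = np.repeat(chain_ensemble.coordinates[:1], 10, axis=0)
        ens = Ensemble(coords, chain_ensemble.topology)
        assert ls.central_structure(ens, selection="all") == 0

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 0.01, (16, 5, 3))
        b = rng.normal(5.0, 0.01, (4, 5, 3))
        coords = np.concatenate([a, b])
        import pandas as pd

        from idpensemble.trajio import TOPOLOGY_COLUMNS

        top = pd.DataFrame(
            {"name": ["CA"] * 5, "element": ["C"] * 5, "mass": np.ones(5),
             "resid": np.arange(1, 6), "resname": ["GLY"] * 5},
            columns=TOPOLOGY_COLUMNS,
        )
        medoid = ls.central_structure(Ensemble(coords, top), selection="all")
        assert medoid < 16  # lies in the 80% cluster

    def test_medoid_beats_mean_pairwise_rmsd(self, chain_ensemble):
        from idpensemble._geometry import rmsd_to_reference

        sub = chain_ensemble.subset_frames(np.arange(40))
        medoid = ls.central_structure(sub, selection="all")
        coords = sub.coordinates
        all_means = np.array(
            [rmsd_to_reference(coords, coords[k]).mean() for k in range(40)]
        )
        assert all_means[medoid] <= all_means.mean()


class TestPCA:
    def test_recovers_known_directions(self):
        # wide rigid scaffold + one probe atom displaced with variance 9:1:0
        # along x/y/z; superposition cannot absorb the probe's motion
        rng = np.random.default_rng(7)
        n, n_scaffold = 4000, 50
        scaffold = rng.uniform(-5.0, 5.0, (n_scaffold, 3))
        coords = np.broadcast_to(scaffold, (n, n_scaffold, 3)).copy()
        probe = np.zeros((n, 1, 3))
        probe[:, 0, 0] = rng.normal(0, 0.3, n)
        probe[:, 0, 1] = rng.normal(0, 0.1, n)
        coords = np.concatenate([coords, probe + np.array([6.0, 0.0, 0.0])], axis=1)
        import pandas as pd

        from idpensemble.trajio import TOPOLOGY_COLUMNS

        m = n_scaffold + 1
        top = pd.DataFrame(
            {"name": ["CA"] * m, "element": ["C"] * m, "mass": np.ones(m),
             "resid": np.arange(1, m + 1), "resname": ["GLY"] * m},
            columns=TOPOLOGY_COLUMNS,
        )
        basis = ls.fit_pca(Ensemble(coords, top), selection="all")
        fractions = basis.variance_fractions
        assert fractions[0] == pytest.approx(0.9, abs=0.02)
        assert fractions[1] == pytest.approx(0.1, abs=0.02)
        c1 = basis.components[0].reshape(m, 3)[-1]
        c2 = basis.components[1].reshape(m, 3)[-1]
        ang1 = np.degrees(np.arccos(min(1.0, abs(c1[0]) / np.linalg.norm(c1))))
        ang2 = np.degrees(np.arccos(min(1.0, abs(c2[1]) / np.linalg.norm(c2))))
        assert ang1 < 2.0 and ang2 < 2.0

    def test_full_reconstruction(self, chain_ensemble):
        sub = chain_ensemble.subset_frames(np.arange(60))
        basis = ls.fit_pca(sub, selection="all")
        proj = ls.project(basis, sub, n_components=basis.components.shape[0])
        recon = proj @ basis.components + basis.mean
        from idpensemble._geometry import superpose

        aligned = superpose(sub.coordinates, basis.reference).reshape(60, -1)
        assert np.abs(recon - aligned).max() < 1e-8

    def test_shared_basis_symmetric_projections(self, chain_ensemble):
        sub = chain_ensemble.subset_frames(np.arange(50))
        basis = ls.fit_pca([sub, sub], selection="all")
        p1 = ls.project(basis, sub)
        p2 = ls.project(basis, sub)
        assert np.array_equal(p1, p2)

    def test_variance_report(self, chain_ensemble):
        basis = ls.fit_pca(chain_ensemble.subset_frames(np.arange(100)), selection="all")
        v = ls.variance_report(basis)
        assert 0.0 <= v <= 1.0
        assert basis.variance_fractions[0] >= basis.variance_fractions[1]

    def test_planar_data_fully_captured(self):
        pts = two_gaussian_points(500)
        # embed 2D points as a single-atom ensemble with z = 0
        coords = np.zeros((500, 2, 3))
        coords[:, 0, :2] = pts
        coords[:, 1, :2] = -pts
        import pandas as pd

        from idpensemble.trajio import TOPOLOGY_COLUMNS

        top = pd.DataFrame(
            {"name": ["CA", "CA"], "element": ["C", "C"], "mass": [1.0, 1.0],
             "resid": [1, 2], "resname": ["GLY", "GLY"]},
            columns=TOPOLOGY_COLUMNS,
        )
        basis = ls.fit_pca(Ensemble(coords, top), selection="all")
        assert ls.variance_report(basis) == pytest.approx(1.0, abs=1e-9)


class TestFreeEnergySurface:
    def test_single_gaussian_one_shallow_basin(self):
        pts = np.random.default_rng(1).normal(0, 0.5, (5000, 2))
        surf = ls.assign_basins(ls.free_energy_surface(pts, grid=100))
        banded = [m for m in surf.minima if m.band is not None]
        assert len(banded) == 1
        assert np.nanmin(surf.free_energy) == 0.0

    def test_two_cluster_depth_gap(self):
        surf = ls.free_energy_surface(two_gaussian_points(), grid=120)
        ls.assign_basins(surf)
        banded = sorted((m for m in surf.minima if m.band is not None), key=lambda m: m.depth)
        assert len(banded) == 2
        gap = banded[1].depth - banded[0].depth
        assert abs(gap - np.log(0.7 / 0.3)) < 0.15

    def test_basin_labels_partition_unmasked_cells(self):
        surf = ls.assign_basins(ls.free_energy_surface(two_gaussian_points(seed=5), grid=90))
        unmasked = ~surf.mask
        assert np.all(surf.basins[unmasked] >= 0)
        assert np.all(surf.basins[~unmasked] == -1)

    def test_boundary_near_density_saddle_for_equal_weights(self):
        pts = two_gaussian_points(20000, weight=0.5, separation=3.0, seed=8)
        surf = ls.assign_basins(ls.free_energy_surface(pts, grid=150))
        banded = [m for m in surf.minima if m.band is not None]
        xs = sorted(m.pc1 for m in banded)
        # boundary column between the two attractors
        lab0 = surf.basins[np.argmin(np.abs(surf.pc1 - xs[0])), 75]
        boundary = None
        for i, x in enumerate(surf.pc1):
            if xs[0] < x < xs[1] and surf.basins[i, 75] != lab0:
                boundary = x
                break
        assert boundary is not None
        assert abs(boundary - 1.5) < 0.25  # analytic saddle at the midpoint

    def test_min_is_exactly_zero_and_cap_masks(self):
        surf = ls.free_energy_surface(two_gaussian_points(seed=2), grid=80)
        assert np.nanmin(surf.free_energy) == 0.0
        assert np.all(np.isnan(surf.free_energy[surf.mask]))

    def test_depth_gap_converges_with_sample_size(self):
        # fixed absolute bandwidth; the gap approaches ln(0.7/0.3)
        target = np.log(0.7 / 0.3)
        errors = []
        for n in (1000, 100000):
            surf = ls.free_energy_surface(
                two_gaussian_points(n=n, seed=3), grid=80, bandwidth=0.15
            )
            ls.assign_basins(surf)
            banded = sorted(
                (m for m in surf.minima if m.band is not None), key=lambda m: m.depth
            )
            errors.append(abs(banded[1].depth - banded[0].depth - target))
        assert errors[-1] < errors[0] or errors[-1] < 0.03

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            ls.free_energy_surface(np.zeros((50, 2)))
        with pytest.raises(AnalysisError):
            ls.free_energy_surface(np.zeros((200, 2)))
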