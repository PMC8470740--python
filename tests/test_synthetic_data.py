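import numpy as np
import pytest

from idpensemble import sequence_charge as sc
from idpensemble import synthetic_data as sd
from idpensemble.trajio import InfeasibleError, ParameterError


def brute_min_residue_distance(ens, i, j):
    by_res = ens.atom_indices_by_residue()
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        a = ens.coordinates[f, by_res[i]]
        b = ens.coordinates[f, by_res[j]]
        out[f] = min(
            np.linalg.norm(x - y) for x in a for y in b
        )
    return out


class TestIdealChain:
    def test_two_beads_fixed_bond(self):
        ens = sd.generate_ideal_chain(sd.ChainModelSpec(n_beads=2, bond_length=0.38, n_frames=50, seed=0))
        d = np.linalg.norm(ens.coordinates[:, 1] - ens.coordinates[:, 0], axis=1)
        assert np.allclose(d, 0.38, atol=1e-12)

    def test_mean_square_end_to_end(self, ideal_chain_50):
        ree2 = np.sum((ideal_chain_50.coordinates[:, -1] - ideal_chain_50.coordinates[:, 0]) ** 2, axis=1)
        expected = 49 * 0.38**2
        se = ree2.std(ddof=1) / np.sqrt(len(ree2))
        assert abs(ree2.mean() - expected) < 3 * se

    def test_deterministic_given_seed(self):
        spec = sd.ChainModelSpec(n_beads=50, n_frames=100, seed=42)
        a = sd.generate_ideal_chain(spec)
        b = sd.generate_ideal_chain(spec)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_ree2_over_rg2_approaches_six(self):
        # Gaussian-chain ratio <Ree^2>/<Rg^2> -> 6 for long chains
        ens = sd.generate_ideal_chain(sd.ChainModelSpec(n_beads=200, n_frames=50000, seed=9))
        ree2 = np.sum((ens.coordinates[:, -1] - ens.coordinates[:, 0]) ** 2, axis=1).mean()
        com = ens.coordinates.mean(axis=1, keepdims=True)
        rg2 = np.mean(np.sum((ens.coordinates - com) ** 2, axis=2))
        assert abs(ree2 / rg2 - 6.0) / 6.0 < 0.05

    @pytest.mark.parametrize("kwargs", [
        {"n_beads": 1}, {"bond_length": 0.0}, {"n_frames": 0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        base = dict(n_beads=5, bond_length=0.38, n_frames=10, seed=0)
        base.update(kwargs)
        with pytest.raises(ParameterError):
            sd.ChainModelSpec(**base)


class TestBuildBackbone:
    def test_dihedral_round_trip(self):
        seq = sc.parse_sequence("A" * 10)
        ens = sd.build_backbone(seq, sd.BackboneGeometry.uniform(10, -57.0, -47.0))
        phi, psi, omega = sd.backbone_dihedrals(ens)
        assert np.allclose(phi[0, 1:], -57.0, atol=0.5)
        assert np.allclose(psi[0, :-1], -47.0, atol=0.5)
        assert np.allclose(np.abs(omega[0, :-1]), 180.0, atol=0.5)

    def test_two_residues_trailing_psi_ignored(self):
        seq = sc.parse_sequence("AA")
        ens = sd.build_backbone(seq, sd.BackboneGeometry.uniform(2, -60.0, -40.0))
        assert ens.n_frames == 1
        phi, psi, _ = sd.backbone_dihedrals(ens)
        assert np.isnan(psi[0, -1])  # no psi defined for the last residue
        assert abs(phi[0, 1] + 60.0) < 0.5

    def test_ppii_ca_ca_distances(self, ppii_6):
        ca = ppii_6.coordinates[0][ppii_6.topology["name"].to_numpy() == "CA"]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(d, 0.38, atol=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            sd.build_backbone(sc.parse_sequence("AAA"), sd.BackboneGeometry.uniform(4, -57.0, -47.0))

    def test_proline_has_no_amide_hydrogen(self):
        ens = sd.build_backbone(sc.parse_sequence("APA"), sd.BackboneGeometry.uniform(3, -75.0, 145.0))
        top = ens.topology
        pro_atoms = top[top["resid"] == 2]["name"].tolist()
        assert "H" not in pro_atoms
        assert "H" in top[top["resid"] == 3]["name"].tolist()


class TestPlantContacts:
    def test_zero_fraction_removes_all_contacts(self, ideal_chain_30):
        spec = sd.PlantedContactSpec(5, 25, 0.0)
        out = sd.plant_contacts(ideal_chain_30, [spec], seed=3)
        d = brute_min_residue_distance(out.subset_frames(np.arange(0, out.n_frames, 20)), 5, 25)
        assert np.all(d >= 0.4)

    def test_target_fraction_recovered(self, ideal_chain_30):
        spec = sd.PlantedContactSpec(5, 25, 0.60)
        out = sd.plant_contacts(ideal_chain_30, [spec], seed=3)
        d = sd._min_residue_distance(out, 5, 25)
        assert 0.58 <= np.mean(d < 0.4) <= 0.62
        assert out.n_frames == ideal_chain_30.n_frames

    def test_two_disjoint_pairs(self, ideal_chain_30):
        specs = [sd.PlantedContactSpec(3, 15, 0.4), sd.PlantedContactSpec(20, 28, 0.3)]
        out = sd.plant_contacts(ideal_chain_30, specs, seed=5)
        for s in specs:
            frac = np.mean(sd._min_residue_distance(out, s.i, s.j) < s.cutoff)
            assert abs(frac - s.fraction) <= 0.02

    def test_frames_preserved_exactly(self, ideal_chain_30):
        out = sd.plant_contacts(ideal_chain_30, [sd.PlantedContactSpec(5, 25, 0.5)], seed=1)
        # every output frame is bit-identical to some input frame
        base = {arr.tobytes() for arr in ideal_chain_30.coordinates}
        assert all(arr.tobytes() in base for arr in out.coordinates)

    def test_infeasible_target_raises(self):
        ens = sd.generate_ideal_chain(sd.ChainModelSpec(n_beads=4, bond_length=5.0, n_frames=50, seed=0))
        with pytest.raises(InfeasibleError):
            sd.plant_contacts(ens, [sd.PlantedContactSpec(1, 4, 0.5, cutoff=0.1)], seed=0)


class TestReferenceCurve:
    def test_identity_and_affine(self, ideal_chain_30):
        from idpensemble import scattering as sca

        curve = sca.debye_intensity(ideal_chain_30.subset_frames(np.arange(20)), np.linspace(0.1, 2, 30))
        same = sd.synthesize_reference_curve(curve, f=1.0, c=0.0, sigma=0.0)
        assert np.array_equal(same.I, curve.I)
        affine = sd.synthesize_reference_curve(curve, f=2.0, c=1.0, sigma=0.0)
        assert np.allclose(affine.I, 2.0 * curve.I + 1.0, rtol=0, atol=0)

    def test_noise_reproducible(self, ideal_chain_30):
        from idpensemble import scattering as sca

        curve = sca.debye_intensity(ideal_chain_30.subset_frames(np.arange(10)), np.linspace(0.1, 2, 30))
        a = sd.synthesize_reference_curve(curve, sigma=0.01, seed=12)
        b = sd.synthesize_reference_curve(curve, sigma=0.01, seed=12)
        assert np.array_equal(a.I, b.I)
        assert np.allclose(a.sigma, 0.01)
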