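import numpy as np
import pytest

from idpensemble import sequence_charge as sc
from idpensemble import synthetic_data as sd


@pytest.fixture(scope="session")
def ideal_chain_50():
    """Freely jointed chain, 50 beads x 20000 frames (closed-form stats)."""
    spec = sd.ChainModelSpec(n_beads=50, bond_length=0.38, n_frames=20000, seed=1)
    return sd.generate_ideal_chain(spec)


@pytest.fixture(scope="session")
def ideal_chain_30():
    """Smaller chain for contact/planting tests."""
    spec = sd.ChainModelSpec(n_beads=30, bond_length=0.38, n_frames=2000, seed=7)
    return sd.generate_ideal_chain(spec)


@pytest.fixture(scope="session")
def alpha_helix_12():
    seq = sc.parse_sequence("A" * 12)
    return sd.build_backbone(seq, sd.BackboneGeometry.uniform(12, -57.0, -47.0))


@pytest.fixture(scope="session")
def helix310_8():
    seq = sc.parse_sequence("A" * 8)
    return sd.build_backbone(seq, sd.BackboneGeometry.uniform(8, -49.0, -26.0))


@pytest.fixture(scope="session")
def ppii_6():
    seq = sc.parse_sequence("A" * 6)
    return sd.build_backbone(seq, sd.BackboneGeometry.uniform(6, -75.0, 145.0))


def debye_function_curve(rg, q_max=3.0, n=300, q_min=0.01):
    """Analytic Gaussian-chain (Debye) scattering curve, I(0) = 1."""
    from idpensemble.trajio import ScatteringCurve

    q = np.linspace(q_min, q_max, n)
    x2 = (q * rg) ** 2
    return ScatteringCurve(q, 2.0 * (np.exp(-x2) + x2 - 1.0) / x2**2)
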