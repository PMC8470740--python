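"""Synthetic ensembles, backbones and reference curves with known ground truth.

Every downstream analysis stage (size observables, scattering, contacts,
secondary structure, landscapes) is exercised against data generated here,
where the truth is known by construction:

* :func:`generate_ideal_chain` — freely jointed chains with closed-form
  size statistics (⟨Ree²⟩ = (N−1)b², ⟨Rg²⟩ = b²(N²−1)/(6N));
* :func:`build_backbone` — all-backbone peptide models placed from exact
  internal coordinates (NeRF), so dihedral-defined secondary structure
  (α, 3₁₀, PPII, extended) exists by construction;
* :func:`plant_contacts` — stratified resampling of an ensemble so chosen
  residue pairs are in contact in an exact target fraction of frames;
* :func:`synthesize_reference_curve` — noisy affine transforms of a
  calculated scattering curve, emulating an experimental reference.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import dihedral, place_atom
from .sequence_charge import AnnotatedSequence
from .trajio import (
    TOPOLOGY_COLUMNS,
    Ensemble,
    InfeasibleError,
    ParameterError,
    ScatteringCurve,
)

__all__ = [
    "ChainModelSpec",
    "BackboneGeometry",
    "PlantedContactSpec",
    "generate_ideal_chain",
    "build_backbone",
    "plant_contacts",
    "synthesize_reference_curve",
]

#: Average residue mass (amu); only mass ratios matter for the analyses here.
DEFAULT_BEAD_MASS = 110.0

ATOM_MASS = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}


@dataclass(frozen=True)
class ChainModelSpec:
    """Freely jointed chain model: n_beads beads joined by fixed-length bonds."""

    n_beads: int
    bond_length: float = 0.38  # nm, the CA-CA virtual bond of a trans peptide
    n_frames: int = 1000
    seed: int = 0
    bead_masses: np.ndarray | None = None

    def __post_init__(self):
        if self.n_beads < 2:
            raise ParameterError("n_beads must be >= 2")
        if self.bond_length <= 0:
            raise ParameterError("bond_length must be positive")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.bead_masses is not None:
            masses = np.asarray(self.bead_masses, dtype=float)
            if masses.shape != (self.n_beads,) or np.any(masses <= 0):
                raise ParameterError("bead_masses must be n_beads positive values")
            object.__setattr__(self, "bead_masses", masses)


@dataclass(frozen=True)
class BackboneGeometry:
    """Internal coordinates of a peptide backbone.

    Standard bond lengths/angles (nm, degrees) with per-residue (φ, ψ, ω)
    dihedrals; ω defaults to 180° (trans).  φ of the first residue and ψ of
    the last are not used for chain propagation.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | float = 180.0
    # canonical backbone geometry; fixed values keep DSSP tests deterministic
    bond_n_ca: float = 0.1458
    bond_ca_c: float = 0.1525
    bond_c_n: float = 0.1329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    bond_c_o: float = 0.1231
    angle_ca_c_o: float = 120.8
    bond_n_h: float = 0.098

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        if phi.shape != psi.shape or phi.ndim != 1:
            raise ParameterError("phi and psi must be 1D arrays of equal length")
        omega = np.broadcast_to(np.asarray(self.omega, dtype=float), phi.shape).copy()
        for name, arr in (("phi", phi), ("psi", psi), ("omega", omega)):
            if np.any(arr <= -180.0) or np.any(arr > 180.0):
                raise ParameterError(f"{name} dihedrals must lie in (-180, 180]")
        for attr in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o", "bond_n_h"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be positive")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "omega", omega)

    @classmethod
    def uniform(cls, n_residues: int, phi: float, psi: float, **kwargs):
        """Constant (φ, ψ) for every residue — ideal repeating structures."""
        return cls(np.full(n_residues, float(phi)), np.full(n_residues, float(psi)), **kwargs)

    def __len__(self) -> int:
        return len(self.phi)


@dataclass(frozen=True)
class PlantedContactSpec:
    """Target contact fraction for one residue pair (1-based indices)."""

    i: int
    j: int
    fraction: float
    cutoff: float = 0.4  # nm

    def __post_init__(self):
        if self.i == self.j:
            raise ParameterError("contact pair must involve two distinct residues")
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError("target fraction must lie in [0, 1]")
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")


# ---------------------------------------------------------------------------
# Ideal chains
# ---------------------------------------------------------------------------


def generate_ideal_chain(spec: ChainModelSpec) -> Ensemble:
    """Sample freely jointed chains: fixed bond length, i.i.d. uniform bond
    directions.  One bead per residue (atom name CA); deterministic given
    the seed."""
    rng = np.random.default_rng(spec.seed)
    n_bonds = spec.n_beads - 1
    # uniform directions on the sphere
    z = rng.uniform(-1.0, 1.0, size=(spec.n_frames, n_bonds))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(spec.n_frames, n_bonds))
    s = np.sqrt(1.0 - z**2)
    steps = spec.bond_length * np.stack(
        [s * np.cos(phi), s * np.sin(phi), z], axis=-1
    )
    coords = np.zeros((spec.n_frames, spec.n_beads, 3))
    coords[:, 1:] = np.cumsum(steps, axis=1)
    masses = (
        spec.bead_masses
        if spec.bead_masses is not None
        else np.full(spec.n_beads, DEFAULT_BEAD_MASS)
    )
    topology = pd.DataFrame(
        {
            "name": ["CA"] * spec.n_beads,
            "element": ["C"] * spec.n_beads,
            "mass": masses,
            "resid": np.arange(1, spec.n_beads + 1),
            "resname": ["GLY"] * spec.n_beads,
        },
        columns=TOPOLOGY_COLUMNS,
    )
    return Ensemble(coords, topology)


# ---------------------------------------------------------------------------
# Dihedral-exact backbones
# ---------------------------------------------------------------------------


def build_backbone(sequence: AnnotatedSequence, geometry: BackboneGeometry) -> Ensemble:
    """Build a single-frame all-backbone ensemble by sequential
    internal-coordinate (NeRF) placement.

    Atoms N, H, CA, C, O per residue (no amide H on proline).  The amide H
    is placed 0.098 nm from N along the C(i−1)→O(i−1) direction reversed —
    i.e. trans to the carbonyl O in the peptide plane (DSSP convention);
    the first residue's H is placed by torsion H–N–CA–C = 180°.
    Recomputing (φ, ψ, ω) from the produced coordinates returns the inputs
    to well within 0.5°.
    """
    n = len(sequence)
    if len(geometry) != n:
        raise ParameterError(
            f"geometry has {len(geometry)} (phi, psi) pairs for {n} residues"
        )
    g = geometry
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    # first residue in a canonical frame
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [g.bond_n_ca, 0.0, 0.0]
    theta = np.radians(g.angle_n_ca_c)
    C[0] = CA[0] + g.bond_ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], g.bond_c_n, g.angle_ca_c_n, g.psi[i])
        CA[i + 1] = place_atom(
            CA[i], C[i], N[i + 1], g.bond_n_ca, g.angle_c_n_ca, g.omega[i]
        )
        C[i + 1] = place_atom(
            C[i], N[i + 1], CA[i + 1], g.bond_ca_c, g.angle_n_ca_c, g.phi[i + 1]
        )
    for i in range(n):
        # carbonyl O trans to the next amide N across the C: torsion
        # N–CA–C–O = psi − 180 (last residue uses its supplied psi)
        o_torsion = g.psi[i] - 180.0
        O[i] = place_atom(N[i], CA[i], C[i], g.bond_c_o, g.angle_ca_c_o, o_torsion)

    rows = []
    coords = []
    resnames = sequence.resnames
    for i in range(n):
        resid = i + 1
        rows.append(("N", "N", ATOM_MASS["N"], resid, resnames[i]))
        coords.append(N[i])
        if sequence.residues[i] != "P":
            if i == 0:
                H = place_atom(C[0], CA[0], N[0], g.bond_n_h, 118.2, 180.0)
            else:
                direction = C[i - 1] - O[i - 1]
                H = N[i] + g.bond_n_h * direction / np.linalg.norm(direction)
            rows.append(("H", "H", ATOM_MASS["H"], resid, resnames[i]))
            coords.append(H)
        rows.append(("CA", "C", ATOM_MASS["C"], resid, resnames[i]))
        coords.append(CA[i])
        rows.append(("C", "C", ATOM_MASS["C"], resid, resnames[i]))
        coords.append(C[i])
        rows.append(("O", "O", ATOM_MASS["O"], resid, resnames[i]))
        coords.append(O[i])
    topology = pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS)
    return Ensemble(np.asarray(coords)[None, :, :], topology)


def backbone_dihedrals(ens: Ensemble) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(φ, ψ, ω) per frame per residue from coordinates, NaN where undefined.

    Returns arrays of shape (n_frames, n_residues); φ undefined for the
    first residue, ψ and ω for the last.
    """
    by_res = ens.atom_indices_by_residue()
    names = ens.topology["name"].to_numpy()

    def atom(resid: int, name: str) -> int:
        idx = [a for a in by_res[resid] if names[a] == name]
        if not idx:
            from .trajio import TopologyError

            raise TopologyError(f"residue {resid} lacks atom {name}")
        return idx[0]

    resids = list(ens.residue_ids)
    n = len(resids)
    X = ens.coordinates
    phi = np.full((ens.n_frames, n), np.nan)
    psi = np.full((ens.n_frames, n), np.nan)
    omega = np.full((ens.n_frames, n), np.nan)
    Ni = [atom(r, "N") for r in resids]
    CAi = [atom(r, "CA") for r in resids]
    Ci = [atom(r, "C") for r in resids]
    for k in range(n):
        if k > 0:
            phi[:, k] = dihedral(
                X[:, Ci[k - 1]], X[:, Ni[k]], X[:, CAi[k]], X[:, Ci[k]]
            )
        if k < n - 1:
            psi[:, k] = dihedral(
                X[:, Ni[k]], X[:, CAi[k]], X[:, Ci[k]], X[:, Ni[k + 1]]
            )
            omega[:, k] = dihedral(
                X[:, CAi[k]], X[:, Ci[k]], X[:, Ni[k + 1]], X[:, CAi[k + 1]]
            )
    return phi, psi, omega


# ---------------------------------------------------------------------------
# Planted contacts
# ---------------------------------------------------------------------------


def _min_residue_distance(ens: Ensemble, i: int, j: int) -> np.ndarray:
    """Per-frame minimum inter-atom distance between residues i and j (nm)."""
    by_res = ens.atom_indices_by_residue()
    if i not in by_res or j not in by_res:
        raise ParameterError(f"residue pair ({i}, {j}) not in topology")
    a = ens.coordinates[:, by_res[i]]
    b = ens.coordinates[:, by_res[j]]
    d = np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1)
    return d.min(axis=(1, 2))


def plant_contacts(
    base: Ensemble, specs: list[PlantedContactSpec], seed: int = 0
) -> Ensemble:
    """Resample frames so each spec's residue pair is in contact in the
    target fraction of frames (within rounding of the frame count).

    Stratified resampling: frames are partitioned by their contact pattern
    across all specs, target counts per stratum follow the product of the
    independent marginals, and frames are drawn with replacement inside
    each stratum.  Per-frame coordinates are preserved exactly; only the
    frame multiset changes.
    """
    if not specs:
        return base
    rng = np.random.default_rng(seed)
    n = base.n_frames
    qualifies = np.stack(
        [_min_residue_distance(base, s.i, s.j) < s.cutoff for s in specs], axis=1
    )
    for k, s in enumerate(specs):
        if s.fraction > 0 and not qualifies[:, k].any():
            raise InfeasibleError(
                f"no frame has residues ({s.i}, {s.j}) in contact; "
                f"cannot reach fraction {s.fraction}"
            )
        if s.fraction < 1 and qualifies[:, k].all():
            raise InfeasibleError(
                f"every frame has residues ({s.i}, {s.j}) in contact; "
                f"cannot reach fraction {s.fraction}"
            )
    k = len(specs)
    patterns = [tuple(bits) for bits in np.ndindex(*([2] * k))]
    probs = np.array(
        [
            np.prod([s.fraction if b else 1.0 - s.fraction for s, b in zip(specs, bits)])
            for bits in patterns
        ]
    )
    members = {
        bits: np.flatnonzero((qualifies == np.array(bits, dtype=bool)).all(axis=1))
        for bits in patterns
    }
    # largest-remainder rounding of target stratum counts
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    # strata with demand but no members: push the demand onto a feasible
    # stratum with the same bit for every nonzero-probability spec
    for idx, bits in enumerate(patterns):
        if counts[idx] > 0 and len(members[bits]) == 0:
            donors = [
                jdx
                for jdx, other in enumerate(patterns)
                if len(members[other]) > 0
                and all(
                    o == b
                    for o, b, s in zip(other, bits, specs)
                    if 0.0 < s.fraction < 1.0
                )
            ]
            if not donors:
                raise InfeasibleError(
                    f"no frames available for contact pattern {bits}"
                )
            counts[donors[0]] += counts[idx]
            counts[idx] = 0
    chosen = []
    for idx, bits in enumerate(patterns):
        if counts[idx] > 0:
            chosen.append(rng.choice(members[bits], size=counts[idx], replace=True))
    frame_indices = np.sort(np.concatenate(chosen))
    return base.subset_frames(frame_indices)


# ---------------------------------------------------------------------------
# Reference curves
# ---------------------------------------------------------------------------


def synthesize_reference_curve(
    calc: ScatteringCurve,
    f: float = 1.0,
    c: float = 0.0,
    sigma: float | np.ndarray = 0.0,
    seed: int = 0,
) -> ScatteringCurve:
    """I_ref(q) = f·I_calc(q) + c + Gaussian(0, σ); σ becomes the error column.

    ``sigma`` may be a scalar or a per-point vector; with σ = 0 the error
    column is omitted (no noise, exact affine map).
    """
    sigma_arr = np.broadcast_to(np.asarray(sigma, dtype=float), calc.q.shape).copy()
    if np.any(sigma_arr < 0):
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = np.where(sigma_arr > 0, rng.normal(0.0, 1.0, size=calc.q.shape), 0.0)
    I_ref = f * calc.I + c + sigma_arr * noise
    out_sigma = sigma_arr if np.all(sigma_arr > 0) else None
    return ScatteringCurve(calc.q.copy(), I_ref, out_sigma)
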