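"""Residue contacts, hydrogen bonds and salt-bridge occupancy.

Two residues are in contact in a frame when the shortest distance between
any two of their atoms (hydrogens included) is below 0.4 nm.  Salt bridges
between phosphate/carboxylate acceptors and ammonium/guanidinium donors
are scored through a distance–angle hydrogen-bond criterion: a bond exists
iff the donor–acceptor heavy-atom distance satisfies

    r_DA < d_max − k·θ²

with θ the H–donor–acceptor angle in degrees, d_max = 0.33 nm and
k = 4.4·10⁻⁵ nm/deg² by default (both configurable, since the constants
must remain auditable).  Occupancy is the fraction of frames in which at
least one qualifying bond joins the pair's donor and acceptor atom sets,
with a block-averaging error from the per-frame indicator series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observables import ScalarSeries, block_error
from .trajio import Ensemble, ParameterError, TopologyError

__all__ = [
    "ContactMap",
    "SaltBridgePair",
    "HBondCriterion",
    "contact_map",
    "detect_hbonds",
    "salt_bridge_occupancy",
]

#: Default contact cutoff (nm): shortest inter-atom distance below this.
CONTACT_CUTOFF = 0.4


@dataclass(frozen=True)
class HBondCriterion:
    """Distance–angle hydrogen-bond criterion r_DA < d_max − k·θ²."""

    d_max: float = 0.33  # nm
    k: float = 4.4e-5  # nm / deg^2

    def accepts(self, r_da: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
        return r_da < self.d_max - self.k * np.asarray(theta_deg) ** 2


@dataclass
class ContactMap:
    """Residue × residue contact probability (symmetric, diagonal 1)."""

    probability: np.ndarray
    residue_ids: np.ndarray
    cutoff: float

    def __post_init__(self):
        p = np.asarray(self.probability, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ParameterError("contact map must be square")
        if np.any(p < 0) or np.any(p > 1):
            raise ParameterError("contact probabilities must lie in [0, 1]")
        self.probability = p


@dataclass
class SaltBridgePair:
    """Occupancy of one donor/acceptor residue pair."""

    donor: int | str
    acceptor: int | str
    occupancy: float
    error: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ParameterError("occupancy must lie in [0, 1]")
        if self.donor == self.acceptor:
            raise ParameterError("donor and acceptor residues must differ")


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


def contact_map(ens: Ensemble, cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Fraction of frames with min inter-atom distance < cutoff, per pair.

    All atoms, hydrogens included, enter the minimum; the comparison is
    strict (<).  The diagonal is defined as 1.
    """
    resids = ens.residue_ids
    n_res = len(resids)
    if n_res < 2:
        raise ParameterError("contact map requires at least 2 residues")
    by_res = ens.atom_indices_by_residue()
    prob = np.eye(n_res)
    X = ens.coordinates
    for a in range(n_res):
        ia = by_res[int(resids[a])]
        for b in range(a + 1, n_res):
            ib = by_res[int(resids[b])]
            d = np.linalg.norm(
                X[:, ia, None, :] - X[:, None, ib, :], axis=-1
            ).min(axis=(1, 2))
            prob[a, b] = prob[b, a] = np.mean(d < cutoff)
    return ContactMap(prob, resids, cutoff)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def detect_hbonds(
    frame: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    criterion: HBondCriterion | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds in one frame of coordinates (atoms × 3, nm).

    ``donors`` is a list of (donor heavy atom, attached hydrogen) index
    pairs; ``acceptors`` a list of acceptor heavy-atom indices.  Returns
    (donor, hydrogen, acceptor) triples satisfying the criterion.
    """
    if not donors:
        raise TopologyError("no donor (heavy atom, hydrogen) pairs supplied")
    crit = criterion or HBondCriterion()
    frame = np.asarray(frame, dtype=float)
    bonds = []
    d_idx = np.array([d for d, _ in donors])
    h_idx = np.array([h for _, h in donors])
    a_idx = np.asarray(acceptors, dtype=int)
    D = frame[d_idx]  # (nd, 3)
    H = frame[h_idx]
    A = frame[a_idx]  # (na, 3)
    da = A[None, :, :] - D[:, None, :]
    r_da = np.linalg.norm(da, axis=-1)
    dh = H - D
    dh_norm = np.linalg.norm(dh, axis=-1)
    cos_theta = np.einsum("ni,nai->na", dh, da) / np.maximum(
        dh_norm[:, None] * r_da, np.finfo(float).tiny
    )
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    ok = crit.accepts(r_da, theta) & (r_da > 0)
    for n, a in zip(*np.nonzero(ok)):
        bonds.append((int(d_idx[n]), int(h_idx[n]), int(a_idx[a])))
    return bonds


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

# Donor heavy atoms and their hydrogen-name prefixes, by residue chemistry.
_DONOR_CHEMISTRY = {
    "ARG": {"NE": ("HE",), "NH1": ("HH1",), "NH2": ("HH2",)},
    "LYS": {"NZ": ("HZ",)},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},  # off by default, flag available
}
_NTERM_DONOR = {"N": ("H", "H1", "H2", "H3")}

# Acceptor atom names by residue chemistry.
_ACCEPTOR_CHEMISTRY = {
    "SEP": ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3"),
    "TPO": ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
_CTERM_ACCEPTOR = ("O", "OXT")


def _donor_atoms(ens: Ensemble, residue, include_his: bool):
    """Resolve (heavy, hydrogen) donor index pairs for a residue id or 'NT'."""
    names = ens.topology["name"].to_numpy()
    resid = ens.topology["resid"].to_numpy()
    resname = ens.topology["resname"].to_numpy()
    if residue == "NT":
        rid = int(ens.residue_ids[0])
        chemistry = _NTERM_DONOR
    else:
        rid = int(residue)
        in_res = np.flatnonzero(resid == rid)
        if in_res.size == 0:
            raise TopologyError(f"residue {rid} not in topology")
        rname = resname[in_res[0]]
        chemistry = _DONOR_CHEMISTRY.get(rname)
        if chemistry is None or (rname == "HIS" and not include_his):
            raise TopologyError(
                f"residue {rid} ({rname}) has no recognised donor chemistry"
            )
    in_res = np.flatnonzero(resid == rid)
    pairs = []
    for heavy, h_prefixes in chemistry.items():
        heavy_idx = [a for a in in_res if names[a] == heavy]
        if not heavy_idx:
            continue
        h_idx = [
            a
            for a in in_res
            if any(names[a] == p or names[a].startswith(p) for p in h_prefixes)
            and names[a].startswith("H")
        ]
        if not h_idx:
            raise TopologyError(
                f"donor {heavy} of residue {rid} lacks hydrogen atoms"
            )
        pairs.extend((h_atom, heavy_atom) for heavy_atom in heavy_idx for h_atom in h_idx)
    if not pairs:
        raise TopologyError(f"residue {residue} has no donor atoms present")
    return [(heavy, h) for h, heavy in pairs]


def _acceptor_atoms(ens: Ensemble, residue):
    """Resolve acceptor atom indices for a residue id or 'CT'."""
    names = ens.topology["name"].to_numpy()
    resid = ens.topology["resid"].to_numpy()
    resname = ens.topology["resname"].to_numpy()
    if residue == "CT":
        rid = int(ens.residue_ids[-1])
        wanted = _CTERM_ACCEPTOR
    else:
        rid = int(residue)
        in_res = np.flatnonzero(resid == rid)
        if in_res.size == 0:
            raise TopologyError(f"residue {rid} not in topology")
        rname = resname[in_res[0]]
        wanted = _ACCEPTOR_CHEMISTRY.get(rname)
        if wanted is None:
            raise TopologyError(
                f"residue {rid} ({rname}) has no recognised acceptor chemistry"
            )
    in_res = np.flatnonzero(resid == rid)
    idx = [a for a in in_res if names[a] in wanted]
    if not idx:
        raise TopologyError(f"residue {residue} has no acceptor atoms present")
    return idx


def salt_bridge_occupancy(
    ens: Ensemble,
    pairs: list[tuple],
    criterion: HBondCriterion | None = None,
    include_his: bool = False,
) -> list[SaltBridgePair]:
    """Occupancy ± block error for each (donor, acceptor) residue pair.

    Pair elements are 1-based residue ids, or the tokens ``"NT"`` (donor:
    N-terminal ammonium) / ``"CT"`` (acceptor: C-terminal carboxylate).
    Occupancy is the fraction of frames with at least one qualifying
    hydrogen bond between the pair's atom sets; the error comes from a
    blocking analysis of the per-frame 0/1 indicator (NaN when the
    ensemble is too short to block).
    """
    crit = criterion or HBondCriterion()
    out = []
    for donor_res, acceptor_res in pairs:
        donors = _donor_atoms(ens, donor_res, include_his)
        acceptors = _acceptor_atoms(ens, acceptor_res)
        indicator = np.zeros(ens.n_frames)
        for f in range(ens.n_frames):
            if detect_hbonds(ens.coordinates[f], donors, acceptors, crit):
                indicator[f] = 1.0
        occupancy = float(indicator.mean())
        try:
            err = block_error(ScalarSeries(indicator)).plateau
        except ParameterError:
            err = float("nan")
        out.append(SaltBridgePair(donor_res, acceptor_res, occupancy, err))
    return out
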