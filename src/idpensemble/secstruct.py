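"""Secondary-structure assignment with a polyproline-II extension.

Implements the Kabsch–Sander rules on backbone geometry: the electrostatic
hydrogen-bond energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

(distances in Å, bond iff E < −0.5 kcal/mol) drives n-turn detection
(n = 3, 4, 5), helices (G/H/I from two consecutive turns), bridges and
ladders (B/E), turns (T) and bends (S, CA-direction change > 70°), with
the priority order H > E > B > G > I > T > S > C.  Residues left irregular
whose (φ, ψ) fall inside the polyproline-II window for at least two
consecutive residues are then relabelled P — the PPII content that plain
DSSP hides inside "coil" and that dominates disordered peptides.

Missing amide hydrogens are reconstructed 0.098 nm from N along the
C(i−1)−O(i−1) direction (DSSP convention); prolines have no donor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import ScalarSeries, block_error
from .synthetic_data import backbone_dihedrals
from .trajio import Ensemble, ParameterError, TopologyError

__all__ = [
    "SS_CODES",
    "SSSummary",
    "kabsch_sander_energy",
    "backbone_hbond_energy",
    "assign_dssp",
    "extend_ppii",
    "ss_summary",
]

SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "P", "C")

#: Reporting groups: helix lumps alpha/3-10/pi, strand lumps sheet/bridge.
SS_GROUPS = {
    "helix": ("H", "G", "I"),
    "strand": ("E", "B"),
    "turn": ("T",),
    "bend": ("S",),
    "ppii": ("P",),
    "irregular": ("C",),
}

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
BEND_ANGLE = 70.0  # degrees
#: PPII dihedral window (phi, psi, degrees) and minimum run length.
PPII_PHI = (-104.0, -46.0)
PPII_PSI = (116.0, 174.0)
PPII_MIN_RUN = 2
#: Minimum |donor − acceptor| residue separation for an H-bond to count.
#: Every pattern used below (turns n>=3, bridges |i−j|>=3) needs >= 3, and
#: reconstructed hydrogens make the i,i+1 peptide-bond geometry spuriously
#: pass the energy cutoff.
MIN_SEPARATION = 3


@dataclass
class SSSummary:
    """Mean fraction per reporting group with block-averaging errors."""

    fractions: dict[str, float]
    errors: dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"group fractions sum to {total}, not 1")


def kabsch_sander_energy(r_on, r_ch, r_oh, r_cn):
    """Electrostatic H-bond energy (kcal/mol) from the four distances in Å."""
    return 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _backbone_arrays(ens: Ensemble):
    """Per-residue N, H, CA, C, O coordinates (F, R, 3); H is NaN where the
    residue has no donor (proline, or a first residue without an explicit H).
    Missing hydrogens elsewhere are reconstructed DSSP-style."""
    names = ens.topology["name"].to_numpy()
    resid = ens.topology["resid"].to_numpy()
    resname = ens.topology["resname"].to_numpy()
    resids = ens.residue_ids
    n = len(resids)
    X = ens.coordinates
    out = {}
    for atom in ("N", "CA", "C", "O"):
        idx = []
        for r in resids:
            hits = np.flatnonzero((resid == r) & (names == atom))
            if hits.size == 0:
                raise TopologyError(f"residue {int(r)} lacks backbone atom {atom}")
            idx.append(hits[0])
        out[atom] = X[:, idx]
    H = np.full_like(out["N"], np.nan)
    for k, r in enumerate(resids):
        in_res = np.flatnonzero(resid == r)
        if resname[in_res[0]] == "PRO":
            continue
        hits = [a for a in in_res if names[a] == "H"]
        if hits:
            H[:, k] = X[:, hits[0]]
        elif k > 0:
            direction = out["C"][:, k - 1] - out["O"][:, k - 1]
            direction /= np.linalg.norm(direction, axis=-1, keepdims=True)
            H[:, k] = out["N"][:, k] + 0.098 * direction
    return out["N"], H, out["CA"], out["C"], out["O"]


def _hbond_matrix(ens: Ensemble) -> np.ndarray:
    """HB[f, a, d]: CO of residue a accepts a bond from NH of residue d."""
    N, H, CA, C, O = _backbone_arrays(ens)
    n = N.shape[1]

    def dist(A, B):  # (F, Ra, 3) x (F, Rd, 3) -> (F, Ra, Rd), in Angstrom
        return 10.0 * np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=-1)

    with np.errstate(invalid="ignore"):
        energy = kabsch_sander_energy(
            dist(O, N), dist(C, H), dist(O, H), dist(C, N)
        )
        hb = energy < HBOND_ENERGY_CUTOFF
    hb &= ~np.isnan(energy)
    a_idx, d_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    hb &= (np.abs(a_idx - d_idx) >= MIN_SEPARATION)[None]
    return hb


def backbone_hbond_energy(
    ens: Ensemble, donor: int, acceptor: int, frame: int = 0
) -> float:
    """Kabsch–Sander energy (kcal/mol) between one donor residue's NH and
    one acceptor residue's CO in one frame (1-based residue indices)."""
    resids = list(ens.residue_ids)
    d, a = resids.index(donor), resids.index(acceptor)
    N, H, CA, C, O = _backbone_arrays(ens)
    if np.any(np.isnan(H[frame, d])):
        raise TopologyError(f"residue {donor} has no amide hydrogen (no donor)")
    r = lambda P, Q: 10.0 * float(np.linalg.norm(P - Q))
    return float(
        kabsch_sander_energy(
            r(O[frame, a], N[frame, d]),
            r(C[frame, a], H[frame, d]),
            r(O[frame, a], H[frame, d]),
            r(C[frame, a], N[frame, d]),
        )
    )


def _bend_mask(CA: np.ndarray) -> np.ndarray:
    """S (bend): direction change of the CA trace over i−2 → i → i+2 > 70°."""
    F, n, _ = CA.shape
    mask = np.zeros((F, n), dtype=bool)
    if n < 5:
        return mask
    u = CA[:, 2:-2] - CA[:, :-4]  # CA(i) − CA(i−2)
    v = CA[:, 4:] - CA[:, 2:-2]  # CA(i+2) − CA(i)
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    mask[:, 2:-2] = angle > BEND_ANGLE
    return mask


def assign_dssp(ens: Ensemble) -> np.ndarray:
    """Per-frame, per-residue codes from {H,G,I,E,B,T,S,C} (no P yet).

    Chains shorter than 3 residues are all irregular.
    """
    resids = ens.residue_ids
    n = len(resids)
    F = ens.n_frames
    ss = np.full((F, n), "C", dtype="<U1")
    if n < 3:
        return ss
    hb = _hbond_matrix(ens)
    N, H, CA, C, O = _backbone_arrays(ens)

    turns = {}
    for t in (3, 4, 5):
        tn = np.zeros((F, n), dtype=bool)
        if n > t:
            i = np.arange(n - t)
            tn[:, : n - t] = hb[:, i, i + t]
        turns[t] = tn

    # bridges: Hb(i,j) means CO(i) <- NH(j); pad so i±1, j±1 lookups are safe
    pad = np.zeros((F, n + 2, n + 2), dtype=bool)
    pad[:, 1 : n + 1, 1 : n + 1] = hb
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    P = ii + 1  # padded index of i
    Q = jj + 1
    fr = np.arange(F)[:, None, None]
    parallel = (pad[fr, P - 1, Q] & pad[fr, Q, P + 1]) | (
        pad[fr, Q - 1, P] & pad[fr, P, Q + 1]
    )
    antiparallel = (pad[fr, P, Q] & pad[fr, Q, P]) | (
        pad[fr, P - 1, Q + 1] & pad[fr, Q - 1, P + 1]
    )
    bridge = (parallel | antiparallel) & (np.abs(ii - jj) >= 3)[None]
    bpad = np.zeros((F, n + 2, n + 2), dtype=bool)
    bpad[:, 1 : n + 1, 1 : n + 1] = bridge
    laddered = bridge & (
        bpad[fr, P - 1, Q - 1]
        | bpad[fr, P - 1, Q + 1]
        | bpad[fr, P + 1, Q - 1]
        | bpad[fr, P + 1, Q + 1]
    )
    in_ladder = laddered.any(axis=2) | laddered.any(axis=1)
    in_bridge = bridge.any(axis=2) | bridge.any(axis=1)

    # assign lowest priority first so later labels override
    ss[_bend_mask(CA)] = "S"
    for t in (3, 4, 5):
        for offset in range(1, t):
            hit = np.zeros((F, n), dtype=bool)
            hit[:, offset : n - t + offset] = turns[t][:, : n - t]
            ss[hit] = "T"
    for t, code, length in ((5, "I", 5), (3, "G", 3)):
        run = turns[t][:, 1:] & turns[t][:, :-1]  # consecutive turn starts
        for offset in range(length):
            hit = np.zeros((F, n), dtype=bool)
            hit[:, 1 + offset : n - t + offset] = run[:, : n - t - 1]
            ss[hit] = code
    ss[in_bridge & ~in_ladder] = "B"
    ss[in_ladder] = "E"
    run4 = turns[4][:, 1:] & turns[4][:, :-1]
    for offset in range(4):
        hit = np.zeros((F, n), dtype=bool)
        hit[:, 1 + offset : n - 4 + offset] = run4[:, : n - 5]
        ss[hit] = "H"
    return ss


def extend_ppii(
    ss: np.ndarray,
    phi: np.ndarray,
    psi: np.ndarray,
    phi_window: tuple[float, float] = PPII_PHI,
    psi_window: tuple[float, float] = PPII_PSI,
    min_run: int = PPII_MIN_RUN,
) -> np.ndarray:
    """Relabel irregular (C) residues inside the PPII dihedral window as P
    when at least ``min_run`` consecutive residues qualify.  No other code
    is ever touched, so the extension can only move content out of
    "irregular"."""
    ss = np.asarray(ss).copy()
    with np.errstate(invalid="ignore"):
        in_window = (
            (phi >= phi_window[0])
            & (phi <= phi_window[1])
            & (psi >= psi_window[0])
            & (psi <= psi_window[1])
        )
    in_window &= ~np.isnan(phi) & ~np.isnan(psi)
    eligible = in_window & (ss == "C")
    F, n = ss.shape
    for f in range(F):
        run_start = None
        row = eligible[f]
        for k in range(n + 1):
            if k < n and row[k]:
                if run_start is None:
                    run_start = k
            else:
                if run_start is not None and k - run_start >= min_run:
                    ss[f, run_start:k] = "P"
                run_start = None
    return ss


def compute_phi_psi(ens: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """(φ, ψ) per frame per residue (degrees, NaN at chain ends)."""
    phi, psi, _ = backbone_dihedrals(ens)
    return phi, psi


def ss_summary(ss: np.ndarray) -> SSSummary:
    """Mean fraction per reporting group over frames × residues, with block
    errors from the per-frame group-fraction series."""
    ss = np.asarray(ss)
    if ss.size == 0:
        raise ParameterError("empty secondary-structure matrix")
    fractions, errors = {}, {}
    for group, codes in SS_GROUPS.items():
        per_frame = np.isin(ss, codes).mean(axis=1)
        fractions[group] = float(per_frame.mean())
        try:
            errors[group] = block_error(ScalarSeries(per_frame)).plateau
        except ParameterError:
            errors[group] = float("nan")
    return SSSummary(fractions, errors)
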