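"""Sequence parsing and charge-patterning metrics for phosphopeptides.

Computes the composition and patterning descriptors used to rationalise
how phosphorylation reshapes a disordered peptide's ensemble: the fraction
of charged residues (FCR), the net charge per residue (NCPR) and the
Das–Pappu charge-segregation parameter κ.  Phosphorylated Ser/Thr carry
−2e at physiological pH in the per-residue charge table, but for the
patterning metrics they are equalised to ordinary negative residues
(sign −1), so that κ/FCR/NCPR compare phosphosites and Asp/Glu on the
same footing.

κ is computed with blob sizes g = 5 and 6: every window of g residues
contributes σ_j = (f⁺_j − f⁻_j)²/(f⁺_j + f⁻_j) (zero for windows without
charges), δ_g is the mean squared deviation of σ_j from the whole-sequence
σ, and κ = ((δ₅+δ₆)/2) / δ_max normalised by the most charge-segregated
arrangement of the same composition.  δ_max is found by exhaustive
enumeration of distinct arrangements whenever that is tractable and by a
set of segregated candidate arrangements otherwise; the enumeration is
necessary because for short sequences the blocky arrangement is not always
the δ-maximiser (window edge effects dominate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml
from sympy.utilities.iterables import multiset_permutations

from .trajio import ParameterError, ParseError

__all__ = [
    "AnnotatedSequence",
    "ChargePatternResult",
    "AnnotationError",
    "UndefinedKappaError",
    "parse_sequence",
    "charge_fractions",
    "kappa",
    "analyze",
    "builtin_peptides",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Integer per-residue charge at physiological pH (phospho-S/T: −2).
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1, "H": 0}

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
PHOSPHO_RESNAME = {"S": "SEP", "T": "TPO"}

#: Arrangement-count ceiling below which δ_max is found by full enumeration.
EXHAUSTIVE_LIMIT = 200_000

KAPPA_BLOBS = (5, 6)


class AnnotationError(ParameterError):
    """A phosphosite annotation points at a residue that is not Ser/Thr."""


class UndefinedKappaError(ParameterError):
    """κ is undefined (no charges, a single charge sign, or too short)."""


@dataclass(frozen=True)
class AnnotatedSequence:
    """A one-letter peptide sequence with phosphosite annotations.

    ``phosphosites`` are 1-based positions and must point at Ser or Thr.
    ``charges`` holds the integer per-residue charge at physiological pH
    (D/E −1, K/R +1, H 0, phospho-S/T −2); terminal charges (+1 N, −1 C)
    are carried separately and can be toggled off.
    """

    residues: str
    phosphosites: frozenset[int] = frozenset()
    charged_termini: bool = True

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ParseError("sequence must contain at least one residue")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ParseError(f"unknown residue letter(s): {sorted(bad)}")
        for pos in self.phosphosites:
            if not 1 <= pos <= len(self.residues):
                raise AnnotationError(f"phosphosite {pos} outside sequence")
            if self.residues[pos - 1] not in "ST":
                raise AnnotationError(
                    f"phosphosite {pos} is {self.residues[pos - 1]}, not S/T"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def charges(self) -> np.ndarray:
        """Integer charge per residue (phospho-S/T contribute −2)."""
        out = np.array(
            [RESIDUE_CHARGE.get(a, 0) for a in self.residues], dtype=int
        )
        for pos in self.phosphosites:
            out[pos - 1] = -2
        return out

    @property
    def charge_signs(self) -> np.ndarray:
        """Charge signs with phosphosites equalised to −1 (for FCR/NCPR/κ)."""
        return np.sign(self.charges)

    @property
    def n_terminal_charge(self) -> int:
        return 1 if self.charged_termini else 0

    @property
    def c_terminal_charge(self) -> int:
        return -1 if self.charged_termini else 0

    @property
    def resnames(self) -> list[str]:
        """3-letter residue names, phosphosites as SEP/TPO."""
        names = [THREE_LETTER[a] for a in self.residues]
        for pos in self.phosphosites:
            names[pos - 1] = PHOSPHO_RESNAME[self.residues[pos - 1]]
        return names


@dataclass(frozen=True)
class ChargePatternResult:
    """FCR, NCPR and κ of one sequence (blob sizes used for κ recorded)."""

    fcr: float
    ncpr: float
    kappa: float | None = None
    blobs: tuple[int, ...] = KAPPA_BLOBS

    def __post_init__(self):
        if not 0.0 <= self.fcr <= 1.0:
            raise ParameterError("FCR must lie in [0, 1]")
        if abs(self.ncpr) > self.fcr + 1e-12:
            raise ParameterError("|NCPR| cannot exceed FCR")
        if self.kappa is not None and not 0.0 <= self.kappa <= 1.0:
            raise ParameterError("kappa must lie in [0, 1]")


def parse_sequence(text: str, phosphosites=()) -> AnnotatedSequence:
    """Parse a one-letter sequence (whitespace ignored, case-insensitive)."""
    seq = "".join(text.split()).upper()
    return AnnotatedSequence(seq, frozenset(int(p) for p in phosphosites))


def charge_fractions(seq: AnnotatedSequence) -> ChargePatternResult:
    """FCR and NCPR under the sign convention (phospho counts as one −)."""
    signs = seq.charge_signs
    fcr = float(np.mean(signs != 0))
    ncpr = float(np.mean(signs))
    return ChargePatternResult(fcr=fcr, ncpr=ncpr, kappa=None)


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------


def _sigma(f_plus: np.ndarray, f_minus: np.ndarray) -> np.ndarray:
    total = f_plus + f_minus
    safe = np.where(total > 0, total, 1.0)
    return np.where(total > 0, (f_plus - f_minus) ** 2 / safe, 0.0)


def _delta(signs: np.ndarray, blobs=KAPPA_BLOBS) -> float:
    """Mean over blob sizes of the window-σ mean squared deviation."""
    signs = np.asarray(signs)
    sigma_seq = _sigma(
        np.array([(signs > 0).mean()]), np.array([(signs < 0).mean()])
    )[0]
    parts = []
    for g in blobs:
        windows = np.lib.stride_tricks.sliding_window_view(signs, g)
        sig = _sigma((windows > 0).mean(axis=1), (windows < 0).mean(axis=1))
        parts.append(float(np.mean((sig - sigma_seq) ** 2)))
    return float(np.mean(parts))


def _n_arrangements(n_pos: int, n_neg: int, n_zero: int) -> int:
    n = n_pos + n_neg + n_zero
    return math.factorial(n) // (
        math.factorial(n_pos) * math.factorial(n_neg) * math.factorial(n_zero)
    )


def _candidate_arrangements(n_pos: int, n_neg: int, n_zero: int):
    """Segregated candidate arrangements: charge blocks with the neutral
    residues placed before, after, split between the two ends, or between
    the blocks."""
    pos, neg, zero = [1] * n_pos, [-1] * n_neg, [0] * n_zero
    half = n_zero // 2
    for blocks in ((pos, neg), (neg, pos)):
        a, b = blocks
        yield zero + a + b
        yield a + b + zero
        yield zero[:half] + a + b + zero[half:]
        yield a + zero + b


@lru_cache(maxsize=4096)
def _delta_max(n_pos: int, n_neg: int, n_zero: int, blobs=KAPPA_BLOBS) -> float:
    """δ of the most segregated arrangement of the given composition.

    Exhaustive over distinct arrangements when their count is small enough
    (the blocky arrangement is not always maximal for short sequences);
    otherwise the maximum over segregated candidates.
    """
    if _n_arrangements(n_pos, n_neg, n_zero) <= EXHAUSTIVE_LIMIT:
        base = [1] * n_pos + [-1] * n_neg + [0] * n_zero
        return max(
            _delta(np.array(p), blobs) for p in multiset_permutations(base)
        )
    return max(
        _delta(np.array(c), blobs)
        for c in _candidate_arrangements(n_pos, n_neg, n_zero)
    )


def kappa(seq: AnnotatedSequence, blobs=KAPPA_BLOBS) -> float:
    """Charge-segregation parameter κ ∈ [0, 1] (1 = maximally segregated)."""
    signs = seq.charge_signs
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedKappaError(
            "kappa requires at least one positive and one negative residue"
        )
    if len(signs) < max(blobs):
        raise UndefinedKappaError(
            f"kappa requires length >= {max(blobs)}"
        )
    delta = _delta(signs, blobs)
    dmax = _delta_max(n_pos, n_neg, len(signs) - n_pos - n_neg, tuple(blobs))
    return float(np.clip(delta / dmax, 0.0, 1.0))


def analyze(seq: AnnotatedSequence) -> ChargePatternResult:
    """FCR, NCPR and κ in one result (κ ``None`` where undefined)."""
    fractions = charge_fractions(seq)
    try:
        k = kappa(seq)
    except UndefinedKappaError:
        k = None
    return ChargePatternResult(fcr=fractions.fcr, ncpr=fractions.ncpr, kappa=k)


# ---------------------------------------------------------------------------
# Built-in peptide fixtures
# ---------------------------------------------------------------------------


def builtin_peptides() -> dict[str, AnnotatedSequence]:
    """The four phosphopeptide fixtures shipped with the package.

    Sequences and phosphosite positions are read from
    ``data/peptides.yaml`` (explicit fixture configuration, editable).
    """
    text = resources.files("idpensemble").joinpath("data/peptides.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: parse_sequence(entry["sequence"], entry.get("phosphosites", ()))
        for name, entry in raw["peptides"].items()
    }
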