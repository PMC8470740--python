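"""Trajectory, topology and scattering-curve I/O.

This module owns the two central in-memory containers of the package —
:class:`Ensemble` (a multi-frame set of Cartesian coordinates plus a flat
atom topology) and :class:`ScatteringCurve` (a 1D intensity profile on a
momentum-transfer grid) — together with readers and writers for the plain
text formats the package exchanges with the outside world: multi-model PDB
(always), XTC/DCD (when the mdtraj backend supports them, which it does
here), 3-column scattering-curve text, FASTA, TSV result tables and
YAML/TOML configuration.

Unit conventions
----------------
Coordinates are stored in nanometres regardless of the source format (PDB
ångström values are divided by 10 on read).  Momentum transfer q is stored
in nm⁻¹; curve files may declare ``q_unit=A^-1`` in their header, in which
case q is multiplied by 10 on read.  Residue indices are 1-based in every
user-facing structure; internal arrays are 0-based.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field, replace

import mdtraj as md
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("idpensemble")

#: Binary trajectory formats the I/O backend can read (extension -> loader).
SUPPORTED_BINARY_FORMATS = (".xtc", ".dcd")


def configure_logging(level: str = "INFO") -> None:
    """Configure the package-wide logger (used by the CLI)."""
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class IdpEnsembleError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(IdpEnsembleError, ValueError):
    """An argument violates an operation's precondition."""


class ParseError(IdpEnsembleError, ValueError):
    """A file could not be parsed (malformed record, unknown token)."""


class StructureError(IdpEnsembleError, ValueError):
    """A trajectory is structurally inconsistent (e.g. atom-count mismatch)."""


class FormatError(IdpEnsembleError, ValueError):
    """A data file violates its format contract (e.g. non-monotone q)."""


class TopologyError(IdpEnsembleError, ValueError):
    """A required atom or residue is missing from the topology."""


class FitError(IdpEnsembleError, RuntimeError):
    """A numerical fit failed to converge or has no valid regime."""


class AnalysisError(IdpEnsembleError, RuntimeError):
    """An analysis is undefined on the given input (e.g. zero variance)."""


class InfeasibleError(IdpEnsembleError, RuntimeError):
    """A requested synthetic construction cannot be realised."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

TOPOLOGY_COLUMNS = ["name", "element", "mass", "resid", "resname"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Ensemble:
    """Frames × atoms Cartesian coordinates (nm) with a flat atom topology.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in nanometres.
    topology : pandas.DataFrame
        One row per atom with columns ``name`` (PDB atom name), ``element``
        (symbol), ``mass`` (amu), ``resid`` (1-based residue index,
        non-decreasing) and ``resname`` (3-letter residue name).
    times : ndarray, optional
        Frame times in picoseconds.
    """

    coordinates: np.ndarray
    topology: pd.DataFrame
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ParameterError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ParameterError("coordinates must be finite")
        if len(self.topology) != self.coordinates.shape[1]:
            raise StructureError(
                f"topology has {len(self.topology)} atoms but coordinates have "
                f"{self.coordinates.shape[1]}"
            )
        resid = self.topology["resid"].to_numpy()
        if len(resid) and np.any(np.diff(resid) < 0):
            raise StructureError("residue indices must be non-decreasing")

    # -- basic shape -------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique 1-based residue indices."""
        return np.unique(self.topology["resid"].to_numpy())

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def masses(self) -> np.ndarray:
        return self.topology["mass"].to_numpy(dtype=float)

    # -- selection ---------------------------------------------------------

    def select(self, selection: str = "all") -> np.ndarray:
        """Return 0-based atom indices for a named selection.

        ``"all"``, ``"backbone"`` (N, CA, C, O) or a comma-separated list of
        atom names (e.g. ``"CA"`` or ``"N,CA,C"``).
        """
        names = self.topology["name"].to_numpy()
        if selection == "all":
            idx = np.arange(self.n_atoms)
        elif selection == "backbone":
            idx = np.flatnonzero(np.isin(names, BACKBONE_NAMES))
        else:
            wanted = [s.strip() for s in selection.split(",") if s.strip()]
            idx = np.flatnonzero(np.isin(names, wanted))
        if idx.size == 0:
            raise ParameterError(f"selection {selection!r} matches no atoms")
        return idx

    def atom_indices_by_residue(self) -> dict[int, np.ndarray]:
        """Map 1-based residue index -> 0-based atom indices."""
        resid = self.topology["resid"].to_numpy()
        return {int(r): np.flatnonzero(resid == r) for r in self.residue_ids}

    def subset_frames(self, frame_indices) -> "Ensemble":
        times = None if self.times is None else self.times[frame_indices]
        return Ensemble(self.coordinates[frame_indices], self.topology, times)

    # -- mdtraj bridge -----------------------------------------------------

    def to_mdtraj(self) -> md.Trajectory:
        top = md.Topology()
        chain = top.add_chain()
        residue = None
        last_resid = None
        for row in self.topology.itertuples(index=False):
            if row.resid != last_resid:
                residue = top.add_residue(row.resname, chain, resSeq=int(row.resid))
                last_resid = row.resid
            try:
                element = md.element.get_by_symbol(row.element)
            except KeyError:
                element = md.element.virtual
            top.add_atom(row.name, element, residue)
        return md.Trajectory(self.coordinates.copy(), top, time=self.times)

    @classmethod
    def from_mdtraj(cls, traj: md.Trajectory) -> "Ensemble":
        rows = []
        for atom in traj.topology.atoms:
            element = atom.element.symbol if atom.element is not None else "X"
            mass = atom.element.mass if atom.element is not None else 0.0
            rows.append(
                (atom.name, element, mass, atom.residue.resSeq, atom.residue.name)
            )
        topology = pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS)
        return cls(np.asarray(traj.xyz, dtype=float), topology, traj.time.copy())


@dataclass
class ScatteringCurve:
    """Intensity I(q) on an ascending q grid (nm⁻¹), optional per-point σ."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise FormatError("q and I must be 1D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise FormatError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise FormatError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise FormatError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------


def _validate_pdb_text(path: str) -> None:
    """Scan a PDB file for structural consistency before parsing.

    Raises :class:`ParseError` (with a line number) on malformed ATOM
    coordinate fields and :class:`StructureError` (naming the frame) when a
    MODEL has a different atom count from the first, including silently
    truncated final frames.
    """
    counts: list[int] = []
    current: int | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if current is not None:
                    counts.append(current)
                current = 0
            elif record in ("ATOM", "HETATM"):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate record at line {lineno}"
                    ) from None
                if current is None:  # single-model file without MODEL records
                    current = 0
                current += 1
            elif record == "ENDMDL":
                if current is not None:
                    counts.append(current)
                current = None
    if current is not None:  # file ended inside a model (truncated)
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise ParseError(f"{path}: no ATOM records found")
    ref = counts[0]
    for frame, count in enumerate(counts, start=1):
        if count != ref:
            raise StructureError(
                f"{path}: frame {frame} has {count} atoms, expected {ref}"
            )


def read_trajectory(path: str, topology_path: str | None = None) -> Ensemble:
    """Read a trajectory into an :class:`Ensemble` (coordinates in nm).

    Multi-model PDB is always supported; XTC/DCD require ``topology_path``
    (a PDB).  PDB ångström coordinates are converted to nm.  Atom order is
    preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        _validate_pdb_text(path)
        try:
            traj = md.load_pdb(path, standard_names=False, no_boxchk=True)
        except Exception as exc:  # mdtraj raises assorted exception types
            raise ParseError(f"{path}: {exc}") from exc
    elif ext in SUPPORTED_BINARY_FORMATS:
        if topology_path is None:
            raise ParameterError(f"{ext} input requires a topology file")
        try:
            traj = md.load(path, top=topology_path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    else:
        raise FormatError(f"unsupported trajectory format: {ext!r}")
    return Ensemble.from_mdtraj(traj)


def write_trajectory(ens: Ensemble, path: str) -> None:
    """Write an ensemble as multi-model PDB (or XTC/DCD by extension)."""
    ext = os.path.splitext(path)[1].lower()
    traj = ens.to_mdtraj()
    if ext == ".pdb":
        traj.save_pdb(path)
    elif ext in SUPPORTED_BINARY_FORMATS:
        traj.save(path)
    else:
        raise FormatError(f"unsupported trajectory format: {ext!r}")


# ---------------------------------------------------------------------------
# Scattering-curve I/O
# ---------------------------------------------------------------------------


def read_curve(path: str) -> ScatteringCurve:
    """Read a whitespace-delimited 2–3 column (q, I[, σ]) text file.

    Lines starting with ``#`` are comments; a header token
    ``q_unit=nm^-1`` or ``q_unit=A^-1`` declares the q unit (default nm⁻¹,
    Å⁻¹ values are multiplied by 10).
    """
    unit = "nm^-1"
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                for token in stripped[1:].split():
                    if token.startswith("q_unit="):
                        unit = token.split("=", 1)[1]
                continue
            parts = stripped.split()
            if len(parts) not in (2, 3):
                raise FormatError(
                    f"{path}: expected 2 or 3 columns at line {lineno}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value at line {lineno}"
                ) from None
    if not rows:
        raise FormatError(f"{path}: empty curve file")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise FormatError(f"{path}: inconsistent column count")
    data = np.array(rows)
    q = data[:, 0]
    if unit == "A^-1":
        q = q * 10.0
    elif unit != "nm^-1":
        raise FormatError(f"{path}: unknown q_unit {unit!r}")
    sigma = data[:, 2] if ncols == 3 else None
    if np.any(np.diff(q) <= 0):
        raise FormatError(f"{path}: q values are not strictly increasing")
    return ScatteringCurve(q, data[:, 1], sigma)


def write_curve(curve: ScatteringCurve, path: str, comment: str = "") -> None:
    """Write a curve as 3-column (or 2-column) text, q in nm⁻¹."""
    with open(path, "w") as handle:
        handle.write(f"# q_unit=nm^-1 {comment}".rstrip() + "\n")
        cols = [curve.q, curve.I]
        if curve.sigma is not None:
            cols.append(curve.sigma)
        for row in zip(*cols):
            handle.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Sequences, config, result tables
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> str:
    """Read a single-record FASTA (or bare-sequence) file and return the sequence."""
    with open(path) as handle:
        text = handle.read()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise FormatError(f"{path}: expected exactly one FASTA record")
        return str(records[0].seq)
    return "".join(text.split())


def load_config(path: str) -> dict:
    """Load a YAML or TOML configuration file into a dict."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".yaml", ".yml"):
        import yaml

        with open(path) as handle:
            return yaml.safe_load(handle) or {}
    if ext == ".toml":
        import tomllib

        with open(path, "rb") as handle:
            return tomllib.load(handle)
    raise FormatError(f"unsupported config format: {ext!r}")


def write_tsv(frame: pd.DataFrame, path: str, metadata: dict | None = None) -> None:
    """Write a result table as TSV with ``# key=value`` metadata headers."""
    with open(path, "w") as handle:
        for key, value in (metadata or {}).items():
            handle.write(f"# {key}={value}\n")
        frame.to_csv(handle, sep="\t", index=False)
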