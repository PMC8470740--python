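"""Free-energy landscapes over principal components of backbone coordinates.

The procedure: pick the ensemble's central structure (the RMSD medoid),
least-squares superpose every frame onto it, run PCA on the flattened
backbone Cartesian coordinates, project onto the first two components,
estimate the probability density there with a Gaussian KDE, and convert it
to a conditional free energy F = −ln(ρ/ρ_max) in RT units (minimum exactly
0, cells above a cap masked).  Basins are the attraction regions of local
density maxima under discrete steepest ascent on the grid; each basin's
minimum-F cell is its minimum, classified by depth bands for plotting.

Two ensembles become directly comparable in shared-basis mode: one basis
is fitted on the concatenated ensembles and each is projected separately,
so both landscapes live in the same (PC1, PC2) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from ._geometry import rmsd_to_reference, superpose
from .trajio import AnalysisError, Ensemble, ParameterError

__all__ = [
    "PCABasis",
    "FreeEnergyLandscape",
    "central_structure",
    "fit_pca",
    "project",
    "variance_report",
    "free_energy_surface",
    "assign_basins",
]

PCA_SELECTION = "backbone"  # N, CA, C, O
MEDOID_MAX_FRAMES = 2000
GRID_SIZE = 150
PADDING = 0.10
CAP_RT = 10.0
DEPTH_BANDS = (1.0, 2.0, 3.0)  # RT; marker classes for basin minima


@dataclass
class PCABasis:
    """PCA of superposed, flattened backbone coordinates.

    ``components`` rows are orthonormal; ``variance_fractions`` descend.
    ``reference`` keeps the centred structure used for superposition so
    that new ensembles can be projected into the same frame.
    """

    mean: np.ndarray
    components: np.ndarray
    variance_fractions: np.ndarray
    reference: np.ndarray
    selection: str = PCA_SELECTION

    def __post_init__(self):
        vf = np.asarray(self.variance_fractions, dtype=float)
        if np.any(np.diff(vf) > 1e-12) or vf.sum() > 1.0 + 1e-9:
            raise ParameterError("variance fractions must descend and sum <= 1")


@dataclass
class Minimum:
    """One basin minimum: grid location, PC coordinates, depth, band."""

    basin: int
    cell: tuple[int, int]
    pc1: float
    pc2: float
    depth: float
    band: float | None


@dataclass
class FreeEnergyLandscape:
    """2D free-energy grid over (PC1, PC2) in RT units.

    ``free_energy`` is NaN on masked (beyond-cap) cells; ``basins`` holds
    one basin label per unmasked cell (−1 where masked) after
    :func:`assign_basins`.
    """

    pc1: np.ndarray  # grid centres, shape (nx,)
    pc2: np.ndarray  # grid centres, shape (ny,)
    free_energy: np.ndarray  # (nx, ny), NaN where masked
    density: np.ndarray  # (nx, ny)
    cap: float
    basins: np.ndarray | None = None
    minima: list[Minimum] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        """True on cells beyond the free-energy cap."""
        return np.isnan(self.free_energy)


# ---------------------------------------------------------------------------
# Central structure and PCA
# ---------------------------------------------------------------------------


def central_structure(
    ens: Ensemble, selection: str = PCA_SELECTION, max_frames: int = MEDOID_MAX_FRAMES
) -> int:
    """Index of the medoid frame: minimal mean pairwise RMSD (after optimal
    superposition) over a deterministic stride subsample of ≤ max_frames.

    Ties break toward the earliest frame.
    """
    if ens.n_frames < 2:
        raise ParameterError("central structure requires at least 2 frames")
    idx = ens.select(selection)
    coords = ens.coordinates[:, idx]
    if ens.n_frames > max_frames:
        stride = int(np.ceil(ens.n_frames / max_frames))
        sample = np.arange(0, ens.n_frames, stride)
    else:
        sample = np.arange(ens.n_frames)
    sub = coords[sample]
    mean_rmsd = np.array(
        [rmsd_to_reference(sub, sub[k]).mean() for k in range(len(sample))]
    )
    return int(sample[int(np.argmin(mean_rmsd))])


def fit_pca(
    ensembles: Ensemble | list[Ensemble], selection: str = PCA_SELECTION
) -> PCABasis:
    """PCA basis of backbone coordinates after superposition on the central
    structure.

    Passing a list of ensembles is shared-basis mode: the basis is computed
    on the concatenation, so separate projections of each ensemble are
    directly comparable.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    idx = ensembles[0].select(selection)
    coords = np.concatenate([e.coordinates[:, e.select(selection)] for e in ensembles])
    merged = Ensemble(
        np.concatenate([e.coordinates for e in ensembles]), ensembles[0].topology
    )
    centre = central_structure(merged, selection)
    reference = coords[centre] - coords[centre].mean(axis=0)
    aligned = superpose(coords, reference)
    X = aligned.reshape(len(aligned), -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    if np.allclose(Xc, 0.0):
        raise AnalysisError("zero-variance input: PCA decomposition undefined")
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals**2
    fractions = variances / variances.sum()
    return PCABasis(mean, Vt, fractions, reference, selection)


def project(basis: PCABasis, ens: Ensemble, n_components: int = 2) -> np.ndarray:
    """Project an ensemble onto the basis (superposing onto the stored
    reference first).  Returns (n_frames, n_components)."""
    coords = ens.coordinates[:, ens.select(basis.selection)]
    aligned = superpose(coords, basis.reference)
    X = aligned.reshape(len(aligned), -1) - basis.mean
    return X @ basis.components[:n_components].T


def variance_report(basis: PCABasis) -> float:
    """Fraction of total variance captured by the first two components."""
    return float(np.sum(basis.variance_fractions[:2]))


# ---------------------------------------------------------------------------
# Free-energy surface and basins
# ---------------------------------------------------------------------------


def free_energy_surface(
    projections: np.ndarray,
    grid: int = GRID_SIZE,
    bandwidth=None,
    padding: float = PADDING,
    cap: float = CAP_RT,
) -> FreeEnergyLandscape:
    """Gaussian-KDE density on a padded (PC1, PC2) grid, converted to a
    conditional free energy F = −ln(ρ/ρ_max) in RT units.

    The grid range is the data range padded by ``padding`` per axis;
    ``bandwidth`` follows Scott's rule when None.  min F = 0 exactly;
    cells with F > cap are masked (NaN).
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("projections must have shape (n, 2)")
    if len(pts) < 100:
        raise ParameterError("free-energy surface requires at least 100 points")
    if np.allclose(pts, pts[0]):
        raise AnalysisError("all projected points identical: density degenerate")
    try:
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(f"degenerate density: {exc}") from exc
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = hi - lo
    lo, hi = lo - padding * span, hi + padding * span
    pc1 = np.linspace(lo[0], hi[0], grid)
    pc2 = np.linspace(lo[1], hi[1], grid)
    G1, G2 = np.meshgrid(pc1, pc2, indexing="ij")
    density = kde(np.vstack([G1.ravel(), G2.ravel()])).reshape(grid, grid)
    rho_max = density.max()
    with np.errstate(divide="ignore"):
        F = -np.log(density / rho_max)
    F[F > cap] = np.nan
    return FreeEnergyLandscape(pc1, pc2, F, density, cap)


_NEIGHBOURS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def assign_basins(surface: FreeEnergyLandscape) -> FreeEnergyLandscape:
    """Label every unmasked cell by discrete steepest ascent of density.

    Each cell follows its steepest-ascending 8-neighbour until reaching a
    local density maximum; cells sharing a maximum share a basin.  Ties
    break toward the lower linear cell index (deterministic).  Masked
    cells get label −1.  The surface is annotated in place (labels and the
    minima list, with depth bands) and returned.
    """
    nx, ny = surface.density.shape
    rho = surface.density
    masked = surface.mask
    uphill = np.full((nx, ny), -1, dtype=np.int64)  # linear index of move target
    for i in range(nx):
        for j in range(ny):
            if masked[i, j]:
                continue
            best = rho[i, j]
            target = i * ny + j
            for di, dj in _NEIGHBOURS:
                a, b = i + di, j + dj
                if 0 <= a < nx and 0 <= b < ny and not masked[a, b]:
                    cand = a * ny + b
                    if rho[a, b] > best or (rho[a, b] == best and cand < target):
                        best = rho[a, b]
                        target = cand
            uphill[i, j] = target

    labels = np.full((nx, ny), -1, dtype=np.int64)
    attractor_of: dict[int, int] = {}
    next_label = 0
    flat = uphill.ravel()
    for start in range(nx * ny):
        if masked.flat[start]:
            continue
        path = []
        node = start
        while labels.flat[node] == -1:
            path.append(node)
            nxt = flat[node]
            if nxt == node:  # local maximum
                if node not in attractor_of:
                    attractor_of[node] = next_label
                    next_label += 1
                label = attractor_of[node]
                break
            node = nxt
        else:
            label = labels.flat[node]
        for p in path:
            labels.flat[p] = label

    minima: list[Minimum] = []
    for attractor, label in sorted(attractor_of.items(), key=lambda kv: kv[1]):
        cells = np.flatnonzero(labels.ravel() == label)
        depths = surface.free_energy.ravel()[cells]
        best_cell = int(cells[int(np.nanargmin(depths))])
        i, j = divmod(best_cell, ny)
        depth = float(surface.free_energy[i, j])
        band = next((b for b in DEPTH_BANDS if depth <= b), None)
        minima.append(
            Minimum(label, (i, j), float(surface.pc1[i]), float(surface.pc2[j]), depth, band)
        )
    surface.basins = labels
    surface.minima = minima
    return surface
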