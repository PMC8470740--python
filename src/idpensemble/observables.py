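"""Global-size observables and their statistics.

Per-frame radius of gyration and end-to-end distance, their distributions,
autocorrelation, and block-averaging (Flyvbjerg–Petersen) error estimates
for the correlated series that molecular trajectories produce.  Also hosts
the small worked-example arithmetic used when comparing force-field means
(integer percentage differences, rounded half-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trajio import AnalysisError, Ensemble, ParameterError, TopologyError

__all__ = [
    "ScalarSeries",
    "BlockErrorEstimate",
    "radius_of_gyration",
    "end_to_end",
    "block_error",
    "autocorrelation",
    "histogram",
    "percent_difference",
]


@dataclass
class ScalarSeries:
    """A per-frame scalar observable, with optional frame spacing (ps)."""

    values: np.ndarray
    dt: float | None = None
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ParameterError("series must be a non-empty 1D array")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("series values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class BlockErrorEstimate:
    """Blocking analysis result: SE of the mean per block size, plus the
    plateau estimate and whether a plateau was detected."""

    block_sizes: np.ndarray
    errors: np.ndarray
    plateau: float
    converged: bool


def radius_of_gyration(ens: Ensemble, selection: str = "all") -> ScalarSeries:
    """Mass-weighted Rg per frame (nm): sqrt(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ)."""
    idx = ens.select(selection)
    masses = ens.masses[idx]
    total = masses.sum()
    if total <= 0:
        raise ParameterError("selection has zero total mass")
    x = ens.coordinates[:, idx]
    com = np.einsum("fai,a->fi", x, masses) / total
    sq = np.einsum("fa,a->f", np.sum((x - com[:, None, :]) ** 2, axis=2), masses)
    return ScalarSeries(np.sqrt(sq / total), name=f"Rg[{selection}]")


def end_to_end(ens: Ensemble, convention: str = "nc") -> ScalarSeries:
    """Per-frame distance between the chain's terminal anchors (nm).

    ``convention="nc"``: backbone N of the first residue to backbone C of
    the last; ``"caca"``: CA to CA.  The anchor atom pair is a reporting
    choice, not a physical one, so it is recorded in the series name.
    """
    resids = ens.residue_ids
    if len(resids) < 2:
        raise ParameterError("end-to-end distance requires at least 2 residues")
    first_name, last_name = {"nc": ("N", "C"), "caca": ("CA", "CA")}.get(
        convention, (None, None)
    )
    if first_name is None:
        raise ParameterError(f"unknown end-to-end convention {convention!r}")
    names = ens.topology["name"].to_numpy()
    resid = ens.topology["resid"].to_numpy()

    def anchor(r, name):
        hits = np.flatnonzero((resid == r) & (names == name))
        if hits.size == 0:
            raise TopologyError(f"residue {r} lacks anchor atom {name}")
        return hits[0]

    a = anchor(resids[0], first_name)
    b = anchor(resids[-1], last_name)
    dist = np.linalg.norm(ens.coordinates[:, a] - ens.coordinates[:, b], axis=1)
    return ScalarSeries(dist, name=f"Ree[{convention}]")


def block_error(series: ScalarSeries, rel_tol: float = 0.05) -> BlockErrorEstimate:
    """Flyvbjerg–Petersen blocking: average pairs of blocks repeatedly and
    report the naive SE of the block means at each level.

    The plateau estimate is the first level whose estimate changes by less
    than ``rel_tol`` over the next two doublings; if none qualifies the
    maximum-level estimate is returned with ``converged=False``.
    """
    x = np.asarray(series.values, dtype=float)
    if len(x) < 16:
        raise ParameterError("blocking analysis requires at least 16 points")
    sizes, errors = [], []
    level = 0
    while len(x) >= 4:
        n = len(x)
        var = np.var(x, ddof=1)
        errors.append(math.sqrt(var / n))
        sizes.append(2**level)
        x = 0.5 * (x[: n // 2 * 2 : 2] + x[1 : n // 2 * 2 : 2])
        level += 1
    errors = np.array(errors)
    sizes = np.array(sizes)
    plateau, converged = errors[-1], False
    for l in range(len(errors) - 2):
        if errors[l] == 0.0 and errors[l + 1] == 0.0 and errors[l + 2] == 0.0:
            plateau, converged = 0.0, True
            break
        denom1 = errors[l] if errors[l] > 0 else 1.0
        denom2 = errors[l + 1] if errors[l + 1] > 0 else 1.0
        if (
            abs(errors[l + 1] - errors[l]) < rel_tol * denom1
            and abs(errors[l + 2] - errors[l + 1]) < rel_tol * denom2
        ):
            plateau, converged = errors[l + 2], True
            break
    return BlockErrorEstimate(sizes, errors, float(plateau), converged)


def autocorrelation(series: ScalarSeries) -> tuple[np.ndarray, float]:
    """Normalised autocorrelation function and integrated correlation time.

    ACF(0) = 1; the integrated time is spacing·(1 + 2·Σ ACF(t)) with the
    sum truncated at the first negative ACF value (standard initial
    positive-sequence estimator).
    """
    x = np.asarray(series.values, dtype=float)
    if len(x) < 4:
        raise ParameterError("autocorrelation requires at least 4 points")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0.0:
        raise AnalysisError("autocorrelation undefined for zero-variance series")
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    acf = acov / acov[0]
    dt = series.dt if series.dt is not None else 1.0
    neg = np.flatnonzero(acf[1:] < 0.0)
    stop = (neg[0] + 1) if neg.size else n
    tau = dt * (1.0 + 2.0 * float(np.sum(acf[1:stop])))
    return acf, tau


def histogram(series: ScalarSeries, bins=None) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalised histogram (integrates to 1).

    Default binning is Freedman–Diaconis, falling back to a single bin for
    (near-)constant input where the IQR vanishes.

    Returns ``(edges, density)``.
    """
    x = series.values
    if bins is None:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        if iqr == 0.0 or x.min() == x.max():
            span = max(abs(x[0]), 1.0) * 1e-6
            edges = np.array([x.min() - span, x.max() + span])
            density, edges = np.histogram(x, bins=edges, density=True)
            return edges, density
        bins = "fd"
    density, edges = np.histogram(x, bins=bins, density=True)
    return edges, density


def percent_difference(reference: float, other: float) -> int:
    """Percentage reduction of ``other`` relative to ``reference``,
    rounded half-up to an integer: round(100·(ref − other)/ref)."""
    if reference == 0:
        raise ParameterError("reference value must be nonzero")
    value = 100.0 * (reference - other) / reference
    return int(math.floor(value + 0.5))
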