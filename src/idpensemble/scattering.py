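"""Small-angle scattering analysis: Debye sums, Guinier fits, dimensionless
Kratky representation and the affine χ²(f, c) fit against a reference curve.

The calculated intensity is the orientationally averaged Debye double sum
I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) over scattering centres — by default one
unit-weight bead per residue (centre of mass), which suffices for the
shape-level comparisons (Kratky, Guinier) this package performs; no
hydration-shell or excluded-volume modelling is attempted.

The fit quality against a reference curve is
χ²(f, c) = (1/N_q) Σᵢ [(I_ref(qᵢ) − (f·I_obs(qᵢ) + c)) / σ_ref(qᵢ)]²,
minimised over the scale f and offset c with Nelder–Mead after linearly
interpolating the calculated curve onto the reference q grid; a closed-form
weighted least-squares solution provides an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .trajio import Ensemble, FitError, ParameterError, ScatteringCurve

__all__ = [
    "FormFactorModel",
    "Chi2FitResult",
    "debye_intensity",
    "guinier_rg",
    "dimensionless_kratky",
    "chi2_fit",
    "chi2_affine_wls",
]


@dataclass(frozen=True)
class FormFactorModel:
    """Scattering-centre model: ``residue-bead`` (one unit-weight bead per
    residue centre of mass, the default) or ``uniform-atom`` (every atom a
    unit-weight point).  ``weights`` overrides the per-entity weights."""

    mode: str = "residue-bead"
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("residue-bead", "uniform-atom"):
            raise ParameterError(f"unknown form-factor mode {self.mode!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w <= 0):
                raise ParameterError("scattering weights must be positive")
            object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class Chi2FitResult:
    """Result of the affine χ² fit: scale f, offset c, χ² and N_q used."""

    f: float
    c: float
    chi2: float
    n_points: int

    def __post_init__(self):
        if self.chi2 < 0:
            raise ParameterError("chi2 must be >= 0")
        if self.n_points < 3:
            raise ParameterError("fit needs at least 3 points")


def _scattering_centres(ens: Ensemble, model: FormFactorModel):
    """(positions (F, M, 3), weights (M,)) for the chosen model."""
    if model.mode == "uniform-atom":
        pos = ens.coordinates
        m = pos.shape[1]
    else:
        by_res = ens.atom_indices_by_residue()
        masses = ens.masses
        centres = []
        for r, idx in by_res.items():
            w = masses[idx]
            centres.append(
                np.einsum("fai,a->fi", ens.coordinates[:, idx], w) / w.sum()
            )
        pos = np.stack(centres, axis=1)
        m = pos.shape[1]
    if m == 0:
        raise ParameterError("empty scattering-centre selection")
    weights = (
        model.weights if model.weights is not None else np.ones(m)
    )
    if weights.shape != (m,):
        raise ParameterError(
            f"model has {weights.shape[0]} weights for {m} scattering centres"
        )
    return pos, weights


def debye_intensity(
    ens: Ensemble,
    q_grid: np.ndarray,
    model: FormFactorModel | None = None,
    chunk_frames: int = 64,
) -> ScatteringCurve:
    """Ensemble-averaged Debye intensity on ``q_grid`` (nm⁻¹, ascending).

    The i = j and q = 0 limits are handled analytically (sin x / x → 1).
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or np.any(q < 0) or np.any(np.diff(q) <= 0):
        raise ParameterError("q_grid must be 1D, non-negative and ascending")
    model = model or FormFactorModel()
    pos, w = _scattering_centres(ens, model)
    n_frames, m, _ = pos.shape
    iu, ju = np.triu_indices(m, k=1)
    pair_w = 2.0 * w[iu] * w[ju]
    self_term = float(np.sum(w**2))
    intensity = np.zeros_like(q)
    for start in range(0, n_frames, chunk_frames):
        block = pos[start : start + chunk_frames]
        rij = np.linalg.norm(block[:, iu] - block[:, ju], axis=-1)  # (B, P)
        # np.sinc(x) = sin(pi x)/(pi x)  ->  sin(qr)/(qr) = sinc(qr/pi)
        s = np.sinc(rij[:, :, None] * q[None, None, :] / np.pi)
        intensity += np.einsum("bpq,p->q", s, pair_w)
    intensity = intensity / n_frames + self_term
    return ScatteringCurve(q, intensity)


def guinier_rg(
    curve: ScatteringCurve,
    qrg_max: float = 1.3,
    n_start: int = 10,
    max_iter: int = 50,
    rel_tol: float = 0.01,
) -> tuple[float, float]:
    """Iterative Guinier fit: ln I = ln I(0) − q²Rg²/3 on the low-q window.

    Starts from the ``n_start`` lowest-q points and re-restricts the window
    to q·Rg < ``qrg_max`` until Rg changes by less than ``rel_tol``.
    Returns (Rg, I(0)).
    """
    q, I = curve.q, curve.I
    if np.any(I <= 0):
        raise FitError("Guinier analysis requires positive intensities")
    mask = np.zeros(len(q), dtype=bool)
    mask[: min(n_start, len(q))] = True
    rg = None
    for _ in range(max_iter):
        if mask.sum() < 5:
            raise FitError("fewer than 5 points in the Guinier window")
        slope, intercept = np.polyfit(q[mask] ** 2, np.log(I[mask]), 1)
        if slope >= 0:
            raise FitError("no Guinier regime (non-negative low-q slope)")
        new_rg = float(np.sqrt(-3.0 * slope))
        if rg is not None and abs(new_rg - rg) < rel_tol * rg:
            return new_rg, float(np.exp(intercept))
        rg = new_rg
        mask = q * rg < qrg_max
    raise FitError(f"Guinier fit did not converge in {max_iter} iterations")


def dimensionless_kratky(
    curve: ScatteringCurve, rg: float, i0: float
) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) with x = qRg and y = (qRg)²·I(q)/I(0) — the shape classifier
    separating Gaussian-chain from globular scattering."""
    if rg <= 0 or i0 <= 0:
        raise ParameterError("Rg and I(0) must be positive")
    x = curve.q * rg
    y = x**2 * curve.I / i0
    return x, y


def _interp_overlap(calc: ScatteringCurve, ref: ScatteringCurve):
    """Linearly interpolate the calculated curve onto the reference q grid
    restricted to the overlapping q range."""
    lo, hi = calc.q[0], calc.q[-1]
    mask = (ref.q >= lo) & (ref.q <= hi)
    if mask.sum() < 3:
        raise ParameterError(
            "fewer than 3 reference points inside the calculated q range"
        )
    iobs = np.interp(ref.q[mask], calc.q, calc.I)
    return mask, iobs


def chi2_affine_wls(
    calc: ScatteringCurve,
    ref: ScatteringCurve,
    sigma_policy: str = "constant",
    norm: str = "n",
) -> Chi2FitResult:
    """Closed-form weighted least-squares solution of the affine χ² fit
    (the independent cross-check for the Nelder–Mead route)."""
    mask, iobs = _interp_overlap(calc, ref)
    iref, sigma = ref.I[mask], _resolve_sigma(ref, mask, sigma_policy)
    w = 1.0 / sigma**2
    sw = w.sum()
    mx = np.sum(w * iobs) / sw
    my = np.sum(w * iref) / sw
    sxx = np.sum(w * (iobs - mx) ** 2)
    if sxx == 0:
        raise FitError("calculated curve is constant over the fit window")
    f = np.sum(w * (iobs - mx) * (iref - my)) / sxx
    c = my - f * mx
    return Chi2FitResult(
        float(f), float(c), _chi2_value(f, c, iobs, iref, sigma, norm), int(mask.sum())
    )


def _resolve_sigma(ref, mask, sigma_policy):
    if ref.sigma is not None:
        return ref.sigma[mask]
    if sigma_policy == "constant":
        return np.ones(int(mask.sum()))
    if sigma_policy == "proportional":
        return np.maximum(np.abs(ref.I[mask]), np.finfo(float).tiny) * 0.01
    raise ParameterError(
        "reference curve has no sigma; supply sigma_policy='constant' or "
        "'proportional'"
    )


def _chi2_value(f, c, iobs, iref, sigma, norm):
    resid = (iref - (f * iobs + c)) / sigma
    n = len(iref)
    denom = n if norm == "n" else n - 1
    return float(np.sum(resid**2) / denom)


def chi2_fit(
    calc: ScatteringCurve,
    ref: ScatteringCurve,
    sigma_policy: str = "constant",
    norm: str = "n",
) -> Chi2FitResult:
    """Minimise the affine χ²(f, c) with Nelder–Mead.

    The calculated curve is linearly interpolated onto the reference q
    points (overlap only).  ``norm`` selects 1/N_q (default) or 1/(N_q−1)
    normalisation.  The simplex optimum agrees with
    :func:`chi2_affine_wls` to high precision.
    """
    mask, iobs = _interp_overlap(calc, ref)
    iref, sigma = ref.I[mask], _resolve_sigma(ref, mask, sigma_policy)

    def objective(p):
        return _chi2_value(p[0], p[1], iobs, iref, sigma, norm)

    scale0 = float(np.mean(iref) / max(np.mean(iobs), np.finfo(float).tiny))
    result = minimize(
        objective,
        x0=np.array([scale0 if np.isfinite(scale0) else 1.0, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50_000},
    )
    if not result.success:
        raise FitError(f"Nelder-Mead did not converge: {result.message}")
    f, c = result.x
    return Chi2FitResult(
        float(f), float(c), _chi2_value(f, c, iobs, iref, sigma, norm), int(mask.sum())
    )
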