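# idpensemble

Conformational-ensemble analysis for short intrinsically disordered
phosphopeptides.

Intrinsically disordered proteins (IDPs) have no single native structure:
a trajectory of a disordered peptide is an *ensemble* of conformations,
and phosphorylation — which adds −2e charges at Ser/Thr at physiological
pH — reshapes that ensemble through salt bridges between phosphate groups
and positively charged residues.  `idpensemble` packages the standard
analysis chain used to characterise such ensembles and to compare them
(e.g. across force fields or salt concentrations):

* **Size observables** — per-frame radius of gyration
  R_g = √(Σᵢ mᵢ|rᵢ−r_com|²/Σᵢ mᵢ) and end-to-end distance R_ee,
  distributions, autocorrelation, and Flyvbjerg–Petersen block-averaging
  errors for correlated series.
* **Scattering** — Debye-sum intensities
  I(q) = Σᵢⱼ fᵢfⱼ sin(qr_ij)/(qr_ij), iterative Guinier fits
  (ln I ≈ ln I(0) − q²R_g²/3), the dimensionless Kratky representation
  (qR_g)²I(q)/I(0), and the affine fit
  χ²(f,c) = (1/N_q)Σᵢ[(I_ref − (f·I_obs + c))/σ_ref]² minimised with
  Nelder–Mead (closed-form weighted-least-squares cross-check built in).
* **Interactions** — residue contact maps (min inter-atom distance
  < 0.4 nm), hydrogen bonds via the distance–angle criterion
  r_DA < 0.33 nm − 4.4·10⁻⁵·θ², and salt-bridge occupancies with
  blocking errors.
* **Secondary structure** — Kabsch–Sander rules (H/G/I/E/B/T/S/C from the
  electrostatic H-bond energy) extended with polyproline-II detection
  (φ ∈ [−104°, −46°], ψ ∈ [116°, 174°], ≥2 consecutive residues),
  reported as helix / strand / turn / bend / PPII / irregular groups.
* **Free-energy landscapes** — PCA of superposed backbone coordinates,
  Gaussian-KDE density over (PC1, PC2), conditional free energy
  F = −ln(ρ/ρ_max) in RT units, steepest-ascent basin assignment, and a
  shared-basis mode that makes two ensembles directly comparable.
* **Charge patterning** — FCR, NCPR and the Das–Pappu segregation
  parameter κ ∈ [0, 1], with phosphosites equalised to negative residues.
* **Synthetic data** — freely jointed chains, dihedral-exact backbones,
  planted-contact ensembles and noisy affine reference curves, so every
  stage is testable against known ground truth without any download.

Four phosphopeptide fixtures ship with the package (two tau fragments,
the β-casein 1–25 phosphopeptide, and statherin), with phosphosite
positions as explicit configuration.

## Worked example

```python
import numpy as np
from idpensemble import (
    ChainModelSpec, generate_ideal_chain, radius_of_gyration,
    end_to_end, block_error, debye_intensity, guinier_rg,
    builtin_peptides, charge_fractions, kappa,
)

# a freely jointed 100-bead chain: <Rg^2> = b^2 (n^2-1)/(6n) is known
ens = generate_ideal_chain(ChainModelSpec(n_beads=100, bond_length=0.38,
                                          n_frames=5000, seed=3))
rg = radius_of_gyration(ens)
err = block_error(rg).plateau
print(f"Rg = {rg.values.mean():.3f} +/- {err:.3f} nm")

curve = debye_intensity(ens, np.linspace(0.05, 2.0, 50))
g_rg, i0 = guinier_rg(curve, qrg_max=1.0)   # flexible-chain Guinier window
print(f"Guinier Rg = {g_rg:.3f} nm")

stath = builtin_peptides()["Stath"]
r = charge_fractions(stath)
print(f"Stath: FCR = {r.fcr:.3f}, NCPR = {r.ncpr:+.3f}, kappa = {kappa(stath):.3f}")
```

prints

```
Rg = 1.507 +/- 0.005 nm
Guinier Rg = 1.493 nm
Stath: FCR = 0.233, NCPR = -0.047, kappa = 0.502
```

The closed form gives the RMS size √⟨R_g²⟩ = √(0.38²·(100²−1)/600) =
1.551 nm; the ensemble *mean* R_g sits a few percent below the RMS, as it
must for a fluctuating chain, and the Guinier estimate carries the known
few-percent low-q-window bias of Gaussian-chain curves.  Statherin's
moderate κ reflects its two phosphoserines sitting inside the acidic
N-terminal cluster, well separated from the basic middle residues.

A command-line interface mirrors the library
(`idpens simulate-synthetic|observables|scatter|saltbridges|secstruct|landscape|seqmetrics`,
all with `--seed`, `--log-level`, `--out-dir`).

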