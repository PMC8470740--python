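# Methods

`idpensemble` analyses conformational ensembles of short intrinsically
disordered phosphopeptides: global size observables and their error
analysis, small-angle scattering descriptors, residue interactions,
secondary structure with polyproline-II, free-energy landscapes in a PCA
projection, and sequence charge-patterning metrics.  This note records the
models, the parameters that matter, and the design choices made where the
underlying conventions were genuinely open.

## Containers and units

Coordinates are stored in nanometres, frames × atoms × 3, with a flat atom
table (name, element, mass, 1-based residue index, residue name).
Momentum transfer q is in nm⁻¹ (curve files may declare Å⁻¹ and are
converted on read).  Hydrogen-bond energies are reported in kcal/mol,
free energies in units of RT.

## Synthetic ensembles (what the generator emulates, and what it does not)

The generator provides ensembles in which every downstream result is known
by construction:

* **Freely jointed chains** — n beads joined by fixed-length bonds with
  i.i.d. uniform directions.  Closed forms used as oracles:
  ⟨R²ₑₑ⟩ = (n−1)b² and ⟨R²g⟩ = b²(n²−1)/(6n), with ⟨R²ₑₑ⟩/⟨R²g⟩ → 6.
  The default bond length 0.38 nm is the trans-peptide CA–CA distance and
  the default bead mass 110 amu the average residue mass (only ratios
  matter for mass-weighted Rg).  These chains emulate the *size
  statistics* of a disordered peptide, not its local stiffness, excluded
  volume, or chemistry; at high q (qb ≳ 1) their discrete-chain
  scattering deviates from the continuous Gaussian-chain Debye function,
  which is why the Kratky-plateau check is performed on the analytic
  Debye-function curve rather than on the bead ensemble.
* **Dihedral-exact backbones** — single-frame N/H/CA/C/O models placed by
  sequential internal-coordinate (NeRF) construction from per-residue
  (φ, ψ, ω), using canonical bond lengths N–CA 0.1458, CA–C 0.1525,
  C–N 0.1329 nm and angles 111.2°/116.2°/121.7°.  Fixed canonical
  geometry makes the secondary-structure tests deterministic: (−57°, −47°)
  yields i→i+4 hydrogen bonds, (−49°, −26°) i→i+3, (−75°, +145°) a PPII
  stretch, by construction.  Amide H sits 0.098 nm from N along the
  reversed C(i−1)→O(i−1) direction (trans to the carbonyl O, the DSSP
  reconstruction convention); prolines carry no donor.
* **Planted contacts** — stratified resampling of an existing ensemble so
  that chosen residue pairs are in contact (min inter-atom distance <
  cutoff) in a target fraction of frames.  Frames are partitioned by
  their joint contact pattern, per-stratum counts follow the product of
  the independent marginals with largest-remainder rounding, and frames
  are redrawn with replacement inside strata.  Coordinates are never
  modified, so planted ensembles remain geometrically valid; resampling
  was chosen over biased dynamics because it is exact and fast.  A target
  is infeasible when no frame (or every frame) qualifies.
* **Reference curves** — noisy affine transforms I_ref = f·I_calc + c +
  N(0, σ) of a calculated curve, with σ becoming the error column.

All generators are bit-reproducible under a fixed seed.  Passing tests on
these ensembles demonstrate the *analysis machinery*; they do not
demonstrate force-field accuracy or solvent effects, which require real
trajectories.

## Size observables and statistics

Rg is mass-weighted over all atoms by default (selection configurable),
matching the common trajectory-tool default.  The end-to-end anchor pair
is not standardised across tools, so both N(first)→C(last) (default) and
CA–CA are offered and the convention is recorded in output metadata.

Error estimates for correlated series use Flyvbjerg–Petersen blocking:
block pairs are averaged repeatedly and the naive SE of block means is
reported per level; the plateau is the first level whose estimate changes
by <5% over two successive doublings (otherwise the maximum-level value,
flagged unconverged).  The integrated autocorrelation time is the initial
positive-sequence estimator, truncated at the first negative ACF value.
Histograms are density-normalised with Freedman–Diaconis binning (a single
bin for constant input).  Equilibration trimming is exposed as a
`--discard-frames` option, never automated.

The percentage-difference utility rounds half-up to integers, matching the
precision at which force-field comparison tables are usually printed.

## Scattering

Calculated curves use the Debye double sum over scattering centres —
by default one unit-weight bead at each residue's centre of mass, with a
uniform-atom alternative.  Bead-level curves suffice for the shape-level
Guinier/Kratky comparisons performed here; hydration-shell contrast and
atomic excluded-volume corrections are out of scope.

Guinier analysis iterates ln I vs q² on a low-q window until Rg is stable
to 1%.  The default window bound is q·Rg < 1.3 (the globular-particle
convention); for Gaussian-chain-like curves that window systematically
underestimates Rg by ≈6.5%, so flexible-chain analyses here use the
standard flexible-chain limit q·Rg < 1.0 (bias ≈ −3.7% on the Debye
function).  The bound is an explicit parameter (`qrg_max`).  The
dimensionless Kratky representation is (qRg)² I(q)/I(0) vs qRg; I(0) may
come from Guinier extrapolation (default) or the lowest-q point.

The fit against a reference curve minimises
χ²(f, c) = (1/N_q) Σ [(I_ref − (f·I_obs + c))/σ_ref]² over scale and
offset with Nelder–Mead after linear interpolation onto the reference q
grid (overlap only).  The normalisation prefactor is read as 1/N_q, with
1/(N_q−1) available via a flag and recorded in output metadata.  A
closed-form weighted least-squares solution of the same quadratic is kept
as an internal cross-check; the two agree to relative 1e−6 in the test
suite.  Missing σ columns fall back to a policy: constant σ = 1 (default)
or σ ∝ I_ref.

## Contacts, hydrogen bonds, salt bridges

Residue contact: shortest distance between any two atoms (hydrogens
included) < 0.4 nm, strict inequality.  Hydrogen bonds use the
distance–angle criterion r_DA < d_max − k·θ² with θ the H–donor–acceptor
angle in degrees, d_max = 0.33 nm, k = 4.4·10⁻⁵ nm/deg²; both constants
are configurable so the criterion stays auditable.  Salt bridges are
reported at residue-pair granularity: occupancy is the fraction of frames
with ≥1 qualifying bond between the pair's donor hydrogens (Arg
NE/NH1/NH2, Lys NZ, N-terminal ammonium; His optional and off by default)
and acceptor oxygens (phosphate, carboxylate, C-terminal carboxylate),
with a blocking error on the per-frame indicator.  Kabsch–Sander and
criterion evaluation exclude donor–acceptor separations < 3 residues:
every pattern consumed downstream requires ≥3, and reconstructed amide
hydrogens make the i→i+1 peptide-bond geometry spuriously pass the energy
cutoff.

## Secondary structure

The Kabsch–Sander electrostatic model assigns an H-bond when
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol
(distances in Å).  n-turns (n = 3, 4, 5) feed helices (two consecutive
turns → G/H/I), bridge patterns feed B/E (isolated vs laddered), isolated
turns give T, and a CA-direction change > 70° over i−2 → i → i+2 gives S,
with priority H > E > B > G > I > T > S > C.  Chains shorter than three
residues are all C.

The PPII extension relabels *irregular* residues whose (φ, ψ) fall inside
φ ∈ [−104°, −46°], ψ ∈ [116°, 174°] for ≥2 consecutive residues as P.
Window bounds and run length are configurable (published PPII
parameterisations differ slightly); only C residues are eligible, so the
extension can never reduce helix/strand/turn/bend content.  Reporting
groups lump helix = H+G+I and strand = E+B; group fractions partition
each frame exactly.

## Free-energy landscapes

The central structure is the RMSD medoid (unweighted Kabsch
superposition), computed on a deterministic stride subsample of ≤2000
frames with ties broken toward the earliest frame.  PCA runs on the
flattened N/CA/C/O coordinates after superposing every frame on the
central structure; the heavier four-atom backbone set (rather than
N/CA/C) keeps PPII/turn differences visible, and weighting is uniform by
default.  Shared-basis mode concatenates two ensembles, fits one basis,
and projects each separately so the two landscapes are directly
comparable.

The density of the first two projections is a Gaussian KDE (Scott's rule
per dimension, override available) evaluated on a 150×150 grid padded 10%
per axis; F = −ln(ρ/ρ_max) in RT, minimum exactly 0, cells above 10 RT
masked.  Basins are assigned by discrete steepest ascent of density on
the 8-neighbourhood with ties broken toward the lower linear cell index;
each basin's minimum-F cell is its minimum, classified into the depth
bands ≤1, ≤2, ≤3 RT used as figure markers.  Gaussian-KDE tails of finite
samples contain genuine shallow local maxima (around 6–7 RT for 10⁴
points), so "how many basins" is answered by the band-classified minima;
the partition itself always covers every unmasked cell.

## Charge patterning

Per-residue charges at physiological pH: D/E −1, K/R +1, H 0,
phospho-S/T −2, with +1/−1 terminal charges carried separately.  For
FCR/NCPR/κ the phosphosites are equalised to ordinary negative residues
(sign −1), so phosphorylated and acidic residues are compared on the same
footing; no pKa/charge-regulation model is attempted.

κ uses blob sizes 5 and 6, stride-1 windows fully inside the sequence:
σ_j = (f⁺−f⁻)²/(f⁺+f⁻) per window (0 without charges), δ_g = mean of
(σ_j − σ_seq)², δ = (δ₅+δ₆)/2, κ = δ/δ_max clipped to [0, 1].  δ_max —
the δ of the most segregated arrangement of the same composition — is
found by exhaustive enumeration of distinct arrangements whenever their
count is ≤ 2·10⁵ (all peptides up to ~12 residues), because for short
sequences window edge effects make the blocky arrangement non-maximal
(e.g. "+----+" beats "++----" at length 6).  Longer sequences fall back
to the maximum over segregated candidates: charge blocks with neutrals
placed before, after, split between the ends, or between the blocks.
κ requires both charge signs and length ≥ 6 and is undefined otherwise.

## Problem sizes and numerical choices

Test and acceptance computations use: 100-bead chains × 5000 frames for
the scattering oracle, 50-bead × 20000 for size statistics, 200-bead ×
50000 for the ⟨R²ₑₑ⟩/⟨R²g⟩ → 6 property, 10⁴-point two-Gaussian samples
on a 150×150 grid for the landscape, n = 4096 (i.i.d.) and 65536 (AR(1),
ρ = 0.9) series for the blocking calibration.  Nelder–Mead runs with
xatol 1e−12/fatol 1e−14 from a data-scaled start; the Debye sum handles
the i = j and q → 0 limits analytically and chunks frames to bound
memory.  Degenerate inputs raise typed errors rather than returning
partial results (zero-variance ACF/PCA, all-identical KDE points,
positive Guinier slope, infeasible contact targets).

## Known limitations

Synthetic ensembles carry no excluded volume, solvent, or electrostatics;
salt-bridge chemistry resolution covers the standard donor/acceptor atom
nomenclature (Arg/Lys/His, Asp/Glu, SEP/TPO, termini) and custom naming
schemes need explicit atom lists; the DSSP implementation covers the
rules above but not chain breaks or multi-chain bridge partners; CRYSOL-
style hydration-shell modelling, FRET distance distributions and NMR
comparisons are out of scope.
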