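# Methods

This note documents the physical models, the numerical choices behind them,
and the limits of the synthetic structure generators. Units throughout:
lengths in nm, times in fs, energies in eV, masses in unified atomic mass
units, charges in elementary charges.

## Atomic photoabsorption data

All absorption and photoionization calculations use a single bundled table
(`spisim/data/photoabsorption.csv`) of photoabsorption cross sections
σ(E) in cm² for H, C, N, O, S and P on a 200–700 eV grid, densified around
the C and N K edges. The table is generated by
`scripts/make_atomic_table.py` from the Cromer–Liberman relativistic
calculation of the imaginary anomalous scattering factor f″(E) (as
implemented in `gemmi`) via the optical theorem, σ = 2 r_e λ f″. Hydrogen,
outside the Cromer–Liberman domain, uses the exact nonrelativistic
hydrogenic (Stobbe) photoionization cross section. Lookup interpolates
log σ against log E; energies outside the tabulated range raise
`EnergyRangeError` rather than extrapolating. K-edge positions are stored
per element so edge crossings are handled by the bracketed grid, not by the
interpolant.

The Cromer–Liberman values differ at the tens-of-percent level from the
Henke/CXRO tabulation below the carbon edge. This matters for the
water-window contrast calculation and is absorbed into the calibrated
material density (next section); it does not affect any relative or
ratio-based result.

## Water-window contrast (`xray_optics`)

A material is an empirical formula plus a mass density. Its attenuation
coefficient is μ(E) = ρ N_A / M_formula · Σᵢ nᵢ σᵢ(E) and the absorbed
fraction of a slab of thickness t is 1 − exp(−μt). The imaging contrast
between a particle and its water background is reported as the ratio of the
two absorbed fractions at equal thickness.

The virus-like composition CH₁.₅O₀.₅N₀.₂₅P₀.₀₂₅ is a literature-standard
average over capsid protein and nucleic acid. Its density is a calibration
parameter of the package: it is fixed once, by least squares, so that the
500 nm slab contrast pair across the carbon K edge (4.3 nm / 4.4 nm against
water at 1.0 g/cm³) reproduces the accepted water-window contrast values
for such particles. With the bundled cross sections this gives
ρ = 0.877 g/cm³ and a contrast pair of 3.41 above / 0.83 below the edge
(ratio 4.1). The calibrated density is lower than a physical wet-virus
density (~1.1–1.4 g/cm³) precisely because it also absorbs the
Cromer–Liberman/Henke scale difference below the edge; it should be read as
an effective optical density for this table, not as a mass measurement.

The FEL pulse model is a photon count, a wavelength, a top-hat focus
diameter and a Gaussian temporal envelope (FWHM). Peak fluence is photons
per focal area; the temporal profile only matters for time-resolved
ionization sampling.

## Synthetic structures (`synthetic_structures`)

Two generators provide study objects; both are deterministic given a seed.

**Toy protein.** A self-avoiding random walk backbone with 0.38 nm Cα–Cα
steps (non-adjacent backbone points kept ≥ 0.3 nm apart); each residue
carries the average elemental composition {C:5, N:1, O:1, H:8} placed
uniformly within 0.2 nm of its backbone point with a 0.08 nm minimum
interatomic spacing, plus one S per 30 residues. An n-residue protein has
15n + ⌊n/30⌋ atoms and roughly 50 % hydrogen, matching average protein
stoichiometry. It is a geometric stand-in — no secondary structure, no
bonds, no side-chain chemistry — sufficient for ionization statistics and
Coulomb-explosion geometry, not for scattering fine structure.

**Icosahedral particle.** A regular icosahedron (or sphere) of given
diameter voxelized on a cubic grid, with 3³ subsampling of boundary voxels
for antialiased edges and uniform interior electron density taken from the
material composition. The voxel size must be ≤ 1/10 of the target
resolution.

Structure invariants are enforced on construction: finite coordinates,
positive masses consistent with the element list (within 1 %), minimum
interatomic distance 0.05 nm.

PDB ingestion uses fixed-column parsing with occupancy-based altloc
selection and solvent filtering, converts Å to nm, and warns and skips
elements outside the supported set {H, C, N, O, S, P}.

## CDI forward model (`cdi_forward`)

Expected photon count per pixel: I(q) = Φ r_e² ΔΩ P |F(q)|², with Φ the
peak fluence, ΔΩ the pixel solid angle including the cos³(2θ)
oblique-incidence factor, P the polarization factor (≈ 1 at water-window
angles for the small detector), and F the Fourier transform of the electron
density at the pixel's scattering vector. Measured counts are seeded
Poisson draws from the expected plane; the expected plane is always kept.

The default **flat-Ewald** mode takes the 2D FFT of the beam-axis
projection. Three numerical choices make this accurate to a few percent
through the third speckle minimum of a reference sphere:

1. The projection is embedded, centered on its center of mass, in a
   zero-padded array (default: next power of two ≥ 4× the grid, clamped to
   [512, 4096]) so the FFT q-grid oversamples the speckle period before
   interpolation.
2. The *complex* amplitude F, not |F|², is interpolated bilinearly onto
   detector pixels. F passes smoothly through zero at its dark rings, so
   complex interpolation does not fill in the minima the way intensity
   interpolation does; centering removes the fast phase ramp that would
   otherwise defeat this.
3. Each pixel samples the qz = 0 plane at its exact scattering magnitude
   |q| = (4π/λ) sin θ along the transverse direction, leaving only the
   O(θ²) directional error of the flattened sphere.

The **curved** mode samples the 3D FFT of the (cyclically centered) density
on the true Ewald sphere; it agrees with flat mode to within a few percent
at water-window geometry and serves as its cross-check.

Callers must supply an oversampled grid: the occupied bounding box must fit
in half the grid per axis, or `diffract` raises with the required box size.

The geometry's ideal full-period resolution is reported as
d = λ / (2 sin θ) with θ evaluated at the detector half-width (edge
mid-point): 17.2 nm for the 1024² × 75 µm detector at 15 cm and 4.3 nm.
The common back-of-envelope d ≈ λD/(w/2 · p) ≈ 20 nm differs by the
tan→sin distinction; the convention string is attached to every pattern's
metadata.

## Phase retrieval (`phase_retrieval`)

Standard alternating projections: Error Reduction and Hybrid Input–Output
(feedback β = 0.9 default), with a fixed support constraint (must cover
less than half the array), an optional reality constraint (default on) and
an optional positivity constraint (default off; the pipeline enables it for
nonnegative densities). `hio_er` runs a HIO block followed by an ER block,
the usual refinement schedule. Iterates start from seeded random phases
projected onto the support.

Reconstruction quality is scored by `align_and_score`, which removes the
trivial ambiguities — integer translations (FFT cross-correlation),
conjugate point reflection, and a global scalar — by maximizing |corr|,
then reports the relative L2 error ‖αa − b‖/‖b‖.

## Coulomb explosion (`cei_dynamics`)

**Ionization sampling.** Photoionization is an inhomogeneous Poisson
process per atom: the instantaneous rate is σ_eff(E) × (Gaussian pulse
flux), sampled by time-slicing the ±4σ window at 0.1 fs. The effective
cross section scales with remaining electrons, σ_eff = σ_neutral (Z − q)/Z,
and charge is capped at Z. At 4 nm (310 eV) only the carbon K shell is
accessible among the supported elements.

Auger relaxation after K-shell ionization is modeled by `auger_mode`:
`"off"` (primary photoionization only, the default), `"instant"` (one
secondary electron per K vacancy at the photoionization time) or
`"delayed"` (secondary after an exponential τ = 10 fs). The default is
`"off"` because with the package's toy-protein composition primary-only
ionization reproduces the accepted mean ionization (~0.7 e/atom) for the
reference soft-X-ray pulse, while instant Auger gives ~1.15 e/atom; the
Auger modes are kept as an explicit model-sensitivity envelope (they
roughly double the carbon charge) rather than silently folded into the
default. Secondary-electron transport, field ionization and recombination
are not modeled.

**Dynamics.** Velocity-Verlet integration of point ions with the Coulomb
pair force (k = 1.4399645 eV·nm) plus a purely repulsive soft-core term
A/r¹² with A = k(0.05 nm)¹¹ ≈ 7.0×10⁻¹⁵ eV·nm¹², chosen so the soft-core
equals unit-charge Coulomb repulsion at the generators' 0.05 nm minimum
contact distance and is negligible beyond ~0.1 nm; it exists only to
regularize close passes. Forces act only on pairs containing at least one
ion, so a completely neutral structure is exactly static. Ionization
events inject charge at their sampled times during the trajectory.

Two-phase stepping: dt = 0.05 fs while ionization and close encounters are
active, relaxing to dt_far = 0.5 fs after the last event, with an audit of
relative energy drift (bookkeeping includes the potential-energy jump of
each ionization event) and total momentum. Default integration horizon
300 fs, by which the reference pulse's ion kinetic energies are within a
fraction of a percent of asymptotic. The pair kernel is JIT-compiled with
numba when available, with an identical numpy fallback.

**Fragments.** `detect_fragments` links atom pairs closer than 0.25 nm
whose relative kinetic energy is below their pair potential (soft-core
counted for all pairs here, so neutral matter coheres) and takes connected
components. A system is "atomized" when every fragment is a single atom.

**Atomization scan.** Pulse intensity is scaled over a grid
(×1 … ×8000 by default) with several seeds per point; the threshold is the
smallest achieved mean charge per atom at which all seeds atomize. With
this model the threshold sits near 3.5 e/atom, well above
bonded-force-field estimates of 1–1.5 e/atom, because hydrogen is nearly
transparent at 310 eV: neutral hydrogens are dragged along electrostatically
but a non-negligible fraction remains bound in small fragments until the
carbon skeleton is far more highly charged. The reference pulse itself
(scale 1) does not atomize the toy protein. This is a stated model
limitation, not a tuning target.

## Footprints and classification (`footprint_analysis`)

Final ion velocity directions (charge ≥ 1; exact-zero velocities excluded
and counted) are binned on a 40 (elevation) × 80 (azimuth) equal-angle
spherical grid, elevation = asin(vz/|v|). Footprints are compared by the
L2 norm of the difference of the raw flattened count maps (optional
normalization). Note that equal-angle bins have cos(elevation) solid
angle; tests check the isotropic-source row profile against that law.

Embeddings: deterministic sign-fixed PCA, or t-SNE with seeded PCA
initialization and perplexity auto-capped at min(30, (n−1)/3).
Classification runs seeded k-means on the embedding and scores the best
label permutation via the Hungarian algorithm on the contingency table;
degenerate clusterings fall back to chance level with a warning.

The package's replica of the two-protein reproducibility experiment uses
two 70-residue toy proteins (~1050 atoms each, approaching the ion
statistics of small real proteins) × 20 seeded explosions each; PCA +
k-means separates the families with ≥ 95 % accuracy, and the mean
intra-family footprint distance is below the inter-family one.

## Problem sizes and reproducibility

Default problem sizes are the package's own desk-scale choices: 1024²
detector, ≤ 4096² FFTs, ~500–1050-atom toy proteins, 20–40 explosion runs
per experiment. They keep the full pipeline within minutes on one CPU
while leaving every headline quantity measurable at its stated tolerance.

All randomness flows from explicit integer seeds. Pipeline stages derive
per-stage seeds as the first four bytes of SHA-256 of
`"{master}:{stage}"`, reduced mod 2³¹, so stages are independent and runs
are bit-reproducible across platforms.
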