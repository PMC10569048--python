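# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order the analysis pipeline uses
them.

## Units and conventions

Internal units are Å, ps, e, amu and kJ/mol throughout; conversion
happens only at I/O boundaries (GRO velocities arrive in nm/ps and are
converted on read).  kT at 300 K is 2.494 kJ/mol; the Coulomb constant
is k_e = 1389.35 kJ·Å/(mol·e²); multiplying m[amu]·v²[(Å/ps)²] by 0.01
gives kJ/mol.  Helix long axes lie along +z; θ is measured
counterclockwise in the xy-plane, in radians, wrapped to [0, 2π);
interhelical distances d are quoted in nm.  Boxes are orthorhombic,
periodic in all three dimensions, with the z extent matching the
helical repeat so the duplexes continue across the boundary.

The "center of the helix" for cylindrical profiles and for d itself is
a per-frame least-squares line fit (principal component) through the
helix's phosphates.  A fixed axis would smear profiles whenever the
helix drifts; the frame-wise fit is exact for the rigid fixtures and
robust for real trajectories.

## Synthetic fixtures

The generators produce the study conditions every test runs under:

- **Duplex pairs.**  Reduced B-form-like duplexes: two phosphate
  strands per helix on a cylinder of radius 8.9 Å, rise 3.4 Å/bp,
  twist 36°/bp, strand-2 offset 154° (so minor/major grooves subtend
  154°/206°), plus neutral groove-marker pseudo-atoms on the groove
  bisectors.  Each phosphate carries the full −1e backbone charge.
  All-atom detail is deliberately absent: every analysis here consumes
  positions, charges, masses and group labels only.  The default pair
  (20 bp in a 11.8 × 11.8 × 6.8 nm³ box) matches the simulation-scale
  geometry the analyses are designed for.
- **Ion clouds.**  `uniform_bulk` draws a Poisson count at the molar
  concentration and places uniformly outside a 2 Å hard core;
  `helical_groove_chain` places a fixed count at Gaussian scatter
  (σ configurable) around helical guide curves offset 2 Å outward from
  the backbone along the major-groove bisector — an idealisation of
  the continuous cation chains that decorate condensed duplexes.
  Every placement records its parameters so oracles can recover the
  generating distribution.
- **Velocities.**  Maxwell–Boltzmann draws per component with net
  momentum projected out; an Ornstein–Uhlenbeck velocity process
  (relaxation time τ, stationary MB distribution, D = kTτ/m) provides
  a diffusive "ideal-gas" trajectory with analytic spectrum for the
  2PT gas limit.
- **Toy metadynamics.**  Overdamped Langevin dynamics on an analytic
  F(d, θ): a quartic double well in d (default barrier 12 kJ/mol,
  minima near 2.79/3.79 nm, linear tilt 3 kJ/mol/nm making it
  asymmetric) plus k_θ(1 − cos(θ − θ₀)).  The landscape is separable,
  so the exact projected profile — and hence the exact basin-to-basin
  ΔF — is available in closed form.  Hills follow the standard
  well-tempered rule h = h₀·exp(−V_bias/(kT(γ−1))); defaults γ = 10,
  h₀ ≈ 1 kJ/mol, widths (0.06 nm, 0.35 rad), stride 250 steps of
  dt = 2 fs at friction 1.  These sampler settings are fixture
  conditions chosen for a well-converged run on the toy landscape,
  not a claim about any particular production run.  The integrator is
  explicit Euler–Maruyama; very steep walls with low friction can
  overshoot, which the domain check converts into a hard error rather
  than silent corruption.

What the fixtures do **not** emulate: force-field energetics,
sequence-specific base geometry, solvent-mediated correlations, or
finite sampling of a real ion atmosphere.  Green tests therefore
certify the *analysis machinery* (estimators, normalisations,
integrals, reconstructions), not the biology of any particular
sequence.

## Ion atmosphere

Number densities are voxel histograms (default 1 Å) averaged over
frames; by construction the field integrates back to the mean particle
count (asserted to 1e−6).  Cylindrical profiles use 0.5 Å shells with
volume π(λ_out² − λ_in²)·L_z and report mol/L.  The excess-cation
integral needs c_bulk; when not supplied it is estimated as the
volume-weighted mean of the outermost 20 % of λ-bins.  Shell
membership for the R1/R2/R3 charges uses the distance to the *nearest*
DNA atom (minimum image in all three dimensions) — a surface
criterion, not an axial one, which is what makes the shells meaningful
for grooved surfaces.  The per-species report allows both cation-only
and net (cation − anion) excess-charge accounting downstream.

The SDF normalises the nearest-reference-distance histogram by
accessible shell volumes estimated by seeded Monte-Carlo integration
(default 10⁶ points) because those volumes have no closed form around
an irregular surface; occupied bins whose volume estimate carries more
than ~10 % relative error raise an error advising more samples.

## Electrostatics

Φ is a direct vacuum Coulomb sum over the charges assigned to one
helix's shell (relative permittivity configurable, default 1; probes
closer than 0.1 Å to a source are an error).  U_d is defined as the
**cross** energy between the two shell groups — each helix plus every
charged particle within 10 Å of its surface, particles assigned to the
nearer helix, exact ties excluded and logged.  Self-energy within a
group never enters, so U_d isolates how well each dressed helix
screens the other; the 10 Å thickness corresponds to the Debye length
at the salt conditions of interest.  Whether the DNA's own charges
belong to the shell is a switch (`include_dna`, default on).  No Ewald
summation: the shell restriction embodies a screened, short-ranged
picture, and z-periodic images beyond the primary cell are omitted by
design.  Energy-vs-distance profiles are reported as changes relative
to the largest-d (free-state) bin.

## Hydration

S_g uses the four nearest water oxygens regardless of distance
(minimum image); waters whose fourth neighbour is beyond 5 Å are
skipped and counted rather than polluting the average.  The 3/32
normalisation bounds S_g to [0, 1]; isotropic random neighbours give
⟨S_g⟩ = 1/4 exactly (E[(cos Ψ + 1/3)²] = 4/9 per pair), which the
tests exploit as a Monte-Carlo oracle.  λ-binned ⟨S_g⟩ profiles use
the same 0.5 Å shells as the concentration profiles; the profile
reports ⟨S_g⟩ itself (small = more tetrahedral).

Hydrogen bonds are geometric: donor-O···acceptor ≤ 3.5 Å and
donor−H···acceptor angle ≥ 150°, both configurable — there is no
universal criterion, and these widely used defaults are stated rather
than hidden.  Without hydrogens the package refuses unless the caller
opts into the O···O distance-only fallback, which is then labelled.

## Entropy

**DoS.**  Mass-weighted velocity autocorrelation (unbiased, zero-padded
FFT) up to a correlation length of min(10 ps, half the window), then a
DCT-I cosine transform; no taper is applied.  The normalisation pins
∫DoS dν to the degree-of-freedom count when the temperature is
estimated from the kinetic energy (the default); an explicitly passed
temperature preserves physical normalisation for partially excited
fixtures.  Undamped spectral lines exactly on the transform grid are
leakage-free; off-grid lines leak, and the non-negativity clip then
slightly inflates integrals — the oscillator fixtures therefore use
grid-aligned frequencies (a fixture choice, not an estimator
requirement; physical VACFs decay and do not suffer this).

**2PT.**  The fluidicity f solves the standard self-consistency
polynomial in the normalised diffusivity
Δ = (2s₀/9N)·√(πkT/m)·ρ^{1/3}·(6/π)^{2/3} by bracketed root-finding
(1e−10); s₀ = 0 short-circuits to f = 0.  The gas-like DoS is the
Lorentzian s₀/(1 + (πs₀ν/6fN)²) carrying exactly 3Nf dof, capped at
the measured total; the solid remainder is clipped at zero with the
clipped weight reported.  Solid dof integrate against the QHO entropy
weight W(βhν); gas dof carry the hard-sphere fluid entropy per dof
(Sackur–Tetrode at density fN/V plus the Carnahan–Starling excess at
packing fraction y = f^{5/2}/Δ^{3/2}), or the rigid-rotor weight for
rotational components.  Water is treated as a rigid 3-site body
(center-of-mass translation + angular velocity about principal axes);
ions are translation-only.

**Macromolecule.**  Whole-molecule translational and rotational
vibrational entropy from quasiharmonic treatment: eigenvalues of the
COM position covariance map to mode frequencies ν = (1/2π)√(kT/Mσ²),
and best-fit (Kabsch) rotation vectors against the mean structure,
expressed in the principal frame, do the same with the moments of
inertia.  Zero-variance (frozen) modes contribute zero entropy.  The
topographical term is omitted — negligible for a well-defined double
helix — and the multiscale cell hierarchy below the whole-molecule
level is out of scope, a deliberate simplification.

**Reports.**  −TΔS per component (cation: 2PT atomic; DNA:
quasiharmonic; water: 2PT rigid) between the condensed and free
states, block-averaged over 5 equal blocks by default with the
standard error across blocks as the uncertainty; the total row is the
component sum by construction.  Whole-duplex atoms define "DNA".

## Free-energy surfaces

Bias reconstruction sums the recorded Gaussians on a (d, θ) grid
(defaults 0.02 nm × 2°), truncated at 3σ, with ±2π image hills making
θ exactly periodic (truncation error ≤ e^{−4.5} ≈ 1 % of a hill's
peak).  F = −γ/(γ−1)·V_bias shifted so min F = 0; γ = ∞ (non-tempered
hills files without a bias-factor column) reduces to F = −V.  The 1D
profile is the Boltzmann projection at the run temperature, not a
slice.  ΔF between the bound and free distances uses linear
interpolation — the profiles are smooth at the default grid and
higher-order schemes invite overshoot at well edges — and the per-bp
helper applies linear length additivity.  Minima are grid-local minima
with θ-periodic neighbourhoods, refined by three-point quadratic fits;
θ is reported raw in [0, 2π), with no reduction by helical symmetry.
Convergence diagnostics combine hill-height decay (asymptote flag:
final-quarter mean below 20 % of the first-quarter mean, fraction
configurable) with the spread of ΔF across cumulative-checkpoint
reconstructions.

## Pipeline

Frames are binned by per-frame d at δd = 0.5 Å (defaults span
2.4–4.05 nm; condensed state 2.8 nm, free state 4.0 nm, 500-snapshot
budget); the path table reports ΔN_water(R1), ΔN_HB(R1), ΔN_cation(R3),
N_cation(R2) and ΔU_d per bin, all relative to the largest-d occupied
bin.  Raw binning — not bias reweighting — selects the snapshots; a
failing observable marks its column absent and the run continues.
`full_report` isolates stage failures, writes TSV artifacts plus a
JSON provenance manifest (seed, path spec, config hash), and is
byte-deterministic under a fixed seed.  The package is library-first:
the pipeline functions and the `examples/` scripts are the operational
interface, and all I/O goes through documented readers/writers rather
than a shell entry point.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
fixtures sized for desk-scale verification: 10–20 bp duplex pairs,
10²–10³ ions/waters, velocity windows of ~10³–10⁴ frames, and toy
metadynamics runs of 1.5–3 × 10⁵ Langevin steps (600–1700 hills).
These sizes were chosen so each closed-form comparison resolves well
inside its stated tolerance; all estimators accept arbitrarily larger
windows unchanged.

## Known limitations

- Electrostatics is real-space and unscreened within the shell; no
  Ewald/PME, no dielectric continuum.  Absolute U_d values for bare
  fixtures are therefore large; the physically meaningful quantity is
  ΔU_d along the path with the atmosphere included.
- The DoS estimator assumes a uniform timestep and stationary
  dynamics within the window; it does not deconvolve thermostat
  artefacts.
- The quasiharmonic macromolecule terms assume small-angle orientation
  fluctuations about a single reference; they are not valid through
  large conformational transitions.
- The hills reader supports the two-CV whitespace dialect with `#!`
  headers; binary trajectory formats (XTC/DCD) are not part of the
  core contract.
- Fixture waters are rigid 3-site molecules; no polarisation, no
  dissociation, no residence-time kinetics.
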