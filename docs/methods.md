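# Methods

This note documents the models, numerical choices and defaults behind
`neotrap`, in the spirit of a methods section: what is computed, under which
assumptions, and what the synthetic data can and cannot tell you.

## 1. Continuum electrokinetic model

### Geometry

The computational domain is an axisymmetric r–z slice: a solid membrane slab
(20 nm SiN plus a 5 nm lipid coat on each face, 30 nm total) pierced by a
cylindrical pore (10 nm bare radius, 5 nm effective radius after coating),
with cylindrical reservoirs above (cis) and below (trans), 120 nm radius and
100 nm depth by default. The DNA-origami sphere (radius 20 nm) sits over the
pore mouth on the cis side.

**Seating depth.** A rigid sphere exactly tangent to a flat wall touches at
a single point, leaving an open wedge-shaped gap around the contact. That
configuration is numerically pathological — successive mesh refinements
resolve ever more bypass flow through the ever-thinner wedge, so the
through-pore flow never converges — and physically wrong for a docked
origami, which is pressed onto the mouth by the electrophoretic force and
partially enters it (the docked current blockade is deeper than a
surface-resting sphere would produce, indicating helix tips inside the
pore). The sphere centre is therefore lowered by a default seating depth of
2 nm, which closes the contact line; with it the vertical/horizontal flow
ratio changes by <10% between 1.5 nm and 0.75 nm meshes. The seating is
identical for both orientations, so the vertical/horizontal comparison
remains a pure permeability-tensor contrast.

### Origami material model

Resolving individual 1–2 nm nanochannels would require sub-Angstrom meshes
(the Debye length in 1 M KCl is 0.30 nm); instead the sphere is homogenized
as a Brinkman porous medium:

* **Porosity** phi = 0.3: void (nanochannel) fraction of the honeycomb helix
  lattice.
* **Permeability along channels**: capillary bundle, kappa_par =
  phi d_c^2/32 with channel diameter d_c = 1.5 nm → 2.1e-20 m².
* **Permeability across the lattice**: Gebart's transverse-permeability
  formula for a hexagonal array of rods (radius 1.0 nm, the B-DNA radius),
  appropriate at the high rod fraction (0.7) of the lattice → 1.6e-21 m².
  It is clamped to zero at the close-packing limit and capped at
  kappa_par/2 so the anisotropy contract kappa_par > kappa_perp holds over
  the whole admissible porosity range (the dilute-limit rod formula would
  otherwise cross the capillary value at high porosity).
* **Fixed charge**: two elementary charges per 0.34 nm of helix rise smeared
  over the helix cross-section and weighted by the DNA fraction (1−phi):
  rho_f ≈ −2.1e8 C/m³. Charge regulation and Manning condensation are not
  modelled; all reported flow quantities are ratios, which are insensitive
  to the absolute charge scale (flow is close to linear in rho_f).

A *vertical* sphere carries kappa_par on the z axis and kappa_perp radially;
a *horizontal* sphere the reverse. This is the only difference between the
two configurations. (A truly horizontal helix bundle is not axisymmetric;
like the original finite-element treatment, the axisymmetric tensor swap
captures the essential channels-along-flow vs channels-across-flow physics
but not the real 3D pose.)

### Field equations and discretization

Steady Poisson, Nernst–Planck (K+ and Cl−, bulk 1 M, ideal-solution
diffusivities 1.96/2.03e-9 m²/s) and creeping-flow Stokes with a Brinkman
drag −eta kappa^{-1} v inside the sphere. Inertia is dropped deliberately:
Re ~ 1e-5 at nm/mm-per-second scales, so the full Navier–Stokes momentum
balance reduces to Stokes.

The electric body force on the fluid is −(F sum z_i c_i) grad psi — the
*mobile* charge only. The DNA backbone charge is mechanically anchored to
the rigid sphere, so the field's pull on it goes into the solid, not the
fluid; what drives the EOF is the Donnan counter-charge inside the porous
sphere (≈ +2.1e8 C/m³ at equilibrium), exactly as in classical
electro-osmosis through charged porous plugs. Including the fixed charge in
the fluid force would cancel the driving force almost everywhere and
suppress the orientation contrast entirely.

Discretization: structured, graded tensor-product finite volumes (fine band
0.75 nm over the pore/sphere region by default, geometric growth to 8 nm at
the far boundaries; ~57×148 cells for the default domain, well under the
200×400 budget). Ion fluxes use Scharfetter–Gummel exponential fitting
(positivity-preserving, exact at equilibrium); velocities live on a
staggered MAC grid with half-cell wall ghosts for no-slip; the Stokes
saddle-point system is equilibrated and factorized once per mesh. The face
body force uses per-species *logarithmic-mean* concentrations: at discrete
Boltzmann equilibrium the force is then exactly the gradient of the osmotic
pressure RT sum c_i, which the discrete pressure gradient balances, so a
charged sphere at V = 0 produces machine-zero flow and current instead of
spurious Donnan-interface pumping (the standard pitfall of arithmetic-mean
forces on underresolved double layers).
Boundary conditions: potential ±V/2 and bulk concentrations on the trans
(bottom, +V/2) and cis reservoir boundaries, zero normal stress (ghost
p = 0) there, no-slip/no-flux on walls, free slip on the outer radial
boundary, symmetry on the axis. Wall surface charge is configurable and
defaults to 0 (lipid passivation); the Helmholtz–Smoluchowski validation
uses −5 mC/m².

The outer coupling is a Gummel fixed point: Poisson with Boltzmann-damped
densities (Newton inner loop), then the two Nernst–Planck solves, then
Stokes, under-relaxed by 0.3 per block; convergence is a maximum relative
block update below 1e-6 within 200 outer iterations (~100 iterations for
the docked-sphere cases). Non-convergence returns a flagged solution with
the residual history, never a silent answer. After convergence one final
Nernst–Planck pass makes the stored face fluxes exactly conservative, so
the ionic current and flow rate are plane-independent to solver precision.

**Resolution caveat.** At 1 M KCl the double layer (0.30 nm) is thinner than
the finest cell (0.75 nm), so Donnan *interface* layers at the sphere
surface are smeared over a cell. The homogenized EOF is driven by the
sphere's interior charge, not by interface structure, and the quantities
reported (flow ratios, signs, linearity) are robust to this; absolute
currents and flows at strongly underresolved double layers are good to tens
of percent, which is why the solver's quantitative validation uses the
resolvable limits below.

### Validation oracles

* Pressure-driven uncharged channel vs Hagen–Poiseuille (flow within 2%,
  parabolic profile within 2% of peak).
* Charged channel in 10 mM KCl (Debye 3 nm, resolved) vs the
  Helmholtz–Smoluchowski slip velocity with a Grahame zeta potential
  (within 10%).
* Open-pore conductance vs the access+channel resistance formula
  G = sigma_b [4t/(pi d²) + 1/d]^{-1} (within 15%; the solver is an
  ideal-solution model, so sigma_b is the Nernst–Einstein conductivity).
* V = 0 → identically zero current and flow; bias reversal flips both
  signs and the response is Ohmic within 5% in the small-bias window
  (|V| ≲ 10 mV). At larger bias the docked system genuinely rectifies:
  the origami plug's Donnan counter-ion concentration (≈2.2 M) exceeds
  the 1 M bulk, making it a cation-selective membrane on one side of the
  pore, and concentration polarization produces a quadratic nonlinearity
  (measured current asymmetry 3.8% at ±5 mV, 7.7% at ±10 mV, ~45% at
  ±50 mV). Orientation *ratios* at a fixed bias are unaffected.

### Orientation contrast

At +100 mV with the defaults above, Q_vertical/Q_horizontal ≈ 2.5
(2.54 at the 0.75 nm mesh, 2.72 at 1.5 nm). The number is a genuine
prediction of the homogenized model, not a fit: permeabilities, charge and
geometry are set a priori from the lattice geometry. It is sensitive
(tens of percent) to the seating depth, porosity and transverse-permeability
model, so it should be read as "between 2 and 3", matching the qualitative
claim that vertical docking roughly doubles-to-triples the EOF. The bias
voltage for the comparison is fixed at 100 mV (the trapping measurements'
operating point); in the Ohmic regime the ratio is insensitive to this
choice.

## 2. Synthetic current traces

The generator emulates the recordings the analysis pipeline is meant for;
it is first-class, tested code.

* **Kinetics**: continuous-time Markov chain over open / docked / trapped,
  simulated exactly (Gillespie). Bias gating: docking and capture need
  V > 0 (electrophoretic landing, EOF trapping); undocking of an unlocked
  sphere happens at V > 0 with its own rate; ejection is a separate rate
  active at V < 0 (large for bare spheres, zero for cholesterol-locked
  ones); escape is always active. Protocol segment boundaries advance the
  clock and redraw waiting times, valid by memorylessness.
* **Levels**: open-pore current I0, docked level as a fraction of I0,
  trapped level as a fraction of the docked level (default 0.8 — the
  secondary drop is clearly visible in recordings but its exact depth is
  not critical, and all kinetic analyses are level-agnostic). Levels scale
  linearly with the protocol voltage relative to +100 mV, including sign —
  a simplification that ignores any rectification.
* **Noise**: white floor plus 1/f^alpha excess (alpha = 1 by default),
  the latter synthesized spectrally with seeded Gaussian coefficients. The
  1/f excess models the mechanical wobble of the docked sphere; locking the
  sphere reduces it by an order of magnitude.
* **Acquisition**: causal 4-pole Bessel low-pass at 10 kHz, 125 kHz default
  sampling (a typical patch-clamp digitizer rate; the original recordings'
  rate is not documented). Everything is deterministic per seed.

Preset parameterization, all derived from the study's reported numbers:
sigma = 8 pA with SNR = dI/sigma = 32.5 fixes dI = 260 pA, and the 17%
vertical blockade then fixes I0 = 1529 pA. Vertical avidin kinetics:
capture 7.7/s, escape 11/s; horizontal: capture 3.85/s (half), escape
2970/s (270-fold). Uniformly locked avidin: tau = 50 ms at 100 mV, 98-fold
above the bare-sphere baseline. Pink/white split: white sigma ≈ 7.3 pA
(the open-pore floor) with pink A = 1.5 pA² (locked) / 15 pA² (bare),
reproducing total sigma 8 / 13 pA in the 10 kHz band.

**What the generator does not emulate**: capacitive transients at voltage
steps, amplifier dynamics beyond the single Bessel stage, lipid-rupture
noise bursts, protein-conformation substates within trapped events, and
level drift. Passing recovery tests on these traces therefore demonstrates
the estimators' correctness under the stated noise model, not robustness to
every artefact of real recordings.

## 3. Event analysis

* **Level finding**: Gaussian-KDE all-points histogram, peak-picked; each
  level mean is refined as the mean of the samples nearest that mode
  (KDE-bandwidth-independent for separated levels). Modes holding <2% of
  samples are discarded.
* **Detection**: threshold with hysteresis — open at baseline − 5 sigma,
  close at baseline − 2.5 sigma, minimum duration 3 samples. These are
  standard nanopore-analysis defaults; the original study does not state
  its detector. Events truncated by either trace end are censored: dropped
  from dwell statistics (at the trace lengths used the bias from dropping
  is negligible) but still counted as occupied time.
* **Dwell fit**: tau-hat = mean(dwells) — the exact exponential MLE — and
  escape rate 1/tau-hat. Dwells shorter than ~3 filter rise times
  (rise ≈ 0.34/f_c) carry an attenuation flag.
* **Rates**: capture = events per second of *unoccupied* time (waiting-time
  reading of "molecules/s"; normalizing by total time instead is a caller
  choice by passing the unoccupied time of interest). Uncertainties are
  bootstrap SDs (resampling dwells, and inter-event waiting times for the
  capture rate).

Quantification bias at the defaults: the 3-sample minimum duration censors
a fraction 1 − exp(−t_min/tau) of events; at 125 kHz this is <7% even for
the fastest (0.34 ms) preset and <0.1% for slow ones. Rate-recovery tests
run at sampling rates where this bias is inside the bootstrap error.

## 4. Noise metrics

Welch PSD (Hann, half-overlap, 2^14-sample segments by default;
Parseval-closed within 5%); sigma at a stated bandwidth via a zero-phase
brick-wall low-pass (exact sqrt-bandwidth scaling for white noise);
SNR = (I_open − I_dock)/sigma; pink/white decomposition by least squares on
log S over 1 Hz–1 kHz, where the 1/f excess lives.

## 5. Kinetic interpretation

Fold-change tau_a/tau_b; barrier increase ddG = ln(fold) in kBT — a bare
Boltzmann mapping that assumes the attempt frequency is unchanged between
the compared conditions (reasonable when only the escape pathway, not the
well geometry, changes); a 100-fold extension is ln(100) ≈ 4.6 ≈ 5 kBT.
Stokes drag F = 6 pi eta r v: with eta = 1 mPa s, r = 3 nm and the ~5 cm/s
pore-region EOF velocities of the solver, F is a few pN — the scale of the
hydrodynamic trapping force. The mass-scaling fit regresses ln tau on
molecular mass (homoscedastic in log space, matching the exponential mass
dependence); it is validated on synthetic data because per-protein numeric
tables are not available.

## 6. Problem sizes and determinism

Acceptance-style runs use: 3×600 s traces at 50 kHz for the vertical-avidin
rate recovery; 300 s at 125 kHz per orientation for the capture-rate ratio
(higher rate to keep short-dwell censoring mild); 2000-dwell samples for
the MLE ratio checks; 60 s traces for level finding; and the 0.75 nm-band
mesh (~8300 cells) for the two field solves. All randomness flows from the
single `--seed` argument through `numpy.random.default_rng`; reruns are
bit-identical.

## 7. Known limitations

* The axisymmetric tensor swap cannot represent genuinely 3D docking poses.
* Homogenization hides channel-scale structure; absolute currents/flows at
  1 M are semi-quantitative (ratios and signs are the robust outputs).
* Ideal-solution transport (no activity corrections): measured 1 M KCl
  conductivity is ~30% below the Nernst–Einstein value, so absolute
  currents inherit that bias.
* The exponential dwell model is single-pathway; multi-exponential escape
  (e.g. mixed orientations) would need a mixture fit the package does not
  provide.
* The barrier conversion reports relative changes only; absolute trapping
  energies would require the attempt frequency.
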