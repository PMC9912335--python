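# neotrap

Modelling and analysis tools for the **nanopore electro-osmotic trap**
(NEOtrap): a solid-state nanopore with a porous DNA-origami sphere docked on
top, whose electro-osmotic flow (EOF) traps single unmodified proteins in the
pore for label-free sensing.

The package addresses two questions a NEOtrap experimenter faces:

1. **How does the docking orientation of the origami sphere shape the EOF?**
   The origami "sphere" is a bundle of parallel DNA helices with ~1–2 nm
   nanochannels between them; docked *vertically* the channels align with the
   pore axis (easy flow), docked *horizontally* they lie across it (blocked
   flow). `neotrap` solves the coupled Poisson–Nernst–Planck–Stokes equations
   on an axisymmetric finite-volume mesh, with the sphere homogenized as a
   charged Brinkman porous medium with an anisotropic permeability tensor,
   and compares the through-pore flow rate Q per orientation.

2. **What do the current traces say about trapping kinetics?** Docking and
   trapping appear as stepwise current blockades. The package generates
   realistic synthetic traces (three-level telegraph kinetics + white and
   1/f noise + 10 kHz Bessel filtering + voltage-inversion protocols), detects
   events with a threshold/hysteresis detector, fits exponential dwell-time
   distributions by maximum likelihood (tau-hat = mean dwell, escape rate
   = 1/tau), estimates capture rates as events per unoccupied second with
   bootstrap uncertainties, and converts dwell-time fold-changes into
   trapping-barrier changes via ddG = ln(fold) kBT.

It is aimed at nanopore single-molecule labs and at modellers who want a
desk-scale, fully scripted replacement for a finite-element workflow.

## The model in brief

Steady state, axisymmetric (r, z), SI units:

* Poisson: div(eps eps0 grad psi) = −(F sum_i z_i c_i + rho_f), with the
  smeared DNA charge rho_f < 0 inside the origami sphere;
* Nernst–Planck per ion: div(−D_i grad c_i − (z_i F D_i / RT) c_i grad psi
  + c_i v) = 0, discretized with Scharfetter–Gummel fluxes (c_i ≥ 0);
* Stokes–Brinkman: −grad p + eta lap v − eta kappa^{-1} v + f_e = 0,
  div v = 0, with kappa the orientation-dependent permeability tensor and
  f_e = −(F sum_i z_i c_i) grad psi the force of the *mobile* space charge
  (the DNA backbone charge is anchored to the rigid sphere).

Permeabilities come from the channel geometry: along the channels the
capillary-bundle value kappa_par = phi d_c^2 / 32; across the helix lattice
Gebart's transverse flow-past-rods formula. Dwell times of the memoryless
trap are exponential with rate k_escape; capture is Poisson with rate
k_capture per unoccupied second.

## Worked example

Generate a 60 s trace of avidin trapping with a vertically docked sphere,
detect events and fit the kinetics:

```bash
neotrap simulate-trace --preset vertical_avidin --seed 1 --duration 60 \
    --sample-rate 50000 --out avidin.h5
neotrap detect --in avidin.h5 --k 5 --min-dwell 3 --out events.csv
neotrap fit --events events.csv --bootstrap 1000 --seed 1
```

The `detect` step reports (stderr):

```
258 events (baseline 1269.5 pA, sigma 9.08 pA, unoccupied 36.53 s)
```

and `fit` prints:

```json
{
  "tau_s": 0.0909...,
  "rate_per_s": 10.99...,
  "bootstrap_sd_tau_s": 0.0053...,
  "n_events": 258
}
```

i.e. from the docked baseline of ~1269 pA (an 83% level of the ~1529 pA
open-pore current) the detector finds trapping events whose mean dwell of
~91 ms corresponds to an escape rate of ~11 molecules/s — the
vertical-configuration avidin kinetics the trace was generated with — and
the 258 events in ~37 s of unoccupied time give a capture rate near
7 molecules/s. The same toolchain works on the orientation-contrast,
voltage-inversion and docking-level presets (`neotrap simulate-trace --help`
lists them).

The field solver is exposed the same way:

```bash
neotrap simulate-field --orientation vertical --voltage 0.1 --out vert.json
neotrap simulate-field --orientation horizontal --voltage 0.1 --out horiz.json
```

Each JSON reports the ionic current I and the through-pore flow rate Q; the
ratio Q_vertical/Q_horizontal ≈ 2.5 under the default parameterization.

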