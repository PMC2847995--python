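# Methods

This note documents the model assumptions, the numerical choices, and
the design decisions taken where the model description left genuine
freedom.  Nothing here reports a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Membrane model

The spine is treated as a self-contained diffusion compartment: a
sphere of volume `V_spine` (default 0.5 µm³) whose surface is unrolled
onto a flat square with periodic (toroidal) boundaries.  The PSD is a
disk of `psd_fraction` (default 9%) of the membrane area, centred at
the origin; the remainder is the ESM.  Curvature is ignored — on the
sub-micrometre scale of the spine head the metric distortion of the
flat approximation is small compared with the stochastic variability of
the observables.  Receptors are points; excluded volume and
receptor–receptor interactions are not modelled, so particle radii
enter only through the (independently calibrated) binding radius.

Propagation is a fixed-timestep Euler–Maruyama walk: per axis a
Gaussian increment of standard deviation `√(2 D Δt)` with
`D = 0.45 µm²/s` and `Δt = 1 µs` (rms planar step ≈ 1.3 nm, small
against every geometric feature).  Boundary composition order within a
step: toroidal wrap, then the PSD rim rule, then capture.

**PSD rim.** Crossings are detected from the endpoint membership of
the step (start inside, end outside); with probability `p_reflect` the
radial overshoot is folded back (`r → 2 r_PSD − r` along the same
bearing).  Inward crossings always stand.  At 1 µs steps the rms step
is ~0.3% of `r_PSD`, so path-level crossing detection and alternative
reflection micro-rules differ only at that order.

**Capture.** A receptor whose step path passes within σ (default
0.5 nm, evaluated in the membrane plane: receptor tail and scaffold
share the sub-membrane plane) of an unoccupied scaffold binds
irreversibly: the receptor becomes immobile at the scaffold position
and the site is consumed.  Capture is detected on the straight
displacement segment of each step (`capture_mode="segment"`); the
endpoint-only test used by simple fixed-step schemes is available as
`capture_mode="endpoint"`.  Path detection is the better physical
model — a trap should not be jumped over — and its larger effective
cross-section (the segment sweeps ≈ 2.7 × the endpoint disk at the
default step length) brings all three reported half-saturation
variants closer to the published values (reference 733 vs 796 ms,
confined 448 vs 468 ms, patch 769 vs 807 ms at 200/60 replicates).
If several sites are in range the nearest wins; at σ = 0.5 nm
competing candidates essentially never occur, so the matching rule is
immaterial in practice.  Note the rate ↔ radius calibration describes
the endpoint process — consistent with the published conversion
tables — so under path capture σ is the operative swept parameter and
its molar-rate interpretation is nominal.

**Initial placement.**  Receptors are uniform on the square with
rejection of the PSD disk.  Scaffolds are uniform *per unit area* in
the disk (`r = √R · r_PSD`, R ~ U(0,1)).  The alternative, literal
polar transform `r = R · r_PSD` (density ∝ 1/r, centre-biased) is kept
as `disk_mode="radial"`.  The area-uniform choice for the membrane is a
deliberate identification: it reproduces the reported half-saturation
times of the reference, patch and confined variants, whereas the
centre-biased transform is 25–35% slow across all of them, and it is
the only reading consistent with the reported ordering that the
annular (centre/middle-weighted) distribution saturates more slowly
than the uniform one.  The annular sampler's five ring weights are not
publicly tabulated; they default to a flat placeholder and results that
depend on them are indicative only.  The patch distribution rejects the
uniform sampler into five disks of radius 96 nm whose centres sit
194.4 nm from the origin at pentagon vertices (orientation arbitrary by
symmetry).  Point-source release puts three co-located batches
(18/18/19 by default) at radius `d_half = 583.95 nm`; the annular
source uses the neck-contact radius `d_neck = 872.5 nm` (the
conventionally quoted value; recomputing half the square side gives
872.6 nm, both available).

## Rate ↔ radius calibration

A fixed-timestep pair process (relative Gaussian jump with per-axis sd
`s = √(2 D Δt)`, then absorption of all pairs inside σ) realises a
well-defined steady-state absorption rate.  We compute it by a direct
linear solve for the stationary radial pair density: the density
deviation from uniform is propagated by the exact radial Gaussian
kernel on a grid whose cell edges align with σ (25 cells inside σ, 10
when `s > 2σ`), and beyond `σ + 10 s` the profile is pinned to the
continuum harmonic tail `ρ = 1 − b/r`, which is exact there because
free Gaussian steps *are* continuum diffusion and the absorber's
influence is harmonic outside a boundary layer of a few `s`.  The
depletion amplitude `b` is fixed self-consistently through
`k = 4π D b`; both the solved profile and the flux are affine in `b`,
so two solves determine the pair exactly.  The inverse map (rate → σ)
is obtained by bracketed root finding from the two analytic lower
bounds on σ (ballistic and Smoluchowski).  Verification: the published
rate/radius tables are reproduced within 1.8% worst case, a
brute-force periodic-box absorption simulation agrees within sampling
error, and the small-`Δt` limit approaches `4π D σ N_A` from below
(−1.1% at `Δt = 10⁻¹⁰ s` for σ = 0.5 nm, D = 0.45 µm²/s).

## Cleft signalling model

Geometry: 700 × 700 × 22.5 nm box, PSD disk of radius 295.4 nm on the
floor, release point 1 nm below the ceiling centre, `D_glu`
0.2 µm²/ms, reflective floor/ceiling (implemented as repeated
mirroring, required because the 20 nm per-axis step reaches across the
22.5 nm cleft), absorbing side walls.  The timestep defaults to 1 µs;
the binding-radius calibration at this `Δt` absorbs the coarse
discretisation, and the observables are converged in `Δt` (peak open
probability changes by < 1% between 1 µs and 0.1 µs).

**Gating scheme.**  Seven states: C0/C1/C2 closed with 0/1/2 glutamate
bound, O open, C3/C4 desensitised with 1/2 bound, C5 desensitised from
the open state.  Binding steps C0→C1 (k₊₁), C1→C2 (k₊₂), C3→C4 (k₊₃)
consume one glutamate; their reverses release one.  Opening is C2→O
with rate α = 4240 s⁻¹ and closing O→C2 with β = 900 s⁻¹.  The
direction of the α/β pair is fixed by the observable record: the Q10
adjustment scales all constants equally and hence preserves every
equilibrium ratio, so peak open probabilities in the 0.2–0.6 range are
only attainable with an O:C2 equilibrium of α/β ≈ 4.7, not its
inverse.  Temperature adjustment multiplies each constant by
`Q10^(ΔT/10)` with Q10 = 3 and ΔT = 15 °C (factor 3^1.5), which
reproduces the published adjusted column to 0.1%; note the source
kinetics are quoted at 25 °C, for which ΔT to body temperature would
be 12 °C — the 15 °C span is what the published adjusted values
encode, and we keep it.

**Capture at the floor.**  Receptors are points at z = 0.  Glutamate
binds when its end-of-step 3D distance to a binding-competent receptor
is below the state-dependent σ, calibrated per binding step at
`D_mutual = D_glu` (receptors static).  Because the reflective floor
makes only the upper half of the capture sphere accessible, the
calibration targets 2k so that the realised flux per unit concentration
equals the macroscopic constant k (`floor_correction`, default on).
This choice is validated by a dual route: the particle model's
ensemble open-probability curve matches a master-equation integration
driven by the independently measured concentration transient to ~2%.
Unbinding places the freed glutamate at the unbinding radius (default:
the binding radius of the reversed step) in a uniform random
direction, folded into the cleft; geminate recombination is therefore
possible.

**Receptor placement.**  The 100 static PSD receptors are drawn with
the centre-biased polar transform (`disk_mode="radial"`).  Unlike the
membrane model, here the centre-biased mode is the identified
convention: it reproduces all four published open-channel observables
(both constant sets), whereas area-uniform placement underestimates the
peak open probability by ~20%.  The two sub-models are specified in
separate upstream model files, so differing placement conventions
between them is plausible; both modes remain configurable.

**First-order transitions** use the single-jump approximation: leave
probability `1 − exp(−K Δt)` per step, destination proportional to
rates.  The largest `K Δt` in the adjusted scheme at 1 µs is ≈ 0.04; a
warning is emitted above 0.1.

## Compound model

Each cycle: 100 ms of membrane trapping (continuing positions and
occupancies), snapshot of the bound set at 90 ms, then 10 ms of
signalling over the 100 static receptors plus all receptors
incorporated so far (at their scaffold positions, the spine and cleft
PSD disks being identified), carrying kinetic states across cycles.
Mobile receptors still unbound lie in the ESM, outside the cleft
footprint, and are excluded from glutamate interaction.  "Contributing"
new receptors are those that open at least once in a segment; their
lateral distance is measured from the release axis.  The contribution
percentage is evaluated at the peak of the ensemble-mean trace (the
mean of per-replicate-peak ratios gives the same value within
sampling error, as checked during development).

## Ensembles, seeds and problem sizes

Replicate `i` uses seed `base_seed + i`; placement uses NumPy
generators and the compiled kernels use the same integer seeds, so
every run is exactly reproducible.  Ensembles default to 30 replicates.
Half-saturation runs simulate 2 s (the 0.5 crossing lies at ≈ 0.4–0.9 s
in all reported variants; the scaffold-free control runs the full 5 s);
the compound model in the acceptance script uses 10 replicates, and
the script's half-saturation ensembles use 90 replicates because the
30-replicate crossing estimator carries ±25–40 ms of seed-to-seed
spread.  The
half-saturation time is the first linearly interpolated crossing of
0.5 by the ensemble-mean occupied fraction (denominator: the limiting
species count); rise times take the last upward threshold crossing
before the peak, guarding against early stochastic spikes.

The membrane kernel aggregates consecutive free steps into one
Gaussian jump while a receptor is farther than eight aggregate
standard deviations from the PSD interaction zone — an exact identity
for free Brownian motion on the torus (excursion tail probabilities
< 10⁻¹⁴ per jump) — and always resolves the rim region step by step;
it was validated statistically against a step-by-step NumPy
implementation of the public operations.

## What the simulation does and does not emulate

The model captures the spatial structure that compartment (ODE) models
discard: initial receptor/scaffold geometry, diffusive transport into
the PSD, corralling, and the position-dependence of the glutamate
transient.  It does not include endo-/exocytosis or receptor recycling,
dendrite-level diffusion through the spine neck (the neck enters only
as a release location), excluded volume, interactions among receptors,
transporter-mediated glutamate uptake, or postsynaptic currents in
physical units (open counts only).  Agreement of the test suite with
the published observables therefore supports the diffusion-trap
mechanism under these idealisations, not a quantitative model of any
particular synapse.

## Known limitations

- At large ensembles the half-saturation times sit a few percent above
  the published values (reference ≈ 733 vs 710 ms, patch ≈ 769 vs
  700 ms, fully confined ≈ 448 vs 390 ms at 60–200 replicates), the
  confined variant being the most offset; with endpoint capture the
  offsets are roughly twice as large.  The residual is seed-stable and
  survives cross-validation of the kernel against an independent
  implementation, so it reflects some unstated detail of the original
  software's capture or boundary conventions rather than sampling
  error.  Ensemble-to-ensemble spread of the 30-replicate estimator is
  itself ±25–40 ms.
- The compound model's new-receptor contribution at the eighth cycle
  reaches ≈ 17–19%, short of the published "over 20%", while
  reproducing the published lateral-distance table closely; the
  contribution is sensitive to the centre-bias of the static receptor
  pool, which dominates the signal near the release axis.
- The annular scaffold distribution cannot be quantitatively
  reproduced because its ring weights are not published.
- The single-jump kinetic approximation biases fast cascades once
  `K Δt` approaches 1; at the default timestep the worst case is 4%
  of a step's leave probability.
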