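# Methods

`pgcam` models a two-plane Compton camera for prompt-gamma (PG) range
verification in proton therapy and implements the full processing chain
from raw coincidences to distal fall-off metrics. This note documents the
physics model, the synthetic-data generator, the reconstruction
algorithms, the numerical choices, and the limits of what the toy model
can and cannot reproduce.

## Coordinate and unit conventions

Right-handed lab frame; the proton beam runs along +Y; the origin is at
the center of the water phantom. Depth along the beam is reported as
Y + 100 mm, so the phantom entrance face is at depth 0 and the phantom
center at depth 100 mm. Energies are keV, lengths mm, times ns.

## Detector and scene

One module consists of a monolithic 50×50×15 mm³ scatter (S) crystal and
a 2×2 array of 50×50×25 mm³ absorber (A) crystals of LaCl₃, with an
adjustable focal distance F_d (S–A gap, default 15 mm). The standard
scene places four such modules around a 100×100×200 mm³ water phantom,
one facing each beam-parallel lateral surface at a 50 mm air gap (scatter
front faces 100 mm from the beam axis). The 2×2 absorber array is modeled
gap-free, and passive materials (housings, quartz windows, photosensors)
are omitted. Module poses are restricted to axis-aligned orientations;
this covers every scene the package defines while keeping the transport
kernel branch-free.

## Photon physics

Three interaction processes are modeled in the crystals:

* **Compton (incoherent) scattering.** Angles are sampled by rejection
  from the Klein–Nishina differential cross-section (flat envelope equal
  to the forward-scattering value, exact at every energy); the scattered
  energy follows the Compton law with the electron rest energy fixed at
  511.0 keV. The linear attenuation coefficient is the closed-form total
  Klein–Nishina cross-section times the electron density — exact in the
  free-electron approximation (binding effects are a few percent at
  100 keV and negligible above).
* **Photoelectric absorption.** Parametrised per atom as a Z^4.5 power law
  anchored at the standard-compilation value σ_pe(Pb, 100 keV) = 1750 b,
  falling as E⁻³ below 511 keV, E⁻² to 2044 keV and E⁻¹ above. Accurate
  at the tens-of-percent level for the mid-to-high-Z constituents that
  matter (La); K-edge structure is not modeled (the La K-edge at 39 keV
  lies below the transport cutoff).
* **Pair production.** Z² scaling of an energy shape anchored at
  standard-compilation water pair coefficients between 1.25 and 8 MeV.
  An interaction deposits E − 1022 keV locally and launches two
  back-to-back 511 keV annihilation photons (positron range neglected).

Rayleigh scattering, Doppler broadening, electron transport and
bremsstrahlung are deliberately out of scope. Because secondary-electron
energy is deposited locally, events that in reality lose energy through
electron or bremsstrahlung escape are counted as full-energy here; the
consequences are quantified below.

Attenuation tables for LaCl₃ (ρ = 3.86 g/cm³) and water ship as TSV
resources regenerable with `scripts/make_attenuation_tables.py`; lookup
interpolates log-log (linearly for pair production, which is exactly zero
below threshold).

Transport samples exponential free paths against the total attenuation
coefficient and picks the process proportionally to the partial
coefficients. The water phantom is attenuation-only: a photon interacting
in water terminates (no scattered re-emission); a config flag enables
single Compton re-emission for robustness studies. Photons falling below
30 keV inside a crystal are absorbed on the spot (the photoelectric mean
free path there is far below a millimetre); outside a crystal they are
terminated. Deposits below 1 keV are ignored.

An exact direction-thinning scheme skips the transport of photons whose
direction cannot geometrically reach any module (cones covering each
module's bounding sphere); the emission bookkeeping remains that of full
isotropic emission, so efficiencies are unbiased. Thinning is disabled
automatically when phantom re-emission is on.

## Detector response

Per history and crystal, deposits are merged to an energy-weighted
centroid (monolithic-block readout), then smeared: energy with
FWHM(E) = 4.5% · 500 keV · √(E/500 keV) — the single-anchor 1/√E
scintillator-statistics law — positions with 1.5 mm FWHM per axis clamped
to the crystal, and the coincidence time with 0.5 ns FWHM. Each crystal
applies a 100 keV low-energy threshold after smearing. A coincidence
requires an above-threshold S deposit and at least one above-threshold A
deposit in the same module and history; E_a is the add-back sum over that
module's above-threshold absorber crystals and the A position is taken
from the highest-energy absorber crystal. The truth full-energy flag
compares the pre-smearing total module deposit with the emitted energy
(1 keV tolerance).

## PG source model

The standard phantom source emits four discrete lines — 2.3 MeV (¹⁴N),
4.4 MeV (¹²C), 5.25 MeV (¹⁵O) and 6.1 MeV (¹⁶O) with relative yields
0.30/0.35/0.12/0.23 — from depth profiles of the form
(base + slope·z/100 + amp·Gaussian(z_peak, σ_peak)) × erfc-edge(z_f, σ_f),
i.e. a gently rising track plateau, a production bump near the end of the
proton range, and a sharp distal fall-off near 105–107 mm depth (the
carbon and oxygen lines are the most sharply peaked). Transverse spread
is Gaussian with σ = 3 mm; emissions are prompt (t = 0) and isotropic;
the per-proton PG yield above 1 MeV defaults to 0.081 for water. Depths
are drawn by inverse-CDF sampling on a fine (0.005 mm) trapezoid grid,
and the same analytic profiles provide the generator-truth reference for
fall-off metrics. The profile parameters were fixed once to emulate the
qualitative depth–energy correlation of proton-induced PG emission in
water (range ≈ 107 mm for 120 MeV protons).

A uniform-energy (200 keV – 7 MeV) source from a 200 mm cube placed
50 mm from the detector face generates classifier training data; a
parametric background injector (uniform in time and energy) exists for
stress tests only.

## Event selection

The time-of-flight cut keeps events whose S-plane time falls within
[0, 10] ns of the proton bunch; the energy cut selects on the add-back
sum E_s + E_a. The carbon window is 4.3–4.6 MeV; the other single-line
windows (2.20–2.45, 5.10–5.35, 6.00–6.25 MeV) follow the same
150–300 keV-around-the-peak style; `all_pg` spans 1–7 MeV.

## Full-energy classifier

One binary scorer per add-back bin (14 uniform bins, 200 keV – 7 MeV),
trained on class-balanced truth-labelled events with ten features: the
module-local 3-D positions of the S and A hits, E_s, E_a, the Compton
angle from the energies, and the Klein–Nishina probability density of
that angle at E_γ = E_s + E_a. Features are standardized per bin with
training-set statistics. The default scorer is gradient-boosted trees
(xgboost, 140 trees, depth 4, γ = 0.1); a feed-forward alternative
(3×256 rectified-linear layers, logistic output) sits behind the same
interface. Events are accepted at probability ≥ 0.5; kinematically
invalid events score 0. Bins with fewer than 2000 events per class fall
back to pass-through. Training uses 6×10⁸ emissions by default (about
4–10 k events per class per bin given the generator's coincidence yield;
the per-class cap is 5×10⁴). The highest bin (6.5–7 MeV) is populated
almost exclusively by full-energy events in this model, and its minority
class stays below the training minimum; see Limitations.

## Image reconstruction

Each coincidence defines a cone: apex at the S hit, axis from the A hit
toward the S hit, half-angle from the two deposits via the Compton law;
kinematically forbidden events (cos ω < −1) are excluded. The image
plane for a module is the plane containing the beam axis and parallel to
that module's detection planes (the x = 0 plane for the ±x modules, the
z = 0 plane for ±z); images of modules sharing a plane are summed. The
default plane is 200×200 mm²; the pixelation is configurable (200×200
for display-quality images, 100×100 in the standard benchmark runs,
whose 2 mm pitch is well below the 2.5 mm profile bin).

* **Back-projection (BP).** Each pixel receives
  exp(−Δθ²/2σ²), Δθ the angular distance from the cone surface (σ = 1°
  default); per-event weights are normalised to unit sum so each event
  contributes equally. Normalisation is computed on a 2× padded plane
  and the central window returned: normalising over the truncated window
  alone crams the weight of cones exiting the field of view into
  boundary pixels. Cones that never approach the plane (min Δθ > 3σ)
  are skipped and counted.
* **Stochastic origin ensemble (SOE).** Each event's origin starts at a
  uniform pixel of its cone band (Δθ ≤ 1.5° default); each iteration
  performs N single-event Metropolis–Hastings updates proposing a uniform
  band pixel and accepting with A = min(1, (λ′+1)/λ), where λ counts the
  occupancy of the current pixel (including the moving event) and λ′ of
  the proposed one (excluding it). The chain runs on the padded plane;
  1000 iterations by default. The returned image is the mean occupancy
  over the final 10% of iterations — the posterior-mean estimator of the
  stationary chain. A single end-of-chain snapshot
  (``average_fraction=0``) is the lower-level alternative, but at 2×10⁴
  events its stochastic clumping moves the profile maximum by over a
  centimetre between chain seeds, while the averaged estimator is stable
  at the profile-bin level. Either way the image total equals the event
  count.
* **Analytical algorithm (AA).** The spherical-harmonics inversion
  f(s) = Σ_events Σ_{n≤N_max} (2n+1)/(4π H_n(E_γ)) P_n(cos ω) P_n(ŝ·t̂)
  with H_n(E) = ∫ σ_KN(cos ω) P_n²(cos ω) dcos ω over the instrument
  acceptance ω ∈ [10°, 110°] (configurable; the acceptance bounds are a
  genuinely open choice and are flagged here deliberately). H_n is
  precomputed by Gauss–Legendre quadrature of order ≥ 2(N_max+1) — exact
  for the polynomial factor — on a 50 keV grid over 200–7000 keV and
  interpolated linearly in energy; N_max = 70 by default. Events with ω
  outside the acceptance are excluded, matching the kernel
  normalisation. Raw (possibly negative) pixel values are retained; a
  compiled kernel evaluates the Legendre recurrence per pixel, and a
  naive vectorised reference implementation backs the equality test.

## Depth profiles and fall-off metrics

Images are projected along the beam axis over a 40 mm central transverse
band (beam σ = 3 mm plus the imaging point-spread function; the full
extent is available but lets off-beam cone-ring residue — the transverse
caustics of individual cone ellipses — contaminate the depth profile).
Pixel columns are rebinned into 2.5 mm profile bins with
fractional-overlap weights: center-assignment aliases badly whenever the
pixel pitch does not divide the profile pitch. Negative AA values are
clipped after projection.

Metrics: Max is the center of the maximal bin (lowest index on ties);
F90/F80/F50 are found by scanning distally from the maximum for the
first crossing below the corresponding fraction of the maximum and
interpolating linearly between bin centers. Profile comparisons report
signed recon − truth deviations; replicate runs with independent seeds
give mean and spread.

## Determinism

Every run consumes a single integer seed fanned out to per-stage child
seeds through `numpy.random.SeedSequence` with fixed indices, so a given
configuration and seed reproduce event lists and SOE images bit-exactly.
The compiled transport kernel seeds its own generator from the same
fan-out. Argmax ties resolve to the lowest linear pixel index.

## Benchmark problem sizes

The standard desk-scale study conditions, used by the test suite and the
acceptance script alike: 2×10⁵ histories for the 1 MeV point-source
efficiency; 9×10⁷ emissions per phantom run (≈2.7×10⁴ carbon-window
coincidences); two independent phantom seeds for the replicate protocol;
6×10⁸ / 1.5×10⁸ emissions for classifier training / held-out evaluation;
reconstruction on 100×100 pixels with N_max = 70 and 1000 SOE iterations.
The three-algorithm maximum-recovery benchmark images the
full-energy-deposition subset of the carbon-window selection (the
reference comparison of BP/SOE/AA resolution is defined on full-energy
events); the fall-off benchmark uses the ML-filtered four-line selection.

## What the generator does and does not emulate

It emulates: discrete PG lines with depth-correlated emission and a sharp
distal fall-off, realistic energy/position/time resolutions and
thresholds, add-back spectra with full-energy peaks and partial-deposit
continua, single/double-escape topology at high energy, and
water-attenuation shadowing. It does not emulate: secondary-electron and
bremsstrahlung escape (so full-energy fractions are systematically high —
measured ≈58% at 1 MeV and ≈19% at 7 MeV against ≈47% and ≈5% for full
electron-tracking transport), neutron-induced backgrounds and their time
structure, phantom-scatter re-emission (off by default), passive
materials, and proton transport itself (the depth profiles are a
parametric stand-in, not a nuclear-reaction model). Passing tests
therefore demonstrate the correctness of the processing chain and the
reconstruction algorithms under controlled conditions — not dosimetric
realism of the detector response to a clinical beam.

## Known limitations

* Full-energy fractions inflated by locally deposited electron energy
  (above); this also raises the prior full-energy purity of the top
  add-back bin, capping the attainable classifier purity gain there.
* Attenuation coefficients for photoelectric absorption and pair
  production are anchored parametrisations (tens of percent), so
  absolute efficiencies carry that uncertainty; Compton coefficients are
  exact in the free-electron limit.
* The classifier's top energy bin cannot assemble the minimum balanced
  training sample at desk scale and falls back to pass-through.
* Multi-interaction centroiding in the monolithic crystals biases cone
  axes for a subset of events; this is physical for monolithic readout
  but is not separated from resolution effects in the response model.
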