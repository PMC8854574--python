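# pgcam

A two-plane Compton-camera toolkit for prompt-gamma (PG) range
verification in proton therapy. Protons stop at the Bragg peak, and the
prompt γ rays emitted by nuclear reactions along the track — dominated by
discrete lines at 2.3 MeV (¹⁴N), 4.4 MeV (¹²C), 5.25 MeV (¹⁵O) and
6.1 MeV (¹⁶O) — fall off sharply at the end of the proton range. A
Compton camera images this emission without passive collimation: each
coincidence between its scatter (S) and absorber (A) planes constrains
the photon origin to a cone with apex at the S hit, axis through the two
hits, and half-angle ω from the deposits via

    cos ω = 1 − m_e c² (1/E_a − 1/(E_s + E_a)),

valid when the photon deposits its full energy across the two planes.

The package is aimed at detector physicists and algorithm developers who
need a controlled, truth-labelled test bed for Compton-imaging processing
chains. It provides:

* a fast toy photon-transport Monte Carlo (Klein–Nishina scattering,
  photoelectric absorption, pair production; numba-compiled) that
  generates S&A coincidences with realistic resolutions, thresholds and
  truth labels for a four-module camera around a water phantom;
* event selection (10 ns time-of-flight cut, add-back energy windows);
* machine-learning identification of full-energy events (per-energy-bin
  gradient-boosted trees at a 0.5 probability threshold);
* three image-reconstruction algorithms: cone back-projection (BP), the
  stochastic origin ensemble (SOE, Metropolis–Hastings with acceptance
  min(1, (λ′+1)/λ)), and the analytical spherical-harmonics inversion
  (AA) with precomputed Klein–Nishina angular moments H_n;
* beam-axis depth profiles with the distal fall-off metrics Max, F90,
  F80, F50 (linearly interpolated crossings below the profile maximum).

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Simulate the standard scene (120 MeV-proton-like PG source in a water
phantom, four modules), select the 4.4 MeV carbon line, reconstruct with
the analytical algorithm, and read off the fall-off metrics:

```python
import numpy as np
from pgcam import (build_default_scene, default_pg_source, run_simulation,
                   SelectionCriteria, select_events, precompute_hn)
from pgcam.recon import reconstruct_planes
from pgcam.profiles import (project_profile, combine_profiles,
                            falloff_metrics, truth_profile, compare_profiles)

scene = build_default_scene()          # 4 modules, F_d = 15 mm
source = default_pg_source()           # 4 PG lines, fall-off near 107 mm
sim = run_simulation(scene, source, 20_000_000, seed=11)
print(f"{sim.n_events} coincidences, {sim.efficiency_per_proton:.2e} per proton")

sel, report = select_events(sim.events, SelectionCriteria.from_preset("c12"))
fe = sel[sel.full_energy]          # truth-flagged full-energy deposits
print(f"{len(sel)} in the carbon window, {len(fe)} full-energy")
planes = reconstruct_planes(fe, scene, "aa", n_pixels=100,
                            table=precompute_hn(n_max=70), n_max=70)
prof = combine_profiles([project_profile(img) for img in planes.values()])
prof.values = np.clip(prof.values, 0.0, None)
print({k: round(v, 2) for k, v in falloff_metrics(prof).items()})
print({k: round(v, 2) for k, v in
       compare_profiles(prof, truth_profile(source, lines=(4400.0,))).items()})
```

Output (seed 11):

```
51566 coincidences, 2.09e-04 per proton
5903 in the carbon window, 4579 full-energy
{'Max': 96.25, 'F90': 102.7, 'F80': 104.44, 'F50': 107.81}
{'dMax': -2.5, 'dF90': 2.52, 'dF80': 3.0, 'dF50': 4.03}
```

`Max` is the profile-maximum bin center in depth (mm, phantom entrance at
0); the reconstruction places the emission maximum 2.5 mm proximal of the
generator truth (98.75 mm) and recovers the 80% and 50% distal fall-off
positions to 3–4 mm at this modest event count (the benchmark runs in
`scripts/acceptance.py` use ~4× the statistics and land within ~1–3 mm) —
the scale that matters for range verification. The per-proton coincidence
efficiency (~2×10⁻⁴) counts all S&A coincidences per incident proton
given the configured PG yield.

A `pgcam` command-line interface wraps the same chain
(`pgcam simulate`, `select`, `train-classifier`, `classify`,
`reconstruct`, `profile`, `run-all`); see `pgcam --help`.

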