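"""Synthetic coincidence-event generator.

Samples prompt-gamma (PG) emissions, transports the photons through the
phantom and crystals with the compiled kernel in :mod:`pgcam._transport`,
applies the detector response (energy/position/time resolution and the
per-crystal low-energy threshold) and assembles truth-labelled
scatter-absorber (S&A) coincidences.

The default PG source emits the four discrete lines at 2.3 MeV (14N),
4.4 MeV (12C), 5.25 MeV (15O) and 6.1 MeV (16O) with depth-emission
profiles exhibiting a sharp distal fall-off near 107 mm depth and a
transverse Gaussian spread of sigma = 3 mm, emulating the emission pattern
of a 120 MeV proton pencil beam in water (0.081 PG per proton above 1 MeV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erfc

from pgcam import _transport
from pgcam.constants import C_MM_PER_NS, FWHM_OVER_SIGMA
from pgcam.geometry import Scene
from pgcam.physics import AttenuationTable, load_attenuation_table

__all__ = [
    "DepthProfileSpec",
    "EmissionLine",
    "LineDepthSource",
    "PointSource",
    "UniformCubeSource",
    "ResponseModel",
    "PhotonHit",
    "SimulationResult",
    "default_pg_source",
    "sample_emissions",
    "sample_emission",
    "transport_photon",
    "apply_response",
    "build_coincidences",
    "run_simulation",
    "inject_background",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = [
    "module",
    "xs",
    "ys",
    "zs",
    "xa",
    "ya",
    "za",
    "Es_keV",
    "Ea_keV",
    "t_ns",
    "truth_E_keV",
    "truth_x",
    "truth_y",
    "truth_z",
    "full_energy",
    "particle",
]


# ---------------------------------------------------------------------------
# Source models


@dataclass(frozen=True)
class DepthProfileSpec:
    """Analytic 1-D emission profile over depth z (mm, phantom entrance at 0).

    A gently rising plateau plus a Gaussian production bump near the end of
    the proton range, multiplied by a complementary-error-function distal
    fall-off:  f(z) = (base + slope z/100 + amp G(z)) * erfc-edge(z).
    """

    base: float = 1.0
    slope: float = 0.35
    amp: float = 1.5
    z_peak: float = 98.0
    sigma_peak: float = 4.0
    z_falloff: float = 105.5
    sigma_falloff: float = 1.7
    z_max: float = 120.0

    def __call__(self, z):
        z = np.asarray(z, float)
        body = self.base + self.slope * z / 100.0 + self.amp * np.exp(
            -0.5 * ((z - self.z_peak) / self.sigma_peak) ** 2
        )
        edge = 0.5 * erfc((z - self.z_falloff) / (math.sqrt(2.0) * self.sigma_falloff))
        out = np.where((z >= 0.0) & (z <= self.z_max), body * edge, 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class EmissionLine:
    energy_kev: float
    relative_yield: float
    profile: DepthProfileSpec


def default_pg_source() -> "LineDepthSource":
    """The standard 4-line phantom source."""
    lines = [
        EmissionLine(2300.0, 0.30, DepthProfileSpec(base=1.0, slope=0.30, amp=0.8, z_peak=95.0, sigma_peak=6.0, z_falloff=104.0, sigma_falloff=3.0)),
        EmissionLine(4400.0, 0.35, DepthProfileSpec(base=0.6, slope=0.40, amp=2.0, z_peak=98.0, sigma_peak=4.0, z_falloff=105.5, sigma_falloff=1.6)),
        EmissionLine(5250.0, 0.12, DepthProfileSpec(base=0.8, slope=0.30, amp=1.0, z_peak=96.0, sigma_peak=5.0, z_falloff=104.5, sigma_falloff=2.0)),
        EmissionLine(6100.0, 0.23, DepthProfileSpec(base=0.7, slope=0.30, amp=1.6, z_peak=98.0, sigma_peak=4.0, z_falloff=105.5, sigma_falloff=1.7)),
    ]
    return LineDepthSource(lines=lines)


@dataclass(frozen=True)
class LineDepthSource:
    """Discrete PG lines with per-line depth-emission profiles.

    Depth z runs along +Y with z = y + depth_offset; transverse offsets
    (x, z-lab) are Gaussian with sigma ``transverse_sigma``.
    """

    lines: tuple
    transverse_sigma: float = 3.0
    pg_per_proton: float = 0.081
    depth_offset: float = 100.0

    def __post_init__(self):
        y = np.array([l.relative_yield for l in self.lines], float)
        if np.any(y < 0) or y.sum() <= 0:
            raise ValueError("line yields must be >= 0 and normalizable")

    def line_weights(self) -> np.ndarray:
        y = np.array([l.relative_yield for l in self.lines], float)
        return y / y.sum()

    def sample(self, n, rng):
        w = self.line_weights()
        idx = rng.choice(len(self.lines), size=n, p=w)
        energies = np.array([l.energy_kev for l in self.lines])[idx]
        depth = np.empty(n)
        for k, line in enumerate(self.lines):
            m = idx == k
            if not m.any():
                continue
            zg = np.linspace(0.0, line.profile.z_max, 24_001)
            pdf = line.profile(zg)
            cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]))])
            cdf /= cdf[-1]
            depth[m] = np.interp(rng.random(m.sum()), cdf, zg)
        pos = np.empty((n, 3))
        pos[:, 0] = rng.normal(0.0, self.transverse_sigma, n)
        pos[:, 1] = depth - self.depth_offset
        pos[:, 2] = rng.normal(0.0, self.transverse_sigma, n)
        return pos, energies, np.zeros(n)


@dataclass(frozen=True)
class PointSource:
    """Point-like source; mono-energetic or a discrete line mixture."""

    energy_kev: float = 1000.0
    position: tuple = (0.0, 0.0, 0.0)

    def sample(self, n, rng):
        pos = np.tile(np.asarray(self.position, float), (n, 1))
        return pos, np.full(n, float(self.energy_kev)), np.zeros(n)


@dataclass(frozen=True)
class UniformCubeSource:
    """Uniform-energy emissions from random positions in a cube; the
    classifier-training geometry (200 mm air cube at 50 mm from the
    detector face)."""

    center: tuple = (0.0, 0.0, 0.0)
    half_extent: float = 100.0
    e_min: float = 200.0
    e_max: float = 7000.0

    def sample(self, n, rng):
        c = np.asarray(self.center, float)
        pos = c + rng.uniform(-self.half_extent, self.half_extent, (n, 3))
        e = rng.uniform(self.e_min, self.e_max, n)
        return pos, e, np.zeros(n)


def isotropic_directions(n, rng) -> np.ndarray:
    u = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - u * u)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def sample_emissions(model, n, rng):
    """Vectorised emission sampling: (positions, energies, directions, times)."""
    pos, e, t = model.sample(n, rng)
    return pos, e, isotropic_directions(n, rng), t


def sample_emission(model, rng):
    """Single-draw form of :func:`sample_emissions`."""
    pos, e, d, t = sample_emissions(model, 1, rng)
    return pos[0], float(e[0]), d[0], float(t[0])


# ---------------------------------------------------------------------------
# Detector response


@dataclass(frozen=True)
class ResponseModel:
    """Detector response parameters; zero values mean ideal response.

    Energy resolution follows scintillator counting statistics,
    FWHM(E) = fwhm_frac * anchor * sqrt(E / anchor), anchored at 4.5%
    FWHM at 500 keV.  Positions are smeared per axis with 1.5 mm FWHM and
    clamped to the crystal volume; each crystal applies a 100 keV
    low-energy threshold; the coincidence time carries 0.5 ns FWHM jitter.
    """

    energy_fwhm_frac: float = 0.045
    energy_anchor_kev: float = 500.0
    position_fwhm_mm: float = 1.5
    threshold_kev: float = 100.0
    time_fwhm_ns: float = 0.5

    def __post_init__(self):
        for v in (self.energy_fwhm_frac, self.position_fwhm_mm, self.threshold_kev, self.time_fwhm_ns):
            if v < 0:
                raise ValueError("response parameters must be >= 0")

    def energy_fwhm(self, e_kev):
        e = np.asarray(e_kev, float)
        return self.energy_fwhm_frac * self.energy_anchor_kev * np.sqrt(e / self.energy_anchor_kev)

    @classmethod
    def ideal(cls) -> "ResponseModel":
        return cls(energy_fwhm_frac=0.0, position_fwhm_mm=0.0, threshold_kev=0.0, time_fwhm_ns=0.0)


@dataclass(frozen=True)
class PhotonHit:
    crystal_id: int
    position: np.ndarray
    energy_kev: float
    time_ns: float
    history_id: int


# ---------------------------------------------------------------------------
# Internal helpers


def _table_arrays(table: AttenuationTable):
    e = table.energy_kev
    return (
        np.log(e),
        np.log(np.maximum(table.mu_photo, 1e-300)),
        np.log(np.maximum(table.mu_compton, 1e-300)),
        e.copy(),
        table.mu_pair.copy(),
    )


def _scene_arrays(scene: Scene):
    crystals = scene.crystals
    lo = np.array([c.lo for c in crystals])
    hi = np.array([c.hi for c in crystals])
    module_of = np.array([c.module_id for c in crystals], dtype=np.int64)
    is_scatter = np.array([c.role == "scatter" for c in crystals], dtype=bool)
    if scene.has_phantom:
        ph_lo = scene.phantom_center - scene.phantom_half_extents
        ph_hi = scene.phantom_center + scene.phantom_half_extents
    else:
        ph_lo = np.zeros(3)
        ph_hi = np.zeros(3)
    return lo, hi, module_of, is_scatter, ph_lo, ph_hi


def _cone_keep_mask(pos, dirn, scene: Scene) -> np.ndarray:
    """Directions that can geometrically reach some module (bounding-sphere
    cone cover); the complement is guaranteed hit-free and is skipped."""
    keep = np.zeros(len(pos), dtype=bool)
    for m in scene.modules:
        ctr = m.center
        r = m.bounding_radius
        v = ctr[None, :] - pos
        d = np.linalg.norm(v, axis=1)
        inside = d <= r
        with np.errstate(invalid="ignore"):
            cos_min = np.sqrt(np.maximum(0.0, 1.0 - (r / np.maximum(d, 1e-9)) ** 2))
        cosang = np.einsum("ij,ij->i", dirn, v) / np.maximum(d, 1e-9)
        keep |= inside | (cosang >= cos_min)
    return keep


def _transport_arrays(pos, dirn, energy, time0, hist_offset, scene, det_table, ph_table, phantom_mode, seed):
    lo, hi, _, _, ph_lo, ph_hi = _scene_arrays(scene)
    xl = _table_arrays(det_table)
    wa = _table_arrays(ph_table)
    cap = max(4 * len(pos), 1 << 16)
    while True:
        out = tuple(
            np.empty(cap, dtype=dt)
            for dt in (np.int64, np.int32, np.float64, np.float64, np.float64, np.float64, np.float64)
        )
        n = _transport.transport_batch(
            pos,
            dirn,
            energy,
            time0,
            hist_offset,
            lo,
            hi,
            ph_lo,
            ph_hi,
            scene.has_phantom,
            _transport.PHANTOM_SINGLE_SCATTER if phantom_mode == "single_scatter" else _transport.PHANTOM_REMOVAL,
            *xl,
            *wa,
            seed,
            *out,
        )
        if n >= 0:
            return tuple(a[:n] for a in out)
        cap *= 2


def transport_photon(scene, emission, rng, detector_table=None, phantom_mode="removal"):
    """Transport one photon; returns (list of PhotonHit, truth dict).

    ``emission`` is a (position, energy, direction, time) tuple as produced
    by :func:`sample_emission`.
    """
    pos, e, d, t = emission
    d = np.asarray(d, float)
    nrm = np.linalg.norm(d)
    if nrm <= 0:
        raise ValueError("direction must be unit-norm")
    det = detector_table or load_attenuation_table(scene.detector_material)
    ph = load_attenuation_table(scene.phantom_material)
    seed = int(rng.integers(0, 2**31 - 1))
    hist, cid, x, y, z, he, ht = _transport_arrays(
        np.asarray(pos, float)[None, :],
        (d / nrm)[None, :],
        np.array([float(e)]),
        np.array([float(t)]),
        0,
        scene,
        det,
        ph,
        phantom_mode,
        seed,
    )
    hits = [
        PhotonHit(int(cid[i]), np.array([x[i], y[i], z[i]]), float(he[i]), float(ht[i]), int(hist[i]))
        for i in range(len(cid))
    ]
    truth = {"energy_kev": float(e), "position": np.asarray(pos, float), "total_deposit_kev": float(he.sum())}
    return hits, truth


# ---------------------------------------------------------------------------
# Response application and coincidence building


def _group_reduce(keys, *value_cols):
    """Sort-based grouping: returns (unique_keys, start_indices, sorted value columns)."""
    order = np.argsort(keys, kind="stable")
    sk = keys[order]
    boundaries = np.flatnonzero(np.concatenate([[True], sk[1:] != sk[:-1]]))
    return sk[boundaries], boundaries, [c[order] for c in value_cols]


def merge_hits(hist, crystal, x, y, z, e, t, n_crystals):
    """Merge per-crystal deposits within one history to an energy-weighted
    centroid (pre-smearing), keeping the earliest hit time."""
    key = hist * n_crystals + crystal
    uk, starts, (xs, ys, zs, es, ts) = _group_reduce(key, x, y, z, e, t)
    se = np.add.reduceat(es, starts)
    cx = np.add.reduceat(es * xs, starts) / se
    cy = np.add.reduceat(es * ys, starts) / se
    cz = np.add.reduceat(es * zs, starts) / se
    tm = np.minimum.reduceat(ts, starts)
    return uk // n_crystals, (uk % n_crystals).astype(np.int64), cx, cy, cz, se, tm


def apply_response(merged, scene: Scene, model: ResponseModel, rng):
    """Smear merged per-crystal deposits with the detector response and drop
    sub-threshold crystals.  ``merged`` is the tuple from :func:`merge_hits`;
    returns the same layout with smeared values."""
    hist, crystal, cx, cy, cz, e, t = merged
    n = len(hist)
    if n == 0:
        return hist, crystal, cx, cy, cz, e, t
    lo = np.array([c.lo for c in scene.crystals])
    hi = np.array([c.hi for c in scene.crystals])
    if model.energy_fwhm_frac > 0:
        e = e + rng.normal(0.0, 1.0, n) * (model.energy_fwhm(e) / FWHM_OVER_SIGMA)
        e = np.maximum(e, 0.0)
    if model.position_fwhm_mm > 0:
        sig = model.position_fwhm_mm / FWHM_OVER_SIGMA
        cx = np.clip(cx + rng.normal(0.0, sig, n), lo[crystal, 0], hi[crystal, 0])
        cy = np.clip(cy + rng.normal(0.0, sig, n), lo[crystal, 1], hi[crystal, 1])
        cz = np.clip(cz + rng.normal(0.0, sig, n), lo[crystal, 2], hi[crystal, 2])
    if model.time_fwhm_ns > 0:
        t = t + rng.normal(0.0, model.time_fwhm_ns / FWHM_OVER_SIGMA, n)
    keep = e >= model.threshold_kev
    return hist[keep], crystal[keep], cx[keep], cy[keep], cz[keep], e[keep], t[keep]


def build_coincidences(smeared, presmear, scene: Scene, truth_energy, truth_pos, particle="gamma"):
    """Assemble S&A coincidence events per module.

    Requires an above-threshold scatter deposit and at least one
    above-threshold absorber deposit in the same module and history; the
    absorber energy is the add-back sum over that module's above-threshold
    absorber crystals and the absorber position is taken from the
    highest-energy absorber crystal.  Cross-module coincidences are not
    formed.  The truth full-energy flag compares the pre-smearing total
    module deposit with the emitted energy (1 keV tolerance).
    """
    hist, crystal, cx, cy, cz, e, t = smeared
    if len(hist) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    _, _, module_of, is_scatter, _, _ = _scene_arrays(scene)
    n_mod = max(m.module_id for m in scene.modules) + 1
    mod = module_of[crystal]
    key = hist * n_mod + mod

    s_mask = is_scatter[crystal]
    a_mask = ~s_mask
    if not a_mask.any() or not s_mask.any():
        return pd.DataFrame(columns=EVENT_COLUMNS)
    s_key, s_starts, (s_x, s_y, s_z, s_e, s_t) = _group_reduce(
        key[s_mask], cx[s_mask], cy[s_mask], cz[s_mask], e[s_mask], t[s_mask]
    )
    # one scatter crystal per module: each group is a single row, indexed by s_starts
    a_key_all = key[a_mask]
    e_a_all = e[a_mask]
    order = np.lexsort((e_a_all, a_key_all))  # by key, then energy ascending
    ak = a_key_all[order]
    ae = e_a_all[order]
    ax = cx[a_mask][order]
    ay = cy[a_mask][order]
    az = cz[a_mask][order]
    starts = np.flatnonzero(np.concatenate([[True], ak[1:] != ak[:-1]]))
    a_uk = ak[starts]
    a_sum = np.add.reduceat(ae, starts)
    # highest-energy absorber crystal per group = last row of each segment
    best = np.concatenate([starts[1:], [len(ak)]]) - 1
    a_x, a_y, a_z = ax[best], ay[best], az[best]

    common, si, ai = np.intersect1d(s_key, a_uk, return_indices=True)
    if len(common) == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    ev_hist = common // n_mod
    ev_mod = common % n_mod

    # truth: pre-smearing per-module totals
    p_hist, p_crystal, _, _, _, p_e, _ = presmear
    p_key = p_hist * n_mod + module_of[p_crystal]
    pk, p_starts, (pe,) = _group_reduce(p_key, p_e)
    p_tot = np.add.reduceat(pe, p_starts)
    loc = np.minimum(np.searchsorted(pk, common), len(pk) - 1)
    found = pk[loc] == common
    module_total = np.where(found, p_tot[loc], 0.0)
    full = np.abs(module_total - truth_energy[ev_hist]) <= 1.0

    df = pd.DataFrame(
        {
            "module": ev_mod,
            "xs": s_x[s_starts[si]],
            "ys": s_y[s_starts[si]],
            "zs": s_z[s_starts[si]],
            "xa": a_x[ai],
            "ya": a_y[ai],
            "za": a_z[ai],
            "Es_keV": s_e[s_starts[si]],
            "Ea_keV": a_sum[ai],
            "t_ns": s_t[s_starts[si]],
            "truth_E_keV": truth_energy[ev_hist],
            "truth_x": truth_pos[ev_hist, 0],
            "truth_y": truth_pos[ev_hist, 1],
            "truth_z": truth_pos[ev_hist, 2],
            "full_energy": full,
            "particle": particle,
        }
    )
    df.index = ev_hist
    df.index.name = "history"
    return df


# ---------------------------------------------------------------------------
# Full run


@dataclass
class SimulationResult:
    events: pd.DataFrame
    n_histories: int
    seed: int
    scene_hash: str
    efficiency: float
    efficiency_err: float
    efficiency_per_proton: float | None = None
    full_energy_fraction: float | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


def run_simulation(
    scene: Scene,
    source,
    n_histories: int,
    seed: int = 0,
    response: ResponseModel | None = None,
    phantom_mode: str = "removal",
    thin: bool = True,
    batch_size: int = 2_000_000,
    detector_table: AttenuationTable | None = None,
) -> SimulationResult:
    """Stream ``n_histories`` emissions through transport, response and
    coincidence building.

    Direction thinning skips the transport of photons that cannot reach any
    module (exact bounding-sphere cone test); the emission count bookkeeping
    is that of full isotropic emission.  Thinning is disabled automatically
    when phantom single-scatter re-emission is on, because a re-emitted
    photon can reach a module from any initial direction.
    """
    if n_histories <= 0:
        raise ValueError("n_histories must be positive")
    response = response if response is not None else ResponseModel()
    det = detector_table or load_attenuation_table(scene.detector_material)
    ph = load_attenuation_table(scene.phantom_material)
    thin = thin and not (scene.has_phantom and phantom_mode == "single_scatter")
    ss = np.random.SeedSequence(seed)
    n_crystals = len(scene.crystals)

    frames = []
    done = 0
    transported = 0
    while done < n_histories:
        nb = min(batch_size, n_histories - done)
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        kseed = int(child.generate_state(1, dtype=np.uint32)[0])
        pos, energy, t0 = source.sample(nb, rng)
        dirn = isotropic_directions(nb, rng)
        if thin:
            keep = _cone_keep_mask(pos, dirn, scene)
            pos, energy, dirn, t0 = pos[keep], energy[keep], dirn[keep], t0[keep]
        nk = len(energy)
        if nk:
            hist, cid, x, y, z, he, ht = _transport_arrays(
                np.ascontiguousarray(pos),
                np.ascontiguousarray(dirn),
                np.ascontiguousarray(energy, dtype=float),
                np.ascontiguousarray(t0, dtype=float),
                0,
                scene,
                det,
                ph,
                phantom_mode,
                kseed,
            )
            if len(hist):
                merged = merge_hits(hist, cid, x, y, z, he, ht, n_crystals)
                smeared = apply_response(merged, scene, response, rng)
                df = build_coincidences(smeared, merged, scene, energy, pos)
                if len(df):
                    df.index = df.index + transported  # globally unique history ids
                    frames.append(df)
            transported += nk
        done += nb

    events = pd.concat(frames) if frames else pd.DataFrame(columns=EVENT_COLUMNS)
    n_ev = len(events)
    p = n_ev / n_histories
    err = math.sqrt(max(p * (1.0 - p), 0.0) / n_histories)
    per_proton = None
    if scene.has_phantom and hasattr(source, "pg_per_proton"):
        per_proton = p * source.pg_per_proton
    fef = float(events["full_energy"].mean()) if n_ev else None
    return SimulationResult(
        events=events,
        n_histories=n_histories,
        seed=seed,
        scene_hash=scene.scene_hash(),
        efficiency=p,
        efficiency_err=err,
        efficiency_per_proton=per_proton,
        full_energy_fraction=fef,
    )


def inject_background(events: pd.DataFrame, scene: Scene, n: int, rng, t_range=(0.0, 100.0), e_range=(200.0, 7000.0)) -> pd.DataFrame:
    """Append parametric fake events (uniform in time and add-back energy,
    random positions in the crystals) for stress tests; tagged
    ``particle='background'`` and never full-energy."""
    mods = rng.choice([m.module_id for m in scene.modules], n)
    rows = []
    for mid in mods:
        m = scene.module(int(mid))
        s = m.scatter
        a = m.absorbers[int(rng.integers(0, 4))]
        sp = rng.uniform(s.lo, s.hi)
        ap = rng.uniform(a.lo, a.hi)
        e_tot = rng.uniform(*e_range)
        f = rng.uniform(0.1, 0.9)
        rows.append(
            dict(
                module=int(mid),
                xs=sp[0], ys=sp[1], zs=sp[2],
                xa=ap[0], ya=ap[1], za=ap[2],
                Es_keV=e_tot * f, Ea_keV=e_tot * (1 - f),
                t_ns=rng.uniform(*t_range),
                truth_E_keV=np.nan, truth_x=np.nan, truth_y=np.nan, truth_z=np.nan,
                full_energy=False, particle="background",
            )
        )
    bg = pd.DataFrame(rows)
    return pd.concat([events, bg], ignore_index=False)
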