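"""Compton image reconstruction on a 2-D plane.

Three algorithms operating on the event cones (apex at the scatter-plane
hit, axis from the absorber toward the scatter hit, half-angle from the two
energy deposits via the Compton scattering law):

* back-projection (BP): each cone paints a Gaussian-weighted band where it
  intersects the image plane; per-event weights are normalised to unit sum
  before accumulation;
* stochastic origin ensemble (SOE): a Metropolis-Hastings Markov chain that
  reassigns each event's origin uniformly along its cone band and accepts a
  move with A = min(1, (lambda'+1)/lambda), the ratio of local event
  densities at the proposed and current pixels;
* analytical algorithm (AA): the spherical-harmonics inversion
  f(s) = sum_events sum_n (2n+1)/(4 pi H_n) P_n(cos w) P_n(s.t), with the
  energy-dependent Klein-Nishina angular moments H_n precomputed on an
  energy grid.

The image plane used for a module is the plane containing the beam axis
and parallel to that module's detection planes; images from modules
sharing a plane are summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import eval_legendre

from pgcam.geometry import Scene
from pgcam.physics import cos_from_energies, klein_nishina_dcs

__all__ = [
    "ConeParameters",
    "ImageGrid",
    "HnTable",
    "cone_from_event",
    "cones_from_events",
    "backproject",
    "soe_reconstruct",
    "precompute_hn",
    "aa_reconstruct",
    "module_plane_grid",
    "reconstruct_planes",
]


# ---------------------------------------------------------------------------
# Data types


@dataclass
class ConeParameters:
    apex: np.ndarray  # (3,) scatter-plane hit
    axis: np.ndarray  # (3,) unit vector from absorber toward scatter hit
    cos_omega: float
    omega: float
    e_gamma: float
    weight: float = 1.0


@dataclass
class ImageGrid:
    """2-D reconstruction plane; ``values[iu, iv]`` with the v axis along
    the beam (+Y by convention)."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_u: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    axis_v: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    extent_u: float = 200.0
    extent_v: float = 200.0
    n_u: int = 200
    n_v: int = 200
    values: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axis_u = np.asarray(self.axis_u, float)
        self.axis_v = np.asarray(self.axis_v, float)
        if self.values is None:
            self.values = np.zeros((self.n_u, self.n_v))
        if self.values.shape != (self.n_u, self.n_v):
            raise ValueError("values shape must be (n_u, n_v)")

    @property
    def pitch_u(self) -> float:
        return self.extent_u / self.n_u

    @property
    def pitch_v(self) -> float:
        return self.extent_v / self.n_v

    def u_centers(self) -> np.ndarray:
        return (np.arange(self.n_u) + 0.5) * self.pitch_u - self.extent_u / 2.0

    def v_centers(self) -> np.ndarray:
        return (np.arange(self.n_v) + 0.5) * self.pitch_v - self.extent_v / 2.0

    def pixel_centers(self) -> np.ndarray:
        """(n_u * n_v, 3) lab-frame pixel centers, u-major order."""
        u = self.u_centers()
        v = self.v_centers()
        uu, vv = np.meshgrid(u, v, indexing="ij")
        return (
            self.origin[None, :]
            + uu.reshape(-1, 1) * self.axis_u[None, :]
            + vv.reshape(-1, 1) * self.axis_v[None, :]
        )

    def argmax_position(self) -> np.ndarray:
        """Lab position of the maximal pixel (lowest linear index on ties)."""
        i = int(np.argmax(self.values))
        iu, iv = divmod(i, self.n_v)
        return self.origin + self.u_centers()[iu] * self.axis_u + self.v_centers()[iv] * self.axis_v

    def blank_like(self) -> "ImageGrid":
        return ImageGrid(
            origin=self.origin.copy(),
            axis_u=self.axis_u.copy(),
            axis_v=self.axis_v.copy(),
            extent_u=self.extent_u,
            extent_v=self.extent_v,
            n_u=self.n_u,
            n_v=self.n_v,
        )


# ---------------------------------------------------------------------------
# Cones


def cone_from_event(event) -> ConeParameters:
    """Cone parameters of a single coincidence (a mapping or DataFrame row
    with xs..za, Es_keV, Ea_keV fields)."""
    s = np.array([event["xs"], event["ys"], event["zs"]], float)
    a = np.array([event["xa"], event["ya"], event["za"]], float)
    d = s - a
    nrm = float(np.linalg.norm(d))
    if nrm < 1e-9:
        raise ValueError("degenerate cone: coincident scatter and absorber positions")
    ang = cos_from_energies(float(event["Es_keV"]), float(event["Ea_keV"]))
    if not ang.valid:
        raise ValueError("kinematically invalid event")
    return ConeParameters(
        apex=s,
        axis=d / nrm,
        cos_omega=float(ang.cos_omega),
        omega=float(ang.omega),
        e_gamma=float(event["Es_keV"] + event["Ea_keV"]),
    )


def cones_from_events(events: pd.DataFrame):
    """Vectorised cones; silently drops kinematically invalid or degenerate
    events.  Returns (apex (n,3), axis (n,3), omega (n,), e_gamma (n,))."""
    s = events[["xs", "ys", "zs"]].to_numpy(float)
    a = events[["xa", "ya", "za"]].to_numpy(float)
    es = events["Es_keV"].to_numpy(float)
    ea = events["Ea_keV"].to_numpy(float)
    d = s - a
    nrm = np.linalg.norm(d, axis=1)
    ang = cos_from_energies(es, ea)
    good = ang.valid & (nrm > 1e-9)
    return s[good], d[good] / nrm[good, None], np.asarray(ang.omega)[good], (es + ea)[good]


def _angles_to_pixels(px, apex, axis):
    """theta[e, p]: angle between (pixel - apex_e) and axis_e."""
    diff = px[None, :, :] - apex[:, None, :]
    nrm = np.linalg.norm(diff, axis=2)
    cosang = np.einsum("epk,ek->ep", diff, axis) / np.maximum(nrm, 1e-12)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Back-projection


def _padded_grid(grid: ImageGrid, pad_factor: int) -> ImageGrid:
    """Same pitch and center, extents enlarged ``pad_factor`` times."""
    return ImageGrid(
        origin=grid.origin.copy(),
        axis_u=grid.axis_u.copy(),
        axis_v=grid.axis_v.copy(),
        extent_u=grid.extent_u * pad_factor,
        extent_v=grid.extent_v * pad_factor,
        n_u=grid.n_u * pad_factor,
        n_v=grid.n_v * pad_factor,
    )


def _crop_center(values: np.ndarray, grid: ImageGrid, big: ImageGrid) -> np.ndarray:
    ou = (big.n_u - grid.n_u) // 2
    ov = (big.n_v - grid.n_v) // 2
    return values[ou : ou + grid.n_u, ov : ov + grid.n_v]


def backproject(events, grid: ImageGrid, sigma_deg: float = 1.0, chunk: int = 64, pad_factor: int = 2) -> ImageGrid:
    """Gaussian-band cone back-projection onto ``grid``.

    Per-event weights are computed and normalised on a plane enlarged
    ``pad_factor`` times (same pitch) and the central window is returned:
    normalising over the visible window alone would cram the weight of
    cones that exit the field of view into boundary pixels.  Events whose
    cone comes nowhere near the plane (closest angular distance above
    3 sigma) are skipped and counted in ``meta['n_no_intersection']``.
    """
    apex, axis, omega, _ = _as_cones(events)
    out = grid.blank_like()
    if len(omega) == 0:
        out.meta.update(algorithm="bp", n_events=0, warning="no valid events")
        return out
    big = _padded_grid(grid, pad_factor)
    px = big.pixel_centers()
    sigma = math.radians(sigma_deg)
    acc = np.zeros(px.shape[0])
    n_used = 0
    for i in range(0, len(omega), chunk):
        th = _angles_to_pixels(px, apex[i : i + chunk], axis[i : i + chunk])
        d = np.abs(th - omega[i : i + chunk, None])
        near = d.min(axis=1) <= 3.0 * sigma
        if not near.any():
            continue
        w = np.exp(-0.5 * (d[near] / sigma) ** 2)
        s = w.sum(axis=1, keepdims=True)
        np.divide(w, s, out=w, where=s > 0)
        acc += w.sum(axis=0)
        n_used += int(near.sum())
    out.values = _crop_center(acc.reshape(big.n_u, big.n_v), grid, big).copy()
    out.meta.update(
        algorithm="bp",
        n_events=n_used,
        n_no_intersection=int(len(omega) - n_used),
        sigma_deg=sigma_deg,
        pad_factor=pad_factor,
    )
    return out


def _as_cones(events):
    if isinstance(events, tuple):
        return events
    return cones_from_events(events)


# ---------------------------------------------------------------------------
# Stochastic origin ensemble


@njit(cache=True)
def _soe_chain(assign, band_idx, band_off, occ, acc, n_iter, n_average, seed):
    np.random.seed(seed)
    n = assign.size
    for it in range(n_iter):
        for _k in range(n):
            e = np.random.randint(0, n)
            lo = band_off[e]
            hi = band_off[e + 1]
            j = band_idx[lo + np.random.randint(0, hi - lo)]
            cur = assign[e]
            lam = occ[cur]  # includes the moving event
            lamp = occ[j] - 1 if j == cur else occ[j]  # excludes it
            a = (lamp + 1.0) / lam
            if a >= 1.0 or np.random.random() < a:
                occ[cur] -= 1
                occ[j] += 1
                assign[e] = j
        if it >= n_iter - n_average:
            acc += occ


def soe_acceptance(lam: float, lam_prime: float) -> float:
    """Metropolis-Hastings acceptance A = min(1, (lambda'+1)/lambda)."""
    if lam <= 0:
        raise ValueError("current-pixel occupancy must be >= 1")
    return min(1.0, (lam_prime + 1.0) / lam)


def soe_reconstruct(
    events,
    grid: ImageGrid,
    n_iter: int = 1000,
    seed: int = 0,
    delta_theta_deg: float = 1.5,
    chunk: int = 64,
    pad_factor: int = 2,
    average_fraction: float = 0.1,
    return_state: bool = False,
):
    """Stochastic-origin-ensemble reconstruction (occupancy counts image).

    The chain runs on a plane enlarged ``pad_factor`` times so that cone
    bands leaving the field of view are not truncated; the central window
    is returned.  The image is the mean occupancy over the final
    ``average_fraction`` of the iterations — the posterior-mean estimator
    of the stationary chain, much lower-variance than a single end-of-chain
    snapshot (``average_fraction=0`` recovers the single final sample; the
    image total equals the event count either way).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0.0 <= average_fraction <= 1.0:
        raise ValueError("average_fraction must be in [0, 1]")
    apex, axis, omega, _ = _as_cones(events)
    out = grid.blank_like()
    if len(omega) == 0:
        out.meta.update(algorithm="soe", n_events=0, warning="no valid events")
        return out
    big = _padded_grid(grid, pad_factor)
    px = big.pixel_centers()
    dth = math.radians(delta_theta_deg)
    idx_parts = []
    off = [0]
    for i in range(0, len(omega), chunk):
        th = _angles_to_pixels(px, apex[i : i + chunk], axis[i : i + chunk])
        band = np.abs(th - omega[i : i + chunk, None]) <= dth
        for r in range(band.shape[0]):
            ids = np.flatnonzero(band[r])
            idx_parts.append(ids)
            off.append(off[-1] + ids.size)
    band_off = np.array(off, dtype=np.int64)
    band_idx = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=np.int64)
    sizes = np.diff(band_off)
    keep = sizes > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        band_off = np.concatenate([[0], np.cumsum(sizes[keep])])
        band_idx = np.concatenate([idx_parts[i] for i in np.flatnonzero(keep)])
    n_ev = int(keep.sum())
    if n_ev == 0:
        out.meta.update(algorithm="soe", n_events=0, n_dropped=n_dropped, warning="no valid events")
        return out
    rng = np.random.default_rng(seed)
    assign = np.array(
        [band_idx[band_off[e] + rng.integers(0, band_off[e + 1] - band_off[e])] for e in range(n_ev)],
        dtype=np.int64,
    )
    occ = np.bincount(assign, minlength=px.shape[0]).astype(np.int64)
    n_avg = max(1, int(round(average_fraction * n_iter)))
    acc = np.zeros(px.shape[0])
    _soe_chain(assign, band_idx, band_off, occ, acc, int(n_iter), n_avg, int(seed) & 0x7FFFFFFF)
    out.values = _crop_center((acc / n_avg).reshape(big.n_u, big.n_v), grid, big).copy()
    out.meta.update(
        algorithm="soe",
        n_events=n_ev,
        n_dropped=n_dropped,
        n_iter=int(n_iter),
        delta_theta_deg=delta_theta_deg,
        seed=int(seed),
        pad_factor=pad_factor,
    )
    if return_state:
        return out, assign
    return out


# ---------------------------------------------------------------------------
# Analytical algorithm


@dataclass(frozen=True)
class HnTable:
    """Precomputed angular moments H_n(E) of the Klein-Nishina cross-section
    over the instrument's Compton-angle acceptance [omega_min, omega_max]."""

    energies: np.ndarray  # (nE,) keV, ascending
    values: np.ndarray  # (nE, n_max+1)
    omega_min_deg: float
    omega_max_deg: float

    def __post_init__(self):
        if np.any(self.values[:, 0] <= 0):
            raise ValueError("H_0 must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("H_n values must be finite")

    @property
    def n_max(self) -> int:
        return self.values.shape[1] - 1

    def interpolate(self, e_gamma) -> np.ndarray:
        """(n, n_max+1) linear interpolation on the energy grid."""
        e = np.atleast_1d(np.asarray(e_gamma, float))
        out = np.empty((e.size, self.values.shape[1]))
        for n in range(self.values.shape[1]):
            out[:, n] = np.interp(e, self.energies, self.values[:, n])
        return out

    def covers(self, e_gamma) -> np.ndarray:
        e = np.atleast_1d(np.asarray(e_gamma, float))
        return (e >= self.energies[0]) & (e <= self.energies[-1])


def precompute_hn(
    e_grid=None,
    n_max: int = 70,
    omega_min_deg: float = 10.0,
    omega_max_deg: float = 110.0,
    cross_section=None,
    cache_dir=None,
) -> HnTable:
    """H_n(E) = integral of sigma(cos w) P_n(cos w)^2 d cos w over
    [cos omega_max, cos omega_min] by fixed-order Gauss-Legendre quadrature
    (order >= 2 n_max, exact for the polynomial part).

    ``cross_section(E, cos_w)`` defaults to the Klein-Nishina differential
    cross-section; passing ``lambda e, c: np.ones_like(c)`` with the full
    angular range recovers the Legendre orthogonality values 2/(2n+1).
    Results are cached to ``cache_dir`` keyed by the parameters.
    """
    if not (0.0 <= omega_min_deg < omega_max_deg <= 180.0):
        raise ValueError("require 0 <= omega_min < omega_max <= 180 degrees")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if e_grid is None:
        e_grid = np.arange(200.0, 7000.0 + 50.0, 50.0)
    e_grid = np.asarray(e_grid, float)

    cache_path = None
    if cache_dir is not None and cross_section is None:
        key = f"hn_{n_max}_{omega_min_deg:g}_{omega_max_deg:g}_{e_grid[0]:g}_{e_grid[-1]:g}_{e_grid.size}"
        cache_path = Path(cache_dir) / f"{key}.npz"
        if cache_path.is_file():
            z = np.load(cache_path)
            return HnTable(z["energies"], z["values"], float(omega_min_deg), float(omega_max_deg))

    a = math.cos(math.radians(omega_max_deg))
    b = math.cos(math.radians(omega_min_deg))
    order = max(2 * (n_max + 1), 160)
    x0, w0 = np.polynomial.legendre.leggauss(order)
    x = 0.5 * (b - a) * x0 + 0.5 * (a + b)
    w = 0.5 * (b - a) * w0
    pn2 = eval_legendre(np.arange(n_max + 1)[:, None], x[None, :]) ** 2  # (n_max+1, q)
    sig = klein_nishina_dcs if cross_section is None else cross_section
    values = np.empty((e_grid.size, n_max + 1))
    for i, e in enumerate(e_grid):
        s = np.asarray(sig(e, x), float)
        values[i] = pn2 @ (w * s)
    table = HnTable(e_grid, values, float(omega_min_deg), float(omega_max_deg))
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(cache_path, energies=e_grid, values=values)
    return table


@njit(cache=True)
def _aa_kernel(px, apex, axis, coef, out):
    ne = apex.shape[0]
    npx = px.shape[0]
    nmax = coef.shape[1] - 1
    for e in range(ne):
        ax0, ax1, ax2 = axis[e, 0], axis[e, 1], axis[e, 2]
        for p in range(npx):
            sx = px[p, 0] - apex[e, 0]
            sy = px[p, 1] - apex[e, 1]
            sz = px[p, 2] - apex[e, 2]
            nrm = np.sqrt(sx * sx + sy * sy + sz * sz)
            if nrm < 1e-12:
                x = 1.0
            else:
                x = (sx * ax0 + sy * ax1 + sz * ax2) / nrm
                if x > 1.0:
                    x = 1.0
                elif x < -1.0:
                    x = -1.0
            acc = coef[e, 0]
            if nmax >= 1:
                pm1 = 1.0
                pn = x
                acc += coef[e, 1] * pn
                for nn in range(2, nmax + 1):
                    pnext = ((2.0 * nn - 1.0) * x * pn - (nn - 1.0) * pm1) / nn
                    pm1 = pn
                    pn = pnext
                    acc += coef[e, nn] * pn
            out[p] += acc


def _aa_coefficients(omega, e_gamma, table: HnTable, n_max: int):
    n = np.arange(n_max + 1)
    h = table.interpolate(e_gamma)[:, : n_max + 1]
    pcos = eval_legendre(n[None, :], np.cos(omega)[:, None])
    return (2.0 * n[None, :] + 1.0) / (4.0 * np.pi * h) * pcos


def aa_reference(events, grid: ImageGrid, table: HnTable, n_max: int = 70) -> ImageGrid:
    """Naive vectorised evaluation of the analytical inversion (oracle for
    the compiled kernel; identical mathematics)."""
    apex, axis, omega, e_gamma = _as_cones(events)
    ok = table.covers(e_gamma)
    apex, axis, omega, e_gamma = apex[ok], axis[ok], omega[ok], e_gamma[ok]
    coef = _aa_coefficients(omega, e_gamma, table, n_max)
    px = grid.pixel_centers()
    diff = px[None, :, :] - apex[:, None, :]
    nrm = np.linalg.norm(diff, axis=2)
    x = np.clip(np.einsum("epk,ek->ep", diff, axis) / np.maximum(nrm, 1e-12), -1.0, 1.0)
    pn = eval_legendre(np.arange(n_max + 1)[None, None, :], x[:, :, None])  # (ne, npx, n+1)
    acc = np.einsum("epn,en->p", pn, coef)
    out = grid.blank_like()
    out.values = acc.reshape(grid.n_u, grid.n_v)
    out.meta.update(algorithm="aa_reference", n_events=int(len(omega)), n_max=n_max)
    return out


def aa_reconstruct(events, grid: ImageGrid, table: HnTable | None = None, n_max: int = 70) -> ImageGrid:
    """Analytical spherical-harmonics inversion.

    Raw (possibly negative) pixel values are retained; use
    ``np.clip(img.values, 0, None)`` for display or metric computation.
    Events with energies outside the H_n table are skipped and counted in
    ``meta['n_skipped_energy']``.
    """
    if table is None:
        table = precompute_hn(n_max=n_max)
    if n_max > table.n_max:
        raise ValueError(f"table holds orders up to {table.n_max} < n_max={n_max}")
    apex, axis, omega, e_gamma = _as_cones(events)
    out = grid.blank_like()
    ok = table.covers(e_gamma)
    n_skip = int((~ok).sum())
    # only scattering angles inside the instrument acceptance enter the
    # inversion: the kernel normalisation H_n integrates over exactly
    # [omega_min, omega_max]
    in_acc = (omega >= math.radians(table.omega_min_deg)) & (omega <= math.radians(table.omega_max_deg))
    n_out_acc = int((ok & ~in_acc).sum())
    ok = ok & in_acc
    apex, axis, omega, e_gamma = apex[ok], axis[ok], omega[ok], e_gamma[ok]
    if len(omega) == 0:
        out.meta.update(algorithm="aa", n_events=0, n_skipped_energy=n_skip, n_outside_acceptance=n_out_acc, warning="no valid events")
        return out
    coef = _aa_coefficients(omega, e_gamma, table, n_max)
    px = grid.pixel_centers()
    acc = np.zeros(px.shape[0])
    _aa_kernel(px, np.ascontiguousarray(apex), np.ascontiguousarray(axis), np.ascontiguousarray(coef), acc)
    out.values = acc.reshape(grid.n_u, grid.n_v)
    out.meta.update(algorithm="aa", n_events=int(len(omega)), n_skipped_energy=n_skip, n_outside_acceptance=n_out_acc, n_max=n_max)
    return out


# ---------------------------------------------------------------------------
# Scene-level orchestration


def module_plane_grid(scene: Scene, module_id: int, n_pixels: int = 200, extent: float = 200.0) -> ImageGrid:
    """The image plane for a module: contains the beam axis (+Y) and is
    parallel to the module's detection planes."""
    m = scene.module(module_id)
    if m.normal in ("+y", "-y"):
        raise ValueError("modules facing along the beam axis have no beam-containing image plane")
    axis_u = {"+x": np.array([0.0, 0.0, 1.0]), "-x": np.array([0.0, 0.0, 1.0]),
              "+z": np.array([1.0, 0.0, 0.0]), "-z": np.array([1.0, 0.0, 0.0])}[m.normal]
    return ImageGrid(
        origin=np.zeros(3),
        axis_u=axis_u,
        axis_v=np.array([0.0, 1.0, 0.0]),
        extent_u=extent,
        extent_v=extent,
        n_u=n_pixels,
        n_v=n_pixels,
    )


def reconstruct_planes(events: pd.DataFrame, scene: Scene, algorithm: str = "bp", n_pixels: int = 200, extent: float = 200.0, **kw) -> dict:
    """Reconstruct each module's events on its image plane and sum images of
    modules sharing a plane.  Returns {plane_key: ImageGrid} with plane keys
    'x' (the x=0 plane, modules facing +-x) and 'z' (the z=0 plane)."""
    algos = {"bp": backproject, "soe": soe_reconstruct, "aa": aa_reconstruct}
    if algorithm not in algos:
        raise KeyError(f"unknown algorithm {algorithm!r}")
    out: dict = {}
    for m in scene.modules:
        sel = events[events["module"] == m.module_id]
        if not len(sel):
            continue
        key = "x" if m.normal in ("+x", "-x") else "z"
        grid = module_plane_grid(scene, m.module_id, n_pixels=n_pixels, extent=extent)
        img = algos[algorithm](sel, grid, **kw)
        if key in out:
            out[key].values = out[key].values + img.values
            out[key].meta["n_events"] += img.meta.get("n_events", 0)
        else:
            out[key] = img
    return out
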