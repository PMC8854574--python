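"""Photon-interaction physics for the Compton-camera toolkit.

Klein-Nishina differential cross-section and angle sampling, Compton
kinematics in both directions (energy from angle and angle from the two
measured energy deposits), per-process linear attenuation lookup for the
detector and phantom materials, and Legendre polynomial evaluation used by
the analytical image reconstruction.

Units: energies keV, lengths mm, attenuation coefficients per mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import eval_legendre

from pgcam.constants import MEC2

__all__ = [
    "ComptonAngle",
    "AttenuationTable",
    "klein_nishina_dcs",
    "klein_nishina_total",
    "sample_compton_angle",
    "scattered_energy",
    "cos_from_energies",
    "load_attenuation_table",
    "lookup_attenuation",
    "legendre_eval",
]


@dataclass(frozen=True)
class ComptonAngle:
    """A Compton scattering angle; ``valid`` is False when the energy pair
    is kinematically forbidden (cos below -1, e.g. after resolution
    smearing) and the event should be discarded by callers."""

    cos_omega: np.ndarray | float
    omega: np.ndarray | float
    valid: np.ndarray | bool


def klein_nishina_dcs(e_gamma, cos_omega):
    """Relative Klein-Nishina differential cross-section dsigma/dOmega.

    In units of the squared classical electron radius (r_e^2 = 1), so the
    forward-scattering value is 1 for every photon energy:

        dsigma/dOmega = (1/2) P^2 (P + 1/P - sin^2 w),
        P = 1 / (1 + a (1 - cos w)),  a = E / 511 keV.

    Parameters
    ----------
    e_gamma : photon energy, keV (> 0)
    cos_omega : cosine of the scattering angle, in [-1, 1]
    """
    e_gamma = np.asarray(e_gamma, dtype=float)
    cos_omega = np.asarray(cos_omega, dtype=float)
    if np.any(e_gamma <= 0):
        raise ValueError("photon energy must be positive")
    if np.any((cos_omega < -1.0 - 1e-12) | (cos_omega > 1.0 + 1e-12)):
        raise ValueError("cos_omega outside [-1, 1]")
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    alpha = e_gamma / MEC2
    p = 1.0 / (1.0 + alpha * (1.0 - cos_omega))
    sin2 = 1.0 - cos_omega**2
    out = 0.5 * p * p * (p + 1.0 / p - sin2)
    if out.ndim == 0:
        return float(out)
    return out


def klein_nishina_total(e_gamma):
    """Closed-form total Klein-Nishina cross-section, in r_e^2 units.

    Integral of :func:`klein_nishina_dcs` over the full solid angle; tends
    to the Thomson value 8 pi / 3 as E -> 0.
    """
    alpha = np.asarray(e_gamma, dtype=float) / MEC2
    if np.any(alpha <= 0):
        raise ValueError("photon energy must be positive")
    a = alpha
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log1p(2.0 * a) / a)
    t2 = np.log1p(2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    out = 2.0 * np.pi * (t1 + t2 - t3)
    if out.ndim == 0:
        return float(out)
    return out


def sample_compton_angle(e_gamma: float, rng: np.random.Generator, size: int | None = None) -> ComptonAngle:
    """Sample scattering angles distributed per the Klein-Nishina shape.

    Rejection sampling of cos(w) uniform on [-1, 1] against the flat
    envelope 1.0 (the forward-scattering value bounds the relative
    cross-section at every energy).
    """
    if e_gamma <= 0:
        raise ValueError("photon energy must be positive")
    n = 1 if size is None else int(size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        c = rng.uniform(-1.0, 1.0, m)
        u = rng.uniform(0.0, 1.0, m)
        acc = c[u < klein_nishina_dcs(e_gamma, c)]
        take = min(acc.size, n - filled)
        out[filled : filled + take] = acc[:take]
        filled += take
    omega = np.arccos(out)
    if size is None:
        return ComptonAngle(float(out[0]), float(omega[0]), True)
    return ComptonAngle(out, omega, np.ones(n, dtype=bool))


def scattered_energy(e_gamma, cos_omega):
    """Compton scattering law: energy of the scattered photon.

    E' = E / (1 + a (1 - cos w)), a = E / 511 keV; 0 < E' <= E.
    """
    e_gamma = np.asarray(e_gamma, dtype=float)
    cos_omega = np.asarray(cos_omega, dtype=float)
    out = e_gamma / (1.0 + (e_gamma / MEC2) * (1.0 - cos_omega))
    if out.ndim == 0:
        return float(out)
    return out


def cos_from_energies(e_s, e_a) -> ComptonAngle:
    """Scattering angle from the two measured deposits.

    Assuming the photon Compton-scatters in the first plane (deposit
    ``e_s``) and is fully absorbed in the second (deposit ``e_a``), the
    incident energy is the add-back sum and

        cos w = 1 - 511 (1 / E_a - 1 / (E_s + E_a)).

    Resolution smearing (or a wrong full-absorption assumption) can push
    the result below -1; such events are flagged invalid.
    """
    e_s = np.asarray(e_s, dtype=float)
    e_a = np.asarray(e_a, dtype=float)
    if np.any(e_a <= 0) or np.any(e_s < 0):
        raise ValueError("require e_s >= 0 and e_a > 0")
    cos = 1.0 - MEC2 * (1.0 / e_a - 1.0 / (e_s + e_a))
    # tolerate pure floating-point excursions at the backscatter boundary;
    # genuinely forbidden partitions overshoot by far more than an ulp
    valid = cos >= -1.0 - 1e-9
    cos_c = np.clip(cos, -1.0, 1.0)
    omega = np.arccos(cos_c)
    if cos.ndim == 0:
        return ComptonAngle(float(cos), float(omega), bool(valid))
    return ComptonAngle(cos, omega, valid)


def legendre_eval(n, x):
    """Legendre polynomial P_n(x) for integer order n >= 0, x in [-1, 1]."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("order must be >= 0")
    out = eval_legendre(n, x)
    if np.ndim(out) == 0:
        return float(out)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Attenuation tables


@dataclass(frozen=True)
class AttenuationTable:
    """Per-process linear attenuation coefficients on an energy grid.

    Coefficients are per mm; processes are photoelectric absorption,
    incoherent (Compton) scattering and pair production.  Pair production
    is identically zero below the 1022 keV threshold.  Lookup interpolates
    log-log between grid points (linearly for pair production, whose
    coefficient vanishes on part of the grid).
    """

    material: str
    energy_kev: np.ndarray
    mu_photo: np.ndarray
    mu_compton: np.ndarray
    mu_pair: np.ndarray
    density: float  # g/cm^3

    def __post_init__(self):
        e = self.energy_kev
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        for mu in (self.mu_photo, self.mu_compton, self.mu_pair):
            if mu.shape != e.shape or np.any(mu < 0):
                raise ValueError("coefficients must be >= 0 on the energy grid")
        if np.any(self.mu_pair[e < 2.0 * MEC2] != 0.0):
            raise ValueError("pair-production coefficient must vanish below 1022 keV")

    @property
    def mu_total(self) -> np.ndarray:
        return self.mu_photo + self.mu_compton + self.mu_pair


_TABLE_CACHE: dict[str, AttenuationTable] = {}


def load_attenuation_table(material: str) -> AttenuationTable:
    """Load a shipped attenuation table ('water' or 'lacl3')."""
    key = material.lower()
    if key in _TABLE_CACHE:
        return _TABLE_CACHE[key]
    ref = resources.files("pgcam") / "data" / f"attenuation_{key}.tsv"
    if not ref.is_file():
        raise ValueError(f"no attenuation table for material {material!r}")
    density = None
    with ref.open() as fh:
        for line in fh:
            if line.startswith("# density_g_cm3"):
                density = float(line.split("=")[1])
            if not line.startswith("#"):
                break
    data = np.loadtxt(str(ref), comments="#", skiprows=0)
    table = AttenuationTable(
        material=key,
        energy_kev=data[:, 0],
        mu_photo=data[:, 1],
        mu_compton=data[:, 2],
        mu_pair=data[:, 3],
        density=density if density is not None else float("nan"),
    )
    _TABLE_CACHE[key] = table
    return table


def lookup_attenuation(table: AttenuationTable, e_kev):
    """Interpolated per-process attenuation coefficients (per mm) at ``e_kev``.

    Returns a dict with keys ``photo``, ``compton``, ``pair`` and ``total``.
    Photoelectric and Compton coefficients interpolate log-log; pair
    production interpolates linearly in (E, mu) because it is exactly zero
    below threshold.  Energies outside the table range raise.
    """
    e = np.asarray(e_kev, dtype=float)
    grid = table.energy_kev
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise ValueError(
            f"energy outside table range [{grid[0]:g}, {grid[-1]:g}] keV for {table.material}"
        )
    loge = np.log(e)
    loggrid = np.log(grid)

    def _loglog(mu):
        return np.exp(np.interp(loge, loggrid, np.log(np.maximum(mu, 1e-300))))

    photo = _loglog(table.mu_photo)
    compton = _loglog(table.mu_compton)
    pair = np.interp(e, grid, table.mu_pair)
    scalar = e.ndim == 0
    out = {
        "photo": float(photo) if scalar else photo,
        "compton": float(compton) if scalar else compton,
        "pair": float(pair) if scalar else pair,
    }
    out["total"] = out["photo"] + out["compton"] + out["pair"]
    return out
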