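"""Event filtering: time-of-flight cut, add-back energy windows, add-back spectrum.

The TOF cut keeps events whose scatter-plane hit time lies within a window
after the proton bunch (default [0, 10] ns), suppressing slow-neutron
related background; the energy windows select on the add-back sum
E_s + E_a.  Named presets cover the whole PG range (1-7 MeV), the four main
PG lines, and the single 4.4 MeV carbon line (4.3-4.6 MeV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionCriteria", "select_events", "addback_spectrum", "WINDOW_PRESETS"]

# keV windows; only the carbon window is a published number, the other three
# single-line windows follow the same 150-300 keV-around-the-peak style.
WINDOW_PRESETS: dict[str, list[tuple[float, float]]] = {
    "all_pg": [(1000.0, 7000.0)],
    "c12": [(4300.0, 4600.0)],
    "n14": [(2200.0, 2450.0)],
    "o15": [(5100.0, 5350.0)],
    "o16": [(6000.0, 6250.0)],
    "four_lines": [(2200.0, 2450.0), (4300.0, 4600.0), (5100.0, 5350.0), (6000.0, 6250.0)],
}


def _merge_windows(windows):
    ws = sorted((float(a), float(b)) for a, b in windows)
    for a, b in ws:
        if b <= a:
            raise ValueError(f"empty energy window ({a}, {b})")
    merged = []
    for a, b in ws:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass(frozen=True)
class SelectionCriteria:
    """TOF window (ns) plus a set of add-back energy windows (keV)."""

    tof_window: tuple[float, float] | None = (0.0, 10.0)
    energy_windows: tuple = ()

    def __post_init__(self):
        if self.tof_window is not None and self.tof_window[0] < 0:
            raise ValueError("TOF lower bound must be >= 0")
        object.__setattr__(self, "energy_windows", tuple(_merge_windows(self.energy_windows)))

    @classmethod
    def from_preset(cls, name: str, tof_window=(0.0, 10.0)) -> "SelectionCriteria":
        if name not in WINDOW_PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(WINDOW_PRESETS)}")
        return cls(tof_window=tof_window, energy_windows=tuple(WINDOW_PRESETS[name]))

    @property
    def empty(self) -> bool:
        return self.tof_window is None and not self.energy_windows


def select_events(events: pd.DataFrame, criteria: SelectionCriteria):
    """Apply the TOF cut, then the energy windows.

    Returns (filtered events, report) where the report gives kept/dropped
    counts per cut stage; kept + dropped equals the stage input size.
    """
    if criteria.empty:
        warnings.warn("empty selection criteria: returning input unchanged")
        return events, {"input": len(events), "tof": None, "energy": None, "kept": len(events)}
    report: dict = {"input": len(events)}
    out = events
    if criteria.tof_window is not None:
        lo, hi = criteria.tof_window
        m = (out["t_ns"] >= lo) & (out["t_ns"] <= hi)
        report["tof"] = {"kept": int(m.sum()), "dropped": int((~m).sum())}
        out = out[m]
    else:
        report["tof"] = None
    if criteria.energy_windows:
        addback = out["Es_keV"] + out["Ea_keV"]
        m = np.zeros(len(out), dtype=bool)
        for a, b in criteria.energy_windows:
            m |= (addback >= a) & (addback <= b)
        report["energy"] = {"kept": int(m.sum()), "dropped": int((~m).sum())}
        out = out[m]
    else:
        report["energy"] = None
    report["kept"] = len(out)
    return out, report


def addback_spectrum(events: pd.DataFrame, bin_width_kev: float = 10.0, e_range=(0.0, 8000.0)):
    """Histogram of the add-back energy E_s + E_a.

    Half-open bins [lo, hi); counts are conserved for events inside
    ``e_range``.  Returns (counts, edges).
    """
    if bin_width_kev <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(e_range[0], e_range[1] + bin_width_kev, bin_width_kev)
    addback = (events["Es_keV"] + events["Ea_keV"]).to_numpy() if len(events) else np.empty(0)
    counts, _ = np.histogram(addback, bins=edges)
    return counts, edges
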