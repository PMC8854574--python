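"""Readers and writers for event lists, images, profiles and run manifests.

Event lists are columnar: TSV with '#'-prefixed metadata header lines, or
HDF5 with one dataset per column and metadata in root attributes.  Images
are a plain-text matrix plus a JSON sidecar with the plane pose and
reconstruction parameters; profiles are two-column TSV plus a JSON sidecar
with the fall-off metrics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pgcam.profiles import DepthProfile
from pgcam.recon import ImageGrid

__all__ = [
    "read_events",
    "write_events",
    "write_image",
    "read_image",
    "write_profile",
    "read_profile",
    "RunManifest",
]

from pgcam.simulate import EVENT_COLUMNS

_FLOAT_COLS = [c for c in EVENT_COLUMNS if c not in ("module", "full_energy", "particle")]


def write_events(events: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write an event list; format chosen by extension (.tsv or .h5)."""
    path = Path(path)
    meta = dict(metadata or {})
    df = events.reset_index() if events.index.name == "history" else events.reset_index(drop=True)
    cols = (["history"] if "history" in df.columns else []) + EVENT_COLUMNS
    df = df[cols]
    if path.suffix == ".tsv":
        with open(path, "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k} = {v}\n")
            fh.write("\t".join(cols) + "\n")
            fmt = []
            for c in cols:
                if c in _FLOAT_COLS:
                    fmt.append(lambda v: f"{v:.17g}")
                elif c == "full_energy":
                    fmt.append(lambda v: "1" if v else "0")
                else:
                    fmt.append(str)
            for row in df.itertuples(index=False):
                fh.write("\t".join(f(v) for f, v in zip(fmt, row)) + "\n")
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            for c in cols:
                data = df[c].to_numpy()
                if c == "particle":
                    fh.create_dataset(c, data=np.array([s.encode() for s in data]))
                else:
                    fh.create_dataset(c, data=data)
            for k, v in meta.items():
                fh.attrs[k] = v
    else:
        raise ValueError(f"unrecognized event-list format {path.suffix!r}")


def read_events(path):
    """Read an event list; returns (events DataFrame, metadata dict)."""
    path = Path(path)
    if path.suffix == ".tsv":
        meta = {}
        with open(path) as fh:
            pos = 0
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    break
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            cols = {}
            for c in fh.keys():
                data = fh[c][...]
                if data.dtype.kind in ("S", "O"):
                    data = np.array([s.decode() for s in data])
                cols[c] = data
            meta = {k: fh.attrs[k] for k in fh.attrs}
        df = pd.DataFrame(cols)
        order = (["history"] if "history" in df.columns else []) + EVENT_COLUMNS
        df = df[order]
    else:
        raise ValueError(f"unrecognized event-list format {path.suffix!r}")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event list {path} is missing column(s): {', '.join(missing)}")
    df["full_energy"] = df["full_energy"].astype(bool)
    df["module"] = df["module"].astype(np.int64)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    if "history" in df.columns:
        df = df.set_index("history")
    return df, meta


def write_image(image: ImageGrid, path) -> None:
    """Plain-text matrix (values, u-major rows) + JSON pose sidecar."""
    path = Path(path)
    np.savetxt(path, image.values, fmt="%.10g", delimiter="\t")
    sidecar = {
        "origin": image.origin.tolist(),
        "axis_u": image.axis_u.tolist(),
        "axis_v": image.axis_v.tolist(),
        "extent_u": image.extent_u,
        "extent_v": image.extent_v,
        "n_u": image.n_u,
        "n_v": image.n_v,
        "meta": _jsonable(image.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_image(path) -> ImageGrid:
    path = Path(path)
    values = np.loadtxt(path, delimiter="\t")
    sc = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ImageGrid(
        origin=np.array(sc["origin"]),
        axis_u=np.array(sc["axis_u"]),
        axis_v=np.array(sc["axis_v"]),
        extent_u=sc["extent_u"],
        extent_v=sc["extent_v"],
        n_u=sc["n_u"],
        n_v=sc["n_v"],
        values=values,
        meta=sc.get("meta", {}),
    )


def write_profile(profile: DepthProfile, path, metrics: dict | None = None) -> None:
    """Two-column TSV (depth bin center, value) + JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("depth_mm\tvalue\n")
        for c, v in zip(profile.centers, profile.values):
            fh.write(f"{c:.10g}\t{v:.10g}\n")
    sidecar = {
        "edges": profile.edges.tolist(),
        "provenance": profile.provenance,
        "depth_offset": profile.depth_offset,
        "metrics": _jsonable(metrics or {}),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_profile(path) -> DepthProfile:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sc = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DepthProfile(
        edges=np.array(sc["edges"]),
        values=data[:, 1] if data.ndim == 2 else data[None, 1],
        provenance=sc["provenance"],
        depth_offset=sc["depth_offset"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class RunManifest:
    """Provenance record tying every pipeline output to its configuration."""

    config: dict
    seed: int
    versions: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}
    timings: dict = field(default_factory=dict)  # stage -> seconds

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(_jsonable(self.config), sort_keys=True).encode()).hexdigest()[:16]

    def register(self, name: str, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        self.outputs[name] = {"path": str(p), "sha256": digest}

    def save(self, path) -> None:
        payload = {
            "config": _jsonable(self.config),
            "config_hash": self.config_hash,
            "seed": self.seed,
            "versions": self.versions,
            "outputs": self.outputs,
            "timings": self.timings,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(config=d["config"], seed=d["seed"], versions=d["versions"], outputs=d["outputs"], timings=d["timings"])
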