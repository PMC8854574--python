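"""End-to-end pipeline orchestration.

Stages: simulate -> select -> (optional classifier train/apply) ->
reconstruct (one or more algorithms) -> profile -> report.  All randomness
derives from the single run-level seed through fixed-index child seeds, so
stages are individually reproducible; stage outputs already present in the
output directory are reused when ``resume`` is on.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

import pgcam
from pgcam import io as pgio
from pgcam.geometry import build_scene
from pgcam.mlfilter import BinnedClassifier, apply_classifier, evaluate_gain, train_classifier
from pgcam.profiles import combine_profiles, compare_profiles, falloff_metrics, project_profile, truth_profile
from pgcam.recon import precompute_hn, reconstruct_planes
from pgcam.selection import SelectionCriteria, select_events
from pgcam.simulate import (
    LineDepthSource,
    PointSource,
    ResponseModel,
    UniformCubeSource,
    default_pg_source,
    run_simulation,
)

__all__ = ["pipeline_run", "build_source", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scene": {"preset": "default", "focal_distance": 15.0},
    "source": {"preset": "pg_water"},
    "simulate": {"n_histories": 1_000_000, "phantom_mode": "removal"},
    "select": {"preset": "four_lines", "tof": [0.0, 10.0]},
    "classifier": {"enabled": False},
    "reconstruct": {"algorithms": ["bp"], "n_pixels": 200, "n_iter": 1000, "n_max": 70, "sigma_deg": 1.0, "delta_theta_deg": 1.5},
    "profile": {"pitch": 2.5},
}

# fixed child-seed indices for stage-level reproducibility
_STAGE_SEED = {"simulate": 0, "train": 1, "soe": 2, "train_sim": 3}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def build_source(cfg: dict):
    preset = cfg.get("preset", "pg_water")
    if preset == "pg_water":
        return default_pg_source()
    if preset == "point":
        return PointSource(energy_kev=cfg.get("energy_kev", 1000.0), position=tuple(cfg.get("position", (0, 0, 0))))
    if preset == "cube":
        return UniformCubeSource(
            center=tuple(cfg.get("center", (0, 0, 0))),
            half_extent=cfg.get("half_extent", 100.0),
            e_min=cfg.get("e_min", 200.0),
            e_max=cfg.get("e_max", 7000.0),
        )
    raise KeyError(f"unknown source preset {preset!r}")


def _stage_seed(seed: int, stage: str) -> int:
    child = np.random.SeedSequence(seed).spawn(max(_STAGE_SEED.values()) + 1)[_STAGE_SEED[stage]]
    return int(child.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def pipeline_run(config: dict, output_dir, resume: bool = False) -> dict:
    """Run the configured pipeline; writes artifacts + manifest to
    ``output_dir`` and returns the in-memory results."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = pgio.RunManifest(config=cfg, seed=seed, versions={"pgcam": pgcam.__version__})
    results: dict = {"config": cfg}

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        finally:
            manifest.timings[stage] = round(time.perf_counter() - t0, 3)

    scene = build_scene(cfg["scene"])
    source = build_source(cfg["source"])

    # --- simulate ---
    ev_path = out / "events.tsv"
    if resume and ev_path.exists():
        events, _ = pgio.read_events(ev_path)
        sim = None
    else:
        def _sim():
            return run_simulation(
                scene,
                source,
                int(cfg["simulate"]["n_histories"]),
                seed=_stage_seed(seed, "simulate"),
                phantom_mode=cfg["simulate"].get("phantom_mode", "removal"),
            )

        sim = timed("simulate", _sim)
        events = sim.events
        pgio.write_events(
            events,
            ev_path,
            metadata={"scene_hash": scene.scene_hash(), "seed": seed, "n_histories": sim.n_histories},
        )
        manifest.register("events", ev_path)
    results["events"] = events
    if sim is not None:
        results["efficiency"] = sim.efficiency
        results["efficiency_per_proton"] = sim.efficiency_per_proton

    # --- select ---
    sel_cfg = cfg["select"]
    criteria = (
        SelectionCriteria.from_preset(sel_cfg["preset"], tof_window=tuple(sel_cfg.get("tof", (0.0, 10.0))))
        if "preset" in sel_cfg
        else SelectionCriteria(tof_window=tuple(sel_cfg.get("tof", (0.0, 10.0))), energy_windows=tuple(sel_cfg.get("windows", ())))
    )
    selected, report = timed("select", lambda: select_events(events, criteria))
    results["selection_report"] = report
    sel_path = out / "events_selected.tsv"
    pgio.write_events(selected, sel_path, metadata={"selection": json.dumps(report)})
    manifest.register("events_selected", sel_path)

    # --- classifier ---
    clf_cfg = cfg["classifier"]
    if clf_cfg.get("enabled"):
        model_dir = out / "classifier"
        if clf_cfg.get("load"):
            model = BinnedClassifier.load(clf_cfg["load"])
        elif resume and (model_dir / "manifest.json").exists():
            model = BinnedClassifier.load(model_dir)
        else:
            def _train():
                from pgcam.geometry import build_single_module_scene

                tr_scene = build_single_module_scene()
                tr_src = UniformCubeSource(center=(-100.0, 0.0, 0.0))
                tr = run_simulation(
                    tr_scene,
                    tr_src,
                    int(clf_cfg.get("n_train_histories", 20_000_000)),
                    seed=_stage_seed(seed, "train_sim"),
                )
                return train_classifier(
                    tr.events,
                    tr_scene,
                    per_class_cap=int(clf_cfg.get("per_class_cap", 50_000)),
                    scorer=clf_cfg.get("scorer", "xgboost"),
                    seed=_stage_seed(seed, "train"),
                )

            model = timed("train_classifier", _train)
            model.save(model_dir)
        accepted, scores, _ = timed("classify", lambda: apply_classifier(selected, model, scene))
        results["classifier_gain"] = evaluate_gain(
            selected["full_energy"], scores >= model.threshold, selected["Es_keV"] + selected["Ea_keV"]
        )
        selected = accepted
        results["events_classified"] = selected

    # --- reconstruct + profile ---
    rc = cfg["reconstruct"]
    pc = cfg["profile"]
    hn = None
    profiles_out: dict = {}
    metrics_out: dict = {}
    truth = truth_profile(source, pitch=pc.get("pitch", 2.5)) if isinstance(source, LineDepthSource) else None
    if truth is not None:
        pgio.write_profile(truth, out / "profile_truth.tsv", metrics=falloff_metrics(truth))
    for algo in rc["algorithms"]:
        kw: dict = {}
        if algo == "soe":
            kw = {"n_iter": int(rc.get("n_iter", 1000)), "seed": _stage_seed(seed, "soe"), "delta_theta_deg": rc.get("delta_theta_deg", 1.5)}
        elif algo == "aa":
            if hn is None:
                hn = precompute_hn(n_max=int(rc.get("n_max", 70)))
            kw = {"table": hn, "n_max": int(rc.get("n_max", 70))}
        elif algo == "bp":
            kw = {"sigma_deg": rc.get("sigma_deg", 1.0)}
        planes = timed(f"reconstruct_{algo}", lambda: reconstruct_planes(selected, scene, algorithm=algo, n_pixels=int(rc.get("n_pixels", 200)), **kw))
        for key, img in planes.items():
            pgio.write_image(img, out / f"image_{algo}_{key}.tsv")
            manifest.register(f"image_{algo}_{key}", out / f"image_{algo}_{key}.tsv")
        prof = combine_profiles([project_profile(img, pitch=pc.get("pitch", 2.5), clip_negative=False) for img in planes.values()])
        m = falloff_metrics(prof)
        if truth is not None:
            m["vs_truth"] = compare_profiles(prof, truth)
        pgio.write_profile(prof, out / f"profile_{algo}.tsv", metrics=m)
        manifest.register(f"profile_{algo}", out / f"profile_{algo}.tsv")
        profiles_out[algo] = prof
        metrics_out[algo] = m
    results["profiles"] = profiles_out
    results["metrics"] = metrics_out
    if truth is not None:
        results["truth_profile"] = truth

    # --- report ---
    report_payload = {
        "selection": report,
        "metrics": pgio._jsonable(metrics_out),
        "n_events": int(len(events)),
        "n_selected": int(len(selected)),
    }
    (out / "report.json").write_text(json.dumps(report_payload, indent=2))
    manifest.save(out / "manifest.json")
    results["manifest"] = manifest
    return results
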