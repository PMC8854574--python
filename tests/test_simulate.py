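"""Synthetic-data generator: sources, transport, response, coincidences."""

import numpy as np
import pandas as pd
import pytest

from pgcam import physics
from pgcam.constants import FWHM_OVER_SIGMA
from pgcam.geometry import build_single_module_scene, build_default_scene
from pgcam.physics import AttenuationTable, load_attenuation_table, lookup_attenuation
from pgcam.simulate import (
    LineDepthSource,
    PointSource,
    ResponseModel,
    UniformCubeSource,
    apply_response,
    build_coincidences,
    default_pg_source,
    merge_hits,
    run_simulation,
    sample_emission,
    sample_emissions,
    transport_photon,
)


def _uniform_table(mu_pe, mu_c, mu_pair=0.0, material="custom"):
    e = np.array([1.0, 10.0, 1022.0, 8000.0])
    return AttenuationTable(
        material=material,
        energy_kev=e,
        mu_photo=np.full(4, mu_pe),
        mu_compton=np.full(4, mu_c),
        mu_pair=np.array([0.0, 0.0, 0.0, mu_pair]),
        density=1.0,
    )


class TestSources:
    def test_line_frequencies_match_relative_yields(self):
        src = default_pg_source()
        rng = np.random.default_rng(0)
        pos, e, d, t = sample_emissions(src, 100_000, rng)
        w = src.line_weights()
        for line, wk in zip(src.lines, w):
            frac = (e == line.energy_kev).mean()
            sigma = np.sqrt(wk * (1 - wk) / len(e))
            assert abs(frac - wk) < 3 * sigma + 1e-9

    def test_single_line_source_is_degenerate(self):
        src = LineDepthSource(lines=(default_pg_source().lines[1],))
        _, e, _, _ = sample_emissions(src, 1000, np.random.default_rng(1))
        assert np.all(e == 4400.0)

    def test_depth_histogram_matches_profile(self):
        src = LineDepthSource(lines=(default_pg_source().lines[1],))
        rng = np.random.default_rng(2)
        pos, _, _, _ = sample_emissions(src, 200_000, rng)
        depth = pos[:, 1] + 100.0
        edges = np.linspace(0, 120, 41)
        counts, _ = np.histogram(depth, bins=edges)
        # expected counts: fine-grid integral of the analytic profile per bin
        fine = np.linspace(0, 120, 48_001)
        pdf = src.lines[0].profile(fine)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]))])
        cdf /= cdf[-1]
        expected = np.diff(np.interp(edges, fine, cdf)) * counts.sum()
        mask = expected > 20
        chi2 = np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask])
        assert chi2 / mask.sum() < 2.0

    def test_transverse_spread_is_3mm(self):
        src = default_pg_source()
        pos, _, _, _ = sample_emissions(src, 50_000, np.random.default_rng(3))
        assert np.std(pos[:, 0]) == pytest.approx(3.0, rel=0.03)
        assert np.std(pos[:, 2]) == pytest.approx(3.0, rel=0.03)

    def test_all_zero_yields_rejected(self):
        line = default_pg_source().lines[0]
        with pytest.raises(ValueError):
            LineDepthSource(lines=(type(line)(line.energy_kev, 0.0, line.profile),))

    def test_single_emission_wrapper(self):
        pos, e, d, t = sample_emission(PointSource(1000.0), np.random.default_rng(0))
        assert e == 1000.0
        assert np.linalg.norm(d) == pytest.approx(1.0)


class TestTransport:
    def test_vacuum_scene_produces_no_hits(self):
        scene = build_single_module_scene()
        table = _uniform_table(0.0, 0.0)
        hits, truth = transport_photon(
            scene, (np.zeros(3), 1000.0, np.array([1.0, 0, 0]), 0.0), np.random.default_rng(0), detector_table=table
        )
        assert hits == []

    def test_pure_photoelectric_crystal_gives_one_full_energy_hit(self):
        scene = build_single_module_scene()
        table = _uniform_table(10.0, 0.0)  # certain absorption within <1 mm
        hits, truth = transport_photon(
            scene, (np.zeros(3), 1000.0, np.array([1.0, 0, 0]), 0.0), np.random.default_rng(0), detector_table=table
        )
        assert len(hits) == 1
        assert hits[0].energy_kev == pytest.approx(1000.0)

    def test_slab_interaction_fraction_matches_closed_form(self):
        """1 MeV photons on the 15 mm scatter slab: interaction fraction
        equals 1 - exp(-mu_total * 15) within 3 sigma binomial."""
        scene = build_single_module_scene()
        table = load_attenuation_table("lacl3")
        rng = np.random.default_rng(5)
        n = 100_000
        interacted = 0
        from pgcam.simulate import _transport_arrays

        pos = np.tile([0.0, 0.0, 0.0], (n, 1))
        dirn = np.tile([1.0, 0.0, 0.0], (n, 1))
        # remove the absorber plane so only the S slab is in the path
        from pgcam.geometry import Scene, DetectorModule

        hist, cid, hx, hy, hz, he, ht = _transport_arrays(
            pos, dirn, np.full(n, 1000.0), np.zeros(n), 0, scene, table,
            load_attenuation_table("water"), "removal", 99,
        )
        # count histories whose FIRST interaction (earliest hit) is in the
        # scatter slab (crystal 0); later S hits can come from absorber
        # back-scatter and do not belong to the slab-transmission law
        import pandas as pd

        df = pd.DataFrame({"hist": hist, "cid": cid, "t": ht})
        first = df.loc[df.groupby("hist")["t"].idxmin()]
        p = (first["cid"] == 0).sum() / n
        mu = lookup_attenuation(table, 1000.0)["total"]
        expected = 1.0 - np.exp(-mu * 15.0)
        assert abs(p - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_energy_conservation_per_history(self, point_run_1mev):
        scene, res = point_run_1mev
        ev = res.events
        assert np.all(ev["Es_keV"] + ev["Ea_keV"] > 0)
        # truth flag consistency is built upstream from pre-smearing deposits;
        # smeared add-back of full-energy events still clusters near 1 MeV
        fe = ev[ev.full_energy]
        addback = fe["Es_keV"] + fe["Ea_keV"]
        assert np.abs(addback.mean() - 1000.0) < 10.0

    def test_kinematic_consistency_with_ideal_response(self):
        """With zero smearing, events consisting of exactly one Compton
        interaction in S and one full absorption in A reproduce the
        geometric scattering angle from the two deposits within 0.5 deg."""
        import pandas as pd

        from pgcam.simulate import _transport_arrays

        scene = build_single_module_scene()
        table = load_attenuation_table("lacl3")
        rng = np.random.default_rng(8)
        n = 200_000
        u = rng.uniform(0.9, 1.0, n)  # aimed loosely at the module
        phi = rng.uniform(0, 2 * np.pi, n)
        s_ = np.sqrt(1 - u**2)
        dirn = np.column_stack([u, s_ * np.cos(phi), s_ * np.sin(phi)])
        hist, cid, hx, hy, hz, he, ht = _transport_arrays(
            np.zeros((n, 3)), dirn, np.full(n, 1000.0), np.zeros(n), 0, scene, table,
            load_attenuation_table("water"), "removal", 12,
        )
        df = pd.DataFrame({"hist": hist, "cid": cid, "x": hx, "y": hy, "z": hz, "e": he, "t": ht})
        sizes = df.groupby("hist").size()
        two = sizes[sizes == 2].index
        df = df[df["hist"].isin(two)].sort_values(["hist", "t"])
        first = df.groupby("hist").first()
        second = df.groupby("hist").last()
        # exact energy closure excludes chains with a dropped sub-floor
        # deposit, which are double-Compton events in disguise
        full = np.abs(first.e + second.e - 1000.0) <= 0.01
        ok = full & (first.cid == 0) & (second.cid > 0)
        assert ok.sum() > 200
        s = first[ok][["x", "y", "z"]].to_numpy()
        a = second[ok][["x", "y", "z"]].to_numpy()
        d_in = s / np.linalg.norm(s, axis=1)[:, None]
        d_sc = a - s
        d_sc /= np.linalg.norm(d_sc, axis=1)[:, None]
        geo = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", d_in, d_sc), -1, 1)))
        ang = physics.cos_from_energies(first[ok].e.to_numpy(), second[ok].e.to_numpy())
        kin = np.degrees(np.asarray(ang.omega))
        assert np.abs(kin - geo).max() < 0.5

    def test_efficiency_scales_with_inverse_square_distance(self):
        effs = []
        for dist in (200.0, 400.0):
            scene = build_single_module_scene(source_distance=dist)
            res = run_simulation(scene, PointSource(1000.0), 400_000, seed=13)
            effs.append(res.efficiency)
        ratio = effs[0] / effs[1]
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_zero_histories_rejected(self):
        scene = build_single_module_scene()
        with pytest.raises(ValueError):
            run_simulation(scene, PointSource(1000.0), 0)

    def test_determinism_same_seed_identical_events(self):
        scene = build_single_module_scene()
        a = run_simulation(scene, PointSource(1000.0), 50_000, seed=21).events
        b = run_simulation(scene, PointSource(1000.0), 50_000, seed=21).events
        pd.testing.assert_frame_equal(a, b)

    def test_thinning_does_not_change_physics(self):
        scene = build_single_module_scene()
        a = run_simulation(scene, PointSource(1000.0), 100_000, seed=22, thin=True)
        b = run_simulation(scene, PointSource(1000.0), 100_000, seed=22, thin=False)
        # same bookkeeping, statistically identical efficiency
        err = np.sqrt(a.efficiency_err**2 + b.efficiency_err**2)
        assert abs(a.efficiency - b.efficiency) < 4 * err + 1e-9


class TestResponse:
    def test_energy_fwhm_anchor_and_scaling(self):
        m = ResponseModel()
        assert m.energy_fwhm(500.0) == pytest.approx(22.5)
        assert m.energy_fwhm(1000.0) == pytest.approx(22.5 * np.sqrt(2.0))

    def test_smearing_reproduces_the_model_fwhm(self):
        m = ResponseModel()
        scene = build_single_module_scene()
        n = 10_000
        merged = (
            np.arange(n),
            np.zeros(n, dtype=np.int64),
            np.full(n, 55.0),
            np.zeros(n),
            np.zeros(n),
            np.full(n, 1000.0),
            np.zeros(n),
        )
        rng = np.random.default_rng(3)
        out = apply_response(merged, scene, m, rng)
        fwhm = np.std(out[5]) * FWHM_OVER_SIGMA
        assert fwhm == pytest.approx(m.energy_fwhm(1000.0), rel=0.05)

    def test_ideal_response_is_identity(self):
        scene = build_single_module_scene()
        merged = (
            np.array([0]),
            np.array([0], dtype=np.int64),
            np.array([55.0]),
            np.array([1.0]),
            np.array([2.0]),
            np.array([123.4]),
            np.array([0.5]),
        )
        out = apply_response(merged, scene, ResponseModel.ideal(), np.random.default_rng(0))
        for got, want in zip(out, merged):
            np.testing.assert_array_equal(got, want)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            ResponseModel(position_fwhm_mm=-1.0)


class TestCoincidences:
    def _merged(self, hist, crystal, e):
        n = len(hist)
        return (
            np.asarray(hist),
            np.asarray(crystal, dtype=np.int64),
            np.zeros(n),
            np.zeros(n),
            np.zeros(n),
            np.asarray(e, float),
            np.zeros(n),
        )

    def test_scatter_only_history_gives_no_event(self):
        scene = build_single_module_scene()
        m = self._merged([0], [0], [500.0])  # crystal 0 = scatter
        ev = build_coincidences(m, m, scene, np.array([1000.0]), np.zeros((1, 3)))
        assert len(ev) == 0

    def test_full_energy_flag_by_construction(self):
        scene = build_single_module_scene()
        m = self._merged([0, 0], [0, 1], [300.0, 700.0])
        ev = build_coincidences(m, m, scene, np.array([1000.0]), np.zeros((1, 3)))
        assert len(ev) == 1
        assert bool(ev["full_energy"].iloc[0])
        assert ev["Ea_keV"].iloc[0] == pytest.approx(700.0)

    def test_escaped_energy_clears_the_flag(self):
        scene = build_single_module_scene()
        m = self._merged([0, 0], [0, 1], [300.0, 500.0])
        ev = build_coincidences(m, m, scene, np.array([1000.0]), np.zeros((1, 3)))
        assert not bool(ev["full_energy"].iloc[0])

    def test_sub_threshold_crystal_cannot_seed_a_coincidence(self):
        scene = build_single_module_scene()
        model = ResponseModel(energy_fwhm_frac=0.0, position_fwhm_mm=0.0, threshold_kev=100.0, time_fwhm_ns=0.0)
        merged = self._merged([0, 0], [0, 1], [95.0, 700.0])
        smeared = apply_response(merged, scene, model, np.random.default_rng(0))
        ev = build_coincidences(smeared, merged, scene, np.array([1000.0]), np.zeros((1, 3)))
        assert len(ev) == 0

    def test_absorber_addback_sums_above_threshold_crystals(self):
        scene = build_single_module_scene()
        m = self._merged([0, 0, 0], [0, 1, 2], [300.0, 400.0, 300.0])
        ev = build_coincidences(m, m, scene, np.array([1000.0]), np.zeros((1, 3)))
        assert ev["Ea_keV"].iloc[0] == pytest.approx(700.0)
        assert bool(ev["full_energy"].iloc[0])

    def test_merge_hits_energy_weighted_centroid(self):
        hist = np.array([0, 0])
        crystal = np.array([1, 1], dtype=np.int64)
        x = np.array([0.0, 10.0])
        e = np.array([100.0, 300.0])
        z = np.zeros(2)
        uh, uc, cx, cy, cz, se, tm = merge_hits(hist, crystal, x, z, z, e, np.array([1.0, 0.5]), 5)
        assert se[0] == pytest.approx(400.0)
        assert cx[0] == pytest.approx(7.5)
        assert tm[0] == pytest.approx(0.5)


class TestBookkeeping:
    def test_per_proton_efficiency_scales_with_configured_yield(self):
        import dataclasses

        from pgcam.geometry import build_default_scene

        scene = build_default_scene()
        src = default_pg_source()
        a = run_simulation(scene, src, 300_000, seed=31)
        doubled = dataclasses.replace(src, pg_per_proton=2 * src.pg_per_proton)
        b = run_simulation(scene, doubled, 300_000, seed=31)
        assert b.efficiency_per_proton == pytest.approx(2 * a.efficiency_per_proton)
        assert b.efficiency == pytest.approx(a.efficiency)

    def test_background_injector_tags_events(self):
        from pgcam.geometry import build_default_scene
        from pgcam.simulate import inject_background

        scene = build_default_scene()
        res = run_simulation(scene, default_pg_source(), 300_000, seed=32)
        out = inject_background(res.events, scene, 50, np.random.default_rng(0))
        bg = out[out.particle == "background"]
        assert len(bg) == 50
        assert not bg.full_energy.any()
        assert len(out) == len(res.events) + 50
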