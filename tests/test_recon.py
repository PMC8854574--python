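"""Cone construction and the three reconstruction algorithms."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import entropy

from pgcam.physics import klein_nishina_dcs
from pgcam.recon import (
    HnTable,
    ImageGrid,
    aa_reconstruct,
    aa_reference,
    backproject,
    cone_from_event,
    cones_from_events,
    precompute_hn,
    soe_acceptance,
    soe_reconstruct,
)
from tests.conftest import synthetic_point_source_events


def _argmax_uv(img):
    i = int(np.argmax(np.clip(img.values, 0, None)))
    iu, iv = divmod(i, img.n_v)
    return img.u_centers()[iu], img.v_centers()[iv]


class TestCones:
    def test_hand_values(self):
        ev = dict(xs=0.0, ys=0.0, zs=0.0, xa=0.0, ya=0.0, za=30.0, Es_keV=500.0, Ea_keV=500.0)
        cone = cone_from_event(ev)
        np.testing.assert_allclose(cone.axis, [0.0, 0.0, -1.0])
        assert cone.cos_omega == pytest.approx(0.489)
        assert cone.e_gamma == 1000.0

    def test_coincident_hits_rejected(self):
        ev = dict(xs=1.0, ys=2.0, zs=3.0, xa=1.0, ya=2.0, za=3.0, Es_keV=500.0, Ea_keV=500.0)
        with pytest.raises(ValueError, match="degenerate"):
            cone_from_event(ev)

    def test_forward_limit_degenerates_to_a_line(self):
        ev = dict(xs=0.0, ys=0.0, zs=0.0, xa=0.0, ya=0.0, za=30.0, Es_keV=1e-9, Ea_keV=1000.0)
        cone = cone_from_event(ev)
        assert cone.omega == pytest.approx(0.0, abs=1e-4)

    def test_invalid_kinematics_rejected_scalar_and_dropped_vectorised(self):
        ev = dict(xs=0.0, ys=0.0, zs=0.0, xa=0.0, ya=0.0, za=30.0, Es_keV=5000.0, Ea_keV=200.0)
        with pytest.raises(ValueError, match="invalid"):
            cone_from_event(ev)
        df = pd.DataFrame([ev])
        apex, axis, omega, eg = cones_from_events(df)
        assert len(omega) == 0


class TestBackprojection:
    def test_noiseless_cone_band_passes_through_the_source(self):
        ev = synthetic_point_source_events(1, seed=1)
        grid = ImageGrid(n_u=100, n_v=100)
        img = backproject(ev, grid)
        # the maximal-weight band contains the source pixel (origin)
        iu = np.argmin(np.abs(grid.u_centers()))
        iv = np.argmin(np.abs(grid.v_centers()))
        assert img.values[iu, iv] > 0.5 * img.values.max()

    def test_empty_input_gives_zero_image_with_warning(self):
        grid = ImageGrid(n_u=50, n_v=50)
        img = backproject(pd.DataFrame(columns=["xs", "ys", "zs", "xa", "ya", "za", "Es_keV", "Ea_keV"]), grid)
        assert np.all(img.values == 0)
        assert "warning" in img.meta

    def test_point_source_argmax_within_3mm(self):
        ev = synthetic_point_source_events(2000, seed=2)
        grid = ImageGrid(n_u=100, n_v=100)
        u, v = _argmax_uv(backproject(ev, grid))
        assert abs(u) <= 3.0 and abs(v) <= 3.0


class TestSOE:
    def test_acceptance_rule_values(self):
        assert soe_acceptance(3, 5) == 1.0
        assert soe_acceptance(2, 0) == 0.5

    def test_point_source_argmax_and_concentration(self):
        ev = synthetic_point_source_events(1500, seed=3)
        grid = ImageGrid(n_u=100, n_v=100)
        img0 = soe_reconstruct(ev, grid, n_iter=1, seed=9, pad_factor=1)
        img = soe_reconstruct(ev, grid, n_iter=1000, seed=9, pad_factor=1)
        u, v = _argmax_uv(img)
        assert abs(u) <= 3.0 and abs(v) <= 3.0
        # iterated ensemble is more concentrated than the initial one
        assert entropy(img.values.ravel() + 1e-12) < entropy(img0.values.ravel() + 1e-12)

    def test_occupancy_conserved_across_iterations(self):
        ev = synthetic_point_source_events(300, seed=4)
        grid = ImageGrid(n_u=60, n_v=60)
        for n_iter in (1, 5, 50):
            img = soe_reconstruct(ev, grid, n_iter=n_iter, seed=1, pad_factor=1)
            assert img.values.sum() == pytest.approx(img.meta["n_events"], rel=1e-9)

    def test_uniform_density_random_walk_is_unbiased(self):
        """With one event the acceptance is min(1, 1/1) = 1 everywhere:
        the chain must accept every proposal (flat-proposal limit)."""
        ev = synthetic_point_source_events(1, seed=5)
        grid = ImageGrid(n_u=80, n_v=80)
        img = soe_reconstruct(ev, grid, n_iter=500, seed=2, pad_factor=1)
        assert img.values.sum() == 1

    def test_determinism(self):
        ev = synthetic_point_source_events(200, seed=6)
        grid = ImageGrid(n_u=50, n_v=50)
        a = soe_reconstruct(ev, grid, n_iter=50, seed=3)
        b = soe_reconstruct(ev, grid, n_iter=50, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestHnTable:
    def test_unit_cross_section_recovers_legendre_orthogonality(self):
        table = precompute_hn(
            e_grid=np.array([1000.0]),
            n_max=20,
            omega_min_deg=0.0,
            omega_max_deg=180.0,
            cross_section=lambda e, c: np.ones_like(c),
        )
        n = np.arange(21)
        np.testing.assert_allclose(table.values[0], 2.0 / (2 * n + 1), rtol=1e-12)

    def test_h0_matches_adaptive_quadrature(self):
        table = precompute_hn(e_grid=np.array([1000.0]), n_max=70)
        a = math.cos(math.radians(110.0))
        b = math.cos(math.radians(10.0))
        ref, _ = quad(lambda c: klein_nishina_dcs(1000.0, c), a, b, epsrel=1e-12)
        assert abs(table.values[0, 0] / ref - 1) < 1e-6

    def test_h12_matches_adaptive_quadrature(self):
        from scipy.special import eval_legendre

        table = precompute_hn(e_grid=np.array([4400.0]), n_max=70)
        a = math.cos(math.radians(110.0))
        b = math.cos(math.radians(10.0))
        ref, _ = quad(
            lambda c: klein_nishina_dcs(4400.0, c) * eval_legendre(12, c) ** 2, a, b, epsrel=1e-12
        )
        assert abs(table.values[0, 12] / ref - 1) < 1e-6

    def test_regeneration_is_bit_identical(self):
        a = precompute_hn(e_grid=np.arange(200.0, 1000.0, 50.0), n_max=30)
        b = precompute_hn(e_grid=np.arange(200.0, 1000.0, 50.0), n_max=30)
        np.testing.assert_array_equal(a.values, b.values)

    def test_disk_cache_round_trip(self, tmp_path):
        a = precompute_hn(e_grid=np.arange(200.0, 600.0, 50.0), n_max=10, cache_dir=tmp_path)
        b = precompute_hn(e_grid=np.arange(200.0, 600.0, 50.0), n_max=10, cache_dir=tmp_path)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_angular_range_rejected(self):
        with pytest.raises(ValueError):
            precompute_hn(n_max=5, omega_min_deg=90.0, omega_max_deg=30.0)


class TestAnalytical:
    def test_nmax_zero_gives_flat_image(self, hn70):
        ev = synthetic_point_source_events(5, seed=7)
        grid = ImageGrid(n_u=30, n_v=30)
        img = aa_reconstruct(ev, grid, hn70, n_max=0)
        assert np.allclose(img.values, img.values.flat[0], rtol=1e-9)

    def test_point_source_argmax_within_2mm(self, hn70):
        ev = synthetic_point_source_events(2000, seed=8)
        grid = ImageGrid(n_u=100, n_v=100)
        u, v = _argmax_uv(aa_reconstruct(ev, grid, hn70, n_max=70))
        assert abs(u) <= 2.0 and abs(v) <= 2.0

    def test_compiled_kernel_equals_naive_reference(self, hn70):
        ev = synthetic_point_source_events(100, seed=9)
        grid = ImageGrid(n_u=50, n_v=50)
        fast = aa_reconstruct(ev, grid, hn70, n_max=70)
        ref = aa_reference(ev, grid, hn70, n_max=70)
        scale = np.abs(ref.values).max()
        assert np.abs(fast.values - ref.values).max() / scale < 1e-9

    def test_psf_does_not_widen_with_more_terms(self, hn70):
        ev = synthetic_point_source_events(3000, seed=10)
        grid = ImageGrid(n_u=100, n_v=100)
        widths = []
        for nmax in (10, 30, 70):
            img = aa_reconstruct(ev, grid, hn70, n_max=nmax)
            vals = np.clip(img.values, 0, None)
            prof = vals[:, np.argmin(np.abs(grid.v_centers()))]
            half = prof >= 0.5 * prof.max()
            widths.append(half.sum() * grid.pitch_u)
        assert widths[0] >= widths[1] >= widths[2]

    def test_event_energy_outside_table_is_skipped(self):
        table = precompute_hn(e_grid=np.arange(200.0, 1000.0, 50.0), n_max=10)
        ev = synthetic_point_source_events(10, e_gamma=4400.0, seed=11)
        grid = ImageGrid(n_u=20, n_v=20)
        img = aa_reconstruct(ev, grid, table, n_max=10)
        assert img.meta["n_skipped_energy"] == 10


class TestTranslationCovariance:
    @pytest.mark.parametrize("algo", ["bp", "soe", "aa"])
    def test_shifting_the_whole_setup_shifts_the_argmax(self, algo, hn70):
        """Common 6 mm beam-axis offset of source and detector moves the
        image argmax by the same offset within one pixel."""
        offset = 6.0
        base = synthetic_point_source_events(1200, seed=12)
        shifted = synthetic_point_source_events(1200, source=(0.0, offset, 0.0), seed=12)
        grid = ImageGrid(n_u=100, n_v=100)

        def run(ev):
            if algo == "bp":
                return backproject(ev, grid)
            if algo == "soe":
                return soe_reconstruct(ev, grid, n_iter=300, seed=4)
            return aa_reconstruct(ev, grid, hn70, n_max=50)

        u0, v0 = _argmax_uv(run(base))
        u1, v1 = _argmax_uv(run(shifted))
        assert abs((v1 - v0) - offset) <= grid.pitch_v + 1e-9
        assert abs(u1 - u0) <= grid.pitch_u + 1e-9
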