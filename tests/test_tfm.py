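"""Micropillar TFM: stiffness model, lattice fit, displacement recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from vsmcquant import synthetic as syn
from vsmcquant import tfm
from vsmcquant.tfm import Material, PillarGeometry, pillar_stiffness


def _sympy_corr(aspect, v, tilt_constant=tfm.DEFAULT_TILT_CONSTANT):
    """Independent symbolic evaluation of the warping correction."""
    import sympy as sp

    r, nu, a = sp.symbols("r nu a", positive=True)
    t_tilt = a * (1 + nu) / (2 * sp.pi**2 * (1 - nu)) + 1 - 1 / (4 * (1 - nu))
    corr = (sp.Rational(16, 3) * r**3) / (
        sp.Rational(16, 3) * r**3
        + (7 + 6 * nu) / 3 * r
        + 8 * t_tilt * r**2
    )
    return float(
        corr.subs({r: sp.Float(aspect), nu: sp.Float(v), a: sp.Float(tilt_constant)})
    )


class TestStiffnessModel:
    def test_bending_stiffness_power_laws(self):
        base = pillar_stiffness(PillarGeometry(), Material()).k_bend
        d2 = pillar_stiffness(
            PillarGeometry(diameter=1.0e-6, pitch=2.0e-6), Material()
        ).k_bend
        h2 = pillar_stiffness(PillarGeometry(height=2.6e-6), Material()).k_bend
        assert d2 == pytest.approx(16 * base, rel=1e-12)
        assert h2 == pytest.approx(base / 8, rel=1e-12)

    def test_default_pillar_bending_stiffness_value(self):
        # E=2.0 MPa, D=0.5 um, H=1.3 um -> (3/64)*pi*E*D^4/H^3 = 8.379e-3 N/m
        m = pillar_stiffness(PillarGeometry(), Material())
        assert m.k_bend == pytest.approx(8.379e-3, rel=1e-3)

    @pytest.mark.parametrize("aspect", [1.0, 2.0, 2.6, 5.0, 10.0])
    @pytest.mark.parametrize("v", [0.0, 0.25, 0.49, 0.5])
    def test_corr_matches_symbolic_oracle(self, aspect, v):
        geom = PillarGeometry(diameter=0.5e-6, height=aspect * 0.5e-6, pitch=10e-6)
        m = pillar_stiffness(geom, Material(poisson=v))
        assert m.corr == pytest.approx(_sympy_corr(aspect, v), rel=1e-12)

    @pytest.mark.parametrize("aspect", [1.0, 2.6, 8.0])
    @pytest.mark.parametrize("v", [0.0, 0.3, 0.49])
    def test_corr_bounded_and_k_below_k_bend(self, aspect, v):
        geom = PillarGeometry(diameter=0.5e-6, height=aspect * 0.5e-6, pitch=10e-6)
        m = pillar_stiffness(geom, Material(poisson=v))
        assert 0 < m.corr <= 1
        assert m.k <= m.k_bend
        assert m.e_eff > 0

    def test_forces_linear_in_modulus(self):
        soft = pillar_stiffness(PillarGeometry(), Material(youngs_modulus=1e6))
        stiff = pillar_stiffness(PillarGeometry(), Material(youngs_modulus=2e6))
        assert stiff.k == pytest.approx(2 * soft.k, rel=1e-12)

    def test_poisson_one_is_rejected(self):
        # v = 1 would zero the (1 - v) denominators in the tilt term
        with pytest.raises(ValueError):
            Material(poisson=1.0)


class TestLocalization:
    def test_blank_image_yields_empty_result_with_warning(self):
        with pytest.warns(UserWarning, match="blank"):
            out = tfm.localize_pillars(np.full((50, 50), 7.0), 1.0, 0.1)
        assert out.shape == (0, 2)

    def test_single_spot_centroid_matches_analytic_mean(self):
        img = 100 + syn._render_gaussian_spots(
            (100, 100), np.array([[5.27, 4.86]]), 0.15, 1000.0, 0.1
        )
        c = tfm.localize_pillars(img, 1.0, 0.1)
        assert len(c) == 1
        assert np.hypot(c[0, 0] - 5.27, c[0, 1] - 4.86) < 1e-3

    def test_noiseless_lattice_recovered_within_20nm_rms(self):
        scene = syn.PillarScene(noise_sd=0.0)
        img, truth = syn.make_pillar_image(scene)
        cents = tfm.localize_pillars(img, 1.0, 0.1)
        d, _ = cKDTree(truth[["x_ideal", "y_ideal"]].to_numpy()).query(cents)
        assert np.sqrt((d**2).mean()) < 0.02


class TestGridFit:
    def _exact_lattice(self, theta_deg=0.0, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ii, jj = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        th = np.deg2rad(theta_deg)
        basis = np.array(
            [[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]
        )
        pts = np.stack([ii.ravel(), jj.ravel()], 1) @ basis + np.array([3.0, 4.0])
        if jitter:
            pts = pts + rng.normal(0, jitter, pts.shape)
        return pts

    def test_exact_axis_aligned_lattice_recovered_perfectly(self):
        lat = tfm.fit_reference_grid(self._exact_lattice(), 1.0)
        recovered = np.abs(lat.basis)
        assert np.allclose(sorted(recovered.max(axis=1)), [1.0, 1.0], atol=1e-9)
        assert np.allclose(recovered.min(axis=1), 0.0, atol=1e-9)
        assert lat.rms_residual < 1e-9

    def test_rotated_lattice_recovered_within_tolerance(self):
        lat = tfm.fit_reference_grid(self._exact_lattice(theta_deg=5.0), 1.0)
        angles = np.rad2deg(np.arctan2(lat.basis[:, 1], lat.basis[:, 0])) % 90.0
        assert min(abs(angles - 5.0)) < 0.1
        assert np.allclose(np.linalg.norm(lat.basis, axis=1), 1.0, atol=0.005)

    def test_jittered_lattice_reports_matching_residual(self):
        res = [
            tfm.fit_reference_grid(
                self._exact_lattice(jitter=0.02, seed=s), 1.0
            ).rms_residual
            for s in range(8)
        ]
        # rms residual ~ sqrt(2)*0.02 per-point jitter across both axes
        assert abs(np.mean(res) - 0.02 * np.sqrt(2)) < 0.006

    def test_fit_is_rigid_motion_equivariant(self):
        pts = self._exact_lattice(jitter=0.01, seed=3)
        lat = tfm.fit_reference_grid(pts, 1.0)
        th = np.deg2rad(17.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([5.0, -2.0])
        lat2 = tfm.fit_reference_grid(moved, 1.0)
        assert lat2.rms_residual == pytest.approx(lat.rms_residual, rel=1e-6)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError, match="6 reference"):
            tfm.fit_reference_grid(self._exact_lattice()[:5], 1.0)


class TestDisplacements:
    def test_three_four_five_magnitude(self):
        lat = tfm.PillarLattice(
            origin=np.zeros(2), basis=np.eye(2), rms_residual=0.0
        )
        field = tfm.compute_displacements(
            np.array([[3.03, 4.04]]), lat, None, 0.1, noise_floor=0.02
        )
        assert field.table["magnitude"].iloc[0] == pytest.approx(0.05)
        assert field.table["above_noise"].iloc[0]

    def test_far_centroid_flagged_unassigned(self):
        lat = tfm.PillarLattice(
            origin=np.zeros(2), basis=np.eye(2) * 1.0, rms_residual=0.0
        )
        # exactly between nodes would be > pitch/2 only if farther; use 0.8
        field = tfm.compute_displacements(
            np.array([[0.51, 0.51]]), lat, None, 0.1, noise_floor=0.02
        )
        assert not field.table["assigned"].iloc[0]

    def test_undisplaced_scene_has_no_above_noise_pillars(self):
        scene = syn.PillarScene(noise_sd=0.0)
        img, truth = syn.make_pillar_image(scene)
        cents = tfm.localize_pillars(img, 1.0, 0.1)
        lat = tfm.fit_reference_grid(cents, 1.0)
        field = tfm.compute_displacements(cents, lat, None, 0.1, noise_floor=0.02)
        assert not field.table["above_noise"].any()

    def test_imposed_displacement_recovered(self):
        scene = syn.make_contractile_scene(seed=6)
        img, truth = syn.make_pillar_image(scene)
        cents = tfm.localize_pillars(img, 1.0, 0.1)
        d, i = cKDTree(truth[["x_true", "y_true"]].to_numpy()).query(cents)
        lat = tfm.fit_reference_grid(cents, 1.0, ~truth["inside_cell"].to_numpy()[i])
        field = tfm.compute_displacements(cents, lat, scene.cell_mask, 0.1)
        err = np.hypot(
            field.table["dx"].to_numpy() - truth["dx_true"].to_numpy()[i],
            field.table["dy"].to_numpy() - truth["dy_true"].to_numpy()[i],
        )
        assert np.sqrt((err**2).mean()) < field.noise_floor
        displaced = truth["inside_cell"].to_numpy()[i]
        assert field.table["above_noise"].to_numpy()[displaced].mean() > 0.95


class TestNoiseFloor:
    def test_all_zero_references_give_zero_floor(self):
        assert tfm.estimate_noise_floor(np.zeros(10)) == 0.0

    def test_percentile_matches_sort_and_interpolate_oracle(self):
        mags = np.array([10.0, 10.0, 10.0, 10.0, 10.0, 30.0])  # nm
        # oracle: rank position 0.95*(n-1)=4.75 between 10 and 30 -> 25
        srt = np.sort(mags)
        pos = 0.95 * (len(srt) - 1)
        lo, frac = int(pos), pos - int(pos)
        oracle = srt[lo] + frac * (srt[lo + 1] - srt[lo])
        assert oracle == pytest.approx(25.0)
        assert tfm.estimate_noise_floor(mags) == pytest.approx(oracle)

    def test_rayleigh_jitter_floor_near_24nm(self, rng):
        mags = np.hypot(rng.normal(0, 0.01, 200_000), rng.normal(0, 0.01, 200_000))
        # 95th percentile of Rayleigh(sigma) = sigma*sqrt(2 ln 20) = 0.0245
        assert tfm.estimate_noise_floor(mags) == pytest.approx(0.0245, abs=0.001)

    def test_too_few_references_rejected(self):
        with pytest.raises(ValueError):
            tfm.estimate_noise_floor(np.zeros(5))


class TestForces:
    def _field(self, rows):
        lat = tfm.PillarLattice(np.zeros(2), np.eye(2), 0.0)
        table = pd.DataFrame(rows)
        return tfm.DisplacementField(table=table, noise_floor=0.02, lattice=lat)

    def test_42_pN_scale_example(self):
        # |d| = 0.05 um at k = 8.379e-3 N/m -> |F| = 0.419 nN
        model = pillar_stiffness(PillarGeometry(), Material())
        field = self._field(
            [dict(x=0, y=0, dx=0.03, dy=0.04, magnitude=0.05,
                  inside_cell=True, above_noise=True, assigned=True)]
        )
        forces = tfm.displacement_to_force(
            field, tfm.StiffnessModel(model.k_bend, 0, 1.0, model.k_bend, 1)
        )
        assert forces["force_nN"].iloc[0] == pytest.approx(0.419, abs=0.002)

    def test_sub_noise_pillars_carry_zero_force_and_linearity(self):
        model = pillar_stiffness(PillarGeometry(), Material())
        rows = [
            dict(x=0, y=0, dx=0.05, dy=0.0, magnitude=0.05,
                 inside_cell=True, above_noise=True, assigned=True),
            dict(x=1, y=0, dx=0.01, dy=0.0, magnitude=0.01,
                 inside_cell=True, above_noise=False, assigned=True),
        ]
        f1 = tfm.displacement_to_force(self._field(rows), model)
        assert f1["force_nN"].iloc[1] == 0.0
        rows2 = [dict(r, dx=2 * r["dx"], magnitude=2 * r["magnitude"]) for r in rows]
        f2 = tfm.displacement_to_force(self._field(rows2), model)
        assert f2["force_nN"].iloc[0] == pytest.approx(2 * f1["force_nN"].iloc[0])


class TestEdgeBand:
    def _disk_mask(self, radius_um, shape=(900, 900), px=0.1):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        c = shape[0] * px / 2
        return np.hypot(cols * px - c, rows * px - c) <= radius_um

    def _forces_at(self, points):
        rows = [
            dict(x=p[0], y=p[1], dx=0.05, dy=0.0, magnitude=0.05,
                 inside_cell=True, above_noise=True, assigned=True,
                 fx_nN=0.4, fy_nN=0.0, force_nN=0.4)
            for p in points
        ]
        return pd.DataFrame(rows)

    def test_central_pillars_fall_outside_a_10um_band(self):
        mask = self._disk_mask(40.0)
        forces = self._forces_at([(45.0, 45.0), (44.0, 45.0)])  # centre
        s = tfm.edge_band_summary(forces, mask, 0.1, band_width_um=10.0)
        assert s["n_above_noise"] == 0
        assert np.isnan(s["mean_force_nN"])

    def test_band_counts_match_construction(self):
        mask = self._disk_mask(20.0, shape=(500, 500))
        centre = 25.0
        band_pts = [(centre + 13.0, centre + 0.1 * k) for k in range(12)]
        core_pts = [(centre + 0.2 * k, centre) for k in range(5)]
        s = tfm.edge_band_summary(
            self._forces_at(band_pts + core_pts), mask, 0.1, band_width_um=10.0
        )
        assert s["n_above_noise"] == 12

    def test_band_wider_than_cell_equals_whole_cell_summary(self):
        mask = self._disk_mask(15.0, shape=(400, 400))
        pts = [(20.0 + dx, 20.0) for dx in np.linspace(-10, 10, 9)]
        wide = tfm.edge_band_summary(self._forces_at(pts), mask, 0.1, band_width_um=50.0)
        whole = tfm.edge_band_summary(self._forces_at(pts), mask, 0.1, band_width_um=1e9)
        assert wide["n_above_noise"] == whole["n_above_noise"]
        assert wide["total_force_nN"] == pytest.approx(whole["total_force_nN"])
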