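"""Phantom generator: mask rasterization, analytic fields, image
warping, specimen synthesis and the cohort table."""

import numpy as np
import pandas as pd
import pytest

import meniscus_strain as ms
from meniscus_strain import phantom


def brute_force_annulus_count(geom: ms.PhantomGeometry) -> int:
    """Independent per-voxel inclusion test for a full annulus (no
    attachments), looping voxel by voxel."""
    count = 0
    nx, ny, nz = geom.grid_shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                x = geom.origin[0] + i * geom.spacing[0] - geom.center[0]
                y = geom.origin[1] + j * geom.spacing[1] - geom.center[1]
                z = geom.origin[2] + k * geom.spacing[2]
                r = np.hypot(x, y)
                if not geom.inner_radius <= r <= geom.outer_radius:
                    continue
                frac = (r - geom.inner_radius) / (geom.outer_radius - geom.inner_radius)
                h = geom.inner_height + (geom.peripheral_height - geom.inner_height) * frac
                if geom.z_base <= z <= geom.z_base + h:
                    count += 1
    return count


class TestMask:
    def test_full_annulus_matches_brute_force(self):
        geom = ms.PhantomGeometry(angular_span=360.0, attachment_span=0.0,
                                  grid_shape=(40, 40, 12), spacing=(2.0, 2.0, 1.0),
                                  origin=(-39.0, -39.0, 0.0))
        mask = ms.make_meniscus_mask(geom)
        assert (mask.labels > 0).sum() == brute_force_annulus_count(geom)
        assert set(np.unique(mask.labels)) == {0, phantom.BODY}

    def test_mirror_symmetry(self):
        """A C-shape symmetric about the y axis equals its own mirror."""
        geom = ms.PhantomGeometry(start_angle=-90.0, angular_span=180.0,
                                  attachment_span=10.0,
                                  grid_shape=(41, 41, 12), spacing=(2.0, 2.0, 1.0),
                                  origin=(-40.0, -40.0, 0.0))
        lab = ms.make_meniscus_mask(geom).labels
        mirrored = lab[:, ::-1, :]  # reflect y: theta -> -theta
        swap = {phantom.ARA: phantom.PRA, phantom.PRA: phantom.ARA}
        expected = np.vectorize(lambda v: swap.get(v, v))(mirrored)
        np.testing.assert_array_equal(lab, expected)

    def test_thin_shell_monotone(self, small_geom):
        import dataclasses
        thin = dataclasses.replace(small_geom, inner_radius=small_geom.outer_radius - 2.0)
        full = ms.make_meniscus_mask(small_geom)
        shell = ms.make_meniscus_mask(thin)
        n_thin, n_full = (shell.labels > 0).sum(), (full.labels > 0).sum()
        assert 0 < n_thin < n_full

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            ms.PhantomGeometry(inner_radius=30.0, outer_radius=15.0)
        with pytest.raises(ValueError, match="bounds"):
            ms.make_meniscus_mask(ms.PhantomGeometry(outer_radius=200.0))


class TestDisplacement:
    def test_uniform_axial_linear(self, small_mask):
        spec = ms.DeformationSpec("uniform_axial", {"strain": -0.05, "z_ref": 0.0})
        fld = ms.make_displacement(spec, small_mask)
        k = 10  # voxel center at z = 10 mm on the 1 mm axial grid
        assert small_mask.voxel_to_world((0, 0, k))[2] == pytest.approx(10.0)
        np.testing.assert_allclose(fld.vectors[:, :, k, 2], -0.5)
        np.testing.assert_allclose(fld.vectors[..., :2], 0.0)

    def test_null_rigid_is_zero(self, small_mask):
        spec = ms.DeformationSpec("rigid", {"angle_deg": 0.0, "translation": (0, 0, 0)})
        fld = ms.make_displacement(spec, small_mask)
        np.testing.assert_allclose(fld.vectors, 0.0)

    def test_composite_additivity(self, small_mask):
        """Composite field equals the independent sum of its members at
        random voxels."""
        rng = np.random.default_rng(5)
        m1 = ms.DeformationSpec("radial", {"alpha": 0.01, "center": (1.0, -2.0)})
        m2 = ms.DeformationSpec("uniform_axial", {"strain": -0.03, "z_ref": 2.0})
        comp = ms.make_displacement(ms.DeformationSpec("composite", {"members": [m1, m2]}),
                                    small_mask)
        f1 = ms.make_displacement(m1, small_mask)
        f2 = ms.make_displacement(m2, small_mask)
        idx = rng.integers(0, np.array(small_mask.shape), size=(100, 3))
        for i, j, k in idx:
            np.testing.assert_allclose(comp.vectors[i, j, k],
                                       f1.vectors[i, j, k] + f2.vectors[i, j, k],
                                       atol=1e-14)

    def test_affine_mode_exactly_affine(self, small_mask):
        rng = np.random.default_rng(6)
        A = rng.normal(scale=0.01, size=(3, 3))
        b = rng.normal(size=3)
        fld = ms.make_displacement(ms.DeformationSpec("affine", {"matrix": A, "offset": b}),
                                   small_mask)
        ii, jj, kk = 3, 17, 9
        p = small_mask.voxel_to_world((ii, jj, kk))
        np.testing.assert_allclose(fld.vectors[ii, jj, kk], A @ p + b, atol=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="unknown"):
            ms.DeformationSpec("spiral", {})


class TestWarp:
    def test_zero_field_identity(self, small_mask):
        rng = np.random.default_rng(7)
        vol = ms.ImageVolume(rng.normal(size=small_mask.shape),
                             small_mask.spacing, small_mask.origin)
        zero = ms.DisplacementField(np.zeros(small_mask.shape + (3,)),
                                    small_mask.spacing, small_mask.origin)
        out = ms.warp_image(vol, zero)
        np.testing.assert_allclose(out.data, vol.data)

    def test_integer_shift(self):
        """A constant field of exactly +2 voxels along x shifts a
        piecewise-constant image by 2 voxels."""
        spacing = np.array([0.5, 0.5, 0.5])
        img = np.zeros((12, 6, 6))
        img[3:6] = 7.0
        vol = ms.ImageVolume(img, spacing)
        u = np.zeros(img.shape + (3,))
        u[..., 0] = 2 * spacing[0]
        out = ms.warp_image(vol, ms.DisplacementField(u, spacing), background=0.0)
        np.testing.assert_allclose(out.data[5:8], 7.0)
        np.testing.assert_allclose(out.data[:5], 0.0)
        np.testing.assert_allclose(out.data[8:], 0.0)

    def test_smooth_warp_against_analytic(self):
        """Warping a closed-form image under a Gaussian-bump field agrees
        with evaluating the analytically warped image."""
        spacing = np.array([0.5, 0.5, 0.5])
        shape = (40, 40, 40)
        ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        image_fn = lambda x, y, z: np.sin(0.5 * x) + np.cos(0.4 * y) + 0.3 * z
        vol = ms.ImageVolume(image_fn(X, Y, Z), spacing)
        spec = ms.DeformationSpec("gaussian_bump",
                                  {"center": (10.0, 10.0, 10.0),
                                   "amplitude": (0.8, -0.5, 0.4), "width": 4.0})
        fld = ms.make_displacement(spec, vol)
        out = ms.warp_image(vol, fld, background=np.nan)
        # analytic: for each output point y solve x = y - u(x) by iteration
        # on the continuous field, then evaluate the closed-form image
        c = np.array([10.0, 10.0, 10.0])
        amp = np.array([0.8, -0.5, 0.4])
        u_fn = lambda p: amp * np.exp(-((p - c) ** 2).sum() / (2 * 16.0))
        rng = np.random.default_rng(8)
        for _ in range(30):
            idx = rng.integers(5, 35, size=3)
            y = idx * spacing
            x = y.copy()
            for _ in range(60):
                x = y - u_fn(x)
            expected = image_fn(*x)
            got = out.data[tuple(idx)]
            assert got == pytest.approx(expected, abs=0.02)  # interpolation-order error

    def test_non_congruent_grids(self, small_mask):
        vol = ms.ImageVolume(np.zeros(small_mask.shape), small_mask.spacing, small_mask.origin)
        bad = ms.DisplacementField(np.zeros((4, 4, 4, 3)))
        with pytest.raises(ValueError, match="congruent"):
            ms.warp_image(vol, bad)


class TestSpecimen:
    def test_identity_deformation_no_noise(self, small_geom):
        spec = {0.25: ms.DeformationSpec("rigid", {})}
        mask, unloaded, loaded = ms.synthesize_specimen(small_geom, spec, noise_sd=0.0, seed=0)
        vol, fld = loaded[0.25]
        np.testing.assert_allclose(vol.data, unloaded.data)
        np.testing.assert_allclose(fld.vectors, 0.0)

    def test_seed_reproducibility(self, small_geom):
        specs = {1.0: ms.DeformationSpec("uniform_axial", {"strain": -0.05, "z_ref": 2.0})}
        a = ms.synthesize_specimen(small_geom, specs, noise_sd=5.0, seed=42)
        b = ms.synthesize_specimen(small_geom, specs, noise_sd=5.0, seed=42)
        np.testing.assert_array_equal(a[1].data, b[1].data)
        np.testing.assert_array_equal(a[2][1.0][0].data, b[2][1.0][0].data)

    def test_load_scaling_of_ground_truth(self, small_geom, small_mask):
        """Axial strains prescribed at 1 : 1.5 : 3 produce ground-truth
        mean strain over the mask in the same ratio."""
        base = -0.02
        specs = {lv: ms.DeformationSpec("uniform_axial", {"strain": base * s, "z_ref": 2.0})
                 for lv, s in zip((0.25, 0.5, 1.0), (1.0, 1.5, 3.0))}
        _, _, loaded = ms.synthesize_specimen(small_geom, specs, noise_sd=0.0, seed=0)
        fg = small_mask.labels > 0
        means = []
        for lv in (0.25, 0.5, 1.0):
            u = loaded[lv][1].vectors[..., 2]
            # mean du_z/dz over the mask via the analytic field: strain*(z-z_ref)
            means.append(np.mean(u[fg]))
        ratios = np.array(means) / means[0]
        np.testing.assert_allclose(ratios, [1.0, 1.5, 3.0], rtol=1e-12)


class TestCohort:
    def test_near_degenerate_sd_recovers_means(self):
        spec = ms.CohortSpec(n_per_group=3, load_levels=(1.0,),
                             group_sds={"axial": 1e-9, "circumferential": 1e-9, "radial": 1e-9},
                             medial_lateral_split=(0.5, 0.5), seed=0)
        tab = ms.synthesize_cohort(spec)
        ax = tab[(tab.group == "mild") & (tab.direction == "axial")]["strain_pct"]
        np.testing.assert_allclose(ax, -3.1, atol=1e-6)
        ax = tab[(tab.group == "severe") & (tab.direction == "axial")]["strain_pct"]
        np.testing.assert_allclose(ax, -7.3, atol=1e-6)

    def test_axial_compression_is_negative(self):
        tab = ms.synthesize_cohort(ms.CohortSpec(seed=3))
        med = tab[tab.direction == "axial"].groupby("group")["strain_pct"].median()
        assert (med < 0).all()

    def test_schema_and_uniqueness(self):
        tab = ms.synthesize_cohort(ms.CohortSpec(n_per_group=2, seed=0))
        keys = ["specimen", "side", "load", "region", "zone", "direction"]
        assert not tab.duplicated(subset=keys).any()
        assert set(tab.region) == set(phantom.REGIONS)
        assert set(tab.zone) == {"inner", "outer", "attachment"}
        assert np.isfinite(tab.strain_pct).all()

    def test_determinism_and_exchangeability(self):
        a = ms.synthesize_cohort(ms.CohortSpec(seed=11))
        b = ms.synthesize_cohort(ms.CohortSpec(seed=11))
        pd.testing.assert_frame_equal(a, b)
        # permuting specimen ids within a group leaves group statistics alone
        perm = a.copy()
        ids = perm.loc[perm.group == "mild", "specimen"].unique()
        mapping = dict(zip(ids, np.roll(ids, 1)))
        perm.loc[perm.group == "mild", "specimen"] = \
            perm.loc[perm.group == "mild", "specimen"].map(mapping)
        for df in (a, perm):
            df_s = df.groupby(["group", "direction"])["strain_pct"].median()
        pd.testing.assert_series_equal(
            a.groupby(["group", "direction"])["strain_pct"].median(),
            perm.groupby(["group", "direction"])["strain_pct"].median())

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ms.CohortSpec(n_per_group=1)
        with pytest.raises(ValueError):
            ms.CohortSpec(load_levels=(0.0, 1.0))
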