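import math

import numpy as np
import pytest
from scipy import stats

from evstereo import (BodyKind, CultureParams, Scene, generate_scene,
                      render_patch)
from evstereo.errors import (InvalidGeometryError, InvalidInputError,
                             PackingError)
from evstereo.scene import OMEGA_RATE_43PCT


def poisson_gof_pvalue(counts: np.ndarray, lam: float) -> float:
    """Chi-square goodness of fit of integer counts against Poisson(lam)."""
    kmax = max(int(counts.max()), 1)
    obs = np.bincount(counts, minlength=kmax + 1).astype(float)
    exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
    exp[-1] = len(counts) - exp[:-1].sum()  # fold the tail into the last bin
    while len(exp) > 2 and exp[-1] < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    return float(stats.chisquare(obs, exp).pvalue)


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        params = CultureParams(n_cells=20, n_mcmv=10, seed=7)
        a = generate_scene(params).to_json()
        b = generate_scene(params).to_json()
        assert a == b

    def test_different_seed_differs(self):
        params = CultureParams(n_cells=20, n_mcmv=10)
        assert (generate_scene(params, seed=1).to_json()
                != generate_scene(params, seed=2).to_json())

    def test_json_round_trip(self, tmp_path):
        scene = generate_scene(CultureParams(n_cells=5, n_mcmv=5), seed=3)
        path = tmp_path / "scene.json"
        scene.save(path)
        again = Scene.load(path)
        assert again.to_json() == scene.to_json()


class TestSitePlacement:
    def test_zero_rate_gives_no_sites(self):
        scene = generate_scene(CultureParams(n_cells=50, n_mcmv=0,
                                             site_rate=0.0), seed=1)
        assert all(len(c.sites) == 0 for c in scene.cells)

    def test_poisson_site_mean(self):
        lam, n = 0.72, 10000
        scene = generate_scene(CultureParams(n_cells=n, n_mcmv=0,
                                             site_rate=lam), seed=2)
        mean = np.mean([len(c.sites) for c in scene.cells])
        assert abs(mean - lam) <= 3 * math.sqrt(lam / n)

    def test_site_count_distribution_is_poisson(self):
        scene = generate_scene(CultureParams(n_cells=10000, n_mcmv=0,
                                             site_rate=0.75), seed=11)
        counts = np.array([len(c.sites) for c in scene.cells])
        assert poisson_gof_pvalue(counts, 0.75) > 0.01

    def test_lateral_sites_fit_on_wall(self):
        scene = generate_scene(CultureParams(n_cells=500, n_mcmv=0,
                                             site_rate=2.0), seed=4)
        h = scene.params.cell_height_mean
        for c in scene.cells:
            for s in c.sites:
                if s.on_lateral:
                    lo, hi = s.z_interval
                    assert lo >= -1e-12 and hi <= h + 1e-12
                    assert s.z_extent == pytest.approx(2.0)

    def test_lateral_fraction_matches_area_split(self):
        """Sites split face/lateral in proportion to area (25% lateral)."""
        scene = generate_scene(CultureParams(n_cells=5000, n_mcmv=0,
                                             site_rate=1.0), seed=5)
        flags = [s.on_lateral for c in scene.cells for s in c.sites]
        frac = np.mean(flags)
        se = math.sqrt(0.25 * 0.75 / len(flags))
        assert abs(frac - 0.25) <= 3 * se


class TestBodies:
    def test_invariants_hold_over_many_seeds(self):
        for seed in range(100):
            scene = generate_scene(
                CultureParams(n_cells=2, n_mcmv=3, mvb_per_mcmv_mean=2.0),
                seed=seed)
            scene.check_invariants()

    def test_mcmv_never_intersects_coverslip(self):
        scene = generate_scene(CultureParams(n_cells=0, n_mcmv=500,
                                             ilv_occupancy=0.0), seed=6)
        for b in scene.bodies_of_kind(BodyKind.MCMV):
            assert b.z >= b.radius - 1e-12

    def test_mvb_count_distribution_is_poisson(self):
        # small MVBs keep the packing far from jamming so rejection
        # sampling cannot distort the count distribution
        scene = generate_scene(
            CultureParams(n_cells=0, n_mcmv=10000, mvb_per_mcmv_mean=1.0,
                          mvb_diameter_mean=0.15, ilv_occupancy=0.0,
                          omega_rate=0.0), seed=12)
        mcmvs = scene.bodies_of_kind(BodyKind.MCMV)
        counts = np.array([len(scene.children_of(b.body_id)) for b in mcmvs])
        assert poisson_gof_pvalue(counts, 1.0) > 0.01

    def test_omega_count_distribution_and_fraction(self):
        scene = generate_scene(
            CultureParams(n_cells=0, n_mcmv=10000, mvb_per_mcmv_mean=0.0,
                          ilv_occupancy=0.0), seed=14)
        mcmvs = scene.bodies_of_kind(BodyKind.MCMV)
        counts = np.array([len(scene.omega_marks.get(b.body_id, ()))
                           for b in mcmvs])
        assert poisson_gof_pvalue(counts, OMEGA_RATE_43PCT) > 0.01
        # the default rate is calibrated to 43% of MCMVs with >= 1 omega
        frac = (counts >= 1).mean()
        assert abs(frac - 0.43) <= 3 * math.sqrt(0.43 * 0.57 / len(counts))

    def test_ilv_occupancy_converges(self):
        scene = generate_scene(CultureParams(n_cells=0, n_mcmv=3000), seed=13)
        mvbs = scene.bodies_of_kind(BodyKind.MVB)
        occupied = np.array([len(scene.children_of(b.body_id)) > 0
                             for b in mvbs])
        se = math.sqrt(0.65 * 0.35 / len(occupied))
        assert abs(occupied.mean() - 0.65) <= 3 * se

    def test_fixed_count_model(self):
        scene = generate_scene(
            CultureParams(n_cells=0, n_mcmv=50, mvb_per_mcmv_mean=2.0,
                          mvb_count_model="fixed", fixed_sizes=True,
                          ilv_occupancy=0.0, omega_rate=0.0), seed=1)
        for b in scene.bodies_of_kind(BodyKind.MCMV):
            assert len(scene.children_of(b.body_id)) == 2

    def test_impossible_packing_raises(self):
        # two 0.9-μm spheres can never pack into a 1.08-μm container
        params = CultureParams(n_cells=0, n_mcmv=1, mvb_per_mcmv_mean=2.0,
                               mvb_diameter_mean=0.9, mcmv_diameter_mean=1.08,
                               fixed_sizes=True, mvb_count_model="fixed")
        with pytest.raises(PackingError, match="MCMV"):
            generate_scene(params, seed=1)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_scene(CultureParams(ilv_occupancy=1.5), seed=0)
        with pytest.raises(InvalidInputError):
            generate_scene(CultureParams(site_rate=-1.0), seed=0)
        with pytest.raises(InvalidInputError):
            generate_scene(CultureParams(mvb_count_model="negbin"), seed=0)


class TestRenderPatch:
    def test_mask_means_near_targets(self):
        patch = render_patch(180.0, 120.0, 10.0, 367.0, 4.0, seed=8)
        mi = patch.pixels[patch.inside_mask].mean()
        mo = patch.pixels[patch.outside_mask].mean()
        se_i = 10.0 / math.sqrt(patch.inside_mask.sum())
        se_o = 10.0 / math.sqrt(patch.outside_mask.sum())
        # quantisation to 8 bits adds < 0.3 grey levels of extra spread
        assert abs(mi - 180.0) <= 3 * se_i + 0.3
        assert abs(mo - 120.0) <= 3 * se_o + 0.3

    def test_identical_distributions_indistinguishable(self):
        patch = render_patch(140.0, 140.0, 10.0, 367.0, 4.0, seed=9)
        mi = patch.pixels[patch.inside_mask].mean()
        mo = patch.pixels[patch.outside_mask].mean()
        se = 10.0 * math.sqrt(1.0 / patch.inside_mask.sum()
                              + 1.0 / patch.outside_mask.sum())
        assert abs(mi - mo) < 4 * se

    def test_seed_determinism(self):
        a = render_patch(180.0, 120.0, 10.0, 367.0, 4.0, seed=10)
        b = render_patch(180.0, 120.0, 10.0, 367.0, 4.0, seed=10)
        assert np.array_equal(a.pixels, b.pixels)

    def test_disk_too_big_rejected(self):
        with pytest.raises(InvalidGeometryError):
            render_patch(180.0, 120.0, 10.0, 1000.0, 4.0, seed=0, patch_px=64)

    def test_grey_domain_enforced(self):
        with pytest.raises(InvalidInputError):
            render_patch(300.0, 120.0, 10.0, 367.0, 4.0, seed=0)
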