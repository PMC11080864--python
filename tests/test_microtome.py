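import math

import numpy as np
import pytest

from evstereo import (BodyKind, CultureParams, PancakeCell, SectionSlab,
                      SphereBody, band_fraction, generate_scene,
                      section_scene, sections_spanned, tabulate)
from evstereo.errors import InconsistencyError, InvalidInputError
from evstereo.microtome import SectionObservation
from evstereo.scene import CellInstance, ProtrusionSite, Scene


def make_scene(cells=(), bodies=(), omega_marks=None, params=None) -> Scene:
    """Hand-built scene for worked examples."""
    params = params or CultureParams(n_cells=len(cells), n_mcmv=0)
    return Scene(params=params, cells=list(cells), bodies=list(bodies),
                 omega_marks=omega_marks or {}, seed_used=0)


def plane_scan_slab_count(zc_nm, r_nm, thickness_nm, n_slabs, thr_nm=20.0):
    """Independent oracle: a slab shows the sphere iff some z-plane inside
    the slab cuts a chord of at least ``thr_nm``, scanned at 0.25 nm."""
    count = 0
    for k in range(n_slabs):
        z = np.arange(k * thickness_nm, (k + 1) * thickness_nm, 0.25)
        chord = 2 * np.sqrt(np.maximum(r_nm**2 - (z - zc_nm) ** 2, 0.0))
        count += bool((chord >= thr_nm).any())
    return count


class TestWorkedSingleBody:
    """MCMV (d = 1080 nm) resting at z = 0 with a concentric MVB (367 nm),
    serially sectioned at 70 nm."""

    @pytest.fixture()
    def table(self):
        mcmv = SphereBody((0, 0, 0.54), 1.08, BodyKind.MCMV, body_id=0)
        mvb = SphereBody((0, 0, 0.54), 0.367, BodyKind.MVB, parent=mcmv,
                         body_id=1)
        scene = make_scene(bodies=[mcmv, mvb])
        return tabulate(section_scene(scene, thickness_nm=70.0, mode="serial"))

    def test_slab_counts_match_plane_scan_oracle(self, table):
        mcmv_slabs = (table.rows["kind"] == "MCMV").sum()
        mvb_slabs = (table.rows["kind"] == "MVB").sum()
        assert mcmv_slabs == plane_scan_slab_count(540.0, 540.0, 70.0, 20)
        assert mvb_slabs == plane_scan_slab_count(540.0, 183.5, 70.0, 20)
        # frozen oracle values: 16 MCMV slabs, 6 MVB slabs
        assert (mcmv_slabs, mvb_slabs) == (16, 6)

    def test_mean_mvb_profiles_per_mcmv_slab(self, table):
        assert table.mean_mvb_profiles_per_mcmv == pytest.approx(6 / 16)

    def test_profile_diameters_bounded_by_truth(self, table):
        mvb = table.rows[table.rows["kind"] == "MVB"]
        assert (mvb["profile_nm"] <= 367.0 + 1e-9).all()
        assert mvb["profile_nm"].max() == pytest.approx(367.0)


class TestSerialConservation:
    def test_every_body_appears_in_its_span_of_slabs(self):
        """With no detection floor, a body's slab count equals the
        sections_spanned bookkeeping at its own z-offset."""
        scene = generate_scene(
            CultureParams(n_cells=0, n_mcmv=40, mvb_per_mcmv_mean=1.0,
                          ilv_occupancy=0.0, omega_rate=0.0), seed=21)
        obs = section_scene(scene, thickness_nm=70.0, mode="serial",
                            min_profile_nm=0.0)
        table = tabulate(obs)
        seen = table.rows[table.rows["kind"] != "cell"]
        per_body = seen.groupby("object_id").size()
        for b in scene.bodies:
            offset_nm = (b.z_bottom * 1000.0) % 70.0
            expected = sections_spanned(b.diameter * 1000.0, 70.0, offset_nm)
            assert per_body.get(b.body_id, 0) == expected

    def test_detection_floor_only_removes_small_caps(self):
        scene = generate_scene(
            CultureParams(n_cells=0, n_mcmv=40, mvb_per_mcmv_mean=1.0,
                          ilv_occupancy=0.0, omega_rate=0.0), seed=21)
        all_rows = tabulate(section_scene(scene, 70.0, min_profile_nm=0.0)).rows
        flt_rows = tabulate(section_scene(scene, 70.0, min_profile_nm=20.0)).rows
        assert len(flt_rows) <= len(all_rows)
        assert (flt_rows["profile_nm"].dropna() >= 20.0).all()


class TestSites:
    def test_site_within_one_slab_sighted_once(self):
        cell = PancakeCell(24.0, 4.0)
        site = ProtrusionSite(0, z_center=0.105, z_extent=0.02, azimuth=0.0,
                              on_lateral=True)  # [0.095, 0.115] within slab 1
        scene = make_scene(cells=[CellInstance(0, cell, (0, 0), (site,))])
        obs = section_scene(scene, thickness_nm=70.0, mode="serial")
        sighted = [o.slab.index for o in obs if o.cell_sightings[0]]
        assert sighted == [1]

    def test_face_sites_invisible_en_face(self):
        cell = PancakeCell(24.0, 4.0)
        site = ProtrusionSite(0, z_center=0.0, z_extent=2.0, azimuth=0.0,
                              on_lateral=False)
        scene = make_scene(cells=[CellInstance(0, cell, (0, 0), (site,))])
        obs = section_scene(scene, thickness_nm=70.0, mode="serial")
        assert not any(o.cell_sightings[0] for o in obs)

    def test_single_survey_sighting_probability(self):
        """Linchpin: the single-section sighting fraction matches the
        band-sampling model 1 − exp(−λ·p) with p = A_band/A_total."""
        lam, n = 0.75, 20000
        params = CultureParams(n_cells=n, n_mcmv=0, site_rate=lam)
        scene = generate_scene(params, seed=31)
        table = tabulate(section_scene(scene, 70.0,
                                       mode="single_random_per_cell", seed=32))
        p = band_fraction(PancakeCell(24.0, 4.0), 2.0)
        expected = 1.0 - math.exp(-lam * p)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(table.f_sites - expected) <= 3 * se

    def test_single_survey_deterministic_given_seed(self):
        scene = generate_scene(CultureParams(n_cells=200, n_mcmv=0), seed=33)
        a = tabulate(section_scene(scene, 70.0, "single_random_per_cell",
                                   seed=5)).rows
        b = tabulate(section_scene(scene, 70.0, "single_random_per_cell",
                                   seed=5)).rows
        assert a.equals(b)


class TestForwardFactor:
    def test_mean_profiles_ratio_matches_span_ratio(self):
        """Mean MVB profiles per MCMV slab converges to μ_N·(D+T)/(d+T)."""
        mu = 1.0
        params = CultureParams(n_cells=0, n_mcmv=400, mvb_per_mcmv_mean=mu,
                               fixed_sizes=True, mvb_count_model="fixed",
                               ilv_occupancy=0.0, omega_rate=0.0)
        scene = generate_scene(params, seed=41)
        table = tabulate(section_scene(scene, 70.0, mode="serial"))
        counts = table.per_mcmv_counts().astype(float)
        ratio = counts[:, 1].sum() / counts[:, 0].sum()
        resid = counts[:, 1] - ratio * counts[:, 0]
        se = math.sqrt((resid**2).sum()) / counts[:, 0].sum()
        expected = mu * (367.0 + 70.0) / (1080.0 + 70.0)
        assert abs(ratio - expected) <= 3 * se


class TestTabulate:
    def test_empty_scene_yields_empty_table(self):
        obs = section_scene(make_scene(), thickness_nm=70.0)
        assert obs == []
        table = tabulate(obs)
        assert len(table.rows) == 0
        assert math.isnan(table.f_sites)
        assert math.isnan(table.mean_mvb_profiles_per_mcmv)
        assert math.isnan(table.omega_fraction)
        assert math.isnan(table.ilv_fraction)

    def test_f_sites_from_counts(self):
        cell = PancakeCell(24.0, 4.0)
        cells = []
        for i in range(100):
            sites = ()
            if i < 9:  # 9 of 100 cells carry a mid-wall site
                sites = (ProtrusionSite(i, 2.0, 2.0, 0.0, True),)
            cells.append(CellInstance(i, cell, (0, 0), sites))
        scene = make_scene(cells=cells)
        obs = section_scene(scene, 70.0, mode="serial")
        # score a single mid-height section, as a one-section survey would
        mid = [o for o in obs if o.slab.index == 28]
        assert tabulate(mid).f_sites == pytest.approx(0.09)

    def test_omega_saturation(self):
        mcmv = SphereBody((0, 0, 0.54), 1.08, BodyKind.MCMV, body_id=0)
        marks = tuple((k + 0.5) * 0.07 for k in range(16))  # one mark per slab
        scene = make_scene(bodies=[mcmv], omega_marks={0: marks})
        table = tabulate(section_scene(scene, 70.0, mode="serial"))
        assert table.omega_fraction == 1.0

    def test_ilv_cosighting_requires_same_slab(self):
        mcmv = SphereBody((0, 0, 0.54), 1.08, BodyKind.MCMV, body_id=0)
        mvb = SphereBody((0, 0, 0.3), 0.367, BodyKind.MVB, parent=mcmv,
                         body_id=1)
        # ILV tucked at the MVB top: co-sighted only in upper MVB slabs
        ilv = SphereBody((0, 0, 0.42), 0.06, BodyKind.ILV, parent=mvb,
                         body_id=2)
        scene = make_scene(bodies=[mcmv, mvb, ilv])
        table = tabulate(section_scene(scene, 70.0, mode="serial"))
        mvb_rows = table.rows[table.rows["kind"] == "MVB"]
        with_ilv = mvb_rows[mvb_rows["contains_ilv"]]
        ilv_rows = table.rows[table.rows["kind"] == "ILV"]
        assert set(with_ilv["slab_index"]) == set(ilv_rows["slab_index"])
        assert 0.0 < table.ilv_fraction < 1.0

    def test_mixed_thickness_rejected(self):
        o1 = SectionObservation(SectionSlab(0, 0.07), {}, [], {})
        o2 = SectionObservation(SectionSlab(0, 0.05), {}, [], {})
        with pytest.raises(InconsistencyError):
            tabulate([o1, o2])

    def test_summary_recomputed_from_rows(self, tmp_path):
        scene = generate_scene(CultureParams(n_cells=10, n_mcmv=10), seed=51)
        table = tabulate(section_scene(scene, 70.0, mode="serial"))
        path = tmp_path / "counts.csv"
        table.to_csv(path)
        from evstereo.microtome import CountsTable
        again = CountsTable.from_csv(path, 70.0)
        assert again.summary() == pytest.approx(table.summary(), nan_ok=True)

    def test_invalid_mode_rejected(self):
        with pytest.raises(InvalidInputError):
            section_scene(make_scene(), 70.0, mode="oblique")
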