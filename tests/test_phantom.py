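"""Phantom generation, sensitivity fields, and OCT rendering."""

import dataclasses

import numpy as np
import pytest
import shapely

import gaconcord as g
from gaconcord.phantom import SCENARIO_NAMES, scenario_preset


class TestMakePhantom:
    def test_zero_offset_gives_identical_faf(self, concordant_phantom):
        for o, f in zip(concordant_phantom.oct_atrophy, concordant_phantom.faf_atrophy):
            assert o.equals(f)

    def test_positive_offset_dilates_faf(self):
        ph = g.make_phantom(scenario_preset("faf_offset"), seed=0)
        for o, f in zip(ph.oct_atrophy, ph.faf_atrophy):
            assert f.contains(o)
            assert f.area > o.area

    def test_step_sensitivity_field(self):
        cfg = g.PhantomConfig(
            lesions=(g.LesionSpec(center_deg=(0.0, 0.0), radius_deg=2.0),),
            transition_width_deg=0.0,
        )
        ph = g.make_phantom(cfg, seed=0)
        assert ph.sensitivity(0.0, 0.0) == -1.0
        assert ph.sensitivity(3.0, 0.0) == cfg.base_sensitivity_db

    def test_sigmoidal_transition_is_intermediate_at_border(self):
        cfg = g.PhantomConfig(
            lesions=(g.LesionSpec(center_deg=(0.0, 0.0), radius_deg=2.0),),
            transition_width_deg=0.5,
        )
        ph = g.make_phantom(cfg, seed=0)
        border = ph.sensitivity(2.0, 0.0)
        assert -1.0 < border < cfg.base_sensitivity_db
        # lesion centre is four transition widths deep: essentially floored
        assert ph.sensitivity(0.0, 0.0) == pytest.approx(-1.0, abs=0.3)

    def test_determinism_bit_identical(self):
        cfg = scenario_preset("concordant")
        a = g.make_phantom(cfg, seed=5)
        b = g.make_phantom(cfg, seed=5)
        sa = g.render_line_scan(a, "horizontal")
        sb = g.render_line_scan(b, "horizontal")
        assert np.array_equal(sa.image, sb.image)
        assert np.array_equal(sa.bm_rows, sb.bm_rows)

    def test_same_config_two_seeds_same_geometry_different_speckle(self):
        cfg = scenario_preset("concordant")
        a = g.make_phantom(cfg, seed=1)
        b = g.make_phantom(cfg, seed=2)
        assert a.oct_atrophy[0].equals(b.oct_atrophy[0])
        sa = g.render_line_scan(a, "horizontal")
        sb = g.render_line_scan(b, "horizontal")
        assert not np.array_equal(sa.image, sb.image)

    def test_invalid_polygon_rejected(self):
        bowtie = ((0, 0), (1, 1), (1, 0), (0, 1))
        with pytest.raises(ValueError):
            g.make_phantom(
                g.PhantomConfig(lesions=(g.LesionSpec(polygon_deg=bowtie),)), seed=0
            )


class TestRenderLineScan:
    def test_noiseless_no_atrophy_slab_mean_is_exact(self, noiseless_render):
        ph = g.make_phantom(g.PhantomConfig(lesions=()), seed=0)
        scan = g.render_line_scan(ph, "horizontal", noiseless_render)
        prof = g.reflectance_profile(scan)
        assert np.all(prof.mean_raw == noiseless_render.choroid_outside)

    def test_noiseless_lesion_step_profile(self, noiseless_render):
        # lesion spanning [-1, +1] deg on the horizontal axis
        cfg = g.PhantomConfig(
            lesions=(g.LesionSpec(center_deg=(0.0, 0.0), radius_deg=1.0),)
        )
        scan = g.render_line_scan(g.make_phantom(cfg, seed=0), "horizontal", noiseless_render)
        prof = g.reflectance_profile(scan)
        inside = np.abs(prof.positions_um) <= g.deg_to_um(1.0) - scan.lateral_scale_um_per_px
        outside = np.abs(prof.positions_um) >= g.deg_to_um(1.0) + scan.lateral_scale_um_per_px
        assert np.all(prof.mean_raw[inside] == noiseless_render.choroid_inside)
        assert np.all(prof.mean_raw[outside] == noiseless_render.choroid_outside)

    def test_speckle_slab_mean_near_truth(self):
        # law of large numbers: gamma speckle is unit-mean, so the slab mean
        # over hundreds of columns stays within 2 % of the noiseless level
        ph = g.make_phantom(g.PhantomConfig(lesions=()), seed=3)
        scan = g.render_line_scan(ph, "horizontal", g.RenderConfig())
        prof = g.reflectance_profile(scan)
        assert prof.mean_raw.size >= 500
        assert abs(prof.mean_raw.mean() - 80.0) / 80.0 < 0.02

    def test_vertical_axis_uses_y_coordinate(self, noiseless_render):
        cfg = g.PhantomConfig(
            lesions=(g.LesionSpec(center_deg=(0.0, 5.0), radius_deg=1.0),)
        )
        ph = g.make_phantom(cfg, seed=0)
        vert = g.reflectance_profile(
            g.render_line_scan(ph, "vertical", noiseless_render)
        )
        horiz = g.reflectance_profile(
            g.render_line_scan(ph, "horizontal", noiseless_render)
        )
        assert vert.mean_raw.max() == noiseless_render.choroid_inside
        assert horiz.mean_raw.max() == noiseless_render.choroid_outside

    def test_image_bounds_and_bm_recorded(self, noiseless_scan):
        assert noiseless_scan.image.min() >= 0
        assert noiseless_scan.image.max() <= 255
        assert noiseless_scan.bm_rows.shape == (noiseless_scan.image.shape[1],)


class TestScenarioPresets:
    def test_unknown_name_lists_presets(self):
        with pytest.raises(ValueError, match="concordant"):
            scenario_preset("nonexistent")

    def test_all_presets_materialise(self):
        for name in SCENARIO_NAMES:
            ph = g.make_phantom(scenario_preset(name), seed=0)
            assert ph.sensitivity(14.0, 0.0) == 14.0  # far periphery intact

    def test_between_lesions_truth(self, default_grid, noiseless_render):
        # scotoma on the horizontal line without hypertransmission
        ph = g.make_phantom(scenario_preset("between_lesions"), seed=0)
        smap = g.simulate_exam(ph, default_grid)
        line = g.loci_on_axis(smap, "horizontal")
        scot = g.scotoma_intervals(line, terminal_halfwidth_um=145.3)
        scan = g.render_line_scan(ph, "horizontal", noiseless_render)
        hyper = g.segment_hypertransmission(g.reflectance_profile(scan))
        assert not scot.is_empty
        assert hyper.is_empty

    def test_edge_of_lesion_truth(self, default_grid, noiseless_render):
        # hypertransmission without an absolute scotoma
        ph = g.make_phantom(scenario_preset("edge_of_lesion"), seed=0)
        smap = g.simulate_exam(ph, default_grid)
        line = g.loci_on_axis(smap, "horizontal")
        scot = g.scotoma_intervals(line, terminal_halfwidth_um=145.3)
        scan = g.render_line_scan(ph, "horizontal", noiseless_render)
        hyper = g.segment_hypertransmission(g.reflectance_profile(scan))
        assert scot.is_empty
        assert not hyper.is_empty

    def test_faf_offset_direction_monotone_in_dilation(self, default_grid, noiseless_render):
        # growing FAF dilation degrades FAF concordance, leaves OCT untouched
        dscs = []
        for offset in (0.0, 0.4, 0.8):
            cfg = dataclasses.replace(scenario_preset("concordant"), faf_offset_deg=offset)
            ph = g.make_phantom(cfg, seed=0)
            recs, _ = g.analyze_phantom(ph, default_grid, render=noiseless_render)
            faf = np.nanmean([r["dsc"] for r in recs if r["modality"] == "FAF"])
            oct_ = np.nanmean([r["dsc"] for r in recs if r["modality"] == "OCT"])
            dscs.append((oct_, faf))
        octs, fafs = zip(*dscs)
        assert octs[0] == octs[1] == octs[2]
        assert fafs[0] > fafs[1] > fafs[2]
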