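"""Generator contracts: determinism, truth consistency, soma
containment, and the Monte-Carlo behaviours of every synthetic input."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gliamorph import assays, simulate
from gliamorph.geometry import SocialArenaGeometry
from gliamorph.simulate import (
    CellSpec,
    MarkSheetSpec,
    TrackSpec,
    default_flow_populations,
    generate_cell,
    generate_flow_events,
    generate_mark_sheet,
    generate_phagocytosis_scene,
    generate_track,
    render_scene,
)


class TestGenerateCell:
    def test_process_free_cell_is_a_disk(self, rng):
        spec = CellSpec(soma_radius_px=5.0, soma_axis_ratio=1.0, n_primary_processes=0)
        cell, soma, params = generate_cell(spec, rng)
        assert params["cell_area_px"] == params["soma_area_px"]
        assert np.array_equal(cell, soma)

    def test_single_component_and_soma_containment(self):
        from scipy import ndimage

        rng = np.random.default_rng(42)
        for _ in range(20):
            cell, soma, _ = generate_cell(CellSpec(), rng)
            _, n = ndimage.label(cell, structure=np.ones((3, 3), bool))
            assert n == 1
            assert not np.any(soma & ~cell)

    def test_zero_soma_radius_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_cell(CellSpec(soma_radius_px=0.0), rng)

    def test_soma_area_scales_quadratically_with_radius(self):
        # 1.3× the soma radius → soma area ratio ≈ 1.69 over generator draws
        rng = np.random.default_rng(7)
        preset = simulate.resting_preset(seed=0)
        base, scaled = [], []
        for _ in range(200):
            spec = simulate.draw_cell_spec(preset, rng)
            _, _, p = generate_cell(spec, rng)
            base.append(p["soma_area_px"])
            spec2 = dataclasses.replace(spec, soma_radius_px=spec.soma_radius_px * 1.3)
            _, _, p2 = generate_cell(spec2, rng)
            scaled.append(p2["soma_area_px"])
        assert np.mean(scaled) / np.mean(base) == pytest.approx(1.69, abs=0.06)


class TestRenderScene:
    def test_empty_scene_is_pure_background(self):
        preset = simulate.resting_preset(seed=3, n_cells=0)
        scene = render_scene(preset)
        assert scene.truth_labels.max() == 0
        assert len(scene.truth_params) == 0

    def test_truth_labels_count_and_containment(self, standard_scene):
        labels = np.unique(standard_scene.truth_labels)
        assert len(labels[labels > 0]) == 30
        # every labelled soma pixel carries the same cell label
        soma = standard_scene.truth_soma_labels
        cell = standard_scene.truth_labels
        assert np.all(cell[soma > 0] == soma[soma > 0])

    def test_bit_identical_regeneration(self):
        preset = simulate.resting_preset(seed=11, n_cells=6,
                                         stack_shape=(6, 192, 192),
                                         min_center_spacing_px=40.0)
        a = render_scene(preset)
        b = render_scene(preset)
        assert np.array_equal(a.stack, b.stack)
        assert np.array_equal(a.truth_labels, b.truth_labels)
        pd.testing.assert_frame_equal(a.truth_params, b.truth_params)

    def test_truth_params_match_label_pixel_counts(self, standard_scene):
        # ground truth is recomputable by naive counting over the label images
        for _, row in standard_scene.truth_params.iloc[:5].iterrows():
            assert (standard_scene.truth_labels == row.label).sum() == row.cell_area_px
            assert (standard_scene.truth_soma_labels == row.label).sum() == row.soma_area_px

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError):
            render_scene(simulate.resting_preset(seed=0, n_cells=200)).stack


class TestPhagocytosisScene:
    def test_zero_fraction_has_no_engulfed_signal(self, rng):
        sc = generate_phagocytosis_scene(4, 0.0, rng)
        assert not np.any(sc.particle_channel_mask & sc.cell_channel_mask)
        assert sc.truth_engulfed_fraction == 0.0

    @pytest.mark.parametrize("f", [0.1, 0.2, 0.5, 1.0])
    def test_truth_within_one_pixel_quantum(self, f, rng):
        sc = generate_phagocytosis_scene(5, f, rng)
        cell_px = sc.cell_channel_mask.sum()
        assert abs(sc.truth_engulfed_fraction - f) <= 1.0 / cell_px
        # truth is the exact pixel-count ratio
        overlap = int((sc.particle_channel_mask & sc.cell_channel_mask).sum())
        assert sc.truth_engulfed_fraction == overlap / cell_px

    def test_no_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_phagocytosis_scene(0, 0.2, rng)


class TestMarkSheet:
    def test_all_blobs_in_target_circle_gives_100(self):
        spec = MarkSheetSpec(target_bias=1.0, blob_radius_cm=(0.2, 0.3))
        ms = generate_mark_sheet(spec, np.random.default_rng(5))
        # blob centres inside the circle; tolerate rim overhang of big blobs
        assert ms.truth_preference > 95.0

    def test_uniform_placement_matches_area_share(self):
        spec = MarkSheetSpec(target_bias=0.0)
        geo = spec.geometry
        vals = []
        for i in range(500):
            ms = generate_mark_sheet(spec, np.random.default_rng(i))
            if not ms.undefined:
                vals.append(ms.truth_preference)
        expected = 100.0 * np.pi * geo.radius_cm ** 2 / geo.arena_size_cm ** 2
        assert np.mean(vals) == pytest.approx(expected, abs=1.0)

    def test_zero_blobs_flagged_undefined(self):
        ms = generate_mark_sheet(MarkSheetSpec(n_blobs_mean=0.0),
                                 np.random.default_rng(0))
        assert ms.undefined and np.isnan(ms.truth_preference)


class TestTrack:
    def test_equal_propensities_give_unit_quotient(self):
        qs = []
        for i in range(40):
            tr = generate_track(TrackSpec(propensities=(0.25, 0.25, 0.5)),
                                np.random.default_rng(i))
            qs.append(tr.truth_social_s / tr.truth_object_s)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.08)

    def test_double_social_propensity_doubles_quotient(self):
        qs = []
        for i in range(200):
            tr = generate_track(TrackSpec(propensities=(0.4, 0.2, 0.4)),
                                np.random.default_rng(i))
            qs.append(tr.truth_social_s / tr.truth_object_s)
        assert np.mean(qs) == pytest.approx(2.0, abs=0.15)

    def test_truth_equals_per_frame_membership(self):
        tr = generate_track(TrackSpec(duration_s=60.0), np.random.default_rng(9))
        geo = tr.geometry
        x = tr.frames.x.to_numpy()
        y = tr.frames.y.to_numpy()
        assert tr.truth_social_s == pytest.approx(
            geo.in_zone(x, y, "social").sum() * 0.1, abs=1e-9
        )

    def test_overlapping_zones_rejected(self):
        with pytest.raises(ValueError):
            SocialArenaGeometry(social_center_cm=(20, 20), object_center_cm=(25, 25))

    def test_zero_object_time_flagged(self):
        tr = generate_track(
            TrackSpec(duration_s=10.0, propensities=(0.5, 0.0, 0.5)),
            np.random.default_rng(1),
        )
        assert tr.undefined


class TestFlowEvents:
    def test_truth_fraction_exact_by_construction(self, rng):
        pops = default_flow_populations(n_total=10_000, macrophage_frac=0.10)
        events, truth = generate_flow_events(pops, rng)
        assert truth["macrophage"] == 0.100
        assert (events.truth_label == "macrophage").sum() == 1000

    def test_empty_populations_give_empty_table(self, rng):
        pops = default_flow_populations(n_total=0)
        events, _ = generate_flow_events(pops, rng)
        assert len(events) == 0

    def test_separated_mixture_gate_recovers_truth(self, rng):
        events, truth = generate_flow_events(default_flow_populations(), rng)
        gate = assays.GateSpec(
            thresholds={"CD11b": 10 ** 2.0, "CD45": 10 ** 2.25},
            parent=("CD11b", "hi"),
            child=("CD45", "hi"),
        )
        res = assays.gate_fraction(events, gate)
        assert abs(res.value - truth["macrophage"]) < 0.01
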