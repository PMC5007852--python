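"""Scalar assays: exact agreement with generator truth and the stated
boundedness/monotonicity properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from gliamorph import assays, simulate
from gliamorph.assays import (
    GateSpec,
    count_cells,
    count_colocalized,
    gate_fraction,
    marking_preference,
    phagocytic_index,
    si_quotient,
)
from gliamorph.geometry import MarkSheetGeometry, SocialArenaGeometry


def disk(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestPhagocyticIndex:
    def test_no_particle_inside_cells_is_zero(self):
        cells = disk((64, 64), 20, 20, 10)
        particles = disk((64, 64), 50, 50, 5)
        assert phagocytic_index(cells, particles).value == 0.0

    def test_particles_tiling_cells_give_one(self):
        cells = disk((64, 64), 32, 32, 10)
        assert phagocytic_index(cells, cells.copy()).value == 1.0

    def test_particle_fully_inside_is_area_ratio(self):
        cells = disk((64, 64), 32, 32, 12)
        particle = disk((64, 64), 32, 32, 4)
        res = phagocytic_index(cells, particle)
        assert res.value == particle.sum() / cells.sum()

    def test_matches_generator_truth_exactly(self, rng):
        for _ in range(20):
            f = rng.uniform(0.0, 0.9)
            sc = simulate.generate_phagocytosis_scene(4, f, rng)
            res = phagocytic_index(sc.cell_channel_mask, sc.particle_channel_mask)
            assert res.value == sc.truth_engulfed_fraction
            assert 0.0 <= res.value <= 1.0

    def test_zero_cell_area_rejected(self):
        with pytest.raises(ValueError):
            phagocytic_index(np.zeros((8, 8), bool), np.zeros((8, 8), bool))


class TestColocalization:
    def _soma_labels(self, centers, shape=(128, 128), r=4):
        labels = np.zeros(shape, dtype=np.int32)
        for i, (cy, cx) in enumerate(centers, start=1):
            labels[disk(shape, cy, cx, r)] = i
        return labels

    def test_empty_marker_counts_zero(self):
        labels = self._soma_labels([(30, 30), (80, 80)])
        assert count_colocalized(labels, np.zeros(labels.shape, bool)).value == 0

    def test_marker_covering_all_somas_counts_all(self):
        labels = self._soma_labels([(30, 30), (80, 80), (30, 90)])
        assert count_colocalized(labels, np.ones(labels.shape, bool)).value == 3

    def test_random_marker_matches_centroid_membership_loop(self, rng):
        for _ in range(30):
            centers = [(int(rng.integers(10, 118)), int(rng.integers(10, 118)))
                       for _ in range(6)]
            labels = self._soma_labels(centers)
            marker = rng.random(labels.shape) < 0.3
            got = count_colocalized(labels, marker).value
            expect = 0
            for lbl in np.unique(labels[labels > 0]):
                ys, xs = np.nonzero(labels == lbl)
                cy = int(round(ys.mean()))
                cx = int(round(xs.mean()))
                expect += bool(marker[cy, cx])
            assert got == expect

    def test_monotone_under_marker_dilation(self, rng):
        labels = self._soma_labels([(30, 30), (60, 90), (100, 40)])
        marker = rng.random(labels.shape) < 0.1
        prev = count_colocalized(labels, marker).value
        for _ in range(4):
            marker = ndimage.binary_dilation(marker)
            cur = count_colocalized(labels, marker).value
            assert cur >= prev
            prev = cur


class TestCountCells:
    def test_empty_labels_count_zero(self):
        assert count_cells(np.zeros((32, 32), np.int32), (0, 32, 0, 32)).value == 0

    def test_full_frame_window_counts_all(self, standard_scene):
        res = count_cells(standard_scene.truth_soma_labels, (0, 512, 0, 512))
        assert res.value == 30

    def test_window_membership_matches_direct_count(self, standard_scene):
        win = (0, 256, 0, 512)
        got = count_cells(standard_scene.truth_soma_labels, win).value
        soma = standard_scene.truth_soma_labels
        expect = 0
        for lbl in np.unique(soma[soma > 0]):
            ys, xs = np.nonzero(soma == lbl)
            expect += int(round(ys.mean())) < 256
        assert got == expect


class TestGateFraction:
    def _events(self, rng, n=1000):
        return pd.DataFrame({
            "CD11b": 10 ** rng.normal(3.0, 0.2, n),
            "CD45": 10 ** rng.normal(2.0, 0.4, n),
        })

    def test_child_threshold_below_all_events_gives_one(self, rng):
        ev = self._events(rng)
        gate = GateSpec({"CD11b": 0.0, "CD45": 0.0}, ("CD11b", "hi"), ("CD45", "hi"))
        assert gate_fraction(ev, gate).value == 1.0

    def test_empty_parent_rejected(self, rng):
        ev = self._events(rng)
        gate = GateSpec({"CD11b": 1e12, "CD45": 10.0}, ("CD11b", "hi"), ("CD45", "hi"))
        with pytest.raises(ValueError):
            gate_fraction(ev, gate)

    def test_invariant_under_joint_monotone_transform(self, rng):
        ev = self._events(rng)
        thr = {"CD11b": 10 ** 2.8, "CD45": 10 ** 2.1}
        gate = GateSpec(thr, ("CD11b", "hi"), ("CD45", "hi"))
        base = gate_fraction(ev, gate).value
        ev_t = np.arcsinh(ev / 150.0)
        gate_t = GateSpec(
            {k: float(np.arcsinh(v / 150.0)) for k, v in thr.items()},
            ("CD11b", "hi"), ("CD45", "hi"),
        )
        assert gate_fraction(ev_t, gate_t).value == base

    def test_same_channel_parent_child_rejected(self):
        with pytest.raises(ValueError):
            GateSpec({"CD45": 1.0}, ("CD45", "hi"), ("CD45", "lo"))


class TestMarkingPreference:
    def test_all_marks_inside_target_circle_is_100(self):
        geo = MarkSheetGeometry()
        sheet = np.zeros(geo.sheet_shape, bool)
        target = geo.target_circle_mask()
        sheet[target] = True
        assert marking_preference(sheet, geo).value == 100.0

    def test_half_area_inside_is_50(self):
        geo = MarkSheetGeometry()
        target = geo.target_circle_mask()
        inside = np.argwhere(target)[:100]
        outside = np.argwhere(~target & ~geo.circle_mask(1)
                              & ~geo.circle_mask(2) & ~geo.circle_mask(3))[:100]
        sheet = np.zeros(geo.sheet_shape, bool)
        sheet[tuple(inside.T)] = True
        sheet[tuple(outside.T)] = True
        assert marking_preference(sheet, geo).value == 50.0

    def test_matches_pixel_membership_oracle_exactly(self, rng):
        geo = MarkSheetGeometry()
        target = geo.target_circle_mask()
        for _ in range(20):
            sheet = rng.random(geo.sheet_shape) < 0.05
            res = marking_preference(sheet, geo)
            expect = 100.0 * (sheet & target).sum() / sheet.sum()
            assert res.value == expect
            assert 0.0 <= res.value <= 100.0

    def test_adding_marks_outside_every_circle_decreases_preference(self, rng):
        spec = simulate.MarkSheetSpec(target_bias=0.8)
        ms = simulate.generate_mark_sheet(spec, rng)
        before = marking_preference(ms.sheet, ms.geometry).value
        outside_all = ~np.logical_or.reduce(
            [ms.geometry.circle_mask(q) for q in range(4)]
        ) & ~ms.sheet
        extra = np.argwhere(outside_all)[:200]
        sheet2 = ms.sheet.copy()
        sheet2[tuple(extra.T)] = True
        assert marking_preference(sheet2, ms.geometry).value < before

    def test_blank_sheet_flagged_undefined(self):
        geo = MarkSheetGeometry()
        res = marking_preference(np.zeros(geo.sheet_shape, bool), geo)
        assert res.undefined and np.isnan(res.value)


class TestSIQuotient:
    def _track_at(self, geo, zone_frames):
        rows = []
        t = 0.0
        for which, n in zone_frames:
            for _ in range(n):
                if which == "social":
                    x, y = geo.social_center_cm[0] + geo.cylinder_radius_cm + 1.0, \
                        geo.social_center_cm[1]
                elif which == "object":
                    x, y = geo.object_center_cm[0] + geo.cylinder_radius_cm + 1.0, \
                        geo.object_center_cm[1]
                else:
                    x, y = 25.0, 5.0
                rows.append({"t": t, "x": x, "y": y})
                t += 0.1
        return pd.DataFrame(rows)

    def test_equal_dwell_gives_one(self):
        geo = SocialArenaGeometry()
        track = self._track_at(geo, [("social", 50), ("object", 50), ("nowhere", 20)])
        assert si_quotient(track, geo).value == pytest.approx(1.0)

    def test_three_to_one_dwell_ratio(self):
        geo = SocialArenaGeometry()
        track = self._track_at(geo, [("social", 300), ("object", 100)])
        assert si_quotient(track, geo).value == pytest.approx(3.0)

    def test_matches_generator_truth_exactly(self):
        for i in range(10):
            tr = simulate.generate_track(
                simulate.TrackSpec(duration_s=120.0), np.random.default_rng(i)
            )
            res = si_quotient(tr.frames, tr.geometry, 0.1)
            if tr.undefined:
                assert res.undefined
            else:
                assert res.value == tr.truth_social_s / tr.truth_object_s

    def test_zero_object_time_flagged(self):
        geo = SocialArenaGeometry()
        track = self._track_at(geo, [("social", 30)])
        res = si_quotient(track, geo)
        assert res.undefined and np.isnan(res.value)
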