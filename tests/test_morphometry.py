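"""Process classification, 5-point diameter, orientation, Feret coverage."""

import numpy as np
import pytest

from _oracles import feret_sweep
from glioquant.morphometry import (
    OligoCell,
    ProcessTrace,
    TopologyError,
    classify_processes,
    coverage,
    process_diameter,
    process_length,
    process_orientation,
    width_from_image,
)
from glioquant.synthetic_data import gen_oligo_cell, gen_tube_chip


def straight_trace(tid="p0", kind="primary", start=(0, 0), end=(10, 0),
                   widths=None, parent=None, myel=False):
    pl = np.linspace(start, end, 5)
    return ProcessTrace("c1", tid, kind, pl, parent, widths, myel)


def cell_of(traces):
    return OligoCell("c1", (0.0, 0.0), 17.0, tuple(traces))


class TestClassify:
    def test_star_of_five_myelinating_primaries(self):
        traces = [
            straight_trace(f"p{i}", end=(np.cos(a) * 20, np.sin(a) * 20), myel=True)
            for i, a in enumerate(np.linspace(0, 2 * np.pi, 5, endpoint=False))
        ]
        counts = classify_processes(cell_of(traces))
        assert (counts["primary"], counts["secondary"], counts["blind"]) == (5, 0, 0)
        assert counts["myelinating"] == 5
        assert counts["all"] == 5

    def test_mixed_composition(self):
        traces = [straight_trace(f"p{i}", end=(10 + i, 5)) for i in range(3)]
        traces += [
            straight_trace(f"s{j}", "secondary", (5, 2), (8, 8), parent="p0")
            for j in range(2)
        ]
        traces += [straight_trace(f"b{k}", "blind", (0, 0), (2, 1)) for k in range(4)]
        counts = classify_processes(cell_of(traces))
        assert (counts["primary"], counts["secondary"], counts["blind"]) == (3, 2, 4)
        assert counts["all"] == 9

    def test_orphan_secondary_is_topology_error(self):
        with pytest.raises(TopologyError):
            cell_of([straight_trace("s0", "secondary", parent="missing")])
        with pytest.raises(TopologyError):
            ProcessTrace("c1", "s0", "secondary", np.array([[0, 0], [1, 1]]))

    def test_generator_counts_exact_for_50_cells(self):
        rng = np.random.default_rng(0)
        for seed in range(50):
            spec = dict(
                n_primary=int(rng.integers(1, 7)),
                n_secondary=int(rng.integers(0, 4)),
                n_blind=int(rng.integers(0, 5)),
            )
            cell, truth = gen_oligo_cell(**spec, seed=seed)
            counts = classify_processes(cell)
            assert counts["primary"] == truth["counts"]["primary"]
            assert counts["secondary"] == truth["counts"]["secondary"]
            assert counts["blind"] == truth["counts"]["blind"]
            assert counts["myelinating"] == truth["counts"]["myelinating"]


class TestLengthOrientation:
    def test_3_4_5_segment(self):
        t = ProcessTrace("c1", "p0", "primary", np.array([[0, 0], [30, 40]]))
        assert process_length(t) == pytest.approx(50.0)

    def test_zigzag_of_unit_steps(self):
        k = 12
        pts = [(i // 2 + (i % 2) * 0.0, 0.0) for i in range(1)]  # placeholder
        # unit steps alternating +x and +y
        pts = [(0.0, 0.0)]
        for i in range(k):
            x, y = pts[-1]
            pts.append((x + 1, y) if i % 2 == 0 else (x, y + 1))
        t = ProcessTrace("c1", "p0", "primary", np.array(pts))
        assert process_length(t) == pytest.approx(k)

    def test_random_polyline_vs_piecewise_sum(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, (40, 2))
        t = ProcessTrace("c1", "p0", "primary", pts)
        expected = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(len(pts) - 1)
        )
        assert process_length(t) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "end,angle",
        [((10, 0), 0.0), ((0, 10), 90.0), ((1, 1), 45.0), ((-1, 1), 45.0), ((5, -5), 45.0)],
    )
    def test_chord_angle_folded(self, end, angle):
        pl = np.array([[0.0, 0.0], list(end)])
        t = ProcessTrace("c1", "p0", "primary", pl)
        assert process_orientation(t) == pytest.approx(angle)

    def test_zero_chord_undefined(self):
        t = ProcessTrace("c1", "p0", "primary", np.array([[0, 0], [5, 5], [0, 0]]))
        with pytest.raises(ValueError):
            process_orientation(t)


class TestDiameter:
    def test_constant_width(self):
        ws = tuple((f, 1.2) for f in np.linspace(0, 1, 6))
        t = straight_trace(widths=ws)
        assert process_diameter(t) == pytest.approx(1.2)

    def test_linear_taper_2_to_0(self):
        ws = ((0.0, 2.0), (0.5, 1.0), (1.0, 1e-12))
        # width 2*(1-f): samples at .1,.3,.5,.7,.9 -> 1.8,1.4,1.0,0.6,0.2
        ws = tuple((f, 2.0 * (1.0 - f) + 1e-15) for f in np.linspace(0, 1, 11))
        t = straight_trace(widths=ws)
        assert process_diameter(t) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("power", [1, 2])
    def test_monotone_taper_matches_analytic_five_point_mean(self, power):
        f_dense = np.linspace(0, 1, 101)
        ws = tuple((f, 2.0 - 1.5 * f**power) for f in f_dense)
        t = straight_trace(widths=ws)
        expected = np.mean([2.0 - 1.5 * f**power for f in (0.1, 0.3, 0.5, 0.7, 0.9)])
        # dense sampling makes linear interpolation error negligible
        assert process_diameter(t) == pytest.approx(expected, abs=1e-3)

    def test_unmeasurable_center_substitutes_nearest(self):
        # overlap region around f = 0.5 unmeasurable; nearest measurable is f = 0.45
        ws = ((0.0, 2.0), (0.1, 2.0), (0.3, 2.0), (0.45, 2.0), (0.5, float("nan")),
              (0.7, 1.0), (0.9, 1.0), (1.0, 1.0))
        t = straight_trace(widths=ws)
        # fractions .1,.3 -> 2.0 ; .5 -> nearest measurable (0.45) -> 2.0 ; .7,.9 -> 1.0
        d = process_diameter(t)
        assert d == pytest.approx(np.mean([2.0, 2.0, 2.0, 1.0, 1.0]))

    def test_no_measurable_position_gives_nan(self):
        ws = ((0.0, float("nan")), (1.0, float("nan")))
        t = straight_trace(widths=ws)
        assert np.isnan(process_diameter(t))

    def test_generator_taper_matches_truth_exactly(self):
        cell, truth = gen_oligo_cell(n_primary=3, n_secondary=0, n_blind=0, seed=5)
        by_id = {t.trace_id: t for t in cell.traces}
        for tr in truth["traces"]:
            d = process_diameter(by_id[tr["trace_id"]])
            assert d == pytest.approx(tr["diameter_um"], abs=1e-9)

    def test_image_based_width_fwhm(self):
        """FWHM width on a synthetic tube image recovers the planted 0.8 um."""
        chip, _ = gen_tube_chip(
            outer_width_um=0.8, filled=True, snr=50, pixel_size_um=0.05, seed=2
        )
        w = width_from_image(
            chip, point=(5.55 / 2, 5.55 / 2), tangent=(0.0, 1.0), pixel_size_um=0.05
        )
        assert w == pytest.approx(0.8, abs=0.1)


class TestCoverage:
    def test_square_closed_form(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [5, 5]], dtype=float)
        traces = [
            ProcessTrace("c1", f"p{i}", "primary", np.array([[5.0, 5.0], p]))
            for i, p in enumerate(pts[:4])
        ]
        cov = coverage(cell_of(traces))
        assert cov.area_um2 == pytest.approx(100.0)
        assert cov.feret_min_um == pytest.approx(10.0)
        assert cov.feret_max_um == pytest.approx(10 * np.sqrt(2))
        assert cov.shape_ratio == pytest.approx(1 / np.sqrt(2))

    def test_regular_64gon_nearly_round(self):
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        traces = [
            ProcessTrace("c1", f"p{i}", "primary",
                         np.array([[0.0, 0.0], [np.cos(a) * 30, np.sin(a) * 30]]))
            for i, a in enumerate(ang)
        ]
        cov = coverage(cell_of(traces))
        assert cov.shape_ratio >= 0.995

    def test_collinear_cell_degenerate(self):
        traces = [
            ProcessTrace("c1", "p0", "primary", np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        ]
        with pytest.raises(ValueError, match="degenerate"):
            coverage(cell_of(traces))

    def test_feret_extremes_match_projection_sweep(self):
        """Caliper Feret min/max equal the 0.1 degree sweep oracle on 100 clouds."""
        rng = np.random.default_rng(13)
        for _ in range(100):
            pts = rng.uniform(0, 50, (int(rng.integers(5, 30)), 2))
            traces = [ProcessTrace("c1", "p0", "primary", pts)]
            try:
                cov = coverage(cell_of(traces))
            except ValueError:
                continue
            lo, hi = feret_sweep(pts, 0.1)
            assert cov.feret_max_um == pytest.approx(hi, rel=1e-5)
            # sweep can only overestimate the true min by the angular step
            assert cov.feret_min_um == pytest.approx(lo, rel=1e-3)
            assert cov.feret_min_um <= lo + 1e-9

    def test_interior_points_do_not_change_hull(self):
        rng = np.random.default_rng(14)
        pts = rng.uniform(0, 50, (20, 2))
        cov1 = coverage(cell_of([ProcessTrace("c1", "p0", "primary", pts)]))
        centroid = pts.mean(axis=0)
        interior = centroid + 0.1 * (pts - centroid)
        cov2 = coverage(
            cell_of([ProcessTrace("c1", "p0", "primary", np.vstack([pts, interior]))])
        )
        assert cov2.area_um2 == pytest.approx(cov1.area_um2)
        assert cov2.feret_max_um == pytest.approx(cov1.feret_max_um)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(15)
        pts = rng.uniform(0, 40, (15, 2))
        base = coverage(cell_of([ProcessTrace("c1", "p0", "primary", pts)]))
        theta = 37.0
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        rot = pts @ np.array([[c, s], [-s, c]])
        rcov = coverage(cell_of([ProcessTrace("c1", "p0", "primary", rot)]))
        assert rcov.area_um2 == pytest.approx(base.area_um2)
        assert rcov.feret_min_um == pytest.approx(base.feret_min_um)
        assert rcov.feret_max_um == pytest.approx(base.feret_max_um)
        assert rcov.shape_ratio == pytest.approx(base.shape_ratio)
        assert rcov.feret_angle_deg == pytest.approx(
            (base.feret_angle_deg + theta) % 180.0, abs=1e-6
        )


class TestGeneratorRoundTrip:
    def test_morphometrics_match_generator_truth(self):
        """For 50 seeded synthetic cells every morphometric output matches
        the analytic ground truth: counts exact, lengths/orientations to
        high precision, diameters to 1e-9."""
        for seed in range(50):
            cell, truth = gen_oligo_cell(
                n_primary=4, n_secondary=2, n_blind=2, seed=seed
            )
            by_id = {t.trace_id: t for t in cell.traces}
            for tr in truth["traces"]:
                t = by_id[tr["trace_id"]]
                assert process_length(t) == pytest.approx(tr["length_um"], rel=1e-9)
                assert process_orientation(t) == pytest.approx(
                    tr["orientation_deg"], abs=1e-6
                )
                if tr["diameter_um"] is not None:
                    assert process_diameter(t) == pytest.approx(
                        tr["diameter_um"], abs=1e-9
                    )

    def test_planted_orientation_30_degrees(self):
        cell, truth = gen_oligo_cell(
            n_primary=2, n_secondary=0, n_blind=0,
            orientations_deg=[30.0, 150.0], seed=1,
        )
        for t in cell.traces:
            assert process_orientation(t) == pytest.approx(30.0, abs=1e-9)
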