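"""Quantification: counting, fractions, density maps, DP distances, profiles."""

import numpy as np
import pandas as pd
import pytest
import shapely.affinity
import shapely.geometry as sgeom
from matplotlib.path import Path as MplPath

from spinefem.errors import ParameterError, SchemaError, UndefinedValueError
from spinefem.geometry import build_base_geometry
from spinefem.quantify import (
    AnnotatedSection,
    area_fraction_profile,
    assign_regions,
    density_map,
    labeled_fraction,
    min_distance_to_dp,
    region_counts,
    stack_depth,
)
from spinefem.synth import GeneratorConfig, generate_section


def brute_force_counts(section, marker):
    """O(N*M) first-match point-in-polygon scan with matplotlib paths."""
    pts = section.marker_points(marker)
    counts = {name: 0 for name, _ in section.ordered_regions()}
    paths = {}
    for name, poly in section.ordered_regions():
        parts = getattr(poly, "geoms", [poly])
        paths[name] = [
            (
                MplPath(np.asarray(part.exterior.coords)),
                [MplPath(np.asarray(r.coords)) for r in part.interiors],
            )
            for part in parts
        ]
    for p in pts:
        for name, _ in section.ordered_regions():
            hit = any(
                outer.contains_point(p)
                and not any(h.contains_point(p) for h in holes)
                for outer, holes in paths[name]
            )
            if hit:
                counts[name] += 1
                break
    return counts


@pytest.fixture(scope="module")
def synthetic_section():
    return generate_section(GeneratorConfig(), seed=11)


class TestRegionCounts:
    def test_points_in_single_square_region(self):
        pts = pd.DataFrame(
            {"x": np.linspace(1, 9, 10), "y": np.linspace(1, 9, 10), "marker": "hoechst"}
        )
        section = AnnotatedSection(
            frame=(20, 20),
            origin=(0, 0),
            points=pts,
            regions={"dp": sgeom.box(0, 0, 10, 10), "medulla": sgeom.box(12, 12, 19, 19)},
        )
        counts = region_counts(section, "hoechst")
        assert counts == {"dp": 10, "medulla": 0}

    def test_matches_brute_force_scan(self, synthetic_section):
        for marker in ("hoechst", "brdu"):
            assert region_counts(synthetic_section, marker) == brute_force_counts(
                synthetic_section, marker
            )

    def test_missing_marker_gives_zero_counts(self, synthetic_section):
        counts = region_counts(synthetic_section, "ph3")
        assert all(v >= 0 for v in counts.values())
        empty = generate_section(GeneratorConfig(), seed=11)
        assert sum(region_counts(empty, "tunel").values()) >= 0

    def test_counting_conservation(self, synthetic_section):
        """Assigned + unassigned = total, for every marker."""
        for marker in ("hoechst", "brdu", "k71"):
            assigned = assign_regions(synthetic_section, marker)
            counts = region_counts(synthetic_section, marker)
            n_total = len(synthetic_section.marker_points(marker))
            assert sum(counts.values()) + int((assigned == "").sum()) == n_total

    def test_overlapping_regions_warn_and_stay_deterministic(self):
        pts = pd.DataFrame({"x": [5.0], "y": [5.0], "marker": "hoechst"})
        section = AnnotatedSection(
            frame=(20, 20),
            origin=(0, 0),
            points=pts,
            regions={"dp": sgeom.box(0, 0, 10, 10), "medulla": sgeom.box(4, 4, 12, 12)},
        )
        with pytest.warns(UserWarning, match="first-match"):
            counts = region_counts(section, "hoechst")
        assert counts == {"dp": 1, "medulla": 0}  # declared order wins


class TestLabeledFraction:
    def test_all_labeled_gives_one(self):
        pts = pd.DataFrame(
            {
                "x": [1, 2, 3, 1, 2, 3],
                "y": [1, 1, 1, 1, 1, 1],
                "marker": ["hoechst"] * 3 + ["brdu"] * 3,
            }
        )
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts,
            regions={"dp": sgeom.box(0, 0, 5, 5)},
        )
        assert labeled_fraction(section, "dp", "brdu") == 1.0

    def test_equals_bruteforce_subset_ratio(self, synthetic_section):
        region = "posterior_with_brdu"
        num = brute_force_counts(synthetic_section, "brdu")[region]
        den = brute_force_counts(synthetic_section, "hoechst")[region]
        # brute force assigns first-match; the region overlaps no earlier one
        assert labeled_fraction(synthetic_section, region, "brdu") == pytest.approx(
            num / den
        )

    def test_empty_denominator_is_undefined_not_zero(self):
        pts = pd.DataFrame({"x": [1.0], "y": [1.0], "marker": "brdu"})
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts,
            regions={"dp": sgeom.box(5, 5, 9, 9)},
        )
        with pytest.raises(UndefinedValueError):
            labeled_fraction(section, "dp", "brdu")


class TestDensityMap:
    def test_single_point(self):
        pts = pd.DataFrame({"x": [5.0], "y": [5.0], "marker": "tunel"})
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts, regions={"dp": sgeom.box(0, 0, 1, 1)}
        )
        dm = density_map(section, "tunel")
        assert dm.values.max() == 1.0
        xs, ys = dm.grid_points()
        X, Y = np.meshgrid(xs, ys)
        dist = np.hypot(X - 5.0, Y - 5.0)
        assert np.all(dm.values[dist > dm.radius] == 0.0)

    def test_matches_bruteforce_distance_scan(self, synthetic_section):
        dm = density_map(synthetic_section, "hoechst")
        pts = synthetic_section.marker_points("hoechst")
        xs, ys = dm.grid_points()
        X, Y = np.meshgrid(xs, ys)
        nodes = np.column_stack([X.ravel(), Y.ravel()])
        counts = (
            (np.linalg.norm(nodes[:, None, :] - pts[None, :, :], axis=2) <= dm.radius)
            .sum(axis=1)
            .reshape(dm.values.shape)
        )
        assert np.array_equal(dm.values, counts / counts.max())

    def test_homogeneous_smoother_than_clustered(self):
        """Relative density varies less for CSR points than for a cluster."""
        rng = np.random.default_rng(5)
        n = 400
        csr = rng.uniform(0, 100, size=(n, 2))
        cluster = rng.normal(50, 6, size=(n, 2)).clip(0, 100)

        def cv(points):
            pts = pd.DataFrame({"x": points[:, 0], "y": points[:, 1], "marker": "hoechst"})
            sec = AnnotatedSection(
                frame=(100, 100), origin=(0, 0), points=pts,
                regions={"dp": sgeom.box(0, 0, 1, 1)},
            )
            v = density_map(sec, "hoechst").values
            return v.std() / v.mean()

        assert cv(csr) < cv(cluster)

    def test_no_points_flagged_zero_map(self):
        pts = pd.DataFrame(columns=["x", "y", "marker"])
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts, regions={"dp": sgeom.box(0, 0, 1, 1)}
        )
        dm = density_map(section, "brdu")
        assert dm.empty and dm.values.max() == 0.0


class TestMinDistanceToDP:
    def test_point_inside_dp_scores_zero(self):
        pts = pd.DataFrame({"x": [2.0], "y": [2.0], "marker": "brdu"})
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts, regions={"dp": sgeom.box(0, 0, 4, 4)}
        )
        dist, summary = min_distance_to_dp(section, "brdu")
        assert dist[0] == 0.0 and summary["mean"] == 0.0

    def test_distance_to_circular_dp(self):
        r, d = 3.0, 2.5
        dp = sgeom.Point(0, 0).buffer(r, quad_segs=128)
        pts = pd.DataFrame({"x": [r + d], "y": [0.0], "marker": "ph3"})
        section = AnnotatedSection(
            frame=(20, 20), points=pts, regions={"dp": dp}
        )
        dist, _ = min_distance_to_dp(section, "ph3")
        assert dist[0] == pytest.approx(d, abs=1e-3)  # vertex discretization

    def test_matches_edge_scan_oracle(self, synthetic_section):
        dist, summary = min_distance_to_dp(synthetic_section, "brdu")
        dp = synthetic_section.regions["dp"]
        pts = synthetic_section.marker_points("brdu")
        exterior = np.asarray(dp.exterior.coords)
        path = MplPath(exterior)

        def point_segment_distance(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        ref = []
        for p in pts:
            if path.contains_point(p):
                ref.append(0.0)
            else:
                ref.append(
                    min(
                        point_segment_distance(p, exterior[i], exterior[i + 1])
                        for i in range(len(exterior) - 1)
                    )
                )
        assert np.allclose(dist, ref, atol=1e-9)
        assert summary["mean"] == pytest.approx(np.mean(ref))

    def test_no_marker_points_signalled(self):
        pts = pd.DataFrame({"x": [1.0], "y": [1.0], "marker": "hoechst"})
        section = AnnotatedSection(
            frame=(10, 10), origin=(0, 0), points=pts, regions={"dp": sgeom.box(0, 0, 4, 4)}
        )
        with pytest.raises(UndefinedValueError):
            min_distance_to_dp(section, "tunel")


class TestStackDepth:
    @pytest.mark.parametrize(
        "n,thickness,expected", [(41, 7.0, 287.0), (102, 7.0, 714.0), (1, 7.0, 7.0),
                                 (24, 7.0, 168.0)]
    )
    def test_serial_stack_totals(self, n, thickness, expected):
        assert stack_depth(n, thickness) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            stack_depth(0, 7.0)
        with pytest.raises(ParameterError):
            stack_depth(5, -1.0)


class TestAreaFractionProfile:
    def test_identical_levels_flat_trends(self, default_geometry):
        df = area_fraction_profile([default_geometry] * 3)
        assert np.abs(df.drop(columns="level").sum(axis=1) - 1).max() < 1e-9
        for comp, t in df.attrs["trends"].items():
            assert t["net_change"] == pytest.approx(0.0, abs=1e-12)
            assert t["monotone_nondecreasing"] and t["monotone_nonincreasing"]

    def test_fractions_match_shoelace_ratios(self, default_geometry):
        from tests.test_geometry import polygon_area_shoelace

        df = area_fraction_profile([default_geometry] * 2)
        areas = {
            n: polygon_area_shoelace(p)
            for n, p in default_geometry.compartments.items()
        }
        total = sum(areas.values())
        for name, area in areas.items():
            assert df[name].iloc[0] == pytest.approx(area / total, rel=1e-9)

    def test_trajectory_endpoints_match_anchor_fractions(self, full_trajectory):
        df = area_fraction_profile(full_trajectory)
        cortex0 = df.iloc[0]["cortex_posterior"] + df.iloc[0]["cortex_anterior"]
        cortex1 = df.iloc[-1]["cortex_posterior"] + df.iloc[-1]["cortex_anterior"]
        assert 100 * cortex0 == pytest.approx(67.0, abs=1.0)
        assert 100 * cortex1 == pytest.approx(27.0, abs=3.0)

    def test_single_level_rejected(self, default_geometry):
        with pytest.raises(ParameterError):
            area_fraction_profile([default_geometry])

    def test_inconsistent_compartments_schema_error(self, default_geometry):
        partial = build_base_geometry()
        del partial.compartments["outer_ring"]
        with pytest.raises(SchemaError):
            area_fraction_profile([default_geometry, partial])


class TestScaleInvariance:
    def test_counts_and_fractions_invariant_under_rescaling(self, synthetic_section):
        s = 2.7
        sec = synthetic_section
        pts = sec.points.copy()
        pts[["x", "y"]] *= s
        scaled = AnnotatedSection(
            frame=(sec.frame[0] * s, sec.frame[1] * s),
            origin=(sec.origin[0] * s, sec.origin[1] * s),
            points=pts,
            regions={
                n: shapely.affinity.scale(p, xfact=s, yfact=s, origin=(0, 0))
                for n, p in sec.regions.items()
            },
        )
        assert region_counts(scaled, "hoechst") == region_counts(sec, "hoechst")
        assert labeled_fraction(scaled, "posterior_with_brdu", "brdu") == pytest.approx(
            labeled_fraction(sec, "posterior_with_brdu", "brdu")
        )
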