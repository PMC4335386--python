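"""Quantification of annotated follicle sections.

Mirrors how the study's micrographs were analysed: cells are points with a
marker label (Hoechst nuclei, BrdU S-phase, pH3 M-phase, TUNEL apoptotic,
K71 IRS), regions are polygons drawn relative to the dermal papilla (DP),
and all statistics are defined on point-in-region membership:

* region counts per marker (first-match assignment in declared region order);
* labeled fractions (marker-positive over Hoechst nuclei in a region);
* local relative density maps (counts within a radius equal to a fraction of
  the image diagonal, normalized to the map maximum);
* minimal distances of marker-positive cells to the DP boundary (a proxy for
  the range of DP signaling);
* serial-stack depth bookkeeping (n sections x section thickness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from scipy.spatial import cKDTree

from .errors import ParameterError, SchemaError, UndefinedValueError

MARKERS = ("hoechst", "brdu", "ph3", "tunel", "k71")

#: canonical region order: the DP first, then the shaft core, then the six
#: matrix/IRS counting areas; first-match assignment follows this order
REGION_ORDER = (
    "dp",
    "medulla",
    "posterior_with_brdu",
    "posterior_without_brdu",
    "anterior_with_brdu",
    "anterior_without_brdu",
    "irs_posterior",
    "irs_anterior",
)


@dataclass
class AnnotatedSection:
    """Cell points with marker labels plus region polygons for one section."""

    frame: tuple[float, float]  # (width, height), um or px
    points: pd.DataFrame  # columns x, y, marker
    regions: dict[str, sgeom.Polygon]
    origin: tuple[float, float] | None = None  # lower-left corner; default centred
    z_index: int | None = None
    thickness: float | None = None  # um

    def __post_init__(self):
        w, h = self.frame
        if w <= 0 or h <= 0:
            raise ParameterError("frame width/height must be > 0")
        if self.origin is None:
            self.origin = (-w / 2.0, -h / 2.0)
        required = {"x", "y", "marker"}
        if not required.issubset(self.points.columns):
            raise SchemaError(f"points table needs columns {sorted(required)}")
        bad = set(self.points["marker"].unique()) - set(MARKERS)
        if bad:
            raise SchemaError(f"unknown markers {sorted(bad)}; allowed: {MARKERS}")
        x0, y0 = self.origin
        inside = (
            self.points["x"].between(x0, x0 + w) & self.points["y"].between(y0, y0 + h)
        )
        if not inside.all():
            raise ParameterError(
                f"{int((~inside).sum())} points fall outside the image frame"
            )

    @property
    def diagonal(self) -> float:
        return float(np.hypot(*self.frame))

    def marker_points(self, marker: str) -> np.ndarray:
        sel = self.points["marker"] == marker
        return self.points.loc[sel, ["x", "y"]].to_numpy(dtype=float)

    def ordered_regions(self) -> list[tuple[str, sgeom.Polygon]]:
        order = [n for n in REGION_ORDER if n in self.regions]
        order += [n for n in self.regions if n not in REGION_ORDER]
        return [(n, self.regions[n]) for n in order]


@dataclass
class DensityMap:
    """Relative local density on a square grid (values normalized to max 1)."""

    values: np.ndarray  # (ny, nx) in [0, 1]
    radius: float
    spacing: float
    origin: tuple[float, float]
    empty: bool = False

    def grid_points(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.origin[0] + self.spacing * np.arange(nx)
        ys = self.origin[1] + self.spacing * np.arange(ny)
        return xs, ys

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")


def _warn_on_overlap(regions: list[tuple[str, sgeom.Polygon]]) -> None:
    for i, (na, pa) in enumerate(regions):
        for nb, pb in regions[i + 1 :]:
            if pa.intersects(pb) and pa.intersection(pb).area > 1e-9:
                warnings.warn(
                    f"regions '{na}' and '{nb}' overlap; points are assigned "
                    "first-match in declared region order",
                    stacklevel=3,
                )
                return


def assign_regions(section: AnnotatedSection, marker: str) -> np.ndarray:
    """Region name per marker point ('' = unassigned), first-match order."""
    pts = section.marker_points(marker)
    assigned = np.full(len(pts), "", dtype=object)
    if len(pts) == 0:
        return assigned
    regions = section.ordered_regions()
    _warn_on_overlap(regions)
    geoms = shapely.points(pts)
    for name, poly in regions:
        hit = shapely.covers(poly, geoms) & (assigned == "")
        assigned[hit] = name
    return assigned


def region_counts(section: AnnotatedSection, marker: str) -> dict[str, int]:
    """Number of marker points per region (boundary points count as inside)."""
    assigned = assign_regions(section, marker)
    counts = {name: 0 for name, _ in section.ordered_regions()}
    for name in assigned:
        if name:
            counts[name] += 1
    return counts


def labeled_fraction(section: AnnotatedSection, region: str, marker: str) -> float:
    """Marker-positive fraction among Hoechst nuclei inside one region."""
    if region not in section.regions:
        raise KeyError(f"unknown region '{region}'")
    poly = section.regions[region]
    nuclei = section.marker_points("hoechst")
    if len(nuclei) == 0:
        raise UndefinedValueError(f"no nuclei (hoechst) points in region '{region}'")
    n_nuc = int(shapely.covers(poly, shapely.points(nuclei)).sum())
    if n_nuc == 0:
        raise UndefinedValueError(f"no nuclei (hoechst) points in region '{region}'")
    pts = section.marker_points(marker)
    n_pos = int(shapely.covers(poly, shapely.points(pts)).sum()) if len(pts) else 0
    return n_pos / n_nuc


def density_map(
    section: AnnotatedSection,
    marker: str,
    radius_fraction: float = 0.03,
    grid_spacing: float | None = None,
) -> DensityMap:
    """Local relative density of marker points.

    At each node of a square grid the number of marker points within a
    radius of ``radius_fraction`` of the image diagonal is counted and the
    map is normalized by its maximum (blue-to-red rendering in the study).
    Grid spacing defaults to radius/4.
    """
    if radius_fraction <= 0:
        raise ParameterError("radius_fraction must be > 0")
    radius = radius_fraction * section.diagonal
    spacing = grid_spacing if grid_spacing is not None else radius / 4.0
    w, h = section.frame
    x0, y0 = section.origin
    xs = x0 + spacing * np.arange(int(np.floor(w / spacing)) + 1)
    ys = y0 + spacing * np.arange(int(np.floor(h / spacing)) + 1)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    pts = section.marker_points(marker)
    if len(pts) == 0:
        return DensityMap(
            values=np.zeros((len(ys), len(xs))),
            radius=radius,
            spacing=spacing,
            origin=(float(xs[0]), float(ys[0])),
            empty=True,
        )
    tree = cKDTree(pts)
    counts = tree.query_ball_point(nodes, r=radius, return_length=True)
    values = counts.reshape(len(ys), len(xs)).astype(float)
    values /= values.max()
    return DensityMap(
        values=values, radius=radius, spacing=spacing, origin=(float(xs[0]), float(ys[0]))
    )


def min_distance_to_dp(
    section: AnnotatedSection, marker: str
) -> tuple[np.ndarray, dict[str, float]]:
    """Euclidean distance of each marker point to the DP boundary.

    Points inside the DP score 0.  Returns the per-point distances and a
    summary (mean and quartiles/90th percentile) — the mean is the study's
    "range of DP signaling" statistic.
    """
    if "dp" not in section.regions:
        raise KeyError("section has no 'dp' region")
    pts = section.marker_points(marker)
    if len(pts) == 0:
        raise UndefinedValueError(f"no '{marker}' points in section")
    dp = section.regions["dp"]
    geoms = shapely.points(pts)
    dist = shapely.distance(geoms, dp)  # 0 inside/on the polygon
    summary = {
        "n": int(len(dist)),
        "mean": float(np.mean(dist)),
        "q25": float(np.percentile(dist, 25)),
        "median": float(np.percentile(dist, 50)),
        "q75": float(np.percentile(dist, 75)),
        "q90": float(np.percentile(dist, 90)),
    }
    return np.asarray(dist, dtype=float), summary


def stack_depth(n_sections: int, thickness: float) -> float:
    """Total depth (um) covered by ``n_sections`` serial sections."""
    if n_sections < 1:
        raise ParameterError(f"n_sections must be >= 1, got {n_sections}")
    if thickness <= 0:
        raise ParameterError(f"thickness must be > 0, got {thickness}")
    return n_sections * thickness


def area_fraction_profile(levels) -> pd.DataFrame:
    """Per-level compartment area fractions with monotonicity diagnostics.

    ``levels`` may be a :class:`~spinefem.morphogenesis.SimulationTrajectory`,
    a sequence of :class:`~spinefem.geometry.FollicleGeometry`, or a sequence
    of :class:`AnnotatedSection` (region polygon areas are used).  Fractions
    in each row sum to 1; ``df.attrs['trends']`` maps each compartment to its
    net change and whether the series is monotone.
    """
    from .geometry import FollicleGeometry  # local import to avoid cycles

    rows = []
    if hasattr(levels, "records"):  # SimulationTrajectory
        rec = levels.records
        frac_cols = [c for c in rec.columns if c.startswith("frac_")]
        for _, r in rec.iterrows():
            rows.append({c.removeprefix("frac_"): r[c] for c in frac_cols})
    else:
        levels = list(levels)
        for lev in levels:
            if isinstance(lev, FollicleGeometry):
                rows.append(lev.area_fractions())
            elif isinstance(lev, AnnotatedSection):
                areas = {n: p.area for n, p in lev.regions.items()}
                total = sum(areas.values())
                rows.append({n: a / total for n, a in areas.items()})
            else:
                raise SchemaError(f"unsupported level type {type(lev)!r}")
    if len(rows) < 2:
        raise ParameterError("a profile needs at least 2 levels")
    keys = set(rows[0])
    for i, r in enumerate(rows):
        if set(r) != keys:
            raise SchemaError(
                f"level {i} has compartments {sorted(r)} != {sorted(keys)}"
            )
    df = pd.DataFrame(rows)
    df.insert(0, "level", np.arange(len(df)))
    trends = {}
    for k in sorted(keys):
        series = df[k].to_numpy()
        diffs = np.diff(series)
        trends[k] = {
            "net_change": float(series[-1] - series[0]),
            "monotone_nonincreasing": bool(np.all(diffs <= 1e-12)),
            "monotone_nondecreasing": bool(np.all(diffs >= -1e-12)),
        }
    df.attrs["trends"] = trends
    return df
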