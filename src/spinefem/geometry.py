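"""Parametric transverse-section geometry of the spiny-mouse spine follicle.

The follicle cross-section is modelled as a radially stratified ("onion")
domain around the section centroid: going outward along any ray one crosses,
in order, the medulla, the cortex, the inner root sheath (IRS) and the outer
ring (outer root sheath / Henle's layer and confinement).  Every layer
boundary is a single-valued polar curve ``r(theta)``, which makes the domain
star-shaped and lets the mesher produce a conforming triangulation directly
from the analytic curves.

Conventions
-----------
* origin at the follicle centre, units are micrometres (um);
* anterior = -x, posterior = +x (the ``anterior_axis`` field records this);
* angles measured counter-clockwise from the +x (posterior) direction.

The medulla is a two-lobed crescent: the disc bounded by an *outer arc*
(circle of radius ``medulla_outer_radius`` whose centre is shifted toward the
anterior side) minus a posterior *bite* (a second circle carving into the
disc from the posterior side).  The two horns flanking the bite are the
crescent's lobes.  The bite circle is derived, not free: it is sized so that
the posterior cortex at its apex is ``cortex_eccentricity`` times thicker
than the anterior cortex at its apex, and so that the crescent's horn tips
sit at ``medulla_lobe_half_angle`` from the posterior direction.  With
``cortex_eccentricity == 1`` the construction degenerates to concentric
annuli (no bite, no anterior offset).

The anterior IRS carries a protrusion: a smooth local thickening of the IRS
that digs into the anterior cortex, seeded in the base geometry and amplified
by growth during the simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import shapely.geometry as sgeom

from .errors import GeometryError, ParameterError

COMPARTMENTS = (
    "medulla",
    "cortex_posterior",
    "cortex_anterior",
    "irs_posterior",
    "irs_anterior",
    "outer_ring",
)

CORTEX_COMPARTMENTS = ("cortex_posterior", "cortex_anterior")
IRS_COMPARTMENTS = ("irs_posterior", "irs_anterior")


def _wrap(theta):
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(theta, dtype=float), 2.0 * np.pi)


def angular_distance(theta, center):
    """Absolute angular distance between ``theta`` and ``center``."""
    return np.abs(_wrap(np.asarray(theta, dtype=float) - center))


def protrusion_bump(u):
    """Smooth compact bump: cos^2(pi*u/2) on |u| < 1, zero outside."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    out[inside] = np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


@dataclass(frozen=True)
class GeometryParams:
    """Free parameters of the baseline follicle cross-section.

    All lengths in um, angles in radians.  Defaults are stored in the shipped
    default config (``spinefem/data/default_config.yaml``); the values here
    mirror it so ``GeometryParams()`` is usable stand-alone.
    """

    follicle_radius: float = 100.0
    medulla_outer_radius: float = 36.26
    #: explicit anterior offset of the medulla outer arc (um); ``None`` derives
    #: it from ``cortex_eccentricity`` so the posterior:anterior apex thickness
    #: ratio equals the eccentricity exactly.
    medulla_anterior_offset: float | None = None
    #: half-angle (from the posterior direction) at which the crescent's
    #: horn tips sit.
    medulla_lobe_half_angle: float = math.radians(48.0)
    #: depth of the posterior bite as a fraction of the medulla's posterior
    #: apex radius; carves the concavity between the two lobes.
    medulla_bite_depth: float = 0.4
    #: target posterior:anterior cortex apex thickness ratio; 1 = concentric.
    cortex_eccentricity: float = 3.5
    irs_thickness: float = 6.0
    protrusion_depth: float = 8.0
    protrusion_half_width: float = math.radians(30.0)
    ring_thickness: float = 4.0
    #: documented construction target for the cortex share of section area.
    base_cortex_fraction: float = 0.67
    #: polygon sampling density per closed curve.
    n_vertices: int = 256

    def __post_init__(self):
        positive = (
            "follicle_radius",
            "medulla_outer_radius",
            "irs_thickness",
            "ring_thickness",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.cortex_eccentricity < 1.0:
            raise ParameterError(
                "cortex_eccentricity (posterior:anterior thickness ratio) must be"
                f" >= 1, got {self.cortex_eccentricity}"
            )
        if self.protrusion_depth < 0:
            raise ParameterError("protrusion_depth must be >= 0")
        if not 0 < self.medulla_lobe_half_angle < math.pi:
            raise ParameterError("medulla_lobe_half_angle must be in (0, pi)")
        if not 0 < self.protrusion_half_width <= math.pi:
            raise ParameterError("protrusion_half_width must be in (0, pi]")
        if self.medulla_anterior_offset is not None and self.medulla_anterior_offset < 0:
            raise ParameterError("medulla_anterior_offset must be >= 0")
        if not 0 < self.medulla_bite_depth < 1:
            raise ParameterError("medulla_bite_depth must be in (0, 1)")
        if self.n_vertices < 64:
            raise ParameterError("n_vertices must be >= 64 (curve fidelity)")
        if self.medulla_outer_radius >= self.follicle_radius:
            raise ParameterError("medulla_outer_radius must be < follicle_radius")


@dataclass(frozen=True)
class Stratification:
    """Analytic polar description of the layered cross-section.

    Radius curves are single-valued functions of the polar angle; the
    structured mesher and the thickness/weight queries evaluate them exactly.
    """

    follicle_radius: float
    ring_inner_radius: float
    irs_base_inner_radius: float
    protrusion_depth: float
    protrusion_half_width: float
    protrusion_center: float
    medulla_center_offset: float  # effective anterior offset (>= 0)
    medulla_outer_radius: float
    bite_center: float | None  # +x position of bite circle centre, None = no bite
    bite_radius: float | None
    cortex_split_angle: float  # posterior cortex spans |theta| <= this
    irs_split_angle: float = math.pi / 2.0

    def r_outer(self, theta):
        return np.full_like(np.asarray(theta, dtype=float), self.follicle_radius)

    def r_ring_inner(self, theta):
        return np.full_like(np.asarray(theta, dtype=float), self.ring_inner_radius)

    def r_cortex_outer(self, theta):
        """IRS inner boundary = cortex outer boundary (protrusion digs in)."""
        u = angular_distance(theta, self.protrusion_center) / self.protrusion_half_width
        return self.irs_base_inner_radius - self.protrusion_depth * protrusion_bump(u)

    def _r_medulla_arc(self, theta):
        """Outer arc: circle radius R_m centred at (-a, 0), seen from origin."""
        theta = np.asarray(theta, dtype=float)
        a, rm = self.medulla_center_offset, self.medulla_outer_radius
        return -a * np.cos(theta) + np.sqrt(rm**2 - (a * np.sin(theta)) ** 2)

    def _r_bite_near(self, theta):
        """Near edge of the posterior bite circle (NaN where the ray misses it)."""
        theta = np.asarray(theta, dtype=float)
        d, rb = self.bite_center, self.bite_radius
        disc = rb**2 - (d * np.sin(theta)) ** 2
        near = np.where(disc >= 0, d * np.cos(theta) - np.sqrt(np.maximum(disc, 0.0)), np.nan)
        return near

    def r_medulla(self, theta):
        """Medulla boundary: outer arc clipped by the posterior bite."""
        arc = self._r_medulla_arc(theta)
        if self.bite_center is None:
            return arc
        near = self._r_bite_near(theta)
        # the bite carves the posterior side only (forward ray intersections
        # within the lobe span); elsewhere the outer arc stands
        in_bite = (
            (angular_distance(theta, 0.0) <= self.cortex_split_angle + 1e-12)
            & ~np.isnan(near)
            & (near > 0)
        )
        return np.where(in_bite, np.minimum(arc, near), arc)

    def irs_growth_weight(self, theta):
        """Relative growth-rate weight of the anterior-IRS protrusion zone."""
        u = angular_distance(theta, self.protrusion_center) / self.protrusion_half_width
        return protrusion_bump(u)

    def layer_curves(self):
        """Boundary curves from centre outward, as (name, r(theta)) pairs."""
        return [
            ("medulla", self.r_medulla),
            ("cortex", self.r_cortex_outer),
            ("irs", self.r_ring_inner),
            ("ring", self.r_outer),
        ]


@dataclass
class FollicleGeometry:
    """Labelled compartment polygons of one transverse section."""

    compartments: dict[str, sgeom.Polygon]
    anterior_axis: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.0]))
    frame: tuple[float, float, float, float] | None = None
    stratification: Stratification | None = None

    def __post_init__(self):
        if self.frame is None:
            self.frame = tuple(
                shapely.unary_union(list(self.compartments.values())).bounds
            )

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.compartments.values()))

    def area_fractions(self) -> dict[str, float]:
        total = self.total_area
        return {k: p.area / total for k, p in self.compartments.items()}


def _derive_stratification(params: GeometryParams) -> Stratification:
    R = params.follicle_radius
    ring_inner = R - params.ring_thickness
    irs_inner = ring_inner - params.irs_thickness
    if irs_inner <= 0:
        raise ParameterError("ring_thickness + irs_thickness exceed follicle_radius")

    e = params.cortex_eccentricity
    rm = params.medulla_outer_radius
    beta = params.medulla_bite_depth
    c0 = irs_inner  # cortex outer radius at the posterior apex (no protrusion)
    cpi = irs_inner - params.protrusion_depth  # ... at the anterior apex

    if e == 1.0:
        a = 0.0
    elif params.medulla_anterior_offset is not None:
        a = params.medulla_anterior_offset
    else:
        # offset chosen so that, with the bite carved, posterior apex cortex
        # thickness = e * anterior apex cortex thickness:
        #   c0 - (rm - a)(1 - beta) = e * (cpi - rm - a)
        a = (e * (cpi - rm) - c0 + (1.0 - beta) * rm) / (e + 1.0 - beta)
        if a <= 0:
            raise GeometryError(
                "eccentricity target not reachable: derived anterior offset is "
                "non-positive; enlarge the medulla or reduce the protrusion"
            )
    if a >= rm:
        raise ParameterError("anterior offset must stay below medulla_outer_radius")

    strat = Stratification(
        follicle_radius=R,
        ring_inner_radius=ring_inner,
        irs_base_inner_radius=irs_inner,
        protrusion_depth=params.protrusion_depth,
        protrusion_half_width=params.protrusion_half_width,
        protrusion_center=math.pi,
        medulla_center_offset=a,
        medulla_outer_radius=rm,
        bite_center=None,
        bite_radius=None,
        cortex_split_angle=math.pi / 2.0,
    )

    # Anterior apex cortex thickness (protrusion included).
    t_ant = float(strat.r_cortex_outer(math.pi) - strat._r_medulla_arc(math.pi))
    if t_ant <= 0:
        raise GeometryError(
            "anterior IRS protrusion digs deeper than the local cortex thickness"
        )

    if e == 1.0:
        return strat

    # Posterior bite circle: passes through the crescent horn tips at
    # +/- the lobe half-angle and through the bite floor at the posterior apex.
    theta_t = params.medulla_lobe_half_angle
    m_b = (rm - a) * (1.0 - beta)
    if m_b <= 0:
        raise GeometryError("medulla bite reaches the follicle centre")
    r_t = float(strat._r_medulla_arc(theta_t))
    denom = r_t * math.cos(theta_t) - m_b
    if denom <= 0:
        raise GeometryError(
            "lobe half-angle incompatible with the requested bite depth "
            "(horn tip lies anterior of the bite floor)"
        )
    d_b = (r_t**2 - m_b**2) / (2.0 * denom)
    r_b = d_b - m_b
    if r_b <= 0 or d_b <= r_b:
        raise GeometryError("degenerate bite circle; adjust medulla parameters")

    strat = replace(strat, bite_center=d_b, bite_radius=r_b)

    # The bite must cut clean through the outer arc so every ray crosses the
    # medulla at most once (star-shapedness of the crescent).
    th = np.linspace(-theta_t, theta_t, 181)
    disc = r_b**2 - (d_b * np.sin(th)) ** 2
    far = d_b * np.cos(th) + np.sqrt(np.maximum(disc, 0.0))
    if np.any(disc < -1e-9) or np.any(far < strat._r_medulla_arc(th) - 1e-9):
        raise GeometryError(
            "bite circle does not span the lobe range; increase the lobe "
            "half-angle or the bite depth"
        )
    return strat


def _angle_grid(params: GeometryParams, strat: Stratification) -> np.ndarray:
    """Global angle samples including all compartment split meridians."""
    splits = {
        -strat.cortex_split_angle,
        strat.cortex_split_angle,
        -strat.irs_split_angle,
        strat.irs_split_angle,
        -math.pi,
    }
    grid = set(np.linspace(-math.pi, math.pi, params.n_vertices, endpoint=False))
    # snap nearest grid angle onto each split meridian to keep spacing even
    garr = np.array(sorted(grid))
    for s in splits:
        nearest = garr[np.argmin(np.abs(garr - s))]
        grid.discard(nearest)
        grid.add(s)
        garr = np.array(sorted(grid))
    return np.array(sorted(grid))


def _band_polygon(r_in, r_out, thetas, closed: bool) -> sgeom.Polygon:
    """Polygon between two radial curves over an angular range.

    ``closed=True`` builds full annulus-like shapes (hole if r_in > 0);
    otherwise an angular band closed by radial edges at the range ends.
    """
    thetas = np.asarray(thetas, dtype=float)
    ro = np.asarray(r_out, dtype=float)
    ri = np.asarray(r_in, dtype=float)
    outer = np.column_stack([ro * np.cos(thetas), ro * np.sin(thetas)])
    if closed:
        if np.all(ri <= 1e-12):
            return sgeom.Polygon(outer)
        inner = np.column_stack([ri * np.cos(thetas), ri * np.sin(thetas)])
        return sgeom.Polygon(outer, [inner[::-1]])
    inner = np.column_stack([ri * np.cos(thetas), ri * np.sin(thetas)])
    ring = np.vstack([outer, inner[::-1]])
    return sgeom.Polygon(ring)


def _sector_angles(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Grid angles covering [lo, hi], wrapping through pi when lo > hi."""
    if lo <= hi:
        sel = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
        return sel
    # wrap-around sector (through the anterior meridian at pi)
    upper = grid[grid >= lo - 1e-12]
    lower = grid[grid <= hi + 1e-12]
    return np.concatenate([upper, lower + 2.0 * np.pi])


def build_base_geometry(params: GeometryParams | None = None) -> FollicleGeometry:
    """Construct the baseline follicle cross-section.

    Returns a :class:`FollicleGeometry` whose six compartment polygons
    partition the follicle disc (shared boundary vertices are bit-identical,
    so compartment areas telescope to the total).
    """
    params = params or GeometryParams()
    strat = _derive_stratification(params)
    grid = _angle_grid(params, strat)

    r_med = strat.r_medulla(grid)
    r_cor = strat.r_cortex_outer(grid)
    r_irs = strat.r_ring_inner(grid)
    r_out = strat.r_outer(grid)
    if np.any(r_med >= r_cor - 1e-9):
        raise GeometryError("medulla touches the IRS; shrink the medulla or protrusion")

    comps: dict[str, sgeom.Polygon] = {}
    comps["medulla"] = _band_polygon(np.zeros_like(grid), r_med, grid, closed=True)

    ts = strat.cortex_split_angle

    def band(lo, hi, r_lo_fun, r_hi_fun):
        th = _sector_angles(grid, lo, hi)
        return _band_polygon(r_lo_fun(th), r_hi_fun(th), th, closed=False)

    comps["cortex_posterior"] = band(-ts, ts, strat.r_medulla, strat.r_cortex_outer)
    comps["cortex_anterior"] = band(ts, -ts, strat.r_medulla, strat.r_cortex_outer)
    si = strat.irs_split_angle
    comps["irs_posterior"] = band(-si, si, strat.r_cortex_outer, strat.r_ring_inner)
    comps["irs_anterior"] = band(si, -si, strat.r_cortex_outer, strat.r_ring_inner)
    comps["outer_ring"] = _band_polygon(r_irs, r_out, grid, closed=True)

    for name, poly in comps.items():
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"compartment '{name}' polygon is degenerate")

    geom = FollicleGeometry(compartments=comps, stratification=strat)
    return geom


def compartment_area(geom: FollicleGeometry, name: str) -> float:
    """Area (um^2) of one compartment polygon."""
    if name not in geom.compartments:
        raise KeyError(
            f"unknown compartment '{name}'; expected one of {sorted(geom.compartments)}"
        )
    return float(geom.compartments[name].area)


def cortex_thickness_ratio(
    geom: FollicleGeometry,
    apex_half_window: float = math.radians(20.0),
    n_samples: int = 720,
) -> float:
    """Mean posterior / mean anterior cortex thickness, measured along rays.

    Thickness along a ray is the radial extent of the cortex layer (from the
    medulla boundary to the IRS inner boundary).  The comparison follows how
    the sides are compared on micrographs: thickness is averaged over a window
    of rays around the posterior apex and around the anterior apex.
    """
    strat = geom.stratification
    if strat is None:
        strat = stratification_from_polygons(geom)
    th = np.linspace(-math.pi, math.pi, n_samples, endpoint=False)
    thickness = strat.r_cortex_outer(th) - strat.r_medulla(th)
    posterior = angular_distance(th, 0.0) <= apex_half_window
    anterior = angular_distance(th, math.pi) <= apex_half_window
    return float(thickness[posterior].mean() / thickness[anterior].mean())


def stratification_from_polygons(
    geom: FollicleGeometry, n_theta: int = 512
) -> Stratification:
    """Recover an approximate stratification by ray-casting the polygons.

    Used for geometries loaded from GeoJSON, where only polygons are known.
    Assumes the compartments form a radially stratified partition (as all
    geometries built by this package do).
    """
    R = 2.0 * max(abs(v) for v in geom.frame)
    th = np.linspace(-math.pi, math.pi, n_theta, endpoint=False)

    def outer_radius(poly, theta):
        ray = sgeom.LineString([(0, 0), (R * math.cos(theta), R * math.sin(theta))])
        inter = poly.intersection(ray)
        if inter.is_empty:
            return np.nan
        return max(
            math.hypot(x, y)
            for geom_part in getattr(inter, "geoms", [inter])
            for x, y in geom_part.coords
        )

    med = geom.compartments["medulla"]
    cortex = shapely.unary_union(
        [geom.compartments[c] for c in CORTEX_COMPARTMENTS] + [med]
    )
    irs = shapely.unary_union(
        [geom.compartments[c] for c in IRS_COMPARTMENTS] + [cortex]
    )
    whole = shapely.unary_union([geom.compartments["outer_ring"], irs])

    r_med = np.array([outer_radius(med, t) for t in th])
    r_cor = np.array([outer_radius(cortex, t) for t in th])
    r_irs = np.array([outer_radius(irs, t) for t in th])
    r_all = np.array([outer_radius(whole, t) for t in th])

    # angular span of the posterior cortex defines the split angle
    post = geom.compartments["cortex_posterior"]
    pts = np.asarray(post.exterior.coords)
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    split = float(np.percentile(np.abs(ang), 99))

    interp = _PolarInterpStratification(
        th, r_med, r_cor, r_irs, float(np.nanmean(r_all)), split
    )
    return interp


class _PolarInterpStratification(Stratification):
    """Stratification backed by sampled radius curves (loaded geometries)."""

    def __init__(self, th, r_med, r_cor, r_irs, R, split):
        object.__setattr__(self, "_th", th)
        object.__setattr__(self, "_r_med", r_med)
        object.__setattr__(self, "_r_cor", r_cor)
        object.__setattr__(self, "_r_irs", r_irs)
        super().__init__(
            follicle_radius=R,
            ring_inner_radius=float(np.nanmean(r_irs)),
            irs_base_inner_radius=float(np.nanmax(r_cor)),
            protrusion_depth=0.0,
            protrusion_half_width=math.pi / 3,
            protrusion_center=math.pi,
            medulla_center_offset=0.0,
            medulla_outer_radius=float(np.nanmax(r_med)),
            bite_center=None,
            bite_radius=None,
            cortex_split_angle=split,
        )

    def _interp(self, samples, theta):
        th = _wrap(theta)
        return np.interp(th, self._th, samples, period=2.0 * np.pi)

    def r_medulla(self, theta):
        return self._interp(self._r_med, theta)

    def r_cortex_outer(self, theta):
        return self._interp(self._r_cor, theta)

    def r_ring_inner(self, theta):
        return self._interp(self._r_irs, theta)


# ---------------------------------------------------------------------------
# GeoJSON I/O


def geometry_to_geojson(geom: FollicleGeometry, path=None) -> dict:
    """Serialize as a GeoJSON FeatureCollection (one Feature per compartment)."""
    features = []
    for name in COMPARTMENTS:
        if name not in geom.compartments:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": {"compartment": name},
                "geometry": json.loads(shapely.to_geojson(geom.compartments[name])),
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def geometry_from_geojson(source) -> FollicleGeometry:
    """Load a FeatureCollection written by :func:`geometry_to_geojson`."""
    import os

    if isinstance(source, (str, bytes, os.PathLike)) or hasattr(source, "read"):
        if hasattr(source, "read"):
            fc = json.load(source)
        else:
            with open(source) as fh:
                fc = json.load(fh)
    else:
        fc = source
    comps = {}
    for feat in fc["features"]:
        name = feat["properties"]["compartment"]
        comps[name] = sgeom.shape(feat["geometry"])
    missing = set(COMPARTMENTS) - set(comps)
    if missing:
        raise GeometryError(f"GeoJSON geometry missing compartments: {sorted(missing)}")
    return FollicleGeometry(compartments=comps)
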