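"""Synthetic annotated sections and serial stacks.

Generates the statistical structure the quantification stage assumes, so the
whole pipeline is testable without any imaging data: per-region homogeneous
Poisson cell counts placed uniformly inside region polygons, with marker
labels drawn per-point from region-specific Bernoulli probabilities.  Every
marker-positive point coincides with a Hoechst (nucleus) point, so labeled
fractions are well defined by construction.

The default region geometry is derived from the parametric follicle section:
the DP is the central crescent (shrunk toward its centroid), the medulla is
the crescent band around it, the four matrix counting areas are the cortex
compartments split by distance to the DP (the "with BrdU" areas lie within
the DP signaling range), and the IRS areas are taken as-is.

Mean counts anchor on the study's printed numbers: 1,093 DP cells and 80
medulla cells per transverse section, with a 20% BrdU-positive fraction in
the posterior matrix counting area.  Marker probabilities are modulated
along the stack (pseudo-time ``tau``): BrdU fades and TUNEL rises toward the
keratinized levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
import shapely.geometry as sgeom

from .errors import ConfigurationError, ParameterError
from .geometry import FollicleGeometry, GeometryParams, build_base_geometry
from .quantify import MARKERS, REGION_ORDER, AnnotatedSection


def _ramp(tau, start, end):
    return float(np.clip((tau - start) / (end - start), 0.0, 1.0))


DEFAULT_MEAN_COUNTS = {
    "dp": 1093.0,
    "medulla": 80.0,
    "posterior_with_brdu": 260.0,
    "posterior_without_brdu": 160.0,
    "anterior_with_brdu": 90.0,
    "anterior_without_brdu": 30.0,
    "irs_posterior": 60.0,
    "irs_anterior": 80.0,
}

DEFAULT_MARKER_PROBS = {
    "dp": {},
    "medulla": {"tunel": 0.0},
    "posterior_with_brdu": {"brdu": 0.20, "ph3": 0.03, "tunel": 0.0},
    "posterior_without_brdu": {"brdu": 0.0, "ph3": 0.01, "tunel": 0.0},
    "anterior_with_brdu": {"brdu": 0.20, "ph3": 0.03, "tunel": 0.0},
    "anterior_without_brdu": {"brdu": 0.0, "ph3": 0.01, "tunel": 0.0},
    "irs_posterior": {"k71": 0.8, "brdu": 0.02},
    "irs_anterior": {"k71": 0.8, "brdu": 0.10},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-section generator."""

    geometry: GeometryParams = field(default_factory=GeometryParams)
    #: mean Hoechst point count per region (Poisson)
    mean_counts: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_COUNTS))
    #: per-region marker probabilities at the base level (tau = 0)
    marker_probs: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_PROBS))
    #: DP signaling ranges used to split the matrix counting areas (um)
    signaling_range_posterior: float = 25.0
    signaling_range_anterior: float = 35.0
    #: DP polygon = crescent scaled by this factor about its centroid
    dp_scale: float = 0.75
    # stack bookkeeping
    n_sections: int = 24
    thickness: float = 7.0
    # level dependence of marker probabilities
    brdu_fade: tuple[float, float] = (0.3, 0.9)  # BrdU scale 1 -> 0 over this window
    tunel_rise: tuple[float, float] = (0.4, 0.95)
    tunel_max: float = 0.25
    seed: int = 0

    def __post_init__(self):
        for region, probs in self.marker_probs.items():
            for marker, p in probs.items():
                if marker not in MARKERS:
                    raise ConfigurationError(f"unknown marker '{marker}' in {region}")
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"marker probability {region}/{marker}={p} outside [0, 1]"
                    )
        for region, mean in self.mean_counts.items():
            if mean < 0:
                raise ConfigurationError(f"mean count for '{region}' must be >= 0")
        if self.thickness <= 0:
            raise ParameterError("section thickness must be > 0")
        if self.n_sections < 1:
            raise ParameterError("n_sections must be >= 1")
        if not 0 < self.dp_scale < 1:
            raise ParameterError("dp_scale must be in (0, 1)")

    def marker_probability(self, region: str, marker: str, tau: float) -> float:
        p = self.marker_probs.get(region, {}).get(marker, 0.0)
        if marker == "brdu":
            p *= 1.0 - _ramp(tau, *self.brdu_fade)
        elif marker == "tunel":
            base = p
            p = base + (self.tunel_max - base) * _ramp(tau, *self.tunel_rise)
        return p


def make_regions(
    geom: FollicleGeometry, cfg: GeneratorConfig
) -> dict[str, sgeom.Polygon]:
    """Quantification region polygons derived from a follicle geometry."""
    crescent = geom.compartments["medulla"]
    dp = shapely.affinity.scale(
        crescent, xfact=cfg.dp_scale, yfact=cfg.dp_scale, origin="centroid"
    )
    medulla = crescent.difference(dp)

    near_dp = dp.buffer(cfg.signaling_range_posterior)
    near_dp_ant = dp.buffer(cfg.signaling_range_anterior)
    cp = geom.compartments["cortex_posterior"]
    ca = geom.compartments["cortex_anterior"]
    regions = {
        "dp": dp,
        "medulla": medulla,
        "posterior_with_brdu": cp.intersection(near_dp),
        "posterior_without_brdu": cp.difference(near_dp),
        "anterior_with_brdu": ca.intersection(near_dp_ant),
        "anterior_without_brdu": ca.difference(near_dp_ant),
        "irs_posterior": geom.compartments["irs_posterior"],
        "irs_anterior": geom.compartments["irs_anterior"],
    }
    for name, poly in regions.items():
        if poly.is_empty or poly.area <= 0:
            raise ConfigurationError(
                f"derived region '{name}' is empty; adjust signaling ranges"
            )
    return regions


def _sample_in_polygon(poly: sgeom.Polygon, n: int, rng: np.random.Generator):
    """Uniform points inside a polygon by rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = []
    remaining = n
    while remaining > 0:
        m = max(32, int(remaining / max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = cand[shapely.contains_xy(poly, cand[:, 0], cand[:, 1])]
        out.append(keep[:remaining])
        remaining -= len(keep[:remaining])
    return np.vstack(out)


def generate_section(
    cfg: GeneratorConfig | None = None,
    tau: float = 0.0,
    seed: int | None = None,
    geom: FollicleGeometry | None = None,
    regions: dict[str, sgeom.Polygon] | None = None,
    z_index: int | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotatedSection:
    """Generate one annotated section at stack level ``tau``.

    Reproducible: the same seed yields a bit-identical section.  Region
    polygons may be supplied directly (e.g. from a deformed simulation
    level); otherwise they are derived from the (base) geometry.
    """
    cfg = cfg or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if regions is None:
        geom = geom or build_base_geometry(cfg.geometry)
        regions = make_regions(geom, cfg)
    missing = set(regions) - set(cfg.mean_counts)
    if missing:
        raise ConfigurationError(
            f"no nucleus intensity configured for regions: {sorted(missing)}"
        )

    frames = []
    # fixed region iteration order for reproducibility
    names = [n for n in REGION_ORDER if n in regions]
    names += [n for n in regions if n not in REGION_ORDER]
    for name in names:
        n_pts = rng.poisson(cfg.mean_counts[name])
        pts = _sample_in_polygon(regions[name], int(n_pts), rng)
        frames.append(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "marker": "hoechst"}))
        for marker in MARKERS:
            if marker == "hoechst":
                continue
            p = cfg.marker_probability(name, marker, tau)
            if p <= 0 or len(pts) == 0:
                continue
            positive = pts[rng.random(len(pts)) < p]
            if len(positive):
                frames.append(
                    pd.DataFrame(
                        {"x": positive[:, 0], "y": positive[:, 1], "marker": marker}
                    )
                )
    points = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["x", "y", "marker"])
    )

    bounds = shapely.unary_union(list(regions.values())).bounds
    half = max(abs(b) for b in bounds) * 1.05
    return AnnotatedSection(
        frame=(2 * half, 2 * half),
        points=points,
        regions=dict(zip(names, (regions[n] for n in names))),
        z_index=z_index,
        thickness=cfg.thickness,
    )


def generate_stack(
    cfg: GeneratorConfig | None = None,
    trajectory=None,
    seed: int | None = None,
) -> list[AnnotatedSection]:
    """Generate a serial stack of ``cfg.n_sections`` sections (7 um each).

    Levels are mapped to pseudo-time ``tau`` in [0, 1].  When a simulation
    ``trajectory`` is given, region polygons follow the deformed compartments
    of the matching trajectory level; the trajectory must span the stack.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_sections
    taus = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])

    region_sets: list[dict | None]
    if trajectory is not None:
        if len(trajectory.meshes) < n:
            raise ParameterError(
                f"trajectory has {len(trajectory.meshes)} levels < stack size {n}"
            )
        from .morphogenesis import region_boundary_polygon

        region_sets = []
        idx = np.linspace(0, len(trajectory.meshes) - 1, n).round().astype(int)
        for i in idx:
            mesh = trajectory.meshes[i]
            geom_i = FollicleGeometry(
                compartments={
                    lab: region_boundary_polygon(mesh, lab)
                    for lab in np.unique(mesh.element_label)
                }
            )
            region_sets.append(make_regions(geom_i, cfg))
    else:
        geom = build_base_geometry(cfg.geometry)
        base_regions = make_regions(geom, cfg)
        region_sets = [base_regions] * n

    stack = []
    for z, (tau, regions) in enumerate(zip(taus, region_sets)):
        stack.append(
            generate_section(cfg, tau=tau, regions=regions, z_index=z, rng=rng)
        )
    return stack


def points_to_csv(section: AnnotatedSection, path) -> None:
    """Write the point table as CSV (x, y, marker[, z])."""
    df = section.points.copy()
    if section.z_index is not None:
        df["z"] = section.z_index
    df.to_csv(path, index=False)


def points_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
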