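"""Conforming triangular meshes for the stratified follicle cross-section.

The follicle domain is star-shaped with single-valued polar layer boundaries
(:class:`~spinefem.geometry.Stratification`), so a structured "onion" mesh can
be built directly on the analytic curves: nodes sit on concentric ring curves
sampled at a shared set of angles, quadrilateral cells between consecutive
rings are split into triangles, and the innermost ring fans to a centre node.
The mesh is conforming by construction and every element inherits exactly one
compartment label from the band and angular sector it occupies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MeshError, ParameterError
from .geometry import (
    COMPARTMENTS,
    FollicleGeometry,
    Stratification,
    _wrap,
    stratification_from_polygons,
)


@dataclass
class FEMesh:
    """Triangular mesh with per-element compartment labels (units: um)."""

    nodes: np.ndarray  # (n_nodes, 2) float
    elements: np.ndarray  # (n_elements, 3) int, CCW
    element_label: np.ndarray  # (n_elements,) str
    boundary_nodes: np.ndarray  # node indices on the outer boundary

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_label = np.asarray(self.element_label)
        self.boundary_nodes = np.asarray(self.boundary_nodes, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_areas(self) -> np.ndarray:
        """Signed triangle areas (positive for CCW orientation)."""
        p = self.nodes[self.elements]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def compartment_areas(self) -> dict[str, float]:
        areas = self.element_areas()
        return {
            str(lab): float(areas[self.element_label == lab].sum())
            for lab in np.unique(self.element_label)
        }

    def total_area(self) -> float:
        return float(self.element_areas().sum())

    def area_fractions(self) -> dict[str, float]:
        areas = self.compartment_areas()
        total = sum(areas.values())
        return {k: v / total for k, v in areas.items()}

    def copy(self) -> "FEMesh":
        return FEMesh(
            self.nodes.copy(),
            self.elements.copy(),
            self.element_label.copy(),
            self.boundary_nodes.copy(),
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def validate(self) -> None:
        """Raise :class:`MeshError` on inverted elements or dangling nodes."""
        areas = self.element_areas()
        if np.any(areas <= 0):
            raise MeshError(
                f"{int((areas <= 0).sum())} elements have non-positive area"
            )
        if not np.isfinite(self.nodes).all():
            raise MeshError("non-finite node coordinates")


def _band_counts(thickness: float, target_edge: float) -> int:
    return max(1, int(math.ceil(thickness / target_edge)))


def onion_mesh(
    thetas: np.ndarray,
    ring_radii: np.ndarray,
    band_label,
    center_label: str,
) -> FEMesh:
    """Build a structured triangular mesh from ring curves.

    Parameters
    ----------
    thetas
        Sorted angle samples in [-pi, pi), shared by every ring.
    ring_radii
        Array (n_rings, n_angles); ``ring_radii[j, i]`` is the radius of ring
        ``j`` at ``thetas[i]``.  Rings must be strictly increasing outward.
    band_label
        ``band_label(j, mid_theta) -> str`` labelling the band between ring
        ``j-1`` (or the centre for ``j=0``) and ring ``j``.
    center_label
        Label of the innermost fan around the centre node.
    """
    thetas = np.asarray(thetas, dtype=float)
    n_a = len(thetas)
    n_r = len(ring_radii)
    if np.any(np.diff(ring_radii, axis=0) <= 0):
        raise MeshError("ring curves must be strictly increasing outward")

    cos_t, sin_t = np.cos(thetas), np.sin(thetas)
    nodes = [np.zeros((1, 2))]
    for j in range(n_r):
        nodes.append(np.column_stack([ring_radii[j] * cos_t, ring_radii[j] * sin_t]))
    nodes = np.vstack(nodes)

    def idx(j, i):
        return 1 + j * n_a + (i % n_a)

    mid_theta = _wrap(thetas + 0.5 * np.diff(np.append(thetas, thetas[0] + 2 * np.pi)))

    elements, labels = [], []
    for i in range(n_a):
        elements.append((0, idx(0, i), idx(0, i + 1)))
        labels.append(center_label)
    for j in range(1, n_r):
        for i in range(n_a):
            a, d = idx(j - 1, i), idx(j - 1, i + 1)
            b, c = idx(j, i), idx(j, i + 1)
            if (i + j) % 2 == 0:
                elements.append((a, b, c))
                elements.append((a, c, d))
            else:
                elements.append((a, b, d))
                elements.append((b, c, d))
            lab = band_label(j, float(mid_theta[i]))
            labels.extend((lab, lab))

    boundary = np.arange(1 + (n_r - 1) * n_a, 1 + n_r * n_a)
    mesh = FEMesh(nodes, np.array(elements), np.array(labels), boundary)
    mesh.validate()
    return mesh


def mesh_geometry(geom: FollicleGeometry, target_edge_length: float) -> FEMesh:
    """Mesh a follicle cross-section with triangles of ~``target_edge_length``.

    The target edge must not exceed the thinnest layer's mean thickness,
    otherwise a layer could not be resolved by a full band of elements.
    """
    if target_edge_length <= 0:
        raise ParameterError("target_edge_length must be > 0")
    strat = geom.stratification
    if strat is None:
        strat = stratification_from_polygons(geom)

    # shared angle grid: uniform within quadrant sectors so the +-pi/2 split
    # meridians are honoured exactly
    h = target_edge_length
    R = strat.follicle_radius
    sector_bounds = [-math.pi, -math.pi / 2, math.pi / 2, math.pi]
    thetas = []
    for lo, hi in zip(sector_bounds[:-1], sector_bounds[1:]):
        n_seg = max(4, int(math.ceil((hi - lo) * R / h)))
        thetas.append(np.linspace(lo, hi, n_seg, endpoint=False))
    thetas = np.concatenate(thetas)

    curves = {
        "medulla": strat.r_medulla(thetas),
        "cortex": strat.r_cortex_outer(thetas),
        "irs": strat.r_ring_inner(thetas),
        "ring": strat.r_outer(thetas),
    }
    layer_order = ["medulla", "cortex", "irs", "ring"]
    inner = np.zeros_like(thetas)
    mean_thickness = {}
    for name in layer_order:
        mean_thickness[name] = float(np.mean(curves[name] - inner))
        if mean_thickness[name] <= 0:
            raise MeshError(f"layer '{name}' has non-positive thickness")
        inner = curves[name]
    thinnest = min(mean_thickness, key=mean_thickness.get)
    if h > mean_thickness[thinnest] + 1e-9:
        raise MeshError(
            f"target edge {h} um exceeds the mean thickness "
            f"{mean_thickness[thinnest]:.2f} um of compartment layer '{thinnest}'"
        )

    ring_radii = []
    band_layer = []  # layer name per ring (band between ring j-1 and j)
    inner = np.zeros_like(thetas)
    for name in layer_order:
        n_sub = _band_counts(mean_thickness[name], h)
        for j in range(1, n_sub + 1):
            ring_radii.append(inner + (j / n_sub) * (curves[name] - inner))
            band_layer.append(name)
        inner = curves[name]
    ring_radii = np.array(ring_radii)

    split = strat.cortex_split_angle
    irs_split = strat.irs_split_angle

    def band_label(j, mid_theta):
        layer = band_layer[j]
        if layer == "medulla":
            return "medulla"
        if layer == "ring":
            return "outer_ring"
        if layer == "cortex":
            side = "posterior" if abs(mid_theta) <= split else "anterior"
            return f"cortex_{side}"
        side = "posterior" if abs(mid_theta) <= irs_split else "anterior"
        return f"irs_{side}"

    mesh = onion_mesh(thetas, ring_radii, band_label, "medulla")

    present = set(np.unique(mesh.element_label))
    expected = set(COMPARTMENTS)
    if present != expected:
        raise MeshError(f"mesh labels {sorted(present)} != {sorted(expected)}")
    return mesh


def disc_mesh(radius: float, target_edge_length: float, label: str = "domain") -> FEMesh:
    """Uniform mesh of a disc centred at the origin (solver verification)."""
    n_a = max(8, int(math.ceil(2 * math.pi * radius / target_edge_length)))
    n_a += n_a % 2  # keep the +-x and +-y meridians in the node set
    thetas = np.linspace(-math.pi, math.pi, n_a, endpoint=False)
    n_r = max(2, int(math.ceil(radius / target_edge_length)))
    ring_radii = np.array(
        [np.full(n_a, radius * j / n_r) for j in range(1, n_r + 1)]
    )
    return onion_mesh(thetas, ring_radii, lambda j, t: label, label)


def rect_mesh(
    width: float,
    height: float,
    nx: int,
    ny: int,
    label: str = "domain",
    origin: tuple[float, float] = (0.0, 0.0),
) -> FEMesh:
    """Structured mesh of a rectangle; used in patch and closed-form tests."""
    x = origin[0] + np.linspace(0.0, width, nx + 1)
    y = origin[1] + np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    elements = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                elements.append((a, b, c))
                elements.append((a, c, d))
            else:
                elements.append((a, b, d))
                elements.append((b, c, d))
    elements = np.array(elements)
    on_boundary = (
        np.isclose(nodes[:, 0], x[0])
        | np.isclose(nodes[:, 0], x[-1])
        | np.isclose(nodes[:, 1], y[0])
        | np.isclose(nodes[:, 1], y[-1])
    )
    mesh = FEMesh(
        nodes,
        elements,
        np.array([label] * len(elements)),
        np.flatnonzero(on_boundary),
    )
    mesh.validate()
    return mesh


def write_vtk(
    mesh: FEMesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh as legacy ASCII VTK (unstructured grid of triangles).

    The compartment label is always written as cell data ``compartment``,
    encoded as the integer index into :data:`spinefem.geometry.COMPARTMENTS`
    (unknown labels get code -1).
    """
    code = {name: i for i, name in enumerate(COMPARTMENTS)}
    comp_codes = np.array([code.get(str(lab), -1) for lab in mesh.element_label])

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("spinefem follicle section; compartment codes follow "
                 + ",".join(COMPARTMENTS) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.6g} {y:.6g} 0\n")
        fh.write(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}\n")
        for tri in mesh.elements:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("5\n" * mesh.n_elements)

        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS compartment int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(c) for c in comp_codes) + "\n")
        for name, values in (cell_data or {}).items():
            values = np.asarray(values)
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in values) + "\n")

        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                values = np.asarray(values)
                if values.ndim == 2:
                    fh.write(f"VECTORS {name} float\n")
                    for vx, vy in values[:, :2]:
                        fh.write(f"{vx:.6g} {vy:.6g} 0\n")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.6g}" for v in values) + "\n")
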