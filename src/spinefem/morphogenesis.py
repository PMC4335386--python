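"""The three scheduled processes that shape the spine follicle cross-section.

Pseudo-time ``tau`` in [0, 1] stands for height along the follicle's long
axis (base to keratinized shaft).  Three processes act on the cross-section:

1. **Anterior IRS growth** — an isotropic in-plane growth eigenstrain in the
   anterior-IRS protrusion zone (weighted by the protrusion bump profile),
   sustained from the base until keratinization completes: the anterior IRS
   keeps enlarging while the shaft keratinizes.  With the outer boundary
   confined, the growing protrusion bulges inward against the anterior
   cortex and keeps pressing into the shrinking shaft.
2. **Cortex keratinization** — cortex cells elongate axially by a stretch
   ``lambda_z`` while keratin filaments accumulate.  Volume conservation maps
   the axial stretch to an isotropic in-plane contraction
   ``eps* = lambda_z**-0.5 - 1``; the keratinizing cortex simultaneously
   stiffens.  Posterior onset precedes anterior onset.
3. **Medulla foam collapse** — the medulla keratinizes into a closed-cell
   foam (transiently stiffening), then its Young's modulus drops to the
   Gibson-Ashby foam value ``E_solid * rho_rel**exponent`` while cavity
   collapse imposes a contraction eigenstrain; the weakened core is crushed
   by the surrounding layers.

Each process strain is applied in multiplicative increments on the updated
mesh (quasi-static, small-strain per increment).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.geometry as sgeom
from scipy import optimize

from .elastic import (
    BoundaryCondition,
    Eigenstrain,
    Material,
    assemble_system,
    solve,
    update_mesh,
)
from .errors import ParameterError, SolverError
from .geometry import (
    CORTEX_COMPARTMENTS,
    FollicleGeometry,
    GeometryParams,
    build_base_geometry,
    stratification_from_polygons,
)
from .meshing import FEMesh, mesh_geometry

PROCESS_NAMES = ("irs_growth", "cortex_keratinization", "medulla_collapse")

#: default materials (relative stiffness units; only ratios matter for
#: eigenstrain-driven quasi-statics)
DEFAULT_MATERIALS = {
    "medulla": Material(E=1.0, nu=0.3),
    "cortex_posterior": Material(E=1.0, nu=0.3),
    "cortex_anterior": Material(E=1.0, nu=0.3),
    "irs_posterior": Material(E=0.5, nu=0.3),
    "irs_anterior": Material(E=0.5, nu=0.3),
    "outer_ring": Material(E=20.0, nu=0.3),
}


def cortex_inplane_eigenstrain(lambda_z: float) -> Eigenstrain:
    """In-plane eigenstrain equivalent to a volume-conserving axial stretch.

    A cell elongating axially by ``lambda_z`` at constant volume contracts
    isotropically in-plane by ``lambda_z**-0.5``, i.e. the imposed in-plane
    strain is ``lambda_z**-0.5 - 1`` (0 for no stretch, -> -1 as the stretch
    grows without bound).
    """
    if lambda_z < 1.0:
        raise ParameterError(f"axial stretch lambda_z must be >= 1, got {lambda_z}")
    return Eigenstrain.isotropic(lambda_z ** (-0.5) - 1.0)


def foam_modulus(E_solid: float, rho_rel: float, exponent: float = 2.0) -> float:
    """Gibson-Ashby scaling for a closed-cell foam: ``E_solid * rho_rel**n``."""
    if not 0.0 < rho_rel <= 1.0:
        raise ParameterError(f"relative density must be in (0, 1], got {rho_rel}")
    if not E_solid > 0:
        raise ParameterError(f"E_solid must be > 0, got {E_solid}")
    return float(E_solid * rho_rel**exponent)


def _ramp(tau: float, start: float, end: float) -> float:
    """Linear 0->1 ramp over [start, end], clipped outside."""
    if end <= start:
        return 1.0 if tau >= end else 0.0
    return float(np.clip((tau - start) / (end - start), 0.0, 1.0))


@dataclass(frozen=True)
class ProcessSchedule:
    """Pseudo-time courses of the three processes.

    All times are pseudo-time fractions in [0, 1]; moduli are in the same
    relative units as the base materials.
    """

    n_steps: int = 50
    # anterior IRS growth
    irs_growth_start: float = 0.0
    irs_growth_end: float = 0.85
    #: peak total isotropic in-plane growth strain in the protrusion zone
    irs_growth_total_strain: float = 0.18
    irs_growing_modulus: float = 3.0
    # cortex keratinization (axial elongation + stiffening)
    keratinization_onset_posterior: float = 0.30
    keratinization_onset_anterior: float = 0.45
    keratinization_full: float = 0.85
    lambda_z_max: float = 3.2
    cortex_keratinized_modulus: float = 50.0
    # medulla keratinization and foam collapse
    medulla_stiffen_start: float = 0.20
    medulla_stiffen_end: float = 0.50
    medulla_keratinized_modulus: float = 35.0
    collapse_start: float = 0.70
    collapse_end: float = 1.0
    relative_density: float = 0.1
    foam_exponent: float = 2.0
    #: total isotropic in-plane eigenstrain of cavity collapse
    collapse_strain: float = -0.75

    def __post_init__(self):
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if self.lambda_z_max < 1.0:
            raise ParameterError("lambda_z_max must be >= 1 (non-decreasing stretch)")
        if not self.keratinization_onset_posterior < self.keratinization_onset_anterior:
            raise ParameterError(
                "posterior keratinization onset must precede the anterior onset"
            )
        if not 0.0 < self.relative_density <= 1.0:
            raise ParameterError("relative_density must be in (0, 1]")
        if self.irs_growth_total_strain < 0:
            raise ParameterError("irs_growth_total_strain must be >= 0")
        if not -1.0 < self.collapse_strain <= 0.0:
            raise ParameterError("collapse_strain must be in (-1, 0]")
        for name in (
            "irs_growth_start",
            "irs_growth_end",
            "keratinization_onset_posterior",
            "keratinization_onset_anterior",
            "keratinization_full",
            "medulla_stiffen_start",
            "medulla_stiffen_end",
            "collapse_start",
            "collapse_end",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")

    # -- process time courses -------------------------------------------------

    def lambda_z(self, tau: float, compartment: str) -> float:
        onset = (
            self.keratinization_onset_posterior
            if compartment == "cortex_posterior"
            else self.keratinization_onset_anterior
        )
        return 1.0 + (self.lambda_z_max - 1.0) * _ramp(tau, onset, self.keratinization_full)

    def cortex_modulus(self, tau: float, compartment: str, base_E: float) -> float:
        lam = self.lambda_z(tau, compartment)
        if self.lambda_z_max == 1.0:
            return base_E
        frac = (lam - 1.0) / (self.lambda_z_max - 1.0)
        return base_E + (self.cortex_keratinized_modulus - base_E) * frac

    def medulla_modulus(self, tau: float, base_E: float) -> float:
        E_ker = self.medulla_keratinized_modulus
        E = base_E + (E_ker - base_E) * _ramp(
            tau, self.medulla_stiffen_start, self.medulla_stiffen_end
        )
        drop = _ramp(tau, self.collapse_start, self.collapse_end)
        if drop > 0:
            E_foam = foam_modulus(E_ker, self.relative_density, self.foam_exponent)
            # the stiffness loss lags the cavity-collapse strain (cell walls
            # fail after the cavities have been crushed): geometric drop in
            # the squared collapse phase
            E = E * (E_foam / E) ** (drop**2)
        return E

    def irs_growth_phase(self, tau: float) -> float:
        return _ramp(tau, self.irs_growth_start, self.irs_growth_end)

    def collapse_phase(self, tau: float) -> float:
        return _ramp(tau, self.collapse_start, self.collapse_end)

    def disable(self, which: str) -> "ProcessSchedule":
        """Return a copy with one named process inactivated."""
        if which == "irs_growth":
            return replace(self, irs_growth_total_strain=0.0, irs_growing_modulus=1.0)
        if which == "cortex_keratinization":
            return replace(self, lambda_z_max=1.0)
        if which == "medulla_collapse":
            # no foam softening, no cavity collapse; the keratinization
            # stiffening of the medulla is left in place
            return replace(self, collapse_strain=0.0, relative_density=1.0)
        raise ParameterError(
            f"unknown process '{which}'; expected one of {PROCESS_NAMES}"
        )


@dataclass
class SimulationTrajectory:
    """Deformed meshes and per-level shape metrics over pseudo-time."""

    taus: np.ndarray
    meshes: list[FEMesh]
    records: pd.DataFrame  # one row per tau, incl. area fractions and metrics
    config: dict

    @property
    def final(self) -> pd.Series:
        return self.records.iloc[-1]

    def final_cortex_fraction(self) -> float:
        return float(sum(self.final[f"frac_{c}"] for c in CORTEX_COMPARTMENTS))

    def fraction_series(self, compartment: str) -> np.ndarray:
        return self.records[f"frac_{compartment}"].to_numpy()


def region_boundary_polygon(mesh: FEMesh, labels) -> sgeom.Polygon:
    """Outer boundary polygon of the union of elements with the given labels.

    Assumes the selected region is simply connected (true for the medulla
    and for the shaft = cortex + medulla in all geometries built here).
    """
    labels = {labels} if isinstance(labels, str) else set(labels)
    sel = np.isin(mesh.element_label, list(labels))
    tris = mesh.elements[sel]
    edges: dict[tuple[int, int], int] = {}
    for tri in tris:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (a, b) if a < b else (b, a)
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, cnt in edges.items() if cnt == 1]
    nbr: dict[int, list[int]] = {}
    for a, b in boundary:
        nbr.setdefault(a, []).append(b)
        nbr.setdefault(b, []).append(a)
    start = boundary[0][0]
    loop = [start]
    prev, cur = -1, start
    while True:
        nxt = [n for n in nbr[cur] if n != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        loop.append(cur)
    poly = sgeom.Polygon(mesh.nodes[loop])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def furrow_depth(mesh: FEMesh) -> float:
    """Depth of the deepest concavity of the shaft (cortex + medulla) outline.

    Measured as the largest distance from a shaft-boundary vertex to the
    boundary of the shaft's convex hull; a convex shaft scores ~0.
    """
    shaft = region_boundary_polygon(mesh, set(CORTEX_COMPARTMENTS) | {"medulla"})
    hull_ring = shaft.convex_hull.exterior
    pts = shapely.points(np.asarray(shaft.exterior.coords))
    return float(shapely.distance(pts, hull_ring).max())


def medulla_convexity_deficit(mesh: FEMesh) -> float:
    """1 - area/convex-hull-area of the medulla region (0 for convex)."""
    med = region_boundary_polygon(mesh, "medulla")
    return float(1.0 - med.area / med.convex_hull.area)


def _growth_weights(geom: FollicleGeometry, mesh: FEMesh) -> np.ndarray:
    """Protrusion-zone growth weight per element (anterior IRS only)."""
    strat = geom.stratification
    if strat is None:
        strat = stratification_from_polygons(geom)
    cent = mesh.element_centroids()
    theta = np.arctan2(cent[:, 1], cent[:, 0])
    w = strat.irs_growth_weight(theta)
    w[mesh.element_label != "irs_anterior"] = 0.0
    return w


def _metrics_row(tau: float, mesh: FEMesh) -> dict:
    row = {"tau": tau}
    for name, frac in mesh.area_fractions().items():
        row[f"frac_{name}"] = frac
    row["furrow_depth"] = furrow_depth(mesh)
    row["medulla_convexity_deficit"] = medulla_convexity_deficit(mesh)
    row["total_area"] = mesh.total_area()
    return row


def run_simulation(
    geom: FollicleGeometry,
    schedule: ProcessSchedule | None = None,
    materials: dict[str, Material] | None = None,
    mesh_size: float = 3.5,
    n_steps: int | None = None,
    bc: str = "fixed_outer",
) -> SimulationTrajectory:
    """Run the three-process quasi-static simulation over pseudo-time.

    The trajectory is deterministic (no randomness anywhere).  Row 0 of the
    records is the undeformed base section at ``tau = 0``; one row follows
    per increment.
    """
    schedule = schedule or ProcessSchedule()
    if n_steps is not None:
        schedule = replace(schedule, n_steps=n_steps)
    materials = dict(materials or DEFAULT_MATERIALS)

    mesh = mesh_geometry(geom, mesh_size)
    weights = _growth_weights(geom, mesh)
    n = schedule.n_steps
    taus = np.linspace(0.0, 1.0, n + 1)

    if bc == "fixed_outer":
        bc_obj = BoundaryCondition.fixed_outer(mesh)
    elif bc == "pinned":
        bc_obj = BoundaryCondition.pin_rigid_modes(mesh)
    else:
        raise ParameterError(f"unknown boundary condition '{bc}'")

    meshes = [mesh.copy()]
    rows = [_metrics_row(0.0, mesh)]

    # accumulated multiplicative factors of each process strain
    log_growth = math.log1p(schedule.irs_growth_total_strain)
    log_collapse = math.log1p(schedule.collapse_strain) if schedule.collapse_strain else 0.0

    def stretch_factor(tau, comp):
        return schedule.lambda_z(tau, comp) ** (-0.5)

    is_cortex = {
        c: mesh.element_label == c for c in CORTEX_COMPARTMENTS
    }
    is_medulla = mesh.element_label == "medulla"

    for k in range(1, n + 1):
        tau_prev, tau = taus[k - 1], taus[k]

        mats_k = dict(materials)
        for c in CORTEX_COMPARTMENTS:
            base = materials[c]
            mats_k[c] = replace(base, E=schedule.cortex_modulus(tau, c, base.E))
        base_med = materials["medulla"]
        mats_k["medulla"] = replace(
            base_med, E=schedule.medulla_modulus(tau, base_med.E)
        )
        # the grown Huxley's-layer protrusion stays stiffer than resting IRS
        # (large turgid cells), so the bulge it forms is not flattened later
        if schedule.irs_growth_total_strain > 0 and tau > schedule.irs_growth_start:
            base_irs = materials["irs_anterior"]
            mats_k["irs_anterior"] = replace(
                base_irs, E=base_irs.E * schedule.irs_growing_modulus
            )

        eps = np.zeros((mesh.n_elements, 3))
        # IRS growth increment: per-element factor (1+g)^(w * dphase)
        dphase = schedule.irs_growth_phase(tau) - schedule.irs_growth_phase(tau_prev)
        if dphase > 0 and log_growth != 0.0:
            inc = np.expm1(weights * dphase * log_growth)
            eps[:, 0] += inc
            eps[:, 1] += inc
        # cortex keratinization increment (multiplicative in-plane contraction)
        for c in CORTEX_COMPARTMENTS:
            ratio = stretch_factor(tau, c) / stretch_factor(tau_prev, c) - 1.0
            if ratio != 0.0:
                eps[is_cortex[c], 0] += ratio
                eps[is_cortex[c], 1] += ratio
        # medulla cavity collapse increment
        dcol = schedule.collapse_phase(tau) - schedule.collapse_phase(tau_prev)
        if dcol > 0 and log_collapse != 0.0:
            inc = math.expm1(dcol * log_collapse)
            eps[is_medulla, 0] += inc
            eps[is_medulla, 1] += inc

        system = assemble_system(mesh, mats_k, eps, bc_obj)
        try:
            u = solve(system)
        except SolverError as exc:
            raise SolverError(f"step {k} (tau={tau:.3f}): {exc}") from exc
        mesh = update_mesh(mesh, u)
        meshes.append(mesh.copy())
        rows.append(_metrics_row(tau, mesh))

    records = pd.DataFrame(rows)
    config = {
        "schedule": asdict(schedule),
        "materials": {k: asdict(v) for k, v in materials.items()},
        "mesh_size": mesh_size,
        "bc": bc,
    }
    return SimulationTrajectory(taus=taus, meshes=meshes, records=records, config=config)


def run_ablation(
    geom: FollicleGeometry,
    schedule: ProcessSchedule | None = None,
    which: str = "irs_growth",
    **kwargs,
) -> SimulationTrajectory:
    """Re-run the simulation with one named process disabled."""
    schedule = schedule or ProcessSchedule()
    return run_simulation(geom, schedule.disable(which), **kwargs)


def poisson_sweep(
    geom: FollicleGeometry,
    nu_values,
    schedule: ProcessSchedule | None = None,
    materials: dict[str, Material] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full runs across cortex Poisson's ratios; robustness diagnostic.

    Returns one row per ``nu`` with the final compartment fractions; the
    attribute ``df.attrs['cortex_fraction_spread']`` holds the max-min spread
    of the final total cortex fraction (percentage points).
    """
    nu_values = list(nu_values)
    if any(not 0.0 <= v <= 0.49 for v in nu_values):
        raise ParameterError("Poisson ratios must lie in [0, 0.49]")
    materials = dict(materials or DEFAULT_MATERIALS)
    rows = []
    for nu in nu_values:
        mats = dict(materials)
        for c in CORTEX_COMPARTMENTS:
            mats[c] = replace(materials[c], nu=nu)
        traj = run_simulation(geom, schedule, mats, **kwargs)
        row = {"nu": nu, "final_cortex_fraction": traj.final_cortex_fraction()}
        for name in traj.meshes[-1].area_fractions():
            row[f"frac_{name}"] = traj.final[f"frac_{name}"]
        rows.append(row)
    df = pd.DataFrame(rows)
    vals = df["final_cortex_fraction"].to_numpy()
    df.attrs["cortex_fraction_spread"] = float(vals.max() - vals.min()) * 100.0
    return df


def calibrate(
    free_params: dict[str, tuple[float, float]],
    targets: dict[str, float],
    geometry_params: GeometryParams | None = None,
    schedule: ProcessSchedule | None = None,
    mesh_size: float = 4.0,
    n_steps: int = 10,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> dict:
    """Fit free parameters to the area anchors by bounded derivative-free search.

    ``free_params`` maps dotted names (``"geometry.<field>"`` or
    ``"schedule.<field>"``) to (lo, hi) bounds.  ``targets`` may contain
    ``base_cortex_fraction`` and/or ``final_cortex_fraction`` (as fractions
    of total area).  Returns a dict with the fitted ``geometry``/``schedule``
    objects, the achieved anchors, the objective value and a ``converged``
    flag (best-found parameters are returned either way).
    """
    geometry_params = geometry_params or GeometryParams()
    schedule = schedule or ProcessSchedule()
    names = list(free_params)
    if not names:
        anchors = _measure_anchors(geometry_params, schedule, targets, mesh_size, n_steps)
        return {
            "geometry": geometry_params,
            "schedule": schedule,
            "anchors": anchors,
            "objective": _objective_value(anchors, targets),
            "converged": True,
        }

    def apply(x):
        gp, sc = geometry_params, schedule
        for name, val in zip(names, x):
            scope, fieldname = name.split(".", 1)
            if scope == "geometry":
                gp = replace(gp, **{fieldname: float(val)})
            elif scope == "schedule":
                sc = replace(sc, **{fieldname: float(val)})
            else:
                raise ParameterError(f"unknown parameter scope in '{name}'")
        return gp, sc

    def objective(x):
        gp, sc = apply(x)
        anchors = _measure_anchors(gp, sc, targets, mesh_size, n_steps)
        val = _objective_value(anchors, targets)
        if not np.isfinite(val):
            raise SolverError(f"non-finite calibration objective at {dict(zip(names, x))}")
        return val

    bounds = [free_params[n] for n in names]
    x0 = np.array([0.5 * (lo + hi) for lo, hi in bounds])
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": max_iter, "fatol": tol * 0.1, "xatol": 1e-3},
    )
    gp, sc = apply(res.x)
    anchors = _measure_anchors(gp, sc, targets, mesh_size, n_steps)
    value = _objective_value(anchors, targets)
    return {
        "geometry": gp,
        "schedule": sc,
        "anchors": anchors,
        "objective": value,
        "converged": bool(value <= tol),
    }


def _measure_anchors(geometry_params, schedule, targets, mesh_size, n_steps):
    geom = build_base_geometry(geometry_params)
    anchors = {}
    fr = geom.area_fractions()
    anchors["base_cortex_fraction"] = sum(fr[c] for c in CORTEX_COMPARTMENTS)
    if "final_cortex_fraction" in targets:
        traj = run_simulation(geom, schedule, mesh_size=mesh_size, n_steps=n_steps)
        anchors["final_cortex_fraction"] = traj.final_cortex_fraction()
    return anchors


def _objective_value(anchors, targets):
    return float(
        sum((anchors[k] - v) ** 2 for k, v in targets.items() if k in anchors)
    )
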