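"""Synthetic divergence-free flow fields on a structured cylindrical grid.

The compartmentizer consumes a gridded flow solution: cell volumes plus
signed convective mass fluxes and turbulent kinetic energy on the interior
cell faces.  In a CFD-backed workflow those come from a resolved solver;
here a synthetic generator produces them so that the whole pipeline is
self-contained and exactly mass-conservative.

The axial-radial circulation is built from a discrete streamfunction
evaluated on grid *nodes*: the mass flux through any interior face is a
difference of nodal streamfunction values, so the signed flux sum around
every cell telescopes to zero to round-off, with no iterative correction.
A Rushton turbine drives one radial jet that splits into an upper and a
lower recirculation loop, so the default topology carries two
counter-rotating loops per impeller (four for the two-impeller tank).
Azimuthal (swirl) fluxes, when the grid has more than one theta sector, are
theta-uniform and therefore individually divergence-free.

Turbulent kinetic energy is modelled as Gaussian peaks centred on each
impeller plane near the blade tip radius, decaying to a positive background
level; magnitudes scale with the square of the impeller tip speed.  Only
the relative spatial structure matters for the turbulent exchange fluxes —
the absolute scale is an explicit configuration knob, not a hydrodynamic
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import GeometryError, TankGeometry

__all__ = [
    "CirculationLoop",
    "LoopSpec",
    "TurbulenceSpec",
    "GridFlowField",
    "default_loop_spec",
    "build_stirred_tank_field",
    "check_divergence",
]


@dataclass(frozen=True)
class CirculationLoop:
    """One closed axial-radial recirculation loop.

    ``strength`` is the loop's circulating mass flow (kg/s): the mass flow
    crossing a cut through the loop centre.  ``sign`` +1 circulates
    counter-clockwise in the (y, r) plane (up at the wall, down at the
    axis), -1 the reverse.
    """

    center_y: float
    center_r: float
    strength: float
    sign: int = 1
    width_y: float = 1.0
    width_r: float = 0.5

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise GeometryError("loop strength must be non-negative (kg/s)")
        if self.sign not in (-1, 1):
            raise GeometryError("loop sign must be +1 or -1")


@dataclass(frozen=True)
class LoopSpec:
    """Axial-radial circulation: a set of streamfunction bumps plus swirl.

    ``swirl_fraction`` scales solid-body azimuthal transport as a fraction
    of the impeller tip speed at the tank wall (only used when the grid has
    more than one azimuthal sector).
    """

    loops: tuple[CirculationLoop, ...]
    swirl_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.swirl_fraction < 0:
            raise GeometryError("swirl_fraction must be non-negative")


@dataclass(frozen=True)
class TurbulenceSpec:
    """Turbulent-kinetic-energy field: impeller peaks on a positive floor.

    ``peak_fraction`` and ``background_fraction`` express k as a fraction
    of the squared tip speed; widths are in metres.
    """

    peak_fraction: float = 0.012
    background_fraction: float = 1.2e-4
    width_y: float = 0.5
    width_r: float = 0.4

    def __post_init__(self) -> None:
        if self.background_fraction <= 0:
            raise GeometryError("background turbulence must be strictly positive")
        if self.peak_fraction < 0:
            raise GeometryError("peak turbulence fraction must be non-negative")


@dataclass
class GridFlowField:
    """Structured cylindrical grid with face-based convective mass fluxes.

    Cells are indexed flat as ``((iax * nr) + ir) * ntheta + itheta``.
    Only interior faces are stored; wall/axis/surface faces carry zero
    convective flux by construction and are omitted.  ``face_flux`` is the
    signed convective mass flux (kg/s), positive from ``face_cell_a``
    toward ``face_cell_b``.
    """

    geometry: TankGeometry
    nax: int
    nr: int
    ntheta: int
    cell_volume: np.ndarray  # (ncell,) m3
    cell_y: np.ndarray  # (ncell,) m
    cell_r: np.ndarray  # (ncell,) m
    cell_theta: np.ndarray  # (ncell,) rad
    face_cell_a: np.ndarray  # (nface,) int
    face_cell_b: np.ndarray  # (nface,) int
    face_area: np.ndarray  # (nface,) m2
    face_flux: np.ndarray  # (nface,) kg/s signed a->b
    face_kt: np.ndarray  # (nface,) m2/s2

    @property
    def ncell(self) -> int:
        return self.nax * self.nr * self.ntheta

    @property
    def nface(self) -> int:
        return self.face_cell_a.size

    def flat_index(self, iax: np.ndarray, ir: np.ndarray, itheta: np.ndarray) -> np.ndarray:
        return (np.asarray(iax) * self.nr + np.asarray(ir)) * self.ntheta + np.asarray(itheta)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check structural invariants; raise ``GeometryError`` on failure."""
        if np.any(self.cell_volume <= 0):
            raise GeometryError("all cell volumes must be positive")
        vt = self.geometry.liquid_volume
        if abs(self.cell_volume.sum() - vt) > rtol * vt:
            raise GeometryError("cell volumes do not sum to the tank liquid volume")
        if np.any(self.face_kt < 0):
            raise GeometryError("turbulent kinetic energy must be non-negative")
        imbalance, _ = check_divergence(self)
        scale = np.mean(np.abs(self.face_flux)) if self.nface else 0.0
        if scale > 0 and imbalance > rtol * scale:
            raise GeometryError(
                f"flow field is not discretely divergence-free: max cell imbalance "
                f"{imbalance:.3e} kg/s vs mean face flux {scale:.3e} kg/s"
            )


def default_loop_spec(geometry: TankGeometry, pumping_number: float = 0.75) -> LoopSpec:
    """Two counter-rotating loops per Rushton impeller.

    Loop strength is taken from the impeller pumping capacity
    ``Q = Fl * N * D^3`` (m3/s) converted to a mass flow; each impeller's
    radial jet splits evenly into its upper and lower loop.  Loop centres
    sit halfway between the impeller plane and the nearest axial "wall"
    (vessel bottom, mid-plane between impellers, or liquid surface).
    """
    n_rps = geometry.stirrer_rpm / 60.0
    q_pump = pumping_number * n_rps * geometry.impeller_diameter**3  # m3/s
    strength = geometry.rho_liquid * q_pump  # kg/s per impeller
    y_lo, y_hi = geometry.impeller_heights
    y_mid = 0.5 * (y_lo + y_hi)
    r_c = 0.5 * geometry.radius
    h = geometry.liquid_height
    loops = (
        # lower impeller: jet out at y_lo, return below and above
        CirculationLoop(0.5 * y_lo, r_c, strength, sign=-1, width_y=0.6 * y_lo),
        CirculationLoop(0.5 * (y_lo + y_mid), r_c, strength, sign=+1, width_y=0.6 * (y_mid - y_lo)),
        # upper impeller
        CirculationLoop(0.5 * (y_mid + y_hi), r_c, strength, sign=-1, width_y=0.6 * (y_hi - y_mid)),
        CirculationLoop(0.5 * (y_hi + h), r_c, strength, sign=+1, width_y=0.6 * (h - y_hi)),
    )
    return LoopSpec(loops=loops)


def _streamfunction(loop_spec: LoopSpec, geometry: TankGeometry,
                    y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Evaluate the mass streamfunction (kg/s) on a node mesh.

    A sine envelope pins psi to zero on every domain boundary, which makes
    all boundary fluxes vanish identically.
    """
    h = geometry.liquid_height
    rad = geometry.radius
    envelope = np.sin(np.pi * y / h) * np.sin(np.pi * r / rad)
    psi = np.zeros_like(y)
    for loop in loop_spec.loops:
        bump = np.exp(
            -(((y - loop.center_y) / loop.width_y) ** 2)
            - (((r - loop.center_r) / loop.width_r) ** 2)
        )
        psi += loop.sign * loop.strength * bump
    return psi * envelope


def _kt_field(kt_spec: TurbulenceSpec, geometry: TankGeometry,
              y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Turbulent kinetic energy (m2/s2) at the given points."""
    vtip2 = geometry.tip_speed**2
    kt = np.full_like(y, kt_spec.background_fraction * vtip2)
    r_tip = 0.5 * geometry.impeller_diameter
    for y_imp in geometry.impeller_heights:
        kt += (
            kt_spec.peak_fraction
            * vtip2
            * np.exp(
                -(((y - y_imp) / kt_spec.width_y) ** 2)
                - (((r - r_tip) / kt_spec.width_r) ** 2)
            )
        )
    return kt


def build_stirred_tank_field(
    geometry: TankGeometry,
    grid_dims: Sequence[int] = (52, 12, 1),
    loop_spec: LoopSpec | None = None,
    kt_spec: TurbulenceSpec | None = None,
) -> GridFlowField:
    """Build a synthetic, discretely divergence-free stirred-tank field.

    Parameters
    ----------
    geometry:
        Tank dimensions and operating point.
    grid_dims:
        ``(nax, nr, ntheta)`` cell counts; at least ``(8, 4, 1)``.
    loop_spec:
        Circulation loops; defaults to :func:`default_loop_spec`.
    kt_spec:
        Turbulence peaks; defaults to :class:`TurbulenceSpec` defaults.
    """
    nax, nr, ntheta = (int(d) for d in grid_dims)
    if nax < 8 or nr < 4 or ntheta < 1:
        raise GeometryError(f"grid too coarse: need at least (8, 4, 1), got {(nax, nr, ntheta)}")
    if loop_spec is None:
        loop_spec = default_loop_spec(geometry)
    if kt_spec is None:
        kt_spec = TurbulenceSpec()

    h = geometry.liquid_height
    rad = geometry.radius
    rho = geometry.rho_liquid
    dy = h / nax
    y_nodes = np.linspace(0.0, h, nax + 1)
    r_nodes = np.linspace(0.0, rad, nr + 1)
    theta_nodes = np.linspace(0.0, 2 * np.pi, ntheta + 1)

    # cell centres and volumes
    y_c = 0.5 * (y_nodes[:-1] + y_nodes[1:])
    r_c = 0.5 * (r_nodes[:-1] + r_nodes[1:])
    th_c = 0.5 * (theta_nodes[:-1] + theta_nodes[1:])
    ring_area = np.pi * (r_nodes[1:] ** 2 - r_nodes[:-1] ** 2)  # (nr,)
    cell_vol_ax_r = dy * ring_area / ntheta  # (nr,)

    iax_g, ir_g, ith_g = np.meshgrid(
        np.arange(nax), np.arange(nr), np.arange(ntheta), indexing="ij"
    )
    cell_volume = np.broadcast_to(cell_vol_ax_r[None, :, None], iax_g.shape).ravel().copy()
    cell_y = y_c[iax_g].ravel()
    cell_r = r_c[ir_g].ravel()
    cell_theta = th_c[ith_g].ravel()

    def flat(iax, ir, ith):
        return (iax * nr + ir) * ntheta + ith

    # nodal streamfunction (kg/s); boundary nodes evaluate to exactly 0
    yy, rr = np.meshgrid(y_nodes, r_nodes, indexing="ij")
    psi = _streamfunction(loop_spec, geometry, yy, rr)

    cells_a, cells_b, areas, fluxes, kts = [], [], [], [], []

    # axial faces: between (iax, ir, it) and (iax+1, ir, it)
    if nax > 1:
        iax_f, ir_f, ith_f = np.meshgrid(
            np.arange(nax - 1), np.arange(nr), np.arange(ntheta), indexing="ij"
        )
        a = flat(iax_f, ir_f, ith_f).ravel()
        b = flat(iax_f + 1, ir_f, ith_f).ravel()
        area = (ring_area[ir_f] / ntheta).ravel()
        # flux positive in +y through node plane iax+1, spanning rings ir..ir+1
        fl = ((psi[iax_f + 1, ir_f + 1] - psi[iax_f + 1, ir_f]) / ntheta).ravel()
        kt = _kt_field(kt_spec, geometry, y_nodes[iax_f + 1].astype(float), r_c[ir_f]).ravel()
        cells_a.append(a), cells_b.append(b), areas.append(area)
        fluxes.append(fl), kts.append(kt)

    # radial faces: between (iax, ir, it) and (iax, ir+1, it)
    if nr > 1:
        iax_f, ir_f, ith_f = np.meshgrid(
            np.arange(nax), np.arange(nr - 1), np.arange(ntheta), indexing="ij"
        )
        a = flat(iax_f, ir_f, ith_f).ravel()
        b = flat(iax_f, ir_f + 1, ith_f).ravel()
        area = (2 * np.pi * r_nodes[ir_f + 1] * dy / ntheta).ravel()
        # flux positive in +r through node cylinder ir+1, spanning axial nodes iax..iax+1
        fl = (-(psi[iax_f + 1, ir_f + 1] - psi[iax_f, ir_f + 1]) / ntheta).ravel()
        kt = _kt_field(kt_spec, geometry, y_c[iax_f], r_nodes[ir_f + 1].astype(float)).ravel()
        cells_a.append(a), cells_b.append(b), areas.append(area)
        fluxes.append(fl), kts.append(kt)

    # azimuthal faces: theta-uniform solid-body swirl, periodic
    if ntheta > 1:
        iax_f, ir_f, ith_f = np.meshgrid(
            np.arange(nax), np.arange(nr), np.arange(ntheta), indexing="ij"
        )
        a = flat(iax_f, ir_f, ith_f).ravel()
        b = flat(iax_f, ir_f, (ith_f + 1) % ntheta).ravel()
        dr = rad / nr
        area = np.full(a.shape, dr * dy)
        u_theta = loop_spec.swirl_fraction * geometry.tip_speed * (r_c[ir_f] / rad)
        fl = (rho * u_theta * dr * dy).ravel()
        kt = _kt_field(kt_spec, geometry, y_c[iax_f], r_c[ir_f]).ravel()
        cells_a.append(a), cells_b.append(b), areas.append(area)
        fluxes.append(fl), kts.append(kt)

    field_obj = GridFlowField(
        geometry=geometry,
        nax=nax,
        nr=nr,
        ntheta=ntheta,
        cell_volume=cell_volume,
        cell_y=cell_y,
        cell_r=cell_r,
        cell_theta=cell_theta,
        face_cell_a=np.concatenate(cells_a) if cells_a else np.empty(0, dtype=int),
        face_cell_b=np.concatenate(cells_b) if cells_b else np.empty(0, dtype=int),
        face_area=np.concatenate(areas) if areas else np.empty(0),
        face_flux=np.concatenate(fluxes) if fluxes else np.empty(0),
        face_kt=np.concatenate(kts) if kts else np.empty(0),
    )
    field_obj.validate()
    return field_obj


def check_divergence(field: GridFlowField) -> tuple[float, np.ndarray]:
    """Per-cell net signed face-flux sums (kg/s).

    Returns ``(max_abs_imbalance, per_cell_imbalance)`` where each entry is
    the cell's net signed *outflow*.  For a discretely divergence-free
    field the maximum is zero to round-off.
    """
    net = np.zeros(field.ncell)
    np.add.at(net, field.face_cell_a, field.face_flux)
    np.add.at(net, field.face_cell_b, -field.face_flux)
    return (float(np.max(np.abs(net))) if net.size else 0.0), net
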