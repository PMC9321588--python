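"""Compartment generation and inter-compartment flux matrices.

Grid cells are clustered into a homogeneous cylindrical compartment layout
with ``Nax`` axial, ``Nr`` radial and ``Ntheta`` azimuthal divisions,
codified as ``A{Nax}R{Nr}T{Ntheta}``.  Compartment boundaries are
restricted to grid planes (the divisions must divide the grid counts
evenly), so no grid cell ever straddles a compartment and interfaces are
geometrically smooth.

Two flux matrices are aggregated over the grid-cell faces on each
compartment interface:

* the convective matrix ``Phi_c`` (kg/s) is *directional* — entry
  ``[i, j]`` sums only the faces whose signed flux runs from compartment j
  into compartment i, so ``phi_c[i, j] != phi_c[j, i]`` in general;
* the turbulent matrix ``Phi_t`` (kg/s) is *bidirectional* — each face
  contributes the same turbulent exchange flow in both directions, making
  the off-diagonal symmetric.

Per face the turbulent mass flow is ``rho * A_face * sqrt(2 k_t / 3)``:
interface area times the RMS turbulent velocity fluctuation.  Diagonals of
both matrices hold minus the total outflow of the compartment, so every
column sums to zero exactly (outflow bookkeeping); for a divergence-free
input field every row of ``Phi_c`` also sums to zero (per-compartment
in = out).

The combined matrix ``Phi = Phi_c + Phi_t`` drives both the liquid-phase
species transport and the stochastic parcel jumps: compartment ``i`` has
mean residence time ``tau_i = M_i / |phi_ii|`` and an ordered destination
table with cumulative probabilities ``phi_ji / |phi_ii|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .flowfield import GridFlowField
from .geometry import GeometryError

__all__ = [
    "CompartmentLayout",
    "CompartmentModel",
    "LayoutError",
    "parse_layout_code",
    "assign_compartments",
    "aggregate_volumes",
    "convective_fluxes",
    "turbulent_fluxes",
    "build_compartment_model",
    "compartmentize",
]


class LayoutError(ValueError):
    """Raised for inadmissible compartment divisions."""


def parse_layout_code(code: str) -> tuple[int, int, int]:
    """Parse ``'A26R6T1'`` into ``(26, 6, 1)``."""
    import re

    m = re.fullmatch(r"A(\d+)R(\d+)T(\d+)", code.strip())
    if not m:
        raise LayoutError(f"malformed layout code {code!r}; expected e.g. 'A26R6T1'")
    return tuple(int(g) for g in m.groups())  # type: ignore[return-value]


@dataclass(frozen=True)
class CompartmentLayout:
    """Cell-to-compartment assignment for one cylindrical division."""

    nax: int
    nr: int
    ntheta: int
    cell_to_compartment: np.ndarray  # (ncell,) 0-based compartment index

    @property
    def ncomp(self) -> int:
        return self.nax * self.nr * self.ntheta

    @property
    def code(self) -> str:
        return f"A{self.nax}R{self.nr}T{self.ntheta}"


@dataclass
class CompartmentModel:
    """Aggregated compartment network: volumes, fluxes, jump tables.

    ``phi_c`` and ``phi_t`` are sparse CSC matrices in kg/s with the
    column-conservative diagonal convention described in the module
    docstring.  ``destinations``/``cum_prob`` are ragged per-compartment
    jump tables, ordered by ascending destination index so stochastic runs
    are reproducible bit-for-bit at a fixed seed.
    """

    layout: CompartmentLayout
    rho_liquid: float
    volume: np.ndarray  # (nc,) m3
    center_y: np.ndarray
    center_r: np.ndarray
    center_theta: np.ndarray
    phi_c: sparse.csc_matrix  # kg/s
    phi_t: sparse.csc_matrix  # kg/s
    phi: sparse.csc_matrix  # kg/s, phi_c + phi_t
    tau: np.ndarray  # (nc,) s; nan for the degenerate single compartment
    destinations: list[np.ndarray]  # per-compartment destination indices
    cum_prob: list[np.ndarray]  # per-compartment cumulative probabilities

    @property
    def ncomp(self) -> int:
        return self.layout.ncomp

    @property
    def mass(self) -> np.ndarray:
        """Per-compartment broth mass (kg)."""
        return self.rho_liquid * self.volume

    @property
    def no_transport(self) -> bool:
        """True for the degenerate single-compartment model."""
        return self.ncomp == 1

    def locate(self, y: float, r: float, theta: float = 0.0,
               geometry=None) -> int:
        """Compartment index containing the point ``(y, r, theta)``."""
        geometry = geometry or self._geometry
        iax = min(int(y / geometry.liquid_height * self.layout.nax), self.layout.nax - 1)
        ir = min(int(r / geometry.radius * self.layout.nr), self.layout.nr - 1)
        ith = min(int((theta % (2 * np.pi)) / (2 * np.pi) * self.layout.ntheta),
                  self.layout.ntheta - 1)
        return (iax * self.layout.nr + ir) * self.layout.ntheta + ith

    _geometry = None  # set by build_compartment_model when available

    def validate(self, rtol: float = 1e-9) -> dict:
        """Run conservation checks; return a closure report.

        Raises ``LayoutError`` for hard invariant violations (negative
        off-diagonals, positive diagonals, asymmetric turbulence).
        """
        report = {}
        for name, mat in (("phi_c", self.phi_c), ("phi_t", self.phi_t)):
            dense_off = mat - sparse.diags(mat.diagonal())
            if dense_off.size and dense_off.min() < 0:
                raise LayoutError(f"{name} has a negative off-diagonal entry")
            if np.any(mat.diagonal() > 0):
                raise LayoutError(f"{name} has a positive diagonal entry")
        asym = abs(self.phi_t - self.phi_t.T)
        report["phi_t_max_asymmetry"] = float(asym.max()) if asym.nnz else 0.0
        if report["phi_t_max_asymmetry"] != 0.0:
            raise LayoutError("phi_t off-diagonal must be exactly symmetric")
        scale = max(abs(self.phi).max(), 1e-300)
        report["max_column_sum"] = float(
            np.max(np.abs(np.asarray(self.phi.sum(axis=0)).ravel()))
        )
        report["max_row_sum_phi_c"] = float(
            np.max(np.abs(np.asarray(self.phi_c.sum(axis=1)).ravel()))
        )
        report["scale"] = float(scale)
        report["column_conservative"] = report["max_column_sum"] <= rtol * scale
        report["row_conservative_convective"] = report["max_row_sum_phi_c"] <= rtol * scale
        return report


def assign_compartments(field: GridFlowField,
                        divisions: Sequence[int]) -> CompartmentLayout:
    """Assign every grid cell to a cylindrical compartment bin.

    The divisions must divide the grid dimensions evenly so compartment
    boundaries coincide with grid planes.
    """
    nax, nr, ntheta = (int(d) for d in divisions)
    for name, div, dim in (
        ("axial", nax, field.nax),
        ("radial", nr, field.nr),
        ("azimuthal", ntheta, field.ntheta),
    ):
        if div < 1 or div > dim or dim % div != 0:
            raise LayoutError(
                f"{name} division {div} must evenly divide the grid dimension {dim}"
            )
    cells = np.arange(field.ncell)
    ith_cell = cells % field.ntheta
    ir_cell = (cells // field.ntheta) % field.nr
    iax_cell = cells // (field.ntheta * field.nr)
    bax = iax_cell * nax // field.nax
    br = ir_cell * nr // field.nr
    bth = ith_cell * ntheta // field.ntheta
    comp = (bax * nr + br) * ntheta + bth
    return CompartmentLayout(nax=nax, nr=nr, ntheta=ntheta, cell_to_compartment=comp)


def aggregate_volumes(field: GridFlowField, layout: CompartmentLayout) -> np.ndarray:
    """Sum cell volumes per compartment (m3)."""
    return np.bincount(layout.cell_to_compartment, weights=field.cell_volume,
                       minlength=layout.ncomp)


def _interface_faces(field: GridFlowField, layout: CompartmentLayout):
    comp = layout.cell_to_compartment
    ca = comp[field.face_cell_a]
    cb = comp[field.face_cell_b]
    mask = ca != cb
    return ca[mask], cb[mask], mask


def convective_fluxes(field: GridFlowField, layout: CompartmentLayout) -> sparse.csc_matrix:
    """Directional convective flux matrix ``Phi_c`` (kg/s).

    Each interface face contributes its unsigned flux to the entry for its
    actual flow direction: ``phi_c[i, j]`` accumulates faces flowing from
    compartment j to compartment i.
    """
    nc = layout.ncomp
    ca, cb, mask = _interface_faces(field, layout)
    fl = field.face_flux[mask]
    fwd = fl >= 0
    # face a->b with flux f>0: contributes to phi_c[b, a]; f<0 to phi_c[a, b]
    rows = np.concatenate([cb[fwd], ca[~fwd]])
    cols = np.concatenate([ca[fwd], cb[~fwd]])
    vals = np.concatenate([fl[fwd], -fl[~fwd]])
    mat = sparse.coo_matrix((vals, (rows, cols)), shape=(nc, nc)).tocsc()
    outflow = np.asarray(mat.sum(axis=0)).ravel()  # total leaving each column-compartment
    return (mat - sparse.diags(outflow)).tocsc()


def turbulent_fluxes(field: GridFlowField, layout: CompartmentLayout) -> sparse.csc_matrix:
    """Bidirectional turbulent flux matrix ``Phi_t`` (kg/s).

    Per face: ``rho * A_face * sqrt(2 k_t / 3)``, credited symmetrically
    to both directions.
    """
    if np.any(field.face_kt < 0):
        raise GeometryError("turbulent kinetic energy must be non-negative")
    nc = layout.ncomp
    ca, cb, mask = _interface_faces(field, layout)
    ft = field.geometry.rho_liquid * field.face_area[mask] * np.sqrt(
        2.0 * field.face_kt[mask] / 3.0
    )
    # accumulate once per unordered pair, then mirror: exact symmetry even
    # under floating-point summation
    lo = np.minimum(ca, cb)
    hi = np.maximum(ca, cb)
    upper = sparse.coo_matrix((ft, (lo, hi)), shape=(nc, nc)).tocsc()
    mat = (upper + upper.T).tocsc()
    outflow = np.asarray(mat.sum(axis=0)).ravel()
    return (mat - sparse.diags(outflow)).tocsc()


def build_compartment_model(
    field: GridFlowField,
    layout: CompartmentLayout,
    include_turbulence: bool = True,
) -> CompartmentModel:
    """Aggregate a :class:`GridFlowField` into a :class:`CompartmentModel`.

    Residence times use the combined matrix ``Phi = Phi_c + Phi_t`` on a
    mass basis, ``tau_i = rho * V_i / |phi_ii|``; destination tables draw
    from the same combined matrix.
    """
    rho = field.geometry.rho_liquid
    vol = aggregate_volumes(field, layout)
    if np.any(vol <= 0):
        raise LayoutError("every compartment must contain at least one cell")
    phi_c = convective_fluxes(field, layout)
    if include_turbulence:
        phi_t = turbulent_fluxes(field, layout)
    else:
        phi_t = sparse.csc_matrix((layout.ncomp, layout.ncomp))
    phi = (phi_c + phi_t).tocsc()

    cy = np.bincount(layout.cell_to_compartment,
                     weights=field.cell_volume * field.cell_y,
                     minlength=layout.ncomp) / vol
    cr = np.bincount(layout.cell_to_compartment,
                     weights=field.cell_volume * field.cell_r,
                     minlength=layout.ncomp) / vol
    cth = np.bincount(layout.cell_to_compartment,
                      weights=field.cell_volume * field.cell_theta,
                      minlength=layout.ncomp) / vol

    model = _model_from_matrices(layout, rho, vol, cy, cr, cth, phi_c, phi_t)
    model._geometry = field.geometry
    return model


def _model_from_matrices(layout, rho, vol, cy, cr, cth, phi_c, phi_t) -> CompartmentModel:
    """Assemble residence times and jump tables from the flux matrices."""
    nc = layout.ncomp
    phi = (phi_c + phi_t).tocsc()
    outflow = -phi.diagonal()  # |phi_ii|, >= 0
    tau = np.full(nc, np.nan)
    destinations: list[np.ndarray] = []
    cum_prob: list[np.ndarray] = []
    mass = rho * vol
    phi_csc = phi.tocsc()
    for i in range(nc):
        col = phi_csc.getcol(i)
        rows = col.indices
        vals = col.data
        off = rows != i
        dest = rows[off]
        flows = vals[off]
        keep = flows > 0
        dest, flows = dest[keep], flows[keep]
        order = np.argsort(dest)  # ascending index: reproducible jump tables
        dest, flows = dest[order], flows[order]
        if outflow[i] <= 0:
            if nc > 1:
                raise LayoutError(
                    f"compartment {i} has zero total outflow (infinite residence time)"
                )
            destinations.append(np.empty(0, dtype=int))
            cum_prob.append(np.empty(0))
            continue
        tau[i] = mass[i] / outflow[i]
        destinations.append(dest.astype(int))
        cp = np.cumsum(flows) / outflow[i]
        cp[-1] = 1.0  # guard round-off so the table always covers (0, 1]
        cum_prob.append(cp)
    if nc > 1 and np.any(~(tau > 0)):
        raise LayoutError("all residence times must be positive")
    return CompartmentModel(
        layout=layout,
        rho_liquid=rho,
        volume=vol,
        center_y=cy,
        center_r=cr,
        center_theta=cth,
        phi_c=phi_c.tocsc(),
        phi_t=phi_t.tocsc(),
        phi=phi,
        tau=tau,
        destinations=destinations,
        cum_prob=cum_prob,
    )


def compartmentize(field: GridFlowField, divisions: Sequence[int] | str,
                   include_turbulence: bool = True) -> CompartmentModel:
    """One-call helper: layout code or divisions -> validated model."""
    if isinstance(divisions, str):
        divisions = parse_layout_code(divisions)
    layout = assign_compartments(field, divisions)
    model = build_compartment_model(field, layout, include_turbulence=include_turbulence)
    model.validate()
    return model
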