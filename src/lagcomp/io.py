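"""File formats, configuration and run manifests.

On-disk conventions:

* flow fields: HDF5 with ``cells`` (volume, y, r, theta) and ``faces``
  (cell_a, cell_b, area, flux, kt) groups — the documented schema also
  accepts externally produced (e.g. CFD-exported) fields;
* compartment models: the convective and turbulent flux matrices as
  MatrixMarket coordinate files (1-based indices, kg/s) plus a
  ``compartments.csv`` table (1-based index, volume, centre coordinates,
  residence time) whose header comments record units and the layout code
  — a plain-text handoff that external compartmentizers can also write;
* run configuration: YAML mapping onto :class:`SimulationConfig`, with
  unknown keys rejected;
* every run directory gets a ``manifest.json`` (seed, config hash,
  package versions, input checksums) so reruns can be verified
  bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .compartments import (
    CompartmentLayout,
    CompartmentModel,
    LayoutError,
    _model_from_matrices,
    parse_layout_code,
)
from .flowfield import GridFlowField
from .geometry import TankGeometry
from .kinetics import MonodParams
from .simulator import SimulationConfig, SimulationError

__all__ = [
    "save_field",
    "load_field",
    "write_flux_matrices",
    "read_flux_matrices",
    "load_config",
    "save_config",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# flow fields (HDF5)
# ---------------------------------------------------------------------------

def save_field(field: GridFlowField, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "lagcomp-flowfield-1"
        f.attrs["grid_dims"] = (field.nax, field.nr, field.ntheta)
        geo = f.create_group("geometry")
        for key, val in asdict(field.geometry).items():
            geo.attrs[key] = val
        cells = f.create_group("cells")
        cells.create_dataset("volume", data=field.cell_volume)  # m3
        cells.create_dataset("y", data=field.cell_y)  # m
        cells.create_dataset("r", data=field.cell_r)  # m
        cells.create_dataset("theta", data=field.cell_theta)  # rad
        faces = f.create_group("faces")
        faces.create_dataset("cell_a", data=field.face_cell_a)
        faces.create_dataset("cell_b", data=field.face_cell_b)
        faces.create_dataset("area", data=field.face_area)  # m2
        faces.create_dataset("flux", data=field.face_flux)  # kg/s, signed a->b
        faces.create_dataset("kt", data=field.face_kt)  # m2/s2


def load_field(path) -> GridFlowField:
    import h5py

    with h5py.File(path, "r") as f:
        geometry = TankGeometry(**{k: float(v) for k, v in f["geometry"].attrs.items()})
        nax, nr, ntheta = (int(v) for v in f.attrs["grid_dims"])
        field = GridFlowField(
            geometry=geometry,
            nax=nax,
            nr=nr,
            ntheta=ntheta,
            cell_volume=f["cells/volume"][:],
            cell_y=f["cells/y"][:],
            cell_r=f["cells/r"][:],
            cell_theta=f["cells/theta"][:],
            face_cell_a=f["faces/cell_a"][:],
            face_cell_b=f["faces/cell_b"][:],
            face_area=f["faces/area"][:],
            face_flux=f["faces/flux"][:],
            face_kt=f["faces/kt"][:],
        )
    field.validate()
    return field


# ---------------------------------------------------------------------------
# compartment models (MatrixMarket + CSV)
# ---------------------------------------------------------------------------

def write_flux_matrices(model: CompartmentModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(
        directory / "phi_c.mtx", model.phi_c.tocoo(),
        comment="convective inter-compartment flux matrix, kg/s; "
                "entry (i, j) is the flow from compartment j to i; "
                "diagonal is minus the total convective outflow",
    )
    scipy_io.mmwrite(
        directory / "phi_t.mtx", model.phi_t.tocoo(),
        comment="turbulent inter-compartment flux matrix, kg/s; "
                "symmetric off-diagonal; diagonal is minus the total outflow",
    )
    df = pd.DataFrame(
        {
            "compartment": np.arange(1, model.ncomp + 1),
            "volume_m3": model.volume,
            "center_y_m": model.center_y,
            "center_r_m": model.center_r,
            "center_theta_rad": model.center_theta,
            "tau_s": model.tau,
        }
    )
    path = directory / "compartments.csv"
    geo = getattr(model, "_geometry", None)
    with open(path, "w") as fh:
        fh.write(f"# layout = {model.layout.code}\n")
        fh.write(f"# rho_liquid_kg_m3 = {model.rho_liquid!r}\n")
        if geo is not None:
            fh.write(f"# tank_diameter_m = {geo.diameter!r}\n")
            fh.write(f"# liquid_height_m = {geo.liquid_height!r}\n")
            fh.write(f"# stirrer_rpm = {geo.stirrer_rpm!r}\n")
        fh.write("# units: volume m3, coordinates m/rad, residence time s; "
                 "compartment indices are 1-based\n")
        df.to_csv(fh, index=False)


def read_flux_matrices(directory, rtol: float = 1e-9) -> CompartmentModel:
    """Load a compartment model written by :func:`write_flux_matrices`.

    Hard invariant violations (positive diagonal, negative off-diagonal,
    asymmetric turbulence) raise :class:`LayoutError`; conservation
    defects beyond ``rtol`` only warn, with the per-compartment imbalance
    available in the warning message, since externally produced matrices
    may close less tightly.
    """
    directory = Path(directory)
    phi_c = sparse.csc_matrix(scipy_io.mmread(directory / "phi_c.mtx"))
    phi_t = sparse.csc_matrix(scipy_io.mmread(directory / "phi_t.mtx"))
    meta = {}
    with open(directory / "compartments.csv") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(directory / "compartments.csv", comment="#")
    nax, nr, ntheta = parse_layout_code(meta.get("layout", f"A{len(df)}R1T1"))
    rho = float(meta.get("rho_liquid_kg_m3", 1000.0))
    nc = len(df)
    if nax * nr * ntheta != nc or phi_c.shape != (nc, nc) or phi_t.shape != (nc, nc):
        raise LayoutError("inconsistent compartment count between files")
    layout = CompartmentLayout(
        nax=nax, nr=nr, ntheta=ntheta,
        cell_to_compartment=np.arange(nc),  # one pseudo-cell per compartment
    )
    model = _model_from_matrices(
        layout, rho,
        df["volume_m3"].to_numpy(),
        df["center_y_m"].to_numpy(),
        df["center_r_m"].to_numpy(),
        df["center_theta_rad"].to_numpy(),
        phi_c, phi_t,
    )
    if "tank_diameter_m" in meta and "liquid_height_m" in meta:
        h = float(meta["liquid_height_m"])
        # impeller positions scale with the liquid column so any tank height loads
        model._geometry = TankGeometry(
            diameter=float(meta["tank_diameter_m"]),
            liquid_height=h,
            bottom_clearance=h * (1.3 / 7.7),
            impeller_spacing=h * (3.0 / 7.7),
            stirrer_rpm=float(meta.get("stirrer_rpm", 98.0)),
            rho_liquid=rho,
        )
    report = model.validate(rtol=rtol)
    if not (report["column_conservative"] and report["row_conservative_convective"]):
        warnings.warn(
            "loaded flux matrices are not conservative to tolerance: "
            f"max column sum {report['max_column_sum']:.3e} kg/s, "
            f"max convective row sum {report['max_row_sum_phi_c']:.3e} kg/s "
            f"(scale {report['scale']:.3e} kg/s)",
            stacklevel=2,
        )
    return model


# ---------------------------------------------------------------------------
# configuration (YAML)
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "mode", "duration", "n_parcels", "rel_tol", "abs_tol", "dt_max",
    "dt_sample", "output_interval", "seed", "layout", "kinetics",
    "parameter_tag", "feed_rate_g_m3_s", "feed_sample_interval",
    "cx_g_kg", "cs0_mol_kg", "injection_point", "probe_point", "n_lifelines",
}


def load_config(path) -> SimulationConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected with the full offending list; omitted keys
    take the package defaults (Np = 1000, RelTol = 1e-3, dt_max = 0.03 s).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SimulationError(f"config root must be a mapping, got {type(raw).__name__}")
    monod_block = raw.pop("monod", None)
    unknown = sorted(set(raw) - _CONFIG_FIELDS)
    if unknown:
        raise SimulationError(f"unknown configuration keys: {', '.join(unknown)}")
    for key in ("injection_point", "probe_point"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    kwargs = dict(raw)
    if monod_block is not None:
        allowed = {"qs_max_mmol_gdw_h", "ks_umol_kg", "cx_g_kg"}
        bad = sorted(set(monod_block) - allowed)
        if bad:
            raise SimulationError(f"unknown monod keys: {', '.join(bad)}")
        kwargs["monod"] = MonodParams(**monod_block)
    return SimulationConfig(**kwargs)


def save_config(config: SimulationConfig, path) -> None:
    data = asdict(config)
    data.pop("feed_profile", None)  # callables are not serialized
    data["monod"] = asdict(config.monod)
    data["injection_point"] = list(config.injection_point)
    data["probe_point"] = list(config.probe_point)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    data = asdict(config)
    data.pop("feed_profile", None)
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(directory, config: SimulationConfig, inputs: dict | None = None) -> Path:
    """Write ``manifest.json`` describing a run for reproducibility checks."""
    import lagcomp

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for name, path in (inputs or {}).items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        checksums[name] = h.hexdigest()
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "layout": config.layout,
        "mode": config.mode,
        "versions": {
            "lagcomp": lagcomp.__version__,
            "numpy": np.__version__,
        },
        "input_checksums": checksums,
    }
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
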