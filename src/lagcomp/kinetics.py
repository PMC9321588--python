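"""Species balances and black-box (Monod) reaction coupling.

Internal unit conventions (held throughout the package):

* substrate concentration ``Cs``: mol per kg broth;
* specific uptake ``qs``: mol per g dry-weight biomass per second
  (constructors accept the conventional mmol/gdw/h);
* fluxes: kg broth per second; compartment sizes as broth mass (kg).

The liquid-phase mole balance per compartment is

    dCs_i/dt = (Phi @ Cs)_i / M_i + F_i / M_i - Rs_i     [mol/kg/s]

with ``M_i = rho_l * V_i`` the compartment broth mass, ``F_i`` the molar
feed (mol/s, nonzero only in the feed compartment) and ``Rs_i`` the
volumetric uptake sink (mol/kg/s).  Because every column of ``Phi`` sums
to zero the transport term conserves total substrate exactly.

``Rs`` comes in two flavours: Eulerian (``Rs_i = Cx * qs(Cs_i)``, biomass
as a homogeneous field) and Lagrangian (``Rs_i = sum over parcels in i of
qs_p * Cx_p / M_i``, biomass localized to parcels).  At matched total
biomass and uniformly distributed parcels the two coincide as Np grows.

Rate laws are evaluated at ``max(Cs, 0)``: near washout the integrator
may step a concentration marginally negative, and clipping inside the
rate (rather than the state) keeps the error control honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartments import CompartmentModel
from .parcels import ParcelPopulation

__all__ = [
    "GLUCOSE_MOLAR_MASS",
    "MonodParams",
    "FeedSpec",
    "monod_uptake",
    "eulerian_reaction",
    "lagrangian_reaction",
    "transport_rhs",
    "chemostat_steady_state",
]

#: g/mol, anhydrous D-glucose
GLUCOSE_MOLAR_MASS = 180.16

#: conversion factor mmol/gdw/h -> mol/gdw/s
MMOL_PER_H = 1e-3 / 3600.0


class KineticsError(ValueError):
    pass


@dataclass(frozen=True)
class MonodParams:
    """Black-box Monod uptake ``qs = qs_max * Cs / (Ks + Cs)``.

    Defaults are the glucose-limited chemostat parameters for the
    penicillin case: ``qs_max = 1.6 mmol/gdw/h``, ``Ks = 7.8 umol/kg``,
    fixed biomass ``Cx = 55 gdw/kg``.
    """

    qs_max_mmol_gdw_h: float = 1.6
    ks_umol_kg: float = 7.8
    cx_g_kg: float = 55.0

    def __post_init__(self) -> None:
        if self.qs_max_mmol_gdw_h <= 0 or self.ks_umol_kg <= 0 or self.cx_g_kg <= 0:
            raise KineticsError("Monod parameters must all be positive")

    @property
    def qs_max(self) -> float:
        """mol/gdw/s"""
        return self.qs_max_mmol_gdw_h * MMOL_PER_H

    @property
    def ks(self) -> float:
        """mol/kg"""
        return self.ks_umol_kg * 1e-6


@dataclass(frozen=True)
class FeedSpec:
    """Substrate feed localized to one compartment.

    ``rate_g_m3_s`` is the tank-averaged volumetric feed rate (g substrate
    per m3 broth per second); the actual molar inflow ``F = rate * VT /
    molar_mass`` (mol/s) enters entirely in ``compartment``.  A
    time-dependent profile can be supplied as ``profile(t) -> rate``; it
    is sampled and held piecewise-constant every ``sample_interval``
    seconds (feed-controller behaviour).
    """

    compartment: int
    rate_g_m3_s: float = 1.23
    molar_mass: float = GLUCOSE_MOLAR_MASS
    profile: object | None = None  # callable t -> rate (g/m3/s)
    sample_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.rate_g_m3_s < 0:
            raise KineticsError("feed rate must be non-negative")
        if self.sample_interval <= 0:
            raise KineticsError("feed sample interval must be positive")

    def rate_at(self, t: float) -> float:
        """Feed rate (g/m3/s) at time t, sampled-and-held if a profile is set."""
        if self.profile is None:
            return self.rate_g_m3_s
        t_held = np.floor(t / self.sample_interval) * self.sample_interval
        return max(float(self.profile(t_held)), 0.0)

    def molar_feed_vector(self, model: CompartmentModel, t: float = 0.0) -> np.ndarray:
        """Per-compartment molar feed (mol/s)."""
        f = np.zeros(model.ncomp)
        total_volume = model.volume.sum()  # m3
        f[self.compartment] = self.rate_at(t) * total_volume / self.molar_mass
        return f


def monod_uptake(cs: np.ndarray | float, params: MonodParams) -> np.ndarray | float:
    """Specific uptake rate ``qs`` (mol/gdw/s); negative Cs clipped to 0."""
    cs_pos = np.maximum(np.asarray(cs, dtype=float), 0.0)
    out = params.qs_max * cs_pos / (params.ks + cs_pos)
    return float(out) if np.isscalar(cs) else out


def eulerian_reaction(cs: np.ndarray, params: MonodParams) -> np.ndarray:
    """Volumetric uptake sink ``Rs_i = Cx * qs(Cs_i)`` (mol/kg/s)."""
    return params.cx_g_kg * monod_uptake(cs, params)


def lagrangian_reaction(
    qs_per_parcel: np.ndarray,
    pop: ParcelPopulation,
    model: CompartmentModel,
) -> np.ndarray:
    """Parcel-summed uptake sink (mol/kg/s).

    ``Rs_i = (sum over parcels p in i of qs_p * Cx_p) / M_i``; compartments
    without parcels take no substrate.
    """
    if qs_per_parcel.shape != (pop.n_parcels,):
        raise KineticsError("qs_per_parcel must have one entry per parcel")
    uptake = np.bincount(
        pop.compartment, weights=qs_per_parcel * pop.biomass, minlength=model.ncomp
    )  # mol/s per compartment
    return uptake / model.mass


def transport_rhs(
    cs: np.ndarray,
    model: CompartmentModel,
    feed: np.ndarray | None = None,
    reaction: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side of the compartment species balance (mol/kg/s).

    ``feed`` is the molar feed vector (mol/s), ``reaction`` the volumetric
    sink ``Rs`` (mol/kg/s); either may be omitted.
    """
    cs = np.asarray(cs, dtype=float)
    if cs.shape != (model.ncomp,):
        raise KineticsError(
            f"state length {cs.shape} does not match {model.ncomp} compartments"
        )
    dcs = model.phi.dot(cs) / model.mass
    if feed is not None:
        if np.shape(feed) != cs.shape:
            raise KineticsError("feed vector length mismatch")
        dcs = dcs + np.asarray(feed) / model.mass
    if reaction is not None:
        if np.shape(reaction) != cs.shape:
            raise KineticsError("reaction vector length mismatch")
        dcs = dcs - np.asarray(reaction)
    return dcs


def chemostat_steady_state(params: MonodParams, feed_rate_g_m3_s: float,
                           rho_liquid: float = 1000.0,
                           molar_mass: float = GLUCOSE_MOLAR_MASS) -> float:
    """Closed-form steady substrate level of one ideally mixed compartment.

    At steady state the feed balances uptake, ``Cx * qs(Cs*) * rho_l = F``
    per unit volume, which inverts to ``Cs* = Ks * a / (1 - a)`` with
    ``a = F_molar / (Cx * rho_l * qs_max)``.  Raises if the feed exceeds
    the uptake capacity (no steady state).
    """
    f_molar = feed_rate_g_m3_s / molar_mass / rho_liquid  # mol/kg/s
    capacity = params.cx_g_kg * params.qs_max  # mol/kg/s
    alpha = f_molar / capacity
    if alpha >= 1.0:
        raise KineticsError("feed exceeds maximum uptake capacity; no steady state")
    return params.ks * alpha / (1.0 - alpha)
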