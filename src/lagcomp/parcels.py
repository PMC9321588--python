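"""Stochastic biomass-parcel tracking on the compartment network.

The biomass phase is a population of ``Np`` parcels, each carrying a fixed
amount of biomass ``Cx_p = Cx * rho_l * VT / Np`` (g) plus, for structured
kinetics, a vector of intracellular pools.  Parcels are ideal
flow-followers: their transport is driven by the same compartment fluxes
as the liquid, with no inertial physics.

Within a timestep ``dt`` a parcel in compartment ``i`` escapes with
probability ``P_jump = 1 - exp(-dt / tau_i)`` (ideal mixing inside the
compartment implies exponentially distributed residence).  If it jumps,
the destination is drawn with probability ``phi_ji / |phi_ii|``
proportional to the outgoing flows.  Both decisions use one uniform
deviate ``psi`` per parcel per step: conditional on ``psi < P_jump`` the
jump quantifier ``Q = (P_jump - psi) / P_jump`` is itself uniform on
(0, 1] and indexes the cumulative destination table.  At most one jump per
parcel per step is allowed, which biases residence times long when ``dt``
is comparable to ``tau_i``; the mitigation is capping the integrator step
(``dt_max``), not multi-jump chaining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartments import CompartmentModel

__all__ = [
    "ParcelPopulation",
    "jump_probability",
    "step_parcels",
    "stationary_distribution_check",
    "jump_chain_matrix",
]


class ParcelError(ValueError):
    pass


@dataclass
class ParcelPopulation:
    """State of the Lagrangian biomass phase.

    ``compartment`` is the per-parcel compartment index (0-based),
    ``biomass`` the per-parcel biomass ``Cx_p`` in grams, ``pools`` the
    optional intracellular pool matrix (Np, Npool) in umol per g biomass.
    The population owns its RNG stream; parcel draws happen in fixed
    parcel order so a run is reproducible bit-for-bit at a fixed seed.
    """

    compartment: np.ndarray
    biomass: np.ndarray
    rng: np.random.Generator
    pools: np.ndarray | None = None

    @classmethod
    def initialize(
        cls,
        n_parcels: int,
        model: CompartmentModel,
        cx: float,
        seed: int,
        start_compartment: int | None = None,
        pools0: np.ndarray | None = None,
    ) -> "ParcelPopulation":
        """Create ``Np`` parcels of equal biomass ``Cx * rho_l * VT / Np``.

        With ``start_compartment=None`` parcels are spread over
        compartments proportionally to broth mass (the transport chain's
        stationary law for a flux-balanced model); otherwise all parcels
        start in the given compartment (tracer-release protocol).
        ``cx`` is the tank-average biomass concentration in g per kg broth.
        """
        if n_parcels < 1:
            raise ParcelError("need at least one parcel")
        rng = np.random.default_rng(seed)
        total_mass = model.mass.sum()  # kg broth
        cx_p = cx * total_mass / n_parcels  # g biomass per parcel
        if start_compartment is None:
            p = model.mass / total_mass
            comp = rng.choice(model.ncomp, size=n_parcels, p=p)
        else:
            if not 0 <= start_compartment < model.ncomp:
                raise ParcelError(f"invalid start compartment {start_compartment}")
            comp = np.full(n_parcels, start_compartment, dtype=int)
        pools = None
        if pools0 is not None:
            pools0 = np.atleast_1d(np.asarray(pools0, dtype=float))
            pools = np.tile(pools0, (n_parcels, 1))
        return cls(
            compartment=comp.astype(np.int64),
            biomass=np.full(n_parcels, cx_p),
            rng=rng,
            pools=pools,
        )

    @property
    def n_parcels(self) -> int:
        return self.compartment.size

    def counts(self, ncomp: int) -> np.ndarray:
        """Parcels per compartment."""
        return np.bincount(self.compartment, minlength=ncomp)


def jump_probability(dt: float, tau: np.ndarray | float) -> np.ndarray | float:
    """Escape probability ``1 - exp(-dt / tau)`` within a step of ``dt``."""
    if dt < 0:
        raise ParcelError("dt must be non-negative")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0):
        raise ParcelError("residence time tau must be positive")
    out = -np.expm1(-dt / tau_arr)
    return float(out) if np.isscalar(tau) else out


def _padded_tables(model: CompartmentModel):
    """Pad the ragged per-compartment jump tables into rectangular arrays.

    Cached on the model instance; padding with cum-prob 2.0 keeps
    searchsorted from ever selecting a pad column.
    """
    cache = getattr(model, "_jump_table_cache", None)
    if cache is not None:
        return cache
    nc = model.ncomp
    width = max((d.size for d in model.destinations), default=0)
    width = max(width, 1)
    dest = np.zeros((nc, width), dtype=np.int64)
    cum = np.full((nc, width), 2.0)
    for i in range(nc):
        k = model.destinations[i].size
        if k:
            dest[i, :k] = model.destinations[i]
            cum[i, :k] = model.cum_prob[i]
    model._jump_table_cache = (dest, cum)
    return dest, cum


def step_parcels(pop: ParcelPopulation, model: CompartmentModel, dt: float) -> int:
    """Advance every parcel by one jump decision over ``dt`` seconds.

    Mutates ``pop.compartment`` in place (all other state untouched) and
    returns the number of parcels that moved.  One uniform deviate per
    parcel is consumed, in parcel order, from ``pop.rng``.
    """
    if model.no_transport:
        # single compartment: still consume the draws so step counts align
        pop.rng.random(pop.n_parcels)
        return 0
    comp = pop.compartment
    if comp.min() < 0 or comp.max() >= model.ncomp:
        raise ParcelError("parcel in an invalid compartment")
    psi = pop.rng.random(pop.n_parcels)
    p_jump = jump_probability(dt, model.tau)[comp]
    movers = psi < p_jump
    if not np.any(movers):
        return 0
    q = (p_jump[movers] - psi[movers]) / p_jump[movers]  # uniform on (0, 1]
    dest_tab, cum_tab = _padded_tables(model)
    rows_cum = cum_tab[comp[movers]]
    # first destination whose cumulative probability covers q
    idx = (rows_cum < q[:, None]).sum(axis=1)
    comp[movers] = dest_tab[comp[movers], idx]
    return int(movers.sum())


def jump_chain_matrix(model: CompartmentModel, dt: float) -> np.ndarray:
    """Dense one-step transition matrix of the parcel jump chain.

    ``P[i, j]`` is the probability that a parcel in compartment i is in j
    after one step of size ``dt``.  Intended as a brute-force oracle for
    small models (stationary distribution via the left eigenvector).
    """
    nc = model.ncomp
    P = np.zeros((nc, nc))
    p_jump = jump_probability(dt, model.tau)
    for i in range(nc):
        P[i, i] += 1.0 - p_jump[i]
        dests = model.destinations[i]
        cp = model.cum_prob[i]
        probs = np.diff(np.concatenate([[0.0], cp])) * p_jump[i]
        for j, pj in zip(dests, probs):
            P[i, j] += pj
    return P


def stationary_distribution_check(
    pop: ParcelPopulation,
    model: CompartmentModel,
    horizon: float,
    dt: float,
    min_parcels: int = 100,
) -> dict:
    """Step the population for ``horizon`` seconds and compare the final
    parcel distribution with the broth-mass distribution ``M_i / sum M``.

    Returns a report with the empirical fractions, the mass fractions and
    the total-variation distance; with fewer than ``min_parcels`` parcels
    the report is flagged ``insufficient_statistics`` instead of judged.
    """
    nsteps = max(1, int(round(horizon / dt)))
    for _ in range(nsteps):
        step_parcels(pop, model, dt)
    frac = pop.counts(model.ncomp) / pop.n_parcels
    mass_frac = model.mass / model.mass.sum()
    tv = 0.5 * float(np.abs(frac - mass_frac).sum())
    return {
        "parcel_fraction": frac,
        "mass_fraction": mass_frac,
        "total_variation": tv,
        "insufficient_statistics": pop.n_parcels < min_parcels,
    }
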