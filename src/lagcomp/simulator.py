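"""Coupled Euler-Lagrange time integration on the compartment network.

The liquid-phase species balances (and, for structured kinetics, the
``Np * Npool`` intracellular pool balances) form one ODE system that is
advanced with an embedded Bogacki-Shampine 3(2) Runge-Kutta pair: third
order propagation with a second-order error estimate, step size adapted to
a relative tolerance and capped at ``dt_max``.  After every *accepted*
step the biomass parcels perform one stochastic jump pass over the actual
step size; rejected steps consume no random numbers, so a run is
bit-reproducible at a fixed seed regardless of how the error controller
rejects steps.  The Lagrangian reaction source uses the current parcel
assignments (piecewise constant between jump passes) but is continuous in
the concentrations, which the error estimator sees in full.

Protocols
---------
``run_mixing``         tracer pulse in the feed-zone compartment, no
                       biomass; probe curve and coefficient-of-mixing.
``run_parcel_mixing``  the same pulse carried by parcels instead of a
                       scalar field (pure stochastic stepping, no ODE).
``run_protocol``       reactive modes: ``blackbox_euler`` /
                       ``blackbox_lagrange`` (Monod, fixed biomass),
                       ``chemostat`` (structured pools, fixed biomass and
                       transporter), ``fedbatch`` (structured pools,
                       growing per-parcel biomass, imposed feed profile,
                       fixed liquid volume).

Every reactive run carries two auxiliary quadrature states, cumulative
molar feed and cumulative molar uptake, integrated by the same solver;
``(substrate now) - (substrate at start) - feed + uptake`` is then a
round-off-level audit of global conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np

from .compartments import CompartmentModel
from .kinetics import (
    FeedSpec,
    KineticsError,
    MonodParams,
    lagrangian_reaction,
    monod_uptake,
)
from .parcels import ParcelPopulation, step_parcels
from .structured import DemoPoolModel

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "MixingResult",
    "LifelineSet",
    "TrajectoryOutput",
    "AdaptiveBS32",
    "integrate_adaptive",
    "run_mixing",
    "run_parcel_mixing",
    "run_protocol",
]

MODES = ("mixing", "parcel_mixing", "blackbox_euler", "blackbox_lagrange",
         "chemostat", "fedbatch")

#: default tracer injection point (m): feed zone near the liquid surface
INJECTION_POINT = (7.4, 0.75, 0.0)
#: default probe point (m): near the tank bottom, opposite azimuthal side
PROBE_POINT = (0.25, 0.75, np.pi)


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Run settings shared by all protocols.

    ``duration`` in seconds; ``n_parcels`` the Lagrangian population size;
    ``rel_tol``/``abs_tol``/``dt_max`` control the adaptive integrator;
    ``dt_sample`` the lifeline sampling interval; ``output_interval`` the
    cadence of full-state snapshots and scalar series.
    """

    mode: str = "blackbox_lagrange"
    duration: float = 60.0
    n_parcels: int = 1000
    rel_tol: float = 1e-3
    abs_tol: float = 1e-9
    dt_max: float = 0.03
    dt_sample: float = 0.06
    output_interval: float = 1.0
    seed: int = 1
    layout: str = "A26R6T1"
    kinetics: str = "monod"  # "monod" | "demo_pools"
    parameter_tag: str = "TU-A"  # structured uptake tag
    monod: MonodParams = dc_field(default_factory=MonodParams)
    feed_rate_g_m3_s: float = 1.23
    feed_profile: Callable[[float], float] | None = None
    feed_sample_interval: float = 30.0
    cx_g_kg: float = 55.0  # biomass (fixed in chemostat/blackbox; initial in fedbatch)
    cs0_mol_kg: float = 0.0
    injection_point: tuple[float, float, float] = INJECTION_POINT
    probe_point: tuple[float, float, float] = PROBE_POINT
    n_lifelines: int = 0  # number of parcels whose lifelines are recorded

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise SimulationError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise SimulationError("tolerances must be positive")
        if self.dt_max <= 0:
            raise SimulationError("dt_max must be positive")
        if self.dt_sample < 0 or self.duration <= 0:
            raise SimulationError("durations must be positive")
        if self.n_parcels < 0:
            raise SimulationError("n_parcels must be non-negative")


@dataclass
class LifelineSet:
    """Uniformly sampled per-parcel uptake-saturation traces.

    ``ratio[k, n]`` is ``qs/qs_max`` seen by tracked parcel k at
    ``times[n]``; ``compartment`` the parcel's compartment at each sample.
    """

    parcel_ids: np.ndarray
    times: np.ndarray
    ratio: np.ndarray  # (ntracked, nt)
    compartment: np.ndarray  # (ntracked, nt) int


@dataclass
class MixingResult:
    times: np.ndarray
    com: np.ndarray  # coefficient of mixing series
    probe: np.ndarray | None = None  # probe / tank-mean series
    tau95_probe: float = np.nan
    tau95_com: float = np.nan
    threshold_reached: bool = False
    injection_compartment: int = -1
    probe_compartment: int = -1


@dataclass
class TrajectoryOutput:
    """Scalar series, state snapshots and lifelines from a reactive run."""

    times: np.ndarray  # scalar-series times
    cs_mean_vol: np.ndarray  # volumetric mean substrate (mol/kg)
    cs_mean_parcel: np.ndarray  # parcel-registered mean substrate (mol/kg)
    cx_g_kg: np.ndarray  # tank biomass concentration (g/kg)
    mu_mean: np.ndarray  # parcel-mean growth rate (1/s); 0 for black-box
    qp_mean: np.ndarray  # parcel-mean product rate (umol/gx/s); 0 for black-box
    snapshot_times: np.ndarray
    cs_snapshots: np.ndarray  # (nsnap, nc)
    pool_mean: np.ndarray | None  # (nt, npool) parcel-mean pools
    pool_sd: np.ndarray | None  # (nt, npool) across-parcel SD
    final_cs: np.ndarray
    final_population: ParcelPopulation | None
    lifelines: LifelineSet | None
    audit: dict


# ---------------------------------------------------------------------------
# adaptive embedded RK 3(2) core
# ---------------------------------------------------------------------------

class AdaptiveBS32:
    """Embedded Runge-Kutta 3(2) pair with step cap and accept callbacks.

    ``on_accept(t_old, t_new, y, f_old, f_new)`` is invoked after each
    accepted step; it may mutate external state read by ``rhs`` (parcel
    jumps) and use the cubic Hermite pair ``(f_old, f_new)`` for dense
    sampling inside the step.
    """

    # Bogacki-Shampine tableau
    C2, C3 = 0.5, 0.75
    B = (2.0 / 9.0, 1.0 / 3.0, 4.0 / 9.0)
    BHAT = (7.0 / 24.0, 0.25, 1.0 / 3.0, 0.125)

    def __init__(self, rhs: Callable[[float, np.ndarray], np.ndarray],
                 rel_tol: float, abs_tol: float, dt_max: float):
        self.rhs = rhs
        self.rel_tol = rel_tol
        self.abs_tol = abs_tol
        self.dt_max = dt_max
        self.n_accepted = 0
        self.n_rejected = 0

    def integrate(self, t0: float, y0: np.ndarray, t_end: float,
                  on_accept: Callable | None = None) -> np.ndarray:
        t = t0
        y = np.asarray(y0, dtype=float).copy()
        h = min(self.dt_max, max(1e-6, (t_end - t0) * 1e-6))
        f0 = self.rhs(t, y)
        while t < t_end - 1e-12 * max(1.0, abs(t_end)):
            h = min(h, self.dt_max, t_end - t)
            if h < 1e-13 * max(1.0, abs(t)):
                raise SimulationError(f"step size underflow at t={t:.6g}")
            k1 = f0
            k2 = self.rhs(t + self.C2 * h, y + h * self.C2 * k1)
            k3 = self.rhs(t + self.C3 * h, y + h * self.C3 * k2)
            y_new = y + h * (self.B[0] * k1 + self.B[1] * k2 + self.B[2] * k3)
            k4 = self.rhs(t + h, y_new)
            y_hat = y + h * (self.BHAT[0] * k1 + self.BHAT[1] * k2
                             + self.BHAT[2] * k3 + self.BHAT[3] * k4)
            err = y_new - y_hat
            scale = self.abs_tol + self.rel_tol * np.maximum(np.abs(y), np.abs(y_new))
            err_norm = float(np.sqrt(np.mean((err / scale) ** 2)))
            if not np.isfinite(err_norm) or np.any(~np.isfinite(y_new)):
                raise SimulationError(f"non-finite state at t={t:.6g}")
            if err_norm <= 1.0:
                if on_accept is not None:
                    on_accept(t, t + h, y_new, k1, k4)
                t += h
                y = y_new
                # rhs state may have changed in on_accept (parcel jumps):
                # re-evaluate instead of reusing k4 (no FSAL across jumps)
                f0 = self.rhs(t, y)
                self.n_accepted += 1
            else:
                self.n_rejected += 1
            factor = 0.9 * err_norm ** (-1.0 / 3.0) if err_norm > 0 else 5.0
            h *= min(5.0, max(0.2, factor))
        return y


def integrate_adaptive(rhs, t0, y0, t_end, rel_tol=1e-3, abs_tol=1e-9,
                       dt_max=0.03, on_accept=None) -> np.ndarray:
    """Functional one-shot wrapper around :class:`AdaptiveBS32`."""
    solver = AdaptiveBS32(rhs, rel_tol, abs_tol, dt_max)
    return solver.integrate(t0, y0, t_end, on_accept=on_accept)


def hermite_interpolate(t0, t1, y0, y1, f0, f1, ts):
    """Cubic Hermite dense output inside one accepted step."""
    h = t1 - t0
    theta = (np.asarray(ts) - t0) / h
    th2 = theta**2
    th3 = theta**3
    h00 = 2 * th3 - 3 * th2 + 1
    h10 = th3 - 2 * th2 + theta
    h01 = -2 * th3 + 3 * th2
    h11 = th3 - th2
    return (h00[:, None] * y0 + (h * h10)[:, None] * f0
            + h01[:, None] * y1 + (h * h11)[:, None] * f1)


# ---------------------------------------------------------------------------
# mixing protocols
# ---------------------------------------------------------------------------

def _volume_weighted_com(cs: np.ndarray, volumes: np.ndarray) -> float:
    from .analysis import com_value

    return com_value(cs, volumes)


def run_mixing(model: CompartmentModel, config: SimulationConfig | None = None,
               dt_max: float = 0.01) -> MixingResult:
    """Eulerian tracer mixing: unit pulse in the injection compartment.

    The tracer is set to 1 mol/kg in the compartment containing the
    injection point and zero elsewhere; the probe series is recorded in
    the compartment containing the probe point, normalized by the
    (conserved) tank mean.  The run uses a tighter default step cap than
    the reactive protocols because nothing else limits the step.
    """
    config = config or SimulationConfig(mode="mixing")
    inj = model.locate(*config.injection_point)
    probe = model.locate(*config.probe_point)
    nc = model.ncomp
    cs0 = np.zeros(nc)
    cs0[inj] = 1.0
    mass = model.mass
    mean = float((mass * cs0).sum() / mass.sum())

    times = [0.0]
    com = [_volume_weighted_com(cs0, model.volume)]
    probe_series = [cs0[probe] / mean]

    def rhs(t, y):
        return model.phi.dot(y) / mass

    def on_accept(t0, t1, y, f0, f1):
        times.append(t1)
        com.append(_volume_weighted_com(y, model.volume))
        probe_series.append(y[probe] / mean)

    solver = AdaptiveBS32(rhs, config.rel_tol, config.abs_tol, dt_max)
    solver.integrate(0.0, cs0, config.duration, on_accept=on_accept)

    from .analysis import com_tau95, probe_tau95

    t_arr = np.array(times)
    com_arr = np.array(com)
    probe_arr = np.array(probe_series)
    t95p, probe_ok = probe_tau95(t_arr, probe_arr)
    t95c, com_ok = com_tau95(t_arr, com_arr)
    return MixingResult(
        times=t_arr, com=com_arr, probe=probe_arr,
        tau95_probe=t95p, tau95_com=t95c,
        threshold_reached=com_ok and probe_ok,
        injection_compartment=inj, probe_compartment=probe,
    )


def run_parcel_mixing(model: CompartmentModel,
                      config: SimulationConfig | None = None) -> MixingResult:
    """Lagrangian mixing: release all parcels in the injection compartment.

    Parcels are stepped with a fixed step equal to ``dt_max``; the local
    parcel concentration ``Cp_i = Np_i / V_i`` replaces the tracer field
    in the coefficient of mixing.  With few parcels the counting noise
    sets a floor on the CoM and the mixing threshold is never reached;
    the result is then flagged.
    """
    config = config or SimulationConfig(mode="parcel_mixing")
    if config.n_parcels < 1:
        raise SimulationError("parcel mixing needs at least one parcel")
    inj = model.locate(*config.injection_point)
    pop = ParcelPopulation.initialize(
        config.n_parcels, model, cx=1.0, seed=config.seed, start_compartment=inj
    )
    dt = config.dt_max
    nsteps = int(np.ceil(config.duration / dt))
    times = np.empty(nsteps + 1)
    com = np.empty(nsteps + 1)
    times[0] = 0.0
    conc = pop.counts(model.ncomp) / model.volume
    com[0] = _volume_weighted_com(conc, model.volume)
    for n in range(1, nsteps + 1):
        step_parcels(pop, model, dt)
        conc = pop.counts(model.ncomp) / model.volume
        times[n] = n * dt
        com[n] = _volume_weighted_com(conc, model.volume)

    from .analysis import com_tau95

    t95c, reached = com_tau95(times, com)
    return MixingResult(times=times, com=com, probe=None,
                        tau95_com=t95c, threshold_reached=reached,
                        injection_compartment=inj)


# ---------------------------------------------------------------------------
# reactive protocols
# ---------------------------------------------------------------------------

def run_protocol(model: CompartmentModel, config: SimulationConfig,
                 kinetic_model: DemoPoolModel | None = None) -> TrajectoryOutput:
    """Dispatch a reactive protocol (black-box, chemostat or fed-batch)."""
    if config.mode in ("mixing", "parcel_mixing"):
        raise SimulationError("use run_mixing / run_parcel_mixing for mixing modes")
    if config.mode in ("chemostat", "fedbatch"):
        kinetic_model = kinetic_model or DemoPoolModel.from_tag(config.parameter_tag)
        return _run_structured(model, config, kinetic_model)
    return _run_blackbox(model, config)


def _feed_spec(model: CompartmentModel, config: SimulationConfig) -> FeedSpec:
    return FeedSpec(
        compartment=model.locate(*config.injection_point),
        rate_g_m3_s=config.feed_rate_g_m3_s,
        profile=config.feed_profile,
        sample_interval=config.feed_sample_interval,
    )


class _Recorder:
    """Accumulates scalar series, snapshots and lifelines during a run."""

    def __init__(self, config: SimulationConfig, model: CompartmentModel,
                 pop: ParcelPopulation | None, npool: int | None,
                 sat_ratio: Callable[[np.ndarray], np.ndarray]):
        self.config = config
        self.model = model
        self.pop = pop
        self.npool = npool
        self.sat_ratio = sat_ratio  # maps Cs values -> qs/qs_max
        self.times: list[float] = []
        self.cs_mean_vol: list[float] = []
        self.cs_mean_parcel: list[float] = []
        self.cx: list[float] = []
        self.mu: list[float] = []
        self.qp: list[float] = []
        self.pool_mean: list[np.ndarray] = []
        self.pool_sd: list[np.ndarray] = []
        self.snapshot_times: list[float] = []
        self.snapshots: list[np.ndarray] = []
        self.next_output = 0.0
        n_ll = 0
        if pop is not None and config.n_lifelines > 0 and config.dt_sample > 0:
            n_ll = min(config.n_lifelines, pop.n_parcels)
        self.lifeline_ids = np.arange(n_ll)
        self.ll_times: list[float] = []
        self.ll_ratio: list[np.ndarray] = []
        self.ll_comp: list[np.ndarray] = []
        self.next_sample = 0.0

    def record_scalars(self, t, cs, mu_per_parcel=None, qp_per_parcel=None,
                       cx_total=None):
        mass = self.model.mass
        self.times.append(t)
        self.cs_mean_vol.append(float((mass * cs).sum() / mass.sum()))
        if self.pop is not None and self.pop.n_parcels:
            self.cs_mean_parcel.append(float(np.mean(cs[self.pop.compartment])))
        else:
            self.cs_mean_parcel.append(self.cs_mean_vol[-1])
        self.cx.append(cx_total if cx_total is not None else self.config.cx_g_kg)
        self.mu.append(float(np.mean(mu_per_parcel)) if mu_per_parcel is not None else 0.0)
        self.qp.append(float(np.mean(qp_per_parcel)) if qp_per_parcel is not None else 0.0)

    def record_pools(self, pools: np.ndarray):
        self.pool_mean.append(pools.mean(axis=0))
        self.pool_sd.append(pools.std(axis=0))

    def maybe_snapshot(self, t, cs):
        if t >= self.next_output - 1e-12:
            self.snapshot_times.append(t)
            self.snapshots.append(cs.copy())
            self.next_output += self.config.output_interval

    def sample_lifelines(self, t0, t1, y0, y1, f0, f1, nc):
        """Dense-sample tracked parcels on the uniform lifeline grid.

        Uses the parcel assignments in force during the step (pre-jump).
        """
        if self.lifeline_ids.size == 0:
            return
        dt_s = self.config.dt_sample
        ts = []
        while self.next_sample <= t1 + 1e-12:
            if self.next_sample >= t0 - 1e-12:
                ts.append(self.next_sample)
            self.next_sample += dt_s
        if not ts:
            return
        ts_arr = np.array(ts)
        cs_dense = hermite_interpolate(t0, t1, y0[:nc], y1[:nc], f0[:nc], f1[:nc], ts_arr)
        comp = self.pop.compartment[self.lifeline_ids]
        for k, tk in enumerate(ts_arr):
            self.ll_times.append(float(tk))
            self.ll_ratio.append(self.sat_ratio(cs_dense[k][comp]))
            self.ll_comp.append(comp.copy())

    def build_lifelines(self) -> LifelineSet | None:
        if self.lifeline_ids.size == 0 or not self.ll_times:
            return None
        return LifelineSet(
            parcel_ids=self.lifeline_ids,
            times=np.array(self.ll_times),
            ratio=np.array(self.ll_ratio).T,
            compartment=np.array(self.ll_comp, dtype=int).T,
        )


def _finalize(rec: _Recorder, cs, pop, audit) -> TrajectoryOutput:
    has_pools = len(rec.pool_mean) > 0
    return TrajectoryOutput(
        times=np.array(rec.times),
        cs_mean_vol=np.array(rec.cs_mean_vol),
        cs_mean_parcel=np.array(rec.cs_mean_parcel),
        cx_g_kg=np.array(rec.cx),
        mu_mean=np.array(rec.mu),
        qp_mean=np.array(rec.qp),
        snapshot_times=np.array(rec.snapshot_times),
        cs_snapshots=np.array(rec.snapshots) if rec.snapshots else np.empty((0, cs.size)),
        pool_mean=np.array(rec.pool_mean) if has_pools else None,
        pool_sd=np.array(rec.pool_sd) if has_pools else None,
        final_cs=cs.copy(),
        final_population=pop,
        lifelines=rec.build_lifelines(),
        audit=audit,
    )


def _run_blackbox(model: CompartmentModel, config: SimulationConfig) -> TrajectoryOutput:
    """Monod kinetics, fixed total biomass.

    ``blackbox_euler``: biomass is a homogeneous field; any parcels are
    passive concentration readers.  ``blackbox_lagrange``: uptake happens
    only in parcel-containing compartments, scaled by resident biomass.
    """
    params = config.monod
    feed = _feed_spec(model, config)
    nc = model.ncomp
    mass = model.mass
    lagrangian = config.mode == "blackbox_lagrange"
    if lagrangian and config.n_parcels < 1:
        raise SimulationError("blackbox_lagrange requires parcels")

    pop = None
    if config.n_parcels > 0:
        pop = ParcelPopulation.initialize(
            config.n_parcels, model, cx=config.cx_g_kg, seed=config.seed
        )
    # per-compartment resident biomass (g), refreshed after each jump pass
    biomass_in = np.zeros(nc)
    if pop is not None:
        np.add.at(biomass_in, pop.compartment, pop.biomass)

    feed_vec = feed.molar_feed_vector(model)
    sat = lambda cs: cs / (params.ks + np.maximum(cs, 0.0))
    rec = _Recorder(config, model, pop, None, sat)

    def reaction(cs):
        qs = monod_uptake(cs, params)
        if lagrangian:
            return biomass_in * qs / mass
        return params.cx_g_kg * qs

    def rhs(t, y):
        cs = y[:nc]
        rs = reaction(cs)
        dy = np.empty_like(y)
        dy[:nc] = model.phi.dot(cs) / mass + feed_vec / mass - rs
        dy[nc] = feed_vec.sum()  # cumulative feed (mol)
        dy[nc + 1] = (mass * rs).sum()  # cumulative uptake (mol)
        return dy

    y0 = np.concatenate([np.full(nc, config.cs0_mol_kg), [0.0, 0.0]])
    substrate0 = float((mass * y0[:nc]).sum())
    rec.record_scalars(0.0, y0[:nc])
    rec.maybe_snapshot(0.0, y0[:nc])

    def on_accept(t0, t1, y, f0, f1):
        rec.sample_lifelines(t0, t1, on_accept.y_prev, y, f0, f1, nc)
        on_accept.y_prev = y.copy()
        if pop is not None:
            moved = step_parcels(pop, model, t1 - t0)
            if moved and lagrangian:
                biomass_in[:] = 0.0
                np.add.at(biomass_in, pop.compartment, pop.biomass)
        if t1 >= rec.next_output - 1e-12 or t1 >= config.duration - 1e-12:
            rec.record_scalars(t1, y[:nc])
            rec.maybe_snapshot(t1, y[:nc])

    on_accept.y_prev = y0.copy()
    solver = AdaptiveBS32(rhs, config.rel_tol, config.abs_tol, config.dt_max)
    y = solver.integrate(0.0, y0, config.duration, on_accept=on_accept)

    cs = y[:nc]
    audit = _audit(substrate0, float((mass * cs).sum()), y[nc], y[nc + 1], solver)
    return _finalize(rec, cs, pop, audit)


def _run_structured(model: CompartmentModel, config: SimulationConfig,
                    kin: DemoPoolModel) -> TrajectoryOutput:
    """Structured multi-pool kinetics in chemostat or fed-batch closure.

    Chemostat: constant feed, fixed tank biomass and fixed transporter
    pool; steady state arises when uptake balances feed.  Fed-batch:
    per-parcel biomass grows at the parcel's own mu, the transporter pool
    is dynamic, the feed follows the configured profile (sampled and held
    every ``feed_sample_interval`` seconds), and the liquid volume stays
    fixed.
    """
    fedbatch = config.mode == "fedbatch"
    if config.n_parcels < 1:
        raise SimulationError("structured kinetics require parcels")
    feed = _feed_spec(model, config)
    nc = model.ncomp
    mass = model.mass
    total_mass = mass.sum()
    npool = kin.npool
    npar = config.n_parcels

    pop = ParcelPopulation.initialize(
        npar, model, cx=config.cx_g_kg, seed=config.seed,
        pools0=kin.initial_pools(),
    )

    sat = lambda cs: cs / (kin.params.ks + np.maximum(cs, 0.0))
    rec = _Recorder(config, model, pop, npool, sat)

    # state layout: [Cs (nc) | pools (npar*npool) | Cx_p (npar if fedbatch)
    #                | cum_feed | cum_uptake]
    n_pools_flat = npar * npool

    def unpack(y):
        cs = y[:nc]
        pools = y[nc:nc + n_pools_flat].reshape(npar, npool)
        cxp = y[nc + n_pools_flat:nc + n_pools_flat + npar] if fedbatch else pop.biomass
        return cs, pools, cxp

    def rhs(t, y):
        cs, pools, cxp = unpack(y)
        cs_par = cs[pop.compartment]
        qs = kin.uptake(cs_par, pools)  # mol/gdw/s
        uptake_comp = np.bincount(pop.compartment, weights=qs * cxp, minlength=nc)
        rs = uptake_comp / mass  # mol/kg/s
        feed_vec = feed.molar_feed_vector(model, t)
        dy = np.empty_like(y)
        dy[:nc] = model.phi.dot(cs) / mass + feed_vec / mass - rs
        dpools = kin.pool_rhs(cs_par, pools, fix_transporter=not fedbatch)
        dy[nc:nc + n_pools_flat] = dpools.ravel()
        if fedbatch:
            mu = kin.growth_rate(cs_par, pools)
            dy[nc + n_pools_flat:nc + n_pools_flat + npar] = mu * cxp
        dy[-2] = feed_vec.sum()
        dy[-1] = uptake_comp.sum()
        return dy

    y0_parts = [np.full(nc, config.cs0_mol_kg), np.tile(kin.initial_pools(), npar)]
    if fedbatch:
        y0_parts.append(pop.biomass.copy())
    y0_parts.append([0.0, 0.0])
    y0 = np.concatenate(y0_parts)
    substrate0 = float((mass * y0[:nc]).sum())

    def scalars(t, y):
        cs, pools, cxp = unpack(y)
        cs_par = cs[pop.compartment]
        mu = kin.growth_rate(cs_par, pools)
        qp = kin.product_rate(cs_par, pools)
        cx_tank = float(cxp.sum() / total_mass)
        rec.record_scalars(t, cs, mu_per_parcel=mu, qp_per_parcel=qp, cx_total=cx_tank)
        rec.record_pools(pools)
        rec.maybe_snapshot(t, cs)

    scalars(0.0, y0)

    def on_accept(t0, t1, y, f0, f1):
        rec.sample_lifelines(t0, t1, on_accept.y_prev, y, f0, f1, nc)
        on_accept.y_prev = y.copy()
        step_parcels(pop, model, t1 - t0)
        if fedbatch:
            pop.biomass = y[nc + n_pools_flat:nc + n_pools_flat + npar].copy()
        pop.pools = y[nc:nc + n_pools_flat].reshape(npar, npool).copy()
        if t1 >= rec.next_output - 1e-12 or t1 >= config.duration - 1e-12:
            scalars(t1, y)

    on_accept.y_prev = y0.copy()
    solver = AdaptiveBS32(rhs, config.rel_tol, config.abs_tol, config.dt_max)
    y = solver.integrate(0.0, y0, config.duration, on_accept=on_accept)

    cs, pools, cxp = unpack(y)
    pop.pools = pools.copy()
    if fedbatch:
        pop.biomass = cxp.copy()
    audit = _audit(substrate0, float((mass * cs).sum()), y[-2], y[-1], solver)
    return _finalize(rec, cs, pop, audit)


def _audit(substrate0, substrate1, cum_feed, cum_uptake, solver) -> dict:
    """Global substrate balance closure of a finished run."""
    residual = substrate1 - substrate0 - cum_feed + cum_uptake
    scale = max(abs(cum_feed), abs(cum_uptake), abs(substrate1), abs(substrate0), 1e-300)
    return {
        "substrate_initial_mol": substrate0,
        "substrate_final_mol": substrate1,
        "cumulative_feed_mol": float(cum_feed),
        "cumulative_uptake_mol": float(cum_uptake),
        "balance_residual_mol": float(residual),
        "balance_relative_error": float(abs(residual) / scale),
        "steps_accepted": solver.n_accepted,
        "steps_rejected": solver.n_rejected,
    }
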