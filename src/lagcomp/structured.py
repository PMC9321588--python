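"""Structured multi-pool intracellular kinetics.

Parcels can carry an intracellular state vector ``X`` (umol per g biomass)
whose metabolic pools obey

    dX/dt = S . r(Cs, X) - mu * X        [umol/gx/s]

with ``S`` the stoichiometric matrix, ``r`` the reaction-rate vector and
``mu * X`` dilution by growth.  Enzymatic pools follow a separate enzyme
balance (zero-order synthesis, first-order turnover, growth dilution).
Substrate uptake is saturable and proportional to the transporter pool,

    qs = k11 * XE11 * Cs / (Ks + Cs)     [mol/gdw/s],

so a parcel's uptake capacity adapts on the transporter's expression
timescale rather than instantaneously — the qualitative behaviour that
separates structured from black-box kinetics in a heterogeneous tank.

:class:`DemoPoolModel` is a self-contained eight-pool demonstration model
(four metabolic, four enzymatic) built to exercise this framework: a fast
glycolytic pool, an amino-acid pool feeding a Michaelis-Menten product
synthesis, a biosynthetic precursor pool driving growth, a storage pool,
and four enzymes including the glucose transporter ``XE11`` and the
product-synthesis enzyme.  It is a synthetic stand-in calibrated to
realistic orders of magnitude for a slow-growing glucose-limited fungal
process (mu around 0.03 1/h at chemostat conditions), not a published
penicillin model; its role is to exercise the coupling machinery, and the
plug-in contract lets a user register a literature model with its own
``S``, rates and parameters.  The cellular energy state is handled
algebraically (an energy-charge factor scaling growth) instead of through
an explicit ATP pool, which removes the stiffest timescale from the
system.

Two uptake parameter tags are provided: ``TU-A`` (capacity
``k11*XE11 = 1.13 mmol/gdw/h``, ``Ks = 9.8 umol/kg``) and ``TU-B``
(``1.6 mmol/gdw/h``, ``Ks = 7.8 umol/kg``, the black-box Monod values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import MMOL_PER_H, KineticsError

__all__ = [
    "PoolModelParams",
    "DemoPoolModel",
    "structured_pool_rhs",
    "uptake_structured",
]

METABOLIC = "metabolic"
ENZYMATIC = "enzymatic"


@dataclass(frozen=True)
class PoolModelParams:
    """Parameters of the demonstration eight-pool model.

    Rate constants are first-order turnover frequencies (1/s) named after
    the flux they drain; ``f_aa`` splits glycolytic flux between the
    amino-acid and precursor branches; enzyme synthesis rates ``alpha``
    are umol/gx/s and degradation rates ``beta`` 1/s.
    """

    # uptake (tag-dependent)
    uptake_capacity_mmol_gdw_h: float = 1.13  # k11 * XE11 at reference pool
    ks_umol_kg: float = 9.8
    xe11_ref: float = 10.0  # umol/gx reference transporter pool
    # metabolic rate constants (1/s)
    k_gly: float = 1.0 / 30.0
    k_sto_in: float = 1.0 / 300.0
    k_sto_out: float = 1.0 / 3600.0
    k_aa_use: float = 1.0 / 1800.0
    k_pre_use: float = 1.0 / 600.0
    f_aa: float = 0.3
    # product synthesis
    k_prod: float = 3.6e-5  # 1/s per umol/gx of enzyme
    k_aa_sat: float = 50.0  # umol/gx Michaelis constant on the AA pool
    y_aa_per_prod: float = 2.0
    # growth
    y_growth: float = 7.8e-5  # gx per umol precursor+AA consumed
    k_energy: float = 0.02  # umol/gdw/s half-saturation of the energy charge
    # enzyme balances: synthesis alpha (umol/gx/s), degradation beta (1/s)
    alpha_e: tuple[float, float, float, float] = (1.47e-3, 3.9e-4, 2.94e-3, 5.7e-4)
    beta_e: tuple[float, float, float, float] = (
        1.0 / 7200.0,
        1.0 / 14400.0,
        1.0 / 7200.0,
        1.0 / 3600.0,
    )

    @property
    def k11(self) -> float:
        """Uptake rate constant per unit transporter pool (mol/gdw/s per umol/gx)."""
        return self.uptake_capacity_mmol_gdw_h * MMOL_PER_H / self.xe11_ref

    @property
    def ks(self) -> float:
        """mol/kg"""
        return self.ks_umol_kg * 1e-6


class DemoPoolModel:
    """Eight-pool demonstration model implementing the kinetic contract.

    Pools (umol/gx), in state order::

        0 X_gly   glycolytic intermediates   (metabolic, fast)
        1 X_aa    amino acids                (metabolic)
        2 X_pre   biosynthetic precursors    (metabolic)
        3 X_sto   storage carbohydrate       (metabolic, slow)
        4 XE_11   glucose transporter        (enzymatic)
        5 XE_p    product-synthesis enzyme   (enzymatic)
        6 XE_g    growth machinery           (enzymatic)
        7 XE_m    maintenance enzyme         (enzymatic)

    All rate methods are vectorized over parcels: ``cs`` has shape (Np,),
    ``pools`` (Np, 8).
    """

    pool_names = ("X_gly", "X_aa", "X_pre", "X_sto", "XE_11", "XE_p", "XE_g", "XE_m")
    pool_classes = (METABOLIC,) * 4 + (ENZYMATIC,) * 4
    npool = 8
    n_metabolic = 4
    #: reactions: uptake, glycolysis, storage in, storage out, AA use,
    #: precursor use, product synthesis
    reaction_names = ("uptake", "gly", "sto_in", "sto_out", "aa_use", "pre_use", "prod")

    def __init__(self, params: PoolModelParams | None = None, tag: str = "TU-A"):
        self.params = params or PoolModelParams()
        self.tag = tag
        p = self.params
        # stoichiometric matrix: 8 pools x 7 reactions; enzymatic rows are
        # zero (enzymes follow their own synthesis/turnover balance)
        s = np.zeros((self.npool, 7))
        s[0] = [1.0, -1.0, -1.0, 1.0, 0.0, 0.0, 0.0]  # X_gly
        s[1] = [0.0, p.f_aa, 0.0, 0.0, -1.0, 0.0, -p.y_aa_per_prod]  # X_aa
        s[2] = [0.0, 1.0 - p.f_aa, 0.0, 0.0, 0.0, -1.0, 0.0]  # X_pre
        s[3] = [0.0, 0.0, 1.0, -1.0, 0.0, 0.0, 0.0]  # X_sto
        self.stoichiometry = s

    # -- constructors for the two uptake parameter tags -------------------
    @classmethod
    def tu_a(cls) -> "DemoPoolModel":
        """Uptake capacity 1.13 mmol/gdw/h, Ks = 9.8 umol/kg."""
        return cls(PoolModelParams(uptake_capacity_mmol_gdw_h=1.13, ks_umol_kg=9.8),
                   tag="TU-A")

    @classmethod
    def tu_b(cls) -> "DemoPoolModel":
        """Uptake capacity 1.6 mmol/gdw/h, Ks = 7.8 umol/kg."""
        return cls(PoolModelParams(uptake_capacity_mmol_gdw_h=1.6, ks_umol_kg=7.8),
                   tag="TU-B")

    @classmethod
    def from_tag(cls, tag: str) -> "DemoPoolModel":
        tag = tag.upper().replace("_", "-")
        if tag == "TU-A":
            return cls.tu_a()
        if tag == "TU-B":
            return cls.tu_b()
        raise KineticsError(f"unknown parameter tag {tag!r}; use 'TU-A' or 'TU-B'")

    # -- kinetic contract -------------------------------------------------
    def initial_pools(self) -> np.ndarray:
        """A reasonable interior starting state (umol/gx)."""
        return np.array([4.0, 60.0, 5.0, 40.0, 10.0, 5.0, 20.0, 2.0])

    def uptake(self, cs: np.ndarray, pools: np.ndarray) -> np.ndarray:
        """Specific uptake qs (mol/gdw/s), transporter-scaled Monod form."""
        p = self.params
        cs_pos = np.maximum(np.asarray(cs, dtype=float), 0.0)
        xe11 = np.maximum(pools[..., 4], 0.0)
        return p.k11 * xe11 * cs_pos / (p.ks + cs_pos)

    def uptake_capacity(self, pools: np.ndarray) -> np.ndarray:
        """Saturated uptake ``k11 * XE11`` (mol/gdw/s), for qs/qs_max lifelines."""
        return self.params.k11 * np.maximum(pools[..., 4], 0.0)

    def reaction_rates(self, cs: np.ndarray, pools: np.ndarray) -> np.ndarray:
        """Reaction-rate vector r (Np, 7) in umol/gx/s."""
        p = self.params
        x = np.maximum(pools, 0.0)
        u = self.uptake(cs, pools) * 1e6  # mol/gdw/s -> umol/gdw/s
        r = np.empty(x.shape[:-1] + (7,))
        r[..., 0] = u
        r[..., 1] = p.k_gly * x[..., 0]
        r[..., 2] = p.k_sto_in * x[..., 0]
        r[..., 3] = p.k_sto_out * x[..., 3]
        r[..., 4] = p.k_aa_use * x[..., 1]
        r[..., 5] = p.k_pre_use * x[..., 2]
        r[..., 6] = p.k_prod * x[..., 5] * x[..., 1] / (p.k_aa_sat + x[..., 1])
        return r

    def energy_charge(self, cs: np.ndarray, pools: np.ndarray) -> np.ndarray:
        """Algebraic energy-state factor in [0, 1) scaling growth."""
        u = self.uptake(cs, pools) * 1e6
        return u / (u + self.params.k_energy)

    def growth_rate(self, cs: np.ndarray, pools: np.ndarray) -> np.ndarray:
        """Specific growth rate mu (1/s) from anabolic flux times energy charge."""
        r = self.reaction_rates(cs, pools)
        return self.params.y_growth * (r[..., 4] + r[..., 5]) * self.energy_charge(cs, pools)

    def product_rate(self, cs: np.ndarray, pools: np.ndarray) -> np.ndarray:
        """Specific product synthesis rate qp (umol/gx/s)."""
        return self.reaction_rates(cs, pools)[..., 6]

    def pool_rhs(self, cs: np.ndarray, pools: np.ndarray,
                 fix_transporter: bool = False) -> np.ndarray:
        """Full intracellular balance dX/dt (umol/gx/s).

        Metabolic pools: ``S . r - mu X``.  Enzymatic pools: ``alpha -
        beta XE - mu XE``.  With ``fix_transporter`` the XE11 derivative
        is zeroed (chemostat closure).
        """
        p = self.params
        pools = np.asarray(pools, dtype=float)
        if pools.shape[-1] != self.npool:
            raise KineticsError(
                f"pool vector has {pools.shape[-1]} entries, expected {self.npool}"
            )
        r = self.reaction_rates(cs, pools)
        mu = self.growth_rate(cs, pools)
        dx = r @ self.stoichiometry.T
        dx -= mu[..., None] * pools
        xe = pools[..., 4:]
        alpha = np.asarray(p.alpha_e)
        beta = np.asarray(p.beta_e)
        dx[..., 4:] = alpha - beta * xe - mu[..., None] * xe
        if fix_transporter:
            dx[..., 4] = 0.0
        return dx


def structured_pool_rhs(pools: np.ndarray, cs: np.ndarray, model,
                        fix_transporter: bool = False) -> np.ndarray:
    """Functional wrapper around ``model.pool_rhs`` (pools-first signature)."""
    return model.pool_rhs(cs, pools, fix_transporter=fix_transporter)


def uptake_structured(cs: np.ndarray, pools: np.ndarray, model) -> np.ndarray:
    """Functional wrapper around ``model.uptake``."""
    return model.uptake(cs, pools)
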