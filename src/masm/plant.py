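"""Flowsheet simulator: N CSTRs in series, point separator, RAS and wastage.

The plant is the standard activated-sludge loop: influent (flow ``Q``)
enters tank 1 together with the return activated sludge (RAS, flow
``R*Q``); the mixed liquor flows through the tank train; wastage ``Q_w``
is withdrawn from the last tank as mixed liquor (hydraulic sludge-age
control, ``Q_w = V_total / theta_X``); the remainder feeds an ideal point
separator whose pass-set — everything smaller than the separation
threshold — leaves with the effluent and whose retain-set is returned
with the RAS.  A membrane module separates at its effective filtration
size (default 8 nm), so the captured soluble pools ``S_HC`` and ``S_IC``
are retained; a gravity settler separates at 450 nm and lets them pass.

Dissolved oxygen is held non-limiting (the kinetics carry no switching
functions); only the oxygen consumption flux is accounted, for the mass
balance and the aeration demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .components import (
    COD_MASK,
    COMPONENTS,
    INDEX,
    I_SO,
    N_COMPONENTS,
    PARTICULATES,
    StateVector,
)
from .fractionation import MEMBRANE_THRESHOLD_NM, SOLUBLE_THRESHOLD_NM
from .model_core import (
    KineticParams,
    PetersenMatrix,
    build_petersen,
    oxygen_uptake_rate,
    process_rates,
)

logger = logging.getLogger(__name__)

#: components that pass any separator (small solubles)
_ALWAYS_PASS = frozenset({"S_I", "S_S", "S_H", "S_P", "S_O"})

#: default MLSS conversion factors
COD_PER_VSS = 1.42   # mg COD / mg VSS
VSS_PER_TSS = 0.80   # dimensionless

WASHOUT_BIOMASS = 1e-6  # mg/L


class ConvergenceError(RuntimeError):
    """The steady-state solver did not reach the residual tolerance."""


@dataclass(frozen=True)
class SeparatorSpec:
    """Point separator defined by a size threshold.

    Components below the threshold exit with the effluent (pass-set);
    the rest is retained and returned with the RAS.  ``escape_mg_L`` is
    an optional particulate COD allowance in the effluent, for non-ideal
    gravity settling.
    """

    threshold_nm: float = MEMBRANE_THRESHOLD_NM
    escape_mg_L: float = 0.0
    pass_set: frozenset[str] = field(default=frozenset())
    retain_set: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.threshold_nm <= 0:
            raise ValueError("threshold must be positive")
        if self.escape_mg_L < 0:
            raise ValueError("escape allowance must be non-negative")
        if not self.pass_set and not self.retain_set:
            passing = set(_ALWAYS_PASS)
            if self.threshold_nm >= SOLUBLE_THRESHOLD_NM:
                passing |= {"S_IC", "S_HC"}
            object.__setattr__(self, "pass_set", frozenset(passing))
            object.__setattr__(
                self, "retain_set", frozenset(COMPONENTS) - frozenset(passing)
            )
        if self.pass_set & self.retain_set:
            raise ValueError("pass-set and retain-set overlap")
        if self.pass_set | self.retain_set != frozenset(COMPONENTS):
            missing = frozenset(COMPONENTS) - (self.pass_set | self.retain_set)
            raise ValueError(f"separator does not cover components {sorted(missing)}")

    def pass_mask(self) -> np.ndarray:
        return np.array([name in self.pass_set for name in COMPONENTS])


def membrane_separator(escape_mg_L: float = 0.0) -> SeparatorSpec:
    return SeparatorSpec(threshold_nm=MEMBRANE_THRESHOLD_NM, escape_mg_L=escape_mg_L)


def gravity_separator(escape_mg_L: float = 0.0) -> SeparatorSpec:
    return SeparatorSpec(threshold_nm=SOLUBLE_THRESHOLD_NM, escape_mg_L=escape_mg_L)


@dataclass(frozen=True)
class PlantConfig:
    """Flowsheet geometry and operating point.

    Exactly one of ``V_total_m3`` / ``theta_H_h`` defines the reactor
    volume.  ``theta_X_d`` is the sludge age (d), ``recycle_ratio`` the
    RAS flow as a multiple of ``Q``.
    """

    Q: float = 10_000.0               # influent flow, m3/d
    theta_X_d: float = 6.0            # sludge age, d
    n_tanks: int = 3
    V_total_m3: float | None = None
    theta_H_h: float | None = None    # hydraulic retention time, h
    recycle_ratio: float = 1.0
    separator: SeparatorSpec = field(default_factory=SeparatorSpec)
    variant: str = "masm"
    primary_settled: bool = False     # drop X_SS from the influent
    do_setpoint_mg_L: float = 2.0     # reported dissolved oxygen level

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("Q must be positive")
        if self.n_tanks < 1:
            raise ValueError("need at least one tank")
        if (self.V_total_m3 is None) == (self.theta_H_h is None):
            raise ValueError("give exactly one of V_total_m3 or theta_H_h")
        if self.V_total_m3 is not None and self.V_total_m3 <= 0:
            raise ValueError("V_total_m3 must be positive")
        if self.theta_H_h is not None and self.theta_H_h <= 0:
            raise ValueError("theta_H_h must be positive")
        if self.theta_X_d <= 0:
            raise ValueError("theta_X_d must be positive")
        if self.recycle_ratio < 0:
            raise ValueError("recycle ratio must be non-negative")
        if self.theta_X_d < self.theta_H_d:
            raise ValueError(
                f"sludge age {self.theta_X_d} d below hydraulic retention time "
                f"{self.theta_H_d:.3f} d: wastage would exceed the influent flow"
            )
        if self.recycle_ratio == 0 and self.separator.retain_set - {"S_O"}:
            raise ValueError("retained components need a recycle stream (R > 0)")

    @property
    def V_total(self) -> float:
        if self.V_total_m3 is not None:
            return self.V_total_m3
        return self.Q * self.theta_H_h / 24.0

    @property
    def theta_H_d(self) -> float:
        return self.V_total / self.Q


@dataclass(frozen=True)
class SimulationResult:
    tanks: tuple[StateVector, ...]
    effluent: StateVector
    Q_w: float                  # wastage flow, m3/d
    Q_e: float                  # effluent flow, m3/d
    mlss: float                 # mixed liquor suspended solids, mg/L
    S_TE: float                 # effluent total soluble COD, mg/L
    S_HE: float                 # effluent soluble hydrolysable COD, mg/L
    oxygen_demand_kg_d: float
    closure_defect: float       # relative global COD balance defect
    residual: float             # max relative per-component accumulation
    washout: bool
    config: PlantConfig
    influent_fed: StateVector   # influent after any primary-settling adjustment


def wastage_flow_for_srt(
    config: PlantConfig,
    retained_inventory_g: float | None = None,
    wastage_conc_mg_L: float | None = None,
) -> float:
    """Wastage flow (m3/d) enforcing the sludge age.

    With mixed-liquor wastage from the last tank and near-uniform tank
    concentrations this is the hydraulic identity ``Q_w = V_total /
    theta_X``.  When the retained-mass inventory (g) and the wastage
    concentration (mg/L = g/m3) are supplied, the exact inventory form
    ``Q_w = inventory / (theta_X * c_w)`` is used instead.
    """
    if config.theta_X_d < config.theta_H_d:
        raise ValueError("theta_X below theta_H: infeasible wastage")
    if retained_inventory_g is not None and wastage_conc_mg_L:
        return retained_inventory_g / (config.theta_X_d * wastage_conc_mg_L)
    return config.V_total / config.theta_X_d


class _Flowsheet:
    """Precomputed flows, masks and right-hand side for one configuration."""

    def __init__(self, config: PlantConfig, influent: StateVector, params: KineticParams):
        self.config = config
        self.params = params
        self.matrix: PetersenMatrix = build_petersen(params, config.variant)
        if config.primary_settled and influent.X_SS > 0:
            influent = replace(influent, X_SS=0.0)
        self.influent = influent
        self.c_in = influent.as_array()

        self.n = config.n_tanks
        self.V_t = config.V_total / self.n
        self.Q = config.Q
        self.Q_R = config.recycle_ratio * config.Q
        self.Q_w = wastage_flow_for_srt(config)
        self.Q_thru = self.Q + self.Q_R          # flow through every tank
        self.Q_f = self.Q_thru - self.Q_w        # separator feed
        self.Q_e = self.Q - self.Q_w             # effluent

        self.pass_mask = config.separator.pass_mask()
        self.retain_mask = ~self.pass_mask
        # indices of dynamic components (S_O is clamped, not integrated)
        self.dyn = np.array([j for j in range(N_COMPONENTS) if j != I_SO])

    # -- separator --------------------------------------------------------

    def separator_streams(self, c_last: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Effluent and RAS concentration vectors for a given last-tank state."""
        c_e = np.where(self.pass_mask, c_last, 0.0)
        c_ras = np.where(self.pass_mask, c_last, 0.0)
        esc = self.config.separator.escape_mg_L
        ret = self.retain_mask.copy()
        ret[I_SO] = False
        if esc > 0.0:
            feed_particulate = float(c_last[ret].sum())
            if feed_particulate > 0.0:
                frac = min(esc, feed_particulate) / feed_particulate
                c_e[ret] = frac * c_last[ret]
        if self.Q_R > 0:
            c_ras[ret] = (self.Q_f * c_last[ret] - self.Q_e * c_e[ret]) / self.Q_R
        c_e[I_SO] = self.config.do_setpoint_mg_L
        return c_e, c_ras

    # -- dynamics ---------------------------------------------------------

    def _expand(self, y: np.ndarray) -> np.ndarray:
        C = np.empty((self.n, N_COMPONENTS))
        C[:, self.dyn] = y.reshape(self.n, N_COMPONENTS - 1)
        C[:, I_SO] = self.config.do_setpoint_mg_L
        return C

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """d(concentration)/dt for the reduced (S_O-clamped) state."""
        C = self._expand(y)
        _, c_ras = self.separator_streams(C[-1])
        dC = np.empty_like(C)
        for i in range(self.n):
            c = C[i]
            rates = process_rates(np.clip(c, 0.0, None), self.params, self.matrix)
            rxn = self.matrix.stoichiometry.T @ rates
            if i == 0:
                inflow = self.Q * self.c_in + self.Q_R * c_ras
            else:
                inflow = self.Q_thru * C[i - 1]
            dC[i] = (inflow - self.Q_thru * c) / self.V_t + rxn
        return dC[:, self.dyn].ravel()

    def accumulation(self, y: np.ndarray) -> np.ndarray:
        """Net per-tank, per-component mass accumulation (g/d)."""
        return self.rhs(y) * self.V_t

    def initial_guess(self, seed_biomass: float = 500.0) -> np.ndarray:
        C = np.tile(self.c_in, (self.n, 1))
        C[:, INDEX["X_H"]] = np.maximum(C[:, INDEX["X_H"]], seed_biomass)
        return C[:, self.dyn].ravel()


def steady_state_solve(
    config: PlantConfig,
    influent: StateVector,
    params: KineticParams | None = None,
    rel_tol: float = 1e-8,
    horizon_sludge_ages: float = 50.0,
    max_polish_rounds: int = 5,
) -> SimulationResult:
    """Solve the flowsheet to steady state.

    Stiff time integration over ``horizon_sludge_ages * theta_X`` from a
    deterministic influent-fed initial guess, followed by Newton-type
    residual polishing.  Convergence requires every tank's net
    accumulation to be below ``rel_tol`` relative to the influent COD
    flux; heterotrophic washout is reported on the result, not raised.
    """
    params = params or KineticParams()
    fs = _Flowsheet(config, influent, params)

    y = fs.initial_guess()
    t_end = max(horizon_sludge_ages * config.theta_X_d, 10.0 * config.theta_H_d)
    sol = solve_ivp(
        lambda t, y: fs.rhs(y), (0.0, t_end), y, method="BDF",
        rtol=1e-8, atol=1e-8,
    )
    y = np.clip(sol.y[:, -1], 0.0, None)

    flux_scale = max(fs.Q * float(fs.c_in[COD_MASK].sum()), 1.0)  # g COD/d

    def rel_residual(yv: np.ndarray) -> float:
        return float(np.max(np.abs(fs.accumulation(yv))) / flux_scale)

    for _ in range(max_polish_rounds):
        if rel_residual(y) <= rel_tol:
            break
        polished = root(fs.rhs, y, method="hybr", tol=1e-12)
        y_new = np.clip(polished.x, 0.0, None)
        if rel_residual(y_new) < rel_residual(y):
            y = y_new
        else:
            break
    residual = rel_residual(y)
    if residual > rel_tol:
        raise ConvergenceError(
            f"steady state not reached: relative residual {residual:.2e} > {rel_tol:.0e}"
        )

    C = fs._expand(y)
    c_e, _ = fs.separator_streams(C[-1])
    tanks = tuple(StateVector.from_array(row) for row in C)
    effluent = StateVector.from_array(c_e)
    washout = bool(C[-1, INDEX["X_H"]] < WASHOUT_BIOMASS)
    if washout:
        logger.warning("heterotrophic biomass washed out (X_H < %g mg/L)", WASHOUT_BIOMASS)

    our_flux_g_d = sum(
        fs.V_t * oxygen_uptake_rate(tank, params, fs.matrix) for tank in tanks
    )
    result = SimulationResult(
        tanks=tanks,
        effluent=effluent,
        Q_w=fs.Q_w,
        Q_e=fs.Q_e,
        mlss=mlss_estimate(tanks[-1]),
        S_TE=effluent.soluble_cod(),
        S_HE=effluent.S_H,
        oxygen_demand_kg_d=our_flux_g_d / 1000.0,
        closure_defect=0.0,
        residual=residual,
        washout=washout,
        config=config,
        influent_fed=fs.influent,
    )
    defect = mass_balance_report(result).defect
    return replace(result, closure_defect=defect)


def mlss_estimate(
    mixed_liquor: StateVector,
    cod_to_vss: float = COD_PER_VSS,
    vss_to_tss: float = VSS_PER_TSS,
) -> float:
    """Mixed liquor suspended solids (mg/L) from particulate COD.

    The captured soluble pools ``S_HC``/``S_IC`` are excluded: they are
    below the 450 nm suspended-solids boundary and do not weigh in as
    solids even though the membrane retains them.
    """
    if cod_to_vss <= 0 or vss_to_tss <= 0:
        raise ValueError("conversion factors must be positive")
    return mixed_liquor.particulate_cod() / cod_to_vss / vss_to_tss


@dataclass(frozen=True)
class ClosureReport:
    influent_flux: float        # g COD/d
    effluent_flux: float
    wastage_flux: float
    oxygen_flux: float
    defect: float               # relative

    def __str__(self) -> str:  # human-readable closure report
        return (
            "COD balance (g/d): in {0:.1f} = effluent {1:.1f} + wastage {2:.1f} "
            "+ oxygen {3:.1f}  (relative defect {4:.2e})".format(
                self.influent_flux, self.effluent_flux, self.wastage_flux,
                self.oxygen_flux, self.defect,
            )
        )


def mass_balance_report(
    result: SimulationResult,
    config: PlantConfig | None = None,
    influent: StateVector | None = None,
) -> ClosureReport:
    """Global steady-state COD audit of a converged run.

    ``Q*C_T,in`` must equal effluent COD flux + wastage COD flux + oxygen
    consumption flux; the relative defect should not exceed 1e-3.
    """
    config = config or result.config
    influent = influent or result.influent_fed
    Q = config.Q
    influx = Q * influent.total_cod()
    effluent_flux = result.Q_e * result.effluent.total_cod()
    wastage_flux = result.Q_w * result.tanks[-1].total_cod()
    oxygen_flux = result.oxygen_demand_kg_d * 1000.0
    defect = (
        abs(influx - effluent_flux - wastage_flux - oxygen_flux) / influx
        if influx > 0 else abs(effluent_flux + wastage_flux + oxygen_flux)
    )
    return ClosureReport(influx, effluent_flux, wastage_flux, oxygen_flux, defect)
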