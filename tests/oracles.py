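"""Independent numerical oracles used by several test modules.

The time-march oracle re-implements the tank dynamics with plain array
arithmetic (Monod growth, surface-saturation hydrolysis, first-order
decay, flow coupling) and walks them forward with fixed-step explicit
Euler.  A fixed point of that march is a steady state of the flowsheet,
found without the BDF integrator or the Newton polish used by the
package solver.
"""

from __future__ import annotations

import numpy as np

from masm.components import COMPONENTS, INDEX
from masm.fractionation import to_influent_state
from masm.model_core import KineticParams
from masm.plant import PlantConfig

_I = INDEX


def euler_march_steady_state(
    config: PlantConfig,
    frac,
    params: KineticParams,
    dt: float = 5e-4,
    sludge_ages: float = 200.0,
) -> np.ndarray:
    """Brute-force explicit Euler march to stationarity.

    Returns tank concentrations as an (n_tanks, 12) array. Only the masm
    variant with an ideal membrane separator is supported — enough for
    cross-checking the package solver on a membrane scenario.
    """
    assert config.variant == "masm" and config.separator.escape_mg_L == 0.0

    n = config.n_tanks
    V_t = config.V_total / n
    Q = config.Q
    Q_R = config.recycle_ratio * Q
    Q_w = config.V_total / config.theta_X_d
    Q_thru = Q + Q_R
    Q_f = Q_thru - Q_w

    pass_mask = np.array([name in config.separator.pass_set for name in COMPONENTS])
    retain = ~pass_mask
    retain[_I["S_O"]] = False

    c_in = to_influent_state(frac, "masm").as_array()
    C = np.tile(c_in, (n, 1))
    C[:, _I["X_H"]] = np.maximum(C[:, _I["X_H"]], 500.0)

    p = params
    steps = int(round(sludge_ages * config.theta_X_d / dt))
    for _ in range(steps):
        x_h = C[:, _I["X_H"]]
        growth = p.mu_H_hat * C[:, _I["S_S"]] / (p.K_S + C[:, _I["S_S"]]) * x_h
        decay = p.b_H * x_h

        def hyd(col, k, K):
            c = C[:, col]
            return np.where(K * x_h + c > 0, k * c * x_h / (K * x_h + c), 0.0)

        h_sh = hyd(_I["S_H"], p.k_hS, p.K_hS)
        h_shc = hyd(_I["S_HC"], p.k_hS, p.K_hS)
        h_xs = hyd(_I["X_S"], p.k_hX, p.K_hX)
        h_xss = hyd(_I["X_SS"], p.k_hX, p.K_hX)

        rxn = np.zeros_like(C)
        rxn[:, _I["S_S"]] = -growth / p.Y_H + h_sh + h_shc + h_xs
        rxn[:, _I["S_H"]] = -h_sh
        rxn[:, _I["S_HC"]] = -h_shc + h_xss
        rxn[:, _I["X_S"]] = -h_xs
        rxn[:, _I["X_SS"]] = -h_xss
        rxn[:, _I["X_H"]] = growth - decay
        rxn[:, _I["X_P"]] = p.f_X * decay
        rxn[:, _I["S_P"]] = p.f_S * decay

        c_ras = np.where(pass_mask, C[-1], 0.0)
        c_ras[retain] = Q_f * C[-1, retain] / Q_R

        dC = np.empty_like(C)
        dC[0] = (Q * c_in + Q_R * c_ras - Q_thru * C[0]) / V_t + rxn[0]
        dC[1:] = (Q_thru * (C[:-1] - C[1:])) / V_t + rxn[1:]
        dC[:, _I["S_O"]] = 0.0
        C = np.clip(C + dt * dC, 0.0, None)
    return C


def bisect_interpolant(f, lo: float, hi: float, target: float, tol: float = 1e-12) -> float:
    """Solve f(x) = target for monotone increasing f by plain bisection."""
    flo, fhi = f(lo) - target, f(hi) - target
    assert flo * fhi <= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (f(mid) - target) * flo <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
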