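"""Synthetic influent tables and PSD curves for tests and examples.

The generators emulate the *structure* of measured data — a fully
additive COD fraction table and a smooth, monotone cumulative
particle-size distribution from sequential filtration — around the
published textile / domestic characterisations.  They are deterministic
given a seed and never rely on global random state.
"""

from __future__ import annotations

import numpy as np

from .datasets import PROFILES
from .fractionation import CODFractionation, PSDCurve, build_fractionation

#: sequential filtration size grid, nm (coarsest filter first)
PSD_GRID_NM: tuple[float, ...] = (1600, 1000, 450, 220, 100, 50, 25, 13, 8, 4, 2)


def generate_synthetic_influent(
    seed: int,
    profile: str = "textile",
    total_jitter: float = 0.3,
    split_jitter: float = 0.2,
) -> CODFractionation:
    """Draw a random but fully consistent influent fraction table.

    The total COD varies within ``+-total_jitter`` of the reference
    profile; pool splits are the reference proportions perturbed by up to
    ``+-split_jitter`` and renormalised, so every additivity identity
    holds by construction.
    """
    base = PROFILES[profile]
    rng = np.random.default_rng(seed)

    c_t = base.C_T1 * rng.uniform(1 - total_jitter, 1 + total_jitter)
    s_ratio = np.clip(
        base.S_T1 / base.C_T1 * rng.uniform(1 - split_jitter, 1 + split_jitter),
        0.05, 0.95,
    )
    s_t = c_t * s_ratio
    x_t = c_t - s_t

    def split(total: float, base_parts: list[float]) -> list[float]:
        w = np.array(base_parts, dtype=float)
        w = np.where(w > 0, w, 1e-3) * rng.uniform(1 - split_jitter, 1 + split_jitter, w.size)
        return list(total * w / w.sum())

    s_s, s_ht, s_it = split(s_t, [base.S_S1, base.S_HT1, base.S_IT1])
    x_s, x_ss, x_i, x_is = split(x_t, [base.X_S1, base.X_SS1, base.X_I1, base.X_IS1])

    f_hc = np.clip(base.S_HC1 / base.S_HT1 * rng.uniform(0.9, 1.1), 0.0, 1.0)
    f_ic = np.clip(base.S_IC1 / base.S_IT1 * rng.uniform(0.9, 1.1), 0.0, 1.0)
    return build_fractionation(
        C_T1=c_t, S_S1=s_s, S_HT1=s_ht, S_IT1=s_it,
        X_S1=x_s, X_SS1=x_ss, X_I1=x_i, X_IS1=x_is,
        captured_fractions=(float(f_hc), float(f_ic)),
    )


def generate_synthetic_psd(
    seed: int,
    total: float,
    midpoint_nm: float | None = None,
    spread_decades: float | None = None,
    grid: tuple[float, ...] = PSD_GRID_NM,
) -> PSDCurve:
    """Smooth sigmoidal cumulative PSD on the sequential-filtration grid.

    The cumulative COD below size ``s`` follows a logistic profile in
    ``log10(s)`` scaled to equal ``total`` at the coarsest filter.
    ``midpoint_nm`` is the size holding half the (unscaled) mass;
    ``spread_decades`` its logistic width.  Both are drawn from realistic
    ranges when not given.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    rng = np.random.default_rng(seed)
    mid = midpoint_nm if midpoint_nm is not None else rng.uniform(10.0, 80.0)
    width = spread_decades if spread_decades is not None else rng.uniform(0.3, 0.8)

    logs = np.log10(np.asarray(grid, dtype=float))
    raw = 1.0 / (1.0 + np.exp(-(logs - np.log10(mid)) / width))
    cumulative = total * raw / raw[0]
    return PSDCurve(sizes_nm=tuple(grid), cumulative_mg_L=tuple(cumulative))
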