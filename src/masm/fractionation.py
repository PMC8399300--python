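"""Modified COD fractionation and particle-size-distribution tools.

The classical activated-sludge characterisation splits total COD at a
single 450 nm threshold into "soluble" and particulate pools.  A membrane
module imposes a much smaller effective filtration size (about 8 nm once
the cake layer is accounted for), so the soluble hydrolysable and soluble
inert pools are each subdivided into a *passing* fraction, smaller than
the threshold, and a *captured* fraction that is retained in the reactor
with the sludge.  This module holds the fraction table, its additivity
audit, the captured/passing split (from explicit fractions or from a
cumulative particle-size-distribution curve), and the mapping from a
fraction table to an influent state vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, NamedTuple

import numpy as np

from .components import StateVector

#: additivity tolerance for printed (rounded) tables, mg COD/L
ADDITIVITY_TOL = 0.5

#: conventional particulate/soluble boundary, nm
SOLUBLE_THRESHOLD_NM = 450.0

#: default effective filtration size of a membrane plus cake layer, nm
MEMBRANE_THRESHOLD_NM = 8.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (the rounding
    convention of reported percentage tables)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CODFractionation:
    """Influent COD fraction table (all fields mg COD/L).

    Naming: a trailing ``T`` marks a total, ``C`` a captured pool; the
    ``1`` suffix marks influent values.  The table is redundant on
    purpose — the totals are what a characterisation campaign measures,
    and :func:`validate_fractionation` audits the additivity identities.
    """

    C_T1: float = 0.0    # total COD
    S_T1: float = 0.0    # total soluble COD (< 450 nm)
    X_T1: float = 0.0    # total particulate COD
    S_S1: float = 0.0    # readily biodegradable COD
    S_HT1: float = 0.0   # total soluble hydrolysable COD
    S_H1: float = 0.0    # soluble hydrolysable COD below the membrane threshold
    S_HC1: float = 0.0   # captured soluble hydrolysable COD
    S_IT1: float = 0.0   # total soluble inert COD
    S_I1: float = 0.0    # soluble inert COD below the membrane threshold
    S_IC1: float = 0.0   # captured soluble inert COD
    X_ST1: float = 0.0   # total particulate hydrolysable COD
    X_S1: float = 0.0    # suspended particulate hydrolysable COD
    X_SS1: float = 0.0   # settleable biodegradable COD
    X_IT1: float = 0.0   # total particulate inert COD
    X_I1: float = 0.0    # suspended particulate inert COD
    X_IS1: float = 0.0   # settleable particulate inert COD

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative COD fraction {f.name}={getattr(self, f.name)}")

    def replace(self, **kw) -> "CODFractionation":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FIELD_ORDER = tuple(f.name for f in fields(CODFractionation))

#: (label, lhs field, rhs fields) for every additivity identity
_IDENTITIES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("C_T1 = S_T1 + X_T1", "C_T1", ("S_T1", "X_T1")),
    ("S_T1 = S_S1 + S_HT1 + S_IT1", "S_T1", ("S_S1", "S_HT1", "S_IT1")),
    ("S_HT1 = S_H1 + S_HC1", "S_HT1", ("S_H1", "S_HC1")),
    ("S_IT1 = S_I1 + S_IC1", "S_IT1", ("S_I1", "S_IC1")),
    ("X_T1 = X_ST1 + X_IT1", "X_T1", ("X_ST1", "X_IT1")),
    ("X_ST1 = X_S1 + X_SS1", "X_ST1", ("X_S1", "X_SS1")),
    ("X_IT1 = X_I1 + X_IS1", "X_IT1", ("X_I1", "X_IS1")),
)


class IdentityCheck(NamedTuple):
    identity: str
    lhs: float
    rhs: float
    defect: float

    @property
    def ok(self) -> bool:
        return abs(self.defect) <= ADDITIVITY_TOL


def validate_fractionation(frac: CODFractionation) -> list[IdentityCheck]:
    """Evaluate every additivity identity of the fraction table.

    Returns one record per identity with ``defect = lhs - rhs``; an entry
    is acceptable when ``|defect| <= 0.5 mg/L`` (printed tables are
    rounded to whole mg/L).
    """
    report = []
    for label, lhs_name, rhs_names in _IDENTITIES:
        lhs = getattr(frac, lhs_name)
        rhs = sum(getattr(frac, n) for n in rhs_names)
        report.append(IdentityCheck(label, lhs, rhs, lhs - rhs))
    return report


def fractionation_violations(frac: CODFractionation) -> list[IdentityCheck]:
    return [c for c in validate_fractionation(frac) if not c.ok]


def captured_share(frac: CODFractionation, pool: str) -> int:
    """Captured percentage of a soluble pool, rounded to the nearest integer.

    ``pool`` is ``"hydrolysable"`` (100*S_HC1/S_HT1) or ``"inert"``
    (100*S_IC1/S_IT1).
    """
    if pool == "hydrolysable":
        total, captured = frac.S_HT1, frac.S_HC1
    elif pool == "inert":
        total, captured = frac.S_IT1, frac.S_IC1
    else:
        raise ValueError(f"pool must be 'hydrolysable' or 'inert', got {pool!r}")
    if captured == 0:
        return 0
    if total <= 0:
        raise ValueError(f"total {pool} pool is zero; captured share undefined")
    return round_half_up(100.0 * captured / total)


def soluble_hydrolysable_share(frac: CODFractionation) -> int:
    """Soluble hydrolysable COD as an integer percentage of total soluble COD."""
    if frac.S_T1 <= 0:
        raise ValueError("S_T1 is zero; share undefined")
    return round_half_up(100.0 * frac.S_HT1 / frac.S_T1)


# ---------------------------------------------------------------------------
# particle size distribution

@dataclass(frozen=True)
class PSDCurve:
    """Cumulative particle-size distribution of a soluble COD pool.

    ``sizes_nm`` is strictly decreasing (sequential filtration runs from
    the coarsest filter, ~1600 nm, down to ~2 nm); ``cumulative_mg_L[k]``
    is the COD passing (smaller than) ``sizes_nm[k]``, hence non-increasing
    along the grid.  The value at the largest size is the pool total.
    """

    sizes_nm: tuple[float, ...]
    cumulative_mg_L: tuple[float, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes_nm, dtype=float)
        c = np.asarray(self.cumulative_mg_L, dtype=float)
        if s.size != c.size:
            raise ValueError("size grid and cumulative values differ in length")
        if s.size < 3:
            raise ValueError("a PSD curve needs at least 3 points")
        if np.any(s <= 0):
            raise ValueError("sizes must be positive")
        if np.any(np.diff(s) >= 0):
            raise ValueError("sizes must be strictly decreasing")
        if np.any(np.diff(c) > 1e-12):
            raise ValueError("cumulative COD must be non-increasing toward smaller sizes")
        if np.any(c < 0):
            raise ValueError("cumulative COD must be non-negative")

    @property
    def total(self) -> float:
        return float(self.cumulative_mg_L[0])

    def cumulative_at(self, size_nm: float) -> float:
        """Cumulative COD below ``size_nm`` by piecewise-linear interpolation
        on log10(size); clamped to the curve's end values outside the grid."""
        logs = np.log10(np.asarray(self.sizes_nm))[::-1]       # ascending
        cum = np.asarray(self.cumulative_mg_L)[::-1]
        return float(np.interp(np.log10(size_nm), logs, cum))


def effective_filtration_size(curve: PSDCurve, permeate_value: float) -> float:
    """Size (nm) at which the cumulative curve equals the permeate COD.

    Marking the permeate concentration on the reactor's cumulative soluble
    COD distribution identifies the apparent (cake-layer-included) cut-off
    of the membrane.  Monotone piecewise-linear interpolation on
    log10(size); raises when the permeate value lies outside the curve's
    cumulative range.
    """
    cum = np.asarray(curve.cumulative_mg_L, dtype=float)
    if not (cum.min() <= permeate_value <= cum.max()):
        raise ValueError(
            f"permeate COD {permeate_value} outside cumulative range "
            f"[{cum.min()}, {cum.max()}] — curve and permeate do not match"
        )
    logs = np.log10(np.asarray(curve.sizes_nm))[::-1]  # ascending
    c_asc = cum[::-1]                                   # non-decreasing
    # np.interp needs strictly increasing xp only for invertibility; flat
    # stretches return their left edge, which is the smallest matching size
    log_size = float(np.interp(permeate_value, c_asc, logs))
    return 10.0 ** log_size


def captured_fraction_from_curve(curve: PSDCurve, threshold_nm: float) -> float:
    """Fraction of the pool's COD above ``threshold_nm`` (captured)."""
    if curve.total <= 0:
        return 0.0
    smallest, largest = curve.sizes_nm[-1], curve.sizes_nm[0]
    if threshold_nm <= smallest:
        return 0.0
    if threshold_nm >= largest:
        return 1.0
    return 1.0 - curve.cumulative_at(threshold_nm) / curve.total


def split_by_threshold(
    totals: tuple[float, float],
    threshold_nm: float = MEMBRANE_THRESHOLD_NM,
    curves: tuple[PSDCurve, PSDCurve] | None = None,
    captured_fractions: tuple[float, float] | None = None,
) -> tuple[float, float, float, float]:
    """Split total soluble hydrolysable and inert COD at a size threshold.

    ``totals`` is ``(S_HT1, S_IT1)``.  Explicit ``captured_fractions``
    (hydrolysable, inert; each in [0, 1]) take precedence over ``curves``;
    with neither, everything passes.  Returns ``(S_H1, S_HC1, S_I1,
    S_IC1)`` with ``passing + captured == total`` bit-exactly.
    """
    s_ht, s_it = totals
    if captured_fractions is not None:
        fh, fi = captured_fractions
        for f in (fh, fi):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"captured fraction {f} outside [0, 1]")
    elif curves is not None:
        fh = captured_fraction_from_curve(curves[0], threshold_nm)
        fi = captured_fraction_from_curve(curves[1], threshold_nm)
    else:
        fh = fi = 0.0
    s_h, s_hc = _exact_split(s_ht, fh)
    s_i, s_ic = _exact_split(s_it, fi)
    return s_h, s_hc, s_i, s_ic


def _exact_split(total: float, captured_frac: float) -> tuple[float, float]:
    # re-round until passing + captured == total holds bit-exactly;
    # one pass almost always suffices, rare rounding patterns need two
    captured = total * captured_frac
    passing = total - captured
    captured = total - passing
    for _ in range(5):
        if passing + captured == total:
            break
        passing = total - captured
        captured = total - passing
    return passing, captured


def to_influent_state(frac: CODFractionation, variant: str = "masm") -> StateVector:
    """Map a validated fraction table onto an influent state vector.

    ``masm`` keeps the captured pools as components; ``asm1_mod`` lumps
    them into ``S_H``/``S_I`` (the 450 nm view).  Settleable inert COD is
    merged into ``X_I`` — both are inert particulates retained by either
    separator.  Total influent COD equals ``C_T1`` for both variants.
    """
    bad = fractionation_violations(frac)
    if bad:
        raise ValueError(
            "inconsistent fractionation: " + "; ".join(
                f"{c.identity} (defect {c.defect:+.2f} mg/L)" for c in bad
            )
        )
    if variant == "masm":
        return StateVector(
            S_I=frac.S_I1, S_IC=frac.S_IC1, S_S=frac.S_S1,
            S_H=frac.S_H1, S_HC=frac.S_HC1,
            X_S=frac.X_S1, X_SS=frac.X_SS1, X_I=frac.X_I1 + frac.X_IS1,
        )
    if variant == "asm1_mod":
        return StateVector(
            S_I=frac.S_IT1, S_S=frac.S_S1, S_H=frac.S_HT1,
            X_S=frac.X_S1, X_SS=frac.X_SS1, X_I=frac.X_I1 + frac.X_IS1,
        )
    raise ValueError(f"unknown model variant {variant!r}")


def build_fractionation(
    C_T1: float,
    S_S1: float,
    S_HT1: float,
    S_IT1: float,
    X_S1: float,
    X_SS1: float,
    X_I1: float,
    X_IS1: float,
    captured_fractions: tuple[float, float] = (0.0, 0.0),
    threshold_nm: float = MEMBRANE_THRESHOLD_NM,
    curves: tuple[PSDCurve, PSDCurve] | None = None,
) -> CODFractionation:
    """Assemble a fully consistent table from primary measurements, with the
    soluble splits derived from explicit captured fractions or PSD curves."""
    s_h, s_hc, s_i, s_ic = split_by_threshold(
        (S_HT1, S_IT1), threshold_nm=threshold_nm, curves=curves,
        captured_fractions=captured_fractions if curves is None else None,
    )
    s_t = S_S1 + S_HT1 + S_IT1
    return CODFractionation(
        C_T1=C_T1, S_T1=s_t, X_T1=C_T1 - s_t,
        S_S1=S_S1, S_HT1=S_HT1, S_H1=s_h, S_HC1=s_hc,
        S_IT1=S_IT1, S_I1=s_i, S_IC1=s_ic,
        X_ST1=X_S1 + X_SS1, X_S1=X_S1, X_SS1=X_SS1,
        X_IT1=X_I1 + X_IS1, X_I1=X_I1, X_IS1=X_IS1,
    )
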