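"""Model component registry and the per-tank state vector.

All organic components are expressed as chemical oxygen demand (COD,
mg COD/L); dissolved oxygen ``S_O`` is the single non-COD component
(mg O2/L) and is counted as *negative* COD in continuity audits.
The component order below is fixed project-wide and matches the column
order of the stoichiometric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Fixed component order (stoichiometric-matrix column order).
COMPONENTS: tuple[str, ...] = (
    "S_I",   # soluble inert COD below the separation threshold (passes)
    "S_IC",  # captured soluble inert COD (above the membrane threshold)
    "X_I",   # particulate inert COD
    "S_S",   # readily biodegradable COD
    "S_H",   # soluble hydrolysable COD below the separation threshold
    "X_S",   # slowly hydrolysable (suspended) particulate COD
    "S_O",   # dissolved oxygen
    "X_P",   # particulate residual (endogenous) microbial products
    "S_P",   # soluble residual microbial products
    "X_SS",  # settleable biodegradable COD
    "S_HC",  # captured soluble hydrolysable COD
    "X_H",   # active heterotrophic biomass (cell COD)
)

N_COMPONENTS = len(COMPONENTS)

#: name -> column index
INDEX: dict[str, int] = {name: i for i, name in enumerate(COMPONENTS)}

I_SO = INDEX["S_O"]

#: boolean mask over COMPONENTS selecting COD-measured components
COD_MASK = np.array([name != "S_O" for name in COMPONENTS])

#: particulate components (retained by any separator, counted in MLSS)
PARTICULATES: tuple[str, ...] = ("X_I", "X_S", "X_P", "X_SS", "X_H")

#: soluble components other than dissolved oxygen
SOLUBLES: tuple[str, ...] = ("S_I", "S_IC", "S_S", "S_H", "S_P", "S_HC")


@dataclass(frozen=True)
class StateVector:
    """Concentrations in one completely mixed tank (mg/L; ``S_O`` mg O2/L)."""

    S_I: float = 0.0
    S_IC: float = 0.0
    X_I: float = 0.0
    S_S: float = 0.0
    S_H: float = 0.0
    X_S: float = 0.0
    S_O: float = 0.0
    X_P: float = 0.0
    S_P: float = 0.0
    X_SS: float = 0.0
    S_HC: float = 0.0
    X_H: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"negative concentration {f.name}={v}")

    def as_array(self) -> np.ndarray:
        """Return the concentrations in canonical component order."""
        return np.array([getattr(self, name) for name in COMPONENTS], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "StateVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_COMPONENTS,):
            raise ValueError(f"expected {N_COMPONENTS} components, got shape {values.shape}")
        return cls(**{name: float(values[i]) for i, name in enumerate(COMPONENTS)})

    def total_cod(self) -> float:
        """Sum of all COD-measured components (everything except S_O)."""
        return float(self.as_array()[COD_MASK].sum())

    def soluble_cod(self) -> float:
        return float(sum(getattr(self, n) for n in SOLUBLES))

    def particulate_cod(self) -> float:
        return float(sum(getattr(self, n) for n in PARTICULATES))
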