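"""Configuration and tabular file I/O.

Fractionation tables travel as ``parameter,<stream>,...`` CSVs whose row
labels are the fraction symbols; PSD curves as two-column
``size_nm,cumulative_mg_L`` CSVs.  Run configurations are YAML with four
sections (``plant``, ``kinetics``, ``influent``, ``separator``); unknown
keys are rejected and the fully resolved configuration can be dumped
back out for provenance, such that load -> resolve -> dump -> load is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .datasets import PROFILES
from .fractionation import (
    CODFractionation,
    FIELD_ORDER,
    PSDCurve,
    fractionation_violations,
)
from .model_core import KineticParams
from .plant import PlantConfig, SeparatorSpec
from .scenarios import DEFAULT_RECYCLE

_PLANT_KEYS = {
    "Q", "n_tanks", "theta_H_h", "V_total_m3", "theta_X_d",
    "recycle_ratio", "variant", "primary_settled",
}
_KINETIC_KEYS = set(KineticParams().to_dict())
_SEPARATOR_KEYS = {"threshold_nm", "escape_mg_L"}
_INFLUENT_KEYS = {"csv", "column", "profile"} | set(FIELD_ORDER)
_TOP_KEYS = {"plant", "kinetics", "influent", "separator", "output_dir", "verbosity"}

#: separator threshold implied by the variant when none is configured
_DEFAULT_THRESHOLD = {"masm": 8.0, "asm1_mod": 450.0}


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}' section: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# fractionation / PSD CSVs

def write_fractionation_csv(path: str | Path, tables: dict[str, CODFractionation]) -> None:
    """Write one or more fraction tables as a ``parameter,<stream>,...`` CSV."""
    frame = pd.DataFrame(
        {"parameter": FIELD_ORDER}
        | {name: [getattr(t, f) for f in FIELD_ORDER] for name, t in tables.items()}
    )
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def load_fractionation_csv(path: str | Path, column: str | None = None) -> CODFractionation:
    """Read one stream's fraction table from a CSV and validate it.

    ``column`` selects the stream; with ``None`` the first data column is
    used.  Missing rows, non-numeric cells and additivity violations all
    raise with the offending row labels named.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if "parameter" not in frame.columns:
        raise ValueError(f"{path}: missing 'parameter' column")
    if column is None:
        data_cols = [c for c in frame.columns if c != "parameter"]
        if not data_cols:
            raise ValueError(f"{path}: no data columns")
        column = data_cols[0]
    if column not in frame.columns:
        raise ValueError(f"{path}: no column {column!r}")
    series = frame.set_index("parameter")[column]
    missing = [f for f in FIELD_ORDER if f not in series.index]
    if missing:
        raise ValueError(f"{path}: missing row(s) {missing}")
    values = {}
    for f in FIELD_ORDER:
        try:
            values[f] = float(series[f])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric value for row {f!r}: {series[f]!r}") from exc
    frac = CODFractionation(**values)
    bad = fractionation_violations(frac)
    if bad:
        raise ValueError(
            f"{path}: additivity violation(s): "
            + "; ".join(f"{c.identity} (defect {c.defect:+.2f} mg/L)" for c in bad)
        )
    return frac


def write_psd_csv(path: str | Path, curve: PSDCurve) -> None:
    pd.DataFrame(
        {"size_nm": curve.sizes_nm, "cumulative_mg_L": curve.cumulative_mg_L}
    ).to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def load_psd_csv(path: str | Path) -> PSDCurve:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("size_nm", "cumulative_mg_L"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PSDCurve(
        sizes_nm=tuple(frame["size_nm"].astype(float)),
        cumulative_mg_L=tuple(frame["cumulative_mg_L"].astype(float)),
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    plant: PlantConfig
    kinetics: KineticParams
    influent: CODFractionation
    output_dir: str = "masm_out"
    verbosity: str = "info"


def resolve_run_config(raw: dict, base_dir: str | Path = ".") -> RunConfig:
    """Validate a raw configuration mapping and fill documented defaults."""
    _check_keys("top level", raw, _TOP_KEYS)
    plant_raw = dict(raw.get("plant", {}))
    _check_keys("plant", plant_raw, _PLANT_KEYS)
    kin_raw = dict(raw.get("kinetics", {}))
    _check_keys("kinetics", kin_raw, _KINETIC_KEYS)
    sep_raw = dict(raw.get("separator", {}))
    _check_keys("separator", sep_raw, _SEPARATOR_KEYS)
    infl_raw = dict(raw.get("influent", {}))
    _check_keys("influent", infl_raw, _INFLUENT_KEYS)

    variant = plant_raw.setdefault("variant", "masm")
    plant_raw.setdefault("recycle_ratio", DEFAULT_RECYCLE.get(variant, 1.0))
    if "theta_H_h" not in plant_raw and "V_total_m3" not in plant_raw:
        raise ValueError("plant section needs theta_H_h or V_total_m3")
    separator = SeparatorSpec(
        threshold_nm=sep_raw.get("threshold_nm", _DEFAULT_THRESHOLD.get(variant, 8.0)),
        escape_mg_L=sep_raw.get("escape_mg_L", 0.0),
    )
    plant = PlantConfig(separator=separator, **plant_raw)
    kinetics = KineticParams(**kin_raw)

    if "csv" in infl_raw:
        influent = load_fractionation_csv(
            Path(base_dir) / infl_raw["csv"], infl_raw.get("column")
        )
    elif "profile" in infl_raw:
        try:
            influent = PROFILES[infl_raw["profile"]]
        except KeyError:
            raise ValueError(
                f"unknown influent profile {infl_raw['profile']!r}; "
                f"available: {sorted(PROFILES)}"
            ) from None
    else:
        influent = CODFractionation(**infl_raw)
        bad = fractionation_violations(influent)
        if bad:
            raise ValueError(
                "influent section inconsistent: "
                + "; ".join(c.identity for c in bad)
            )
    return RunConfig(
        plant=plant, kinetics=kinetics, influent=influent,
        output_dir=raw.get("output_dir", "masm_out"),
        verbosity=raw.get("verbosity", "info"),
    )


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_run_config(raw, base_dir=path.parent)


def run_config_to_dict(config: RunConfig) -> dict:
    """Resolved configuration as a plain mapping (the provenance echo)."""
    p = config.plant
    plant = {
        "Q": p.Q, "n_tanks": p.n_tanks, "theta_X_d": p.theta_X_d,
        "recycle_ratio": p.recycle_ratio, "variant": p.variant,
        "primary_settled": p.primary_settled,
    }
    if p.theta_H_h is not None:
        plant["theta_H_h"] = p.theta_H_h
    else:
        plant["V_total_m3"] = p.V_total_m3
    return {
        "plant": plant,
        "kinetics": config.kinetics.to_dict(),
        "separator": {
            "threshold_nm": p.separator.threshold_nm,
            "escape_mg_L": p.separator.escape_mg_L,
        },
        "influent": config.influent.to_dict(),
        "output_dir": config.output_dir,
        "verbosity": config.verbosity,
    }


def dump_run_config(config: RunConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(run_config_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
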