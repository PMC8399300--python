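import pytest

from masm import KineticParams, TEXTILE, DOMESTIC
from masm.fractionation import to_influent_state
from masm.plant import PlantConfig, membrane_separator, steady_state_solve
from masm.scenarios import (
    FOOTPRINT_SPECS,
    MATCHED_SPECS,
    solve_scenario,
)
from oracles import euler_march_steady_state


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def textile():
    return TEXTILE


@pytest.fixture(scope="session")
def domestic():
    return DOMESTIC


def _sweep(specs):
    results = {}
    for spec in specs:
        for variant in ("asm1_mod", "masm"):
            results[(spec.theta_X_d, variant)] = solve_scenario(
                TEXTILE, variant, spec.theta_X_d, spec.hrt_h(variant)
            )
    return results


@pytest.fixture(scope="session")
def footprint_results():
    """Steady states of the design-footprint sweep, keyed (SRT, variant)."""
    return _sweep(FOOTPRINT_SPECS)


@pytest.fixture(scope="session")
def matched_results():
    """Steady states of the matched-HRT sweep, keyed (SRT, variant)."""
    return _sweep(MATCHED_SPECS)


@pytest.fixture(scope="session")
def march_comparison(params):
    """Package steady state vs brute-force explicit Euler march on the
    superfast membrane scenario; computed once per session."""
    cfg = PlantConfig(
        Q=10_000.0, n_tanks=3, theta_H_h=1.8, theta_X_d=1.0,
        recycle_ratio=4.0, separator=membrane_separator(), variant="masm",
    )
    res = steady_state_solve(cfg, to_influent_state(TEXTILE, "masm"), params)
    march = euler_march_steady_state(cfg, TEXTILE, params)
    return res, march
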