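import numpy as np
import pytest

from masm.components import COMPONENTS, StateVector
from masm.datasets import TEXTILE
from masm.fractionation import to_influent_state
from masm.model_core import KineticParams, PetersenMatrix, build_petersen
from masm import plant as plant_mod
from masm.plant import (
    PlantConfig,
    SeparatorSpec,
    gravity_separator,
    mass_balance_report,
    membrane_separator,
    mlss_estimate,
    steady_state_solve,
    wastage_flow_for_srt,
)

#: near-inert kinetics (parameter invariants require strictly positive rates)
INERT = KineticParams(
    mu_H_hat=1e-12, K_S=15, b_H=1e-12, k_hS=1e-12, K_hS=0.09, k_hX=1e-12, K_hX=0.28
)


def _config(**kw):
    defaults = dict(Q=10_000.0, n_tanks=3, theta_H_h=6.5, theta_X_d=6.0,
                    recycle_ratio=4.0, separator=membrane_separator(), variant="masm")
    defaults.update(kw)
    return PlantConfig(**defaults)


class TestSeparator:
    def test_membrane_retains_captured_pools(self):
        sep = membrane_separator()
        assert sep.pass_set == {"S_I", "S_S", "S_H", "S_P", "S_O"}
        assert {"S_IC", "S_HC", "X_H", "X_S", "X_SS", "X_I", "X_P"} <= sep.retain_set

    def test_gravity_passes_captured_pools(self):
        sep = gravity_separator()
        assert {"S_IC", "S_HC"} <= sep.pass_set
        assert sep.retain_set == {"X_I", "X_S", "X_SS", "X_P", "X_H"}

    def test_partition_covers_all_components(self):
        for sep in (membrane_separator(), gravity_separator()):
            assert sep.pass_set | sep.retain_set == set(COMPONENTS)
            assert not sep.pass_set & sep.retain_set

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SeparatorSpec(pass_set=frozenset(COMPONENTS), retain_set=frozenset({"X_H"}))


class TestPlantConfig:
    def test_volume_from_hrt(self):
        cfg = _config(theta_H_h=3.6, theta_X_d=1.0)
        assert cfg.V_total == pytest.approx(10_000 * 3.6 / 24)

    def test_exactly_one_volume_spec(self):
        with pytest.raises(ValueError, match="exactly one"):
            _config(V_total_m3=1500.0)  # theta_H_h also set by default

    def test_sludge_age_below_hrt_rejected(self):
        with pytest.raises(ValueError, match="sludge age"):
            _config(theta_H_h=48.0, theta_X_d=1.0)

    def test_retained_components_need_recycle(self):
        with pytest.raises(ValueError, match="recycle"):
            _config(recycle_ratio=0.0)


class TestWastage:
    def test_hydraulic_identity(self):
        cfg = _config(V_total_m3=1500.0, theta_H_h=None, theta_X_d=6.0)
        assert wastage_flow_for_srt(cfg) == pytest.approx(250.0)

    def test_vanishes_at_infinite_sludge_age(self):
        cfg = _config(V_total_m3=1500.0, theta_H_h=None, theta_X_d=1e9)
        assert wastage_flow_for_srt(cfg) == pytest.approx(0.0, abs=1e-5)

    def test_inventory_form_matches_hydraulic_for_uniform_tanks(self):
        cfg = _config(V_total_m3=1500.0, theta_H_h=None, theta_X_d=6.0)
        conc = 4000.0
        inventory = cfg.V_total * conc
        assert wastage_flow_for_srt(cfg, inventory, conc) == pytest.approx(250.0)

    def test_retained_accumulation_law(self):
        """Influent captured COD with hydrolysis off accumulates to
        Q*S_HC1*theta_X/V in a single membrane tank."""
        cfg = _config(n_tanks=1, theta_H_h=2.4, theta_X_d=2.0)
        influent = StateVector(S_HC=50.0)
        res = steady_state_solve(cfg, influent, INERT)
        expected = cfg.Q * 50.0 * cfg.theta_X_d / cfg.V_total
        assert res.tanks[0].S_HC == pytest.approx(expected, rel=1e-8)
        assert res.effluent.S_HC == 0.0


class TestSteadyState:
    def test_zero_influent_gives_zero_state(self, params):
        res = steady_state_solve(_config(theta_X_d=1.0, theta_H_h=2.4), StateVector(), params)
        for tank in res.tanks:
            arr = tank.as_array()
            arr[COMPONENTS.index("S_O")] = 0.0
            assert np.all(arr <= 1e-9)
        assert res.S_HE == 0.0 and res.S_TE <= 1e-9

    def test_first_order_hydrolysis_closed_form(self):
        """Single CSTR, biomass in excess: S_HE = S_H1/(1 + (k_hS/K_hS)*HRT)."""
        p = KineticParams(mu_H_hat=1e-12, b_H=1e-12, k_hS=2.45, K_hS=0.09,
                          k_hX=1e-12, K_hX=0.28)
        cfg = _config(n_tanks=1, theta_H_h=3.6, theta_X_d=2.0)
        influent = StateVector(S_H=5.0, X_H=1000.0)
        res = steady_state_solve(cfg, influent, p)
        theta_h_d = cfg.theta_H_d
        closed_form = 5.0 / (1.0 + (p.k_hS / p.K_hS) * theta_h_d)
        assert res.S_HE == pytest.approx(closed_form, rel=0.01)

    def test_retained_components_absent_from_effluent(self, footprint_results):
        for (srt, variant), res in footprint_results.items():
            for name in res.config.separator.retain_set - {"S_O"}:
                assert getattr(res.effluent, name) == 0.0

    def test_washout_reported_not_raised(self, params):
        cfg = _config(theta_H_h=1.2, theta_X_d=0.05)
        res = steady_state_solve(cfg, to_influent_state(TEXTILE, "masm"), params)
        assert res.washout

    def test_solver_matches_brute_force_time_march(self, march_comparison):
        """BDF + Newton polish agrees with a long explicit Euler march."""
        res, march = march_comparison
        solved = np.array([t.as_array() for t in res.tanks])
        i_so = COMPONENTS.index("S_O")
        for j, name in enumerate(COMPONENTS):
            if j == i_so:
                continue
            a, b = solved[:, j], march[:, j]
            scale = np.maximum(np.abs(b), 0.5)
            assert np.all(np.abs(a - b) / scale <= 0.005), name

    def test_membrane_and_settling_coincide_without_captured_routes(self, params):
        """At a 450 nm threshold with captured pools zero and primary-settled
        influent the membrane model reduces exactly to the reference model."""
        frac450 = TEXTILE.replace(
            S_H1=460.0, S_HC1=0.0, S_I1=225.0, S_IC1=0.0
        )
        results = {}
        for variant in ("masm", "asm1_mod"):
            cfg = _config(variant=variant, separator=gravity_separator(),
                          recycle_ratio=1.0, theta_X_d=2.0, theta_H_h=5.8,
                          primary_settled=True)
            results[variant] = steady_state_solve(
                cfg, to_influent_state(frac450, variant), params
            )
        a = np.array([t.as_array() for t in results["masm"].tanks])
        b = np.array([t.as_array() for t in results["asm1_mod"].tanks])
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-8)
        assert results["masm"].S_HE == pytest.approx(results["asm1_mod"].S_HE, rel=1e-6)


class TestMLSS:
    def test_zero_particulates(self):
        assert mlss_estimate(StateVector(S_S=500.0)) == 0.0

    def test_conversion_arithmetic(self):
        state = StateVector(X_H=4544.0)
        assert mlss_estimate(state, cod_to_vss=1.42, vss_to_tss=0.8) == pytest.approx(4000.0)

    def test_captured_solubles_excluded(self):
        assert mlss_estimate(StateVector(S_HC=2000.0, S_IC=500.0)) == 0.0

    def test_settling_design_band_at_conventional_sludge_ages(self, footprint_results):
        """The gravity-settled sweeps at SRT 6-8 d land in the 4000-4400 mg/L
        design MLSS band."""
        for srt in (6, 8):
            mlss = footprint_results[(srt, "asm1_mod")].mlss
            assert 4000.0 <= mlss <= 4400.0

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            mlss_estimate(StateVector(), cod_to_vss=0.0)


class TestMassBalance:
    def test_closure_on_converged_scenarios(self, footprint_results):
        for res in footprint_results.values():
            assert res.closure_defect <= 1e-3

    def test_pass_through_without_reaction(self):
        """theta_X = theta_H and inert kinetics: the influent leaves via
        wastage unchanged and the COD balance closes exactly."""
        cfg = _config(theta_H_h=24.0, theta_X_d=1.0, variant="masm")
        res = steady_state_solve(cfg, to_influent_state(TEXTILE, "masm"), INERT)
        assert res.closure_defect <= 1e-9
        assert res.Q_e == pytest.approx(0.0)
        assert res.tanks[-1].total_cod() == pytest.approx(TEXTILE.C_T1, rel=1e-8)

    def test_continuity_fault_breaks_closure(self, params, monkeypatch):
        """A perturbed stoichiometric matrix shows up as a closure defect."""
        def leaky_build(p, variant):
            m = build_petersen(p, variant)
            S = m.stoichiometry.copy()
            S[5, COMPONENTS.index("X_P")] += 0.1  # decay creates COD from nothing
            return PetersenMatrix(variant=variant, stoichiometry=S, rate_specs=m.rate_specs)

        monkeypatch.setattr(plant_mod, "build_petersen", leaky_build)
        cfg = _config(theta_X_d=6.0, theta_H_h=6.5)
        res = steady_state_solve(cfg, to_influent_state(TEXTILE, "masm"), params)
        assert res.closure_defect > 1e-3

    def test_report_terms_sum(self, footprint_results):
        res = footprint_results[(6, "masm")]
        rep = mass_balance_report(res)
        assert rep.influent_flux == pytest.approx(
            rep.effluent_flux + rep.wastage_flux + rep.oxygen_flux, rel=1e-9
        )
        assert "relative defect" in str(rep)
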