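"""Detailed IL-4 systems model: structure, conservation and conditions."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_rhs
from il4redox.systems_model import (STANDARD_CONDITIONS, Condition,
                                    Il4SystemsModel, ObservationScaling,
                                    build_systems_network, observe)

TURNOVER_OFF = {"k_stat_syn": 0.0, "k_stat_deg": 0.0, "k_stat_deg_u": 0.0,
                "v_socs": 0.0, "k_socs_deg": 0.0}


@pytest.fixture(scope="module")
def model():
    return Il4SystemsModel()


class TestStructure:
    def test_rhs_matches_brute_force_oracle(self, model):
        # includes the ROS-modified oxidation fluxes and the saturating
        # SOCS production term
        system = model.system
        model._input.fn = lambda t: 7.5
        rng = np.random.default_rng(3)
        rhs = system.make_rhs()
        for _ in range(20):
            y = rng.uniform(0.0, 2.0, size=len(system.species))
            np.testing.assert_allclose(
                rhs(1.0, y), brute_force_rhs(system, 1.0, y),
                rtol=1e-10, atol=1e-12)

    def test_il4_is_clamped(self, model):
        system = model.system
        model._input.fn = lambda t: 1.0
        y = np.full(len(system.species), 0.5)
        dy = system.make_rhs()(0.0, y)
        assert dy[system._index["IL4"]] == 0.0

    def test_no_oxidation_in_nucleus(self, model):
        nuclear = {s for s, c in model.system.compartments.items()
                   if c == "nucleus"}
        for rxn in model.system.reactions:
            if rxn.modifiers:  # ROS-driven oxidation reactions
                names = {n for n, _ in rxn.reactants + rxn.products}
                assert not names & nuclear


class TestConservation:
    def test_moiety_totals_conserved_with_turnover_off(self, model):
        params = {**model.parameters, **TURNOVER_OFF}
        y0 = model.steady_state(model.ros_il4.a, parameters=params)
        df = model.simulate_condition(STANDARD_CONDITIONS["IL4"],
                                      parameters=params, y0=y0)
        moieties = {
            "STAT6": ["S_c", "pS_c", "S_n", "pS_n", "C_RaS", "C_P1pS"],
            "P1": ["P1", "P1ox", "C_P1pS"],
            "P2": ["P2", "P2ox", "C_P2Ra"],
            "receptor": ["R", "Ra", "RaSOCS", "C_RaS", "C_P2Ra"],
            "SOCS": ["SOCS", "RaSOCS"],
        }
        for name, members in moieties.items():
            total = sum(df[m] for m in members).to_numpy()
            if total[0] == 0.0:  # SOCS pool is empty with production off
                assert np.abs(total).max() < 1e-9
                continue
            drift = np.abs(total - total[0]) / total[0]
            assert drift.max() < 1e-6, f"{name} moiety drifts {drift.max():.2e}"


class TestSteadyState:
    def test_zero_ros_zero_basal_has_no_phospho_or_oxidized_pools(self, model):
        params = {**model.parameters, **TURNOVER_OFF, "k_basal": 0.0}
        ss = model.steady_state(0.0, parameters=params)
        idx = model.system._index
        for sp in ("pS_c", "pS_n", "P1ox", "P2ox", "Ra", "C_RaS"):
            assert ss[idx[sp]] == pytest.approx(0.0, abs=1e-7)

    def test_basal_pstat6_positive_and_monotone_in_baseline_ros(self, model):
        idx = model.system._index
        levels = []
        for a in (1.0, 4.0, 16.0):
            ss = model.steady_state(a)
            levels.append(ss[idx["pS_c"]] + ss[idx["pS_n"]] + ss[idx["C_P1pS"]])
        assert levels[0] > 0
        assert levels[0] < levels[1] < levels[2]

    def test_negative_baseline_rejected(self, model):
        with pytest.raises(ValueError):
            model.steady_state(-1.0)


class TestConditions:
    def test_no_ligand_no_bolus_stays_at_rest(self, model):
        df = model.simulate_condition(STANDARD_CONDITIONS["untreated"])
        for obs in ("pSTAT6", "STAT6", "SOCS3"):
            x = df[obs].to_numpy()
            assert np.abs(x - x[0]).max() < 1e-4 * max(x[0], 1e-6)

    def test_mg132_keeps_total_stat6_at_or_above_control(self, model):
        base = model.simulate_condition(STANDARD_CONDITIONS["IL4"])
        mg = model.simulate_condition(STANDARD_CONDITIONS["IL4+MG132"])
        assert np.all(mg["STAT6"].to_numpy()
                      >= base["STAT6"].to_numpy() - 1e-9)

    def test_chx_zeroes_socs_induction(self, model):
        chx = model.simulate_condition(STANDARD_CONDITIONS["IL4+CHX"])
        socs = chx["SOCS3"].to_numpy()
        assert socs.max() <= socs[0] + 1e-9  # no synthesis: SOCS only decays

    def test_redox_effect_flows_only_through_phosphatase_oxidation(self, model):
        # with oxidation rates zeroed, the H2O2 bolus becomes invisible
        params = {**model.parameters, "k_ox1": 0.0, "k_ox2": 0.0}
        y0 = model.steady_state(model.ros_il4.a, parameters=params)
        base = model.simulate_condition(STANDARD_CONDITIONS["IL4"],
                                        parameters=params, y0=y0)
        bolus = model.simulate_condition(STANDARD_CONDITIONS["IL4+H2O2"],
                                         parameters=params, y0=y0)
        np.testing.assert_allclose(bolus["pSTAT6"], base["pSTAT6"],
                                   rtol=1e-5, atol=1e-8)


class TestObserve:
    TRAJ = pd.DataFrame({"time_min": [0.0, 1.0, 2.0],
                         "pSTAT6": [3.0, 1.0, 0.0]})

    def test_identity_scaling(self):
        s = ObservationScaling(alpha={"pSTAT6": 0.0}, beta={"pSTAT6": 1.0})
        out = observe(self.TRAJ, s)
        np.testing.assert_allclose(out["pSTAT6"], self.TRAJ["pSTAT6"])

    def test_affine_arithmetic(self):
        s = ObservationScaling(alpha={"pSTAT6": 1.0}, beta={"pSTAT6": 2.0})
        out = observe(self.TRAJ, s)
        assert out["pSTAT6"].iloc[0] == pytest.approx(7.0)

    def test_gain_rescaling_invariance(self):
        # observing a*x with beta/a differs from observing x with beta only
        # by the (unchanged) offset term
        a = 3.7
        s1 = ObservationScaling(alpha={"pSTAT6": 0.5}, beta={"pSTAT6": 2.0})
        s2 = ObservationScaling(alpha={"pSTAT6": 0.5}, beta={"pSTAT6": 2.0 / a})
        scaled = self.TRAJ.copy()
        scaled["pSTAT6"] = a * scaled["pSTAT6"]
        np.testing.assert_allclose(observe(scaled, s2)["pSTAT6"],
                                   observe(self.TRAJ, s1)["pSTAT6"])

    def test_missing_species_raises(self):
        s = ObservationScaling(alpha={}, beta={"STAT6": 1.0})
        with pytest.raises(KeyError):
            s.apply("pSTAT6", 1.0)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            ObservationScaling(alpha={"x": 0.0}, beta={"x": 0.0})
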