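"""ODE assembly, volume bookkeeping, integration accuracy, conservation
laws and plateau detection."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import brainenergy as be
from brainenergy.simulator import (
    ModelValidationError,
    TimeCourse,
    assemble_odes,
    detect_steady_state,
    simulate,
)

from conftest import make_two_pool_model, two_pool_solution


def _amount_totals(sys_, y, species_names, compartments):
    total = 0.0
    for sp in species_names:
        for c in compartments:
            key = f"{sp}@{c}"
            if key in sys_.index:
                total += y[sys_.index[key]] * sys_.volumes[c]
    return total


class TestAssembly:
    def test_transport_conserves_amounts_by_construction(self):
        model = make_two_pool_model(vx=0.095, vy=0.19)
        sys_ = assemble_odes(model)
        y = np.zeros(sys_.n)
        y[sys_.index["A@x"]] = 1.7
        y[sys_.index["B@y"]] = 0.4
        dy = sys_.rhs(0.0, y)
        # amount change rates sum to zero across the membrane
        total = dy[sys_.index["A@x"]] * 0.095 + dy[sys_.index["B@y"]] * 0.19
        assert total == pytest.approx(0.0, abs=1e-15)

    def test_two_pool_derivatives_match_hand_written_odes(self):
        k1, k2, vx, vy = 0.3, 0.1, 0.2, 0.5
        model = make_two_pool_model(k1=k1, k2=k2, vx=vx, vy=vy)
        sys_ = assemble_odes(model)
        y = np.zeros(sys_.n)
        a, b = 1.3, 0.7
        y[sys_.index["A@x"]] = a
        y[sys_.index["B@y"]] = b
        dy = sys_.rhs(0.0, y)
        assert dy[sys_.index["A@x"]] == pytest.approx(-k1 * a + k2 * b * vy / vx)
        assert dy[sys_.index["B@y"]] == pytest.approx(k1 * a * vx / vy - k2 * b)

    def test_unvalidated_model_is_refused(self, classical_model):
        broken = dataclasses.replace(classical_model)
        broken.species = dict(classical_model.species)
        del broken.species[("Lac", "e")]
        with pytest.raises(ModelValidationError):
            assemble_odes(broken)

    def test_all_zero_state_only_boundary_diffusion_active(self, classical_model):
        sys_ = assemble_odes(classical_model)
        y = np.zeros(sys_.n)
        rates = sys_.reaction_rates(y)
        assert np.all(rates == 0.0)  # PD against zero boundaries is zero too

    def test_zero_initial_conditions_give_zero_trajectory(self):
        model = make_two_pool_model(a0=0.0, b0=0.0)
        tc = simulate(model, t_end=50.0, output_step=5.0)
        assert np.all(tc.data.to_numpy() == 0.0)


class TestIntegration:
    def test_linear_two_pool_matches_matrix_exponential(self):
        k1, k2, a0, vx, vy = 0.3, 0.1, 2.0, 0.2, 0.5
        model = make_two_pool_model(k1=k1, k2=k2, a0=a0, vx=vx, vy=vy)
        tc = simulate(model, t_end=60.0, output_step=1.0)
        expected = two_pool_solution(tc.times, k1=k1, k2=k2, a0=a0, vx=vx, vy=vy)
        got = tc.data[["A@x", "B@y"]].to_numpy()
        scale = np.abs(expected).max()
        assert np.max(np.abs(got - expected)) / scale < 1e-6

    def test_simulation_is_bitwise_reproducible(self, params):
        tc1 = be.run_experiment("classical", "normoxia", params=params, t_end=30.0)
        tc2 = be.run_experiment("classical", "normoxia", params=params, t_end=30.0)
        assert np.array_equal(tc1.data.to_numpy(), tc2.data.to_numpy())

    def test_clamped_species_stay_fixed(self, runs):
        tc = runs[("classical", "hypoxia")]
        assert np.all(tc.series("O2@b").to_numpy() == 0.35)
        tc_s = runs[("anlsh", "starvation")]
        assert np.all(tc_s.series("Glc@b").to_numpy() == 1.0)

    def test_glucose_essentially_depleted_within_50_min(self, runs):
        tc = runs[("classical", "normoxia")]
        assert tc.series("Glc@b").loc[50.0] < 0.05 * 4.56
        for cell in ("Nc", "Ac"):
            assert tc.series(f"Glc@{cell}").loc[50.0] < 0.05 * tc.series(f"Glc@{cell}").iloc[0] + 0.05

    def test_no_negative_concentration_excursions(self, runs):
        for tc in runs.values():
            assert tc.diagnostics == []
            assert tc.data.to_numpy().min() > -1e-9

    def test_halving_tolerances_barely_moves_plateaus(self, params):
        kw = dict(params=params, t_end=120.0)
        tc1 = be.run_experiment("classical", "normoxia", **kw)
        tc2 = be.run_experiment("classical", "normoxia", rtol=5e-9, atol=5e-11, **kw)
        for key in ("ATP@Nm", "Lac@e"):
            a, b = tc1.final(key), tc2.final(key)
            assert abs(a - b) / max(abs(a), 1e-12) < 1e-3


class TestConservation:
    def test_carbon_amount_conserved_in_closed_classical_runs(self, runs, classical_model):
        sys_ = assemble_odes(classical_model)
        for scen in ("normoxia", "hypoxia"):
            tc = runs[("classical", scen)]
            y = tc.data[sys_.keys].to_numpy()
            totals = (y * (sys_.carbon * sys_.volume_of)).sum(axis=1)
            assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6

    def test_moiety_pairs_conserved_per_compartment(self, runs, classical_model):
        sys_ = assemble_odes(classical_model)
        tc = runs[("classical", "normoxia")]
        pairs = [("NAD", "NADH"), ("FAD", "FADH2"), ("Cr", "PCr"), ("ATP", "ADP")]
        for comp in ("Nc", "Ac", "Nm", "Am"):
            for a, b in pairs:
                ka, kb = f"{a}@{comp}", f"{b}@{comp}"
                if ka not in tc.data.columns or kb not in tc.data.columns:
                    continue
                tot = tc.series(ka).to_numpy() + tc.series(kb).to_numpy()
                assert np.max(np.abs(tot - tot[0])) / tot[0] < 1e-6, (comp, a, b)

    def test_mitochondrial_atp_is_non_decreasing(self, runs):
        for (variant, scen), tc in runs.items():
            for key in ("ATP@Nm", "ATP@Am"):
                if key in tc.data.columns:
                    d = np.diff(tc.series(key).to_numpy())
                    assert d.min() > -1e-6, (variant, scen, key)

    def test_blood_glucose_non_increasing_without_clamp(self, runs):
        for (variant, scen), tc in runs.items():
            if scen == "starvation":
                continue
            d = np.diff(tc.series("Glc@b").to_numpy())
            assert d.max() <= 1e-9, (variant, scen)


def _tc_from_series(t, values, key="X@c"):
    return TimeCourse(pd.DataFrame({key: values}, index=t), {"scenario": "synthetic"})


class TestSteadyStateDetection:
    def test_constant_series_plateaus_at_t0(self):
        t = np.linspace(0, 100, 101)
        tc = _tc_from_series(t, np.full_like(t, 3.3))
        rep = detect_steady_state(tc, "X@c", window=20.0)
        assert rep.attained and rep.attainment_time == 0.0
        assert rep.plateau == pytest.approx(3.3)

    def test_exponential_saturation_matches_closed_form_bound(self):
        a, k, rel_tol = 5.0, 0.05, 0.01
        t = np.linspace(0, 400, 801)
        tc = _tc_from_series(t, a * (1 - np.exp(-k * t)))
        rep = detect_steady_state(tc, "X@c", window=30.0, rel_tol=rel_tol)
        assert rep.attained
        assert rep.plateau == pytest.approx(a, rel=rel_tol)
        # analytic bound: |c - A| <= rel_tol*A from t = ln(1/rel_tol)/k
        t_bound = np.log(1.0 / rel_tol) / k
        assert rep.attainment_time <= t_bound * 1.1

    def test_linear_ramp_is_not_attained(self):
        t = np.linspace(0, 100, 101)
        rep = detect_steady_state(_tc_from_series(t, 0.5 * t), "X@c", window=20.0)
        assert not rep.attained
        assert rep.attainment_time is None
        assert rep.plateau == pytest.approx(50.0)  # final value carried

    def test_window_must_fit_span(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            detect_steady_state(_tc_from_series(t, t), "X@c", window=20.0)

    def test_unknown_key_raises(self, runs):
        with pytest.raises(KeyError):
            detect_steady_state(runs[("classical", "normoxia")], "Bogus@zz")


class TestTimeCourseIO:
    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_csv_round_trip(self, layout, params, tmp_path):
        import io

        tc = be.run_experiment("classical", "normoxia", params=params,
                               t_end=10.0, output_step=2.0)
        buf = io.StringIO()
        tc.to_csv(buf, layout=layout)
        buf.seek(0)
        back = TimeCourse.from_csv(buf)
        assert back.metadata["scenario"] == "normoxia"
        assert np.allclose(
            tc.data.to_numpy(), back.data[tc.data.columns].to_numpy(),
            rtol=0, atol=1e-12,
        )

    def test_time_grid_must_increase(self):
        with pytest.raises(ValueError):
            TimeCourse(pd.DataFrame({"X@c": [1, 2]}, index=[1.0, 1.0]), {})
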