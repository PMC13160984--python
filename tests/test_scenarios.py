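import json

import numpy as np
import pytest

import _oracles
from osteonet import (
    CellState,
    Epoch,
    LoadingProtocol,
    ModelParams,
    apply_boundary_motion_events,
    boundary_fluxes,
    builtin_scenario,
    count_topology_events,
    differential_cells_step,
    flux_discrepancy_experiment,
    init_state_from_continuum,
    run_simulation,
    step_occupancies,
    strain_energy_density,
    stress,
    time_to_steady,
    trajectory_vs_wolff_curve,
    update_boundaries,
    validate_params,
)
from osteonet.cell_dynamics import TotalResorption
from osteonet.mechanics import production_rate
from osteonet.scenarios import TIMESERIES_COLUMNS


@pytest.fixture()
def p():
    return validate_params(ModelParams())


def reference_run(protocol, L0, n_steps, params):
    """Pure-NumPy re-implementation of the simulation loop, one module call
    per stage, used as the semantic oracle for the compiled kernel."""
    state = init_state_from_continuum(L0, protocol.force(0.0, 0.0), params)
    cells = CellState()
    events = []
    for _ in range(n_steps):
        F = protocol.force(0.0, state.t)  # uniform protocols only
        sigma = stress(F, state.b_minus, state.b_plus, params.W)
        stim = strain_energy_density(sigma, params.E)
        production = production_rate(stim, state.occupancy, params)
        state = step_occupancies(state, production, params)
        Jm, Jp = boundary_fluxes(state, params)
        cells = differential_cells_step(cells, Jm, Jp, params)
        try:
            b_minus, b_plus = update_boundaries(
                state.b_minus, state.b_plus, cells, params
            )
        except TotalResorption:
            return state, cells, events, "fully_resorbed"
        state, new_events = apply_boundary_motion_events(state, b_minus, b_plus, params)
        events.extend(new_events)
        if state.i_plus < state.i_minus:
            return state, cells, events, "fully_resorbed"
    return state, cells, events, "completed"


class TestRunSimulation:
    def test_zero_duration_returns_initial_record(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.04), 200.0, 0.0, p)
        assert len(ts.t) == 1
        assert ts.t[0] == 0.0
        assert ts.L[0] == 200.0
        assert np.isnan(ts.J_plus[0])

    def test_deterministic_repeat_is_bitwise_identical(self, p):
        proto = LoadingProtocol((Epoch(0.0, 0.04), Epoch(0.2, 0.048)))
        a = run_simulation(proto, 200.0, 0.5, p)
        b = run_simulation(proto, 200.0, 0.5, p)
        assert np.array_equal(a.to_frame().to_numpy(), b.to_frame().to_numpy(), equal_nan=True)

    def test_symmetric_protocol_gives_mirror_series(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.048), 200.0, 2.0, p)
        np.testing.assert_allclose(ts.b_minus[1:], -ts.b_plus[1:], rtol=1e-12)
        np.testing.assert_allclose(ts.J_minus[1:], ts.J_plus[1:], rtol=1e-12)
        np.testing.assert_array_equal(ts.i_minus, -ts.i_plus)
        occ = ts.final_state.occupancy
        np.testing.assert_allclose(occ, occ[::-1], rtol=1e-12)

    def test_kernel_matches_reference_implementation(self, p):
        """The compiled inner loop and the per-step module functions agree.

        Started at a width away from the lattice-registration thresholds so
        the comparison is not at a topology knife edge."""
        n_steps = 3000
        ts = run_simulation(
            LoadingProtocol.constant(0.048), 195.0, n_steps * p.dt, p,
            sample_every=n_steps * p.dt,
        )
        state, cells, events, status = reference_run(
            LoadingProtocol.constant(0.048), 195.0, n_steps, p
        )
        assert status == "completed" == ts.terminal_status
        assert ts.b_plus[-1] == pytest.approx(state.b_plus, rel=1e-12, abs=1e-9)
        assert ts.ob_plus[-1] == pytest.approx(cells.ob_plus, rel=1e-9, abs=1e-15)
        np.testing.assert_allclose(
            ts.final_state.occupancy, state.occupancy, rtol=1e-9
        )
        Jm, Jp = boundary_fluxes(state, p)
        assert ts.J_plus[-1] == pytest.approx(Jp, rel=1e-9)

    def test_kernel_matches_reference_through_topology_events(self, p):
        """Equivalence is preserved across osteocyte creation, at exaggerated
        cell kinetics so events occur within a short run."""
        fast = p.replace(alpha_ob=4000.0, alpha_oc=2000.0, J0=None)
        fast = validate_params(fast)
        n_steps = 4000
        ts = run_simulation(
            LoadingProtocol.constant(0.048), 195.0, n_steps * fast.dt, fast,
            sample_every=n_steps * fast.dt,
        )
        state, cells, events, _ = reference_run(
            LoadingProtocol.constant(0.048), 195.0, n_steps, fast
        )
        assert len(events) > 0, "test premise: events must occur"
        assert len(ts.events) == len(events)
        for a, b in zip(ts.events, events):
            assert (a.kind, a.side, a.index) == (b.kind, b.side, b.index)
            assert a.t == pytest.approx(b.t, abs=1e-9)
        assert ts.b_plus[-1] == pytest.approx(state.b_plus, rel=1e-9)
        np.testing.assert_allclose(ts.final_state.occupancy, state.occupancy, rtol=1e-8)

    def test_registration_invariant_along_run(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.048), 200.0, 1.0, p)
        assert np.all(ts.i_plus * p.dx < ts.b_plus)
        assert np.all(ts.b_plus <= (ts.i_plus + 1) * p.dx)
        assert np.all((ts.i_minus - 1) * p.dx <= ts.b_minus)
        assert np.all(ts.b_minus < ts.i_minus * p.dx)


class TestFluxDiscrepancy:
    def test_matches_exact_fixed_point_oracle(self, p):
        """The iterated fixed-boundary steady flux equals the direct linear
        solve of the lattice fixed point."""
        from osteonet import steady_flux_uniform

        _, J_exact = _oracles.discrete_fixed_point_flux(p, 19)
        J_cont = steady_flux_uniform(200.0, 0.04, p)
        expected = 100.0 * abs(J_exact - J_cont) / J_cont
        assert flux_discrepancy_experiment(p) == pytest.approx(expected, abs=1e-6)

    def test_decreases_under_lattice_refinement(self):
        values = [
            flux_discrepancy_experiment(
                validate_params(ModelParams(dx=dx, dt=1e-5 * (dx / 10.0) ** 2))
            )
            for dx in (10.0, 5.0, 2.5)
        ]
        assert values[0] > values[1] > values[2]

    def test_exact_fixed_point_is_stationary(self, p):
        N, _ = _oracles.discrete_fixed_point_flux(p, 19)
        state = init_state_from_continuum(200.0, 0.04, p)
        state.occupancy = N.copy()
        out = step_occupancies(state, p.lambda1 - p.lambda2 * N, p)
        np.testing.assert_allclose(out.occupancy, N, rtol=1e-12)


class TestScenarioPlumbing:
    def test_unknown_scenario_rejected(self, p):
        with pytest.raises(ValueError, match="unknown scenario"):
            builtin_scenario("refit", p)

    def test_event_counting_empty_window(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.04), 200.0, 0.0, p)
        assert count_topology_events(ts, (0.0, 0.0)) == 0

    def test_csv_contract(self, p, tmp_path):
        ts = run_simulation(LoadingProtocol.constant(0.04), 200.0, 0.05, p)
        ts.write(tmp_path)
        header = (tmp_path / "timeseries.csv").read_text().splitlines()[0]
        assert header == ",".join(TIMESERIES_COLUMNS)
        events_header = (tmp_path / "events.csv").read_text().splitlines()[0]
        assert events_header == "t_day,side,kind,index,freed_molecules"
        meta = json.loads((tmp_path / "meta.json").read_text())
        assert meta["terminal_status"] == "completed"
        assert meta["params"]["dx"] == 10.0

    def test_wolff_trajectory_horizontal_under_constant_force(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.04), 200.0, 0.2, p)
        traj, curve = trajectory_vs_wolff_curve(ts, p)
        assert np.all(traj["F_N"] == 0.04)
        assert curve["F_N"].is_monotonic_increasing

    def test_wolff_trajectory_rejects_gradient(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.04, F_x=5e-5), 200.0, 0.01, p)
        with pytest.raises(ValueError):
            trajectory_vs_wolff_curve(ts, p)

    def test_steady_detector_on_converged_run(self, p):
        ts = run_simulation(LoadingProtocol.constant(0.04), 200.0, 40.0, p, sample_every=0.1)
        t_star = time_to_steady(ts, tol=1e-5, sustain=1.0)
        assert t_star is not None and t_star < 39.0


class TestDisuseEndgame:
    """Behaviour of the discrete model when loading falls below the
    continuum full-resorption threshold (0.0304 N)."""

    def test_deep_disuse_fully_resorbs(self, p):
        proto = LoadingProtocol((Epoch(0.0, 0.04), Epoch(20.0, 0.015)))
        ts = run_simulation(proto, 200.0, 40.0, p)
        assert ts.terminal_status == "fully_resorbed"
        assert ts.t[-1] < 40.0

    def test_moderate_disuse_retains_single_osteocyte_sliver(self, disuse_stress):
        """At 0.02 N the run resorbs almost all bone but is stabilised by the
        last osteocyte: with one producer, stress ~ 1/L makes its output
        diverge and the outgoing flux recrosses the reference value J0 at a
        finite sub-spacing width (a purely discrete effect; the continuum
        model resorbs fully for any force below the threshold)."""
        ts = disuse_stress
        p = ts.params
        assert ts.L.min() < 0.5  # near-total resorption before the rescue
        assert ts.final_state.n_sites == 1
        # analytic single-osteocyte homeostatic width: J(L*) = J0
        s_star = p.reference_flux * (1.0 - p.q_stay + p.lambda2 * p.dt) / (
            p.q_right * p.lambda1
        )
        L_star = (0.02 / p.F_ref) * p.L_ref / s_star
        assert ts.L[-1] == pytest.approx(L_star, rel=1e-3)


class TestCLI:
    def test_calibrate_and_flux_discrepancy_commands(self):
        from click.testing import CliRunner

        from osteonet.cli import main

        runner = CliRunner()
        result = runner.invoke(main, ["calibrate"])
        assert result.exit_code == 0
        assert "J0_per_day" in result.output
        result = runner.invoke(main, ["flux-discrepancy"])
        assert result.exit_code == 0
        assert "%" in result.output

    def test_simulate_writes_outputs(self, tmp_path):
        from click.testing import CliRunner

        from osteonet.cli import main

        runner = CliRunner()
        out = tmp_path / "run"
        result = runner.invoke(
            main,
            ["simulate", "--f-base", "0.04", "--t-end", "0.05", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert (out / "timeseries.csv").exists()
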