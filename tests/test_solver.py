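"""Solver contracts: incompressibility, boundedness, error handling."""

import numpy as np
import pytest

from fontanflow import (CarreauParams, ConfigurationError, ConvergenceError,
                        FlowWaveform, OutletModel, Simulation, TimeStepError,
                        straight_tube, voxelize)
from conftest import (CROSS_Q, CROSS_R, TUBE_D, TUBE_L, TUBE_MU, TUBE_Q,
                      make_symmetric_cross, solve_tube)


class TestSteadySolve:
    def test_discrete_incompressibility(self, cross_symmetric):
        sim, field, mon, _ = cross_symmetric
        div = sim.divergence(field.u, field.v, field.w)
        scale = sim.u_ref / sim.dx
        assert np.max(np.abs(div)) < 1e-10 * scale

    def test_noslip_on_wall_faces(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        for ax, comp in enumerate((field.u, field.v, field.w)):
            inactive = ~sim.active[ax]
            # inlet and outlet port faces are legitimately nonzero
            port_free = inactive.copy()
            for name, (a, sg, idx, area) in sim.inlet_faces.items():
                if a == ax:
                    port_free[idx] = False
            for name, (a, sg, idx) in sim.outlet_faces.items():
                if a == ax:
                    port_free[idx] = False
            assert np.max(np.abs(comp[port_free])) == 0.0

    def test_global_mass_balance(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        assert sim.mass_imbalance(field) < 1e-3

    def test_residual_histories_and_flatness(self, cross_symmetric):
        sim, field, mon, _ = cross_symmetric
        assert mon.converged
        assert len(mon.residual_continuity) > 0
        assert mon.residual_continuity[-1] < mon.tolerance
        assert mon.residual_momentum[-1] < mon.tolerance
        assert mon.monitored_flat(window=5, rel_tol=1e-3)

    def test_solver_is_deterministic(self):
        runs = []
        for _ in range(2):
            _, _, field, _ = solve_tube(5)
            runs.append(field)
        assert np.array_equal(runs[0].u, runs[1].u)
        assert np.array_equal(runs[0].p, runs[1].p)

    def test_nonconvergence_carries_history(self):
        grid = voxelize(straight_tube(TUBE_D, TUBE_L), TUBE_D / 5)
        sim = Simulation(grid, {"IN": TUBE_Q}, {"OUT": OutletModel(1e5)},
                         CarreauParams.newtonian(TUBE_MU))
        with pytest.raises(ConvergenceError) as exc:
            sim.solve_steady(tol=1e-12, max_steps=30)
        assert exc.value.history is not None

    def test_reynolds_reported_and_laminar_warning(self):
        grid = voxelize(straight_tube(TUBE_D, TUBE_L), TUBE_D / 8)
        sim = Simulation(grid, {"IN": TUBE_Q}, {"OUT": OutletModel(1e5)},
                         CarreauParams.newtonian(TUBE_MU))
        # nominal Re = 50; the discrete port area shifts U = Q/A a little
        assert sim.reynolds["IN"] == pytest.approx(50, rel=0.2)
        q_turb = TUBE_Q * 100  # Re ~ 5000
        with pytest.warns(UserWarning, match="Reynolds"):
            Simulation(grid, {"IN": q_turb}, {"OUT": OutletModel(1e5)},
                       CarreauParams.newtonian(TUBE_MU))

    def test_unknown_port_rejected(self, cross_grid):
        with pytest.raises(ConfigurationError, match="AZY"):
            Simulation(cross_grid, {"AZY": CROSS_Q},
                       {"LPA": OutletModel(CROSS_R),
                        "RPA": OutletModel(CROSS_R)}, CarreauParams())

    def test_missing_outlet_model_rejected(self, cross_grid):
        with pytest.raises(ConfigurationError, match="RPA"):
            Simulation(cross_grid, {"IVC": CROSS_Q, "SVC": CROSS_Q},
                       {"LPA": OutletModel(CROSS_R)}, CarreauParams())


class TestHepaticScalar:
    def test_single_tube_delivers_all_scalar(self):
        grid, sim, field, _ = solve_tube(5)
        conc, fluxes = sim.advect_hepatic_scalar(field, "IN")
        assert fluxes["OUT"] == pytest.approx(TUBE_Q, rel=0.01)
        assert conc.min() >= 0.0
        assert conc.max() <= 1.0 + 1e-6

    def test_symmetric_cross_splits_scalar_evenly(self, cross_symmetric):
        sim, field, _, fluxes = cross_symmetric
        assert 100 * fluxes["LPA"] / CROSS_Q == pytest.approx(50.0, abs=2.0)
        assert (fluxes["LPA"] + fluxes["RPA"]) / CROSS_Q == pytest.approx(
            1.0, abs=0.01)

    def test_closing_one_outlet_routes_everything(self, cross_grid):
        sim = Simulation(cross_grid, {"IVC": CROSS_Q, "SVC": CROSS_Q},
                         {"LPA": OutletModel(CROSS_R),
                          "RPA": OutletModel(CROSS_R * 2000)},
                         CarreauParams())
        field, _ = sim.solve_steady(tol=1e-5)
        _, fluxes = sim.advect_hepatic_scalar(field, "IVC")
        assert 100 * fluxes["LPA"] / CROSS_Q == pytest.approx(100.0, abs=1.0)

    def test_source_must_be_inlet(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        with pytest.raises(ConfigurationError):
            sim.advect_hepatic_scalar(field, "LPA")


class TestPulsatile:
    def test_mismatched_periods_rejected(self, cross_grid):
        wa = FlowWaveform.constant(CROSS_Q, 0.6)
        wb = FlowWaveform.constant(CROSS_Q, 0.8)
        sim = Simulation(cross_grid, {"IVC": wa, "SVC": wb},
                         {"LPA": OutletModel(CROSS_R),
                          "RPA": OutletModel(CROSS_R)}, CarreauParams())
        with pytest.raises(ConfigurationError, match="period"):
            sim.solve_pulsatile(cycles=1, steps_per_cycle=100)

    def test_cfl_violation_suggests_time_step(self, cross_grid):
        wf = FlowWaveform.constant(CROSS_Q, 0.6)
        sim = Simulation(cross_grid, {"IVC": wf, "SVC": wf},
                         {"LPA": OutletModel(CROSS_R),
                          "RPA": OutletModel(CROSS_R)}, CarreauParams())
        with pytest.raises(TimeStepError) as exc:
            sim.solve_pulsatile(cycles=1, steps_per_cycle=5)
        assert exc.value.suggested_dt is not None
        assert exc.value.suggested_dt < 0.6 / 5

    def test_low_womersley_tube_is_quasi_steady(self):
        # alpha^2 = omega R^2 / nu ~ 1.3: the oscillatory profile should
        # track the instantaneous Poiseuille solution
        mu, rho, T = 0.033, 1060.0, 4.0
        nu = mu / rho
        u0 = 20 * nu / TUBE_D
        q0 = u0 * np.pi * TUBE_D ** 2 / 4
        harm = np.zeros(15, complex)
        harm[0] = 0.25 * q0 * np.exp(-1j * np.pi / 2)  # 0.5 relative amp
        wf = FlowWaveform.from_harmonics(q0, harm, T)
        grid = voxelize(straight_tube(TUBE_D, TUBE_L), TUBE_D / 8)
        sim = Simulation(grid, {"IN": wf}, {"OUT": OutletModel(1e5)},
                         CarreauParams.newtonian(mu, rho))
        spc = int(np.ceil(T / sim.stable_dt(1.5 * sim.u_peak, 0.7)))
        snaps, mon = sim.solve_pulsatile(cycles=2, steps_per_cycle=spc)
        kmid = grid.shape[2] // 2
        m = grid.fluid_mask[:, :, kmid]
        area = grid.port("OUT").area
        wmax = np.array([0.5 * (f.w[:, :, kmid] + f.w[:, :, kmid + 1])[m].max()
                         for _, f in snaps])
        quasi = np.array([2 * wf.q(t) / area for t, _ in snaps])
        amp_ratio = (wmax.max() - wmax.min()) / (quasi.max() - quasi.min())
        mean_ratio = wmax.mean() / quasi.mean()
        # normalizing by the mean removes the (already-benchmarked)
        # steady discretization bias
        assert amp_ratio / mean_ratio == pytest.approx(1.0, abs=0.05)
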