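"""Shared solve fixtures; the expensive CFD runs are session-cached."""

import numpy as np
import pytest

from fontanflow import (CarreauParams, LimbSpec, OutletModel, Simulation,
                        build_junction, straight_tube, voxelize)

# benchmark tube constants: Re ~ 50, Newtonian blood analogue
TUBE_D = 0.010
TUBE_L = 8 * TUBE_D
TUBE_MU = 0.0035
RHO = 1060.0
TUBE_U = 50 * TUBE_MU / (RHO * TUBE_D)
TUBE_Q = TUBE_U * np.pi * TUBE_D ** 2 / 4

CROSS_D = 0.012
CROSS_Q = 0.8 / 60000.0          # 0.8 L/min per caval inlet
CROSS_R = 2.4e7                  # Pa s / m^3 per lung


def make_symmetric_cross(offset: float = 0.0):
    """Zero-offset TCPC cross with four equal-diameter limbs."""
    D, L = CROSS_D, 3.0 * CROSS_D
    limbs = (
        LimbSpec("IVC", D, L, (0.0, -1.0, 0.0), (offset, 0.0, 0.0), "inlet"),
        LimbSpec("SVC", D, L, (0.0, 1.0, 0.0), (0.0, 0.0, 0.0), "inlet"),
        LimbSpec("LPA", D, L, (1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
        LimbSpec("RPA", D, L, (-1.0, 0.0, 0.0), (0.0, 0.0, 0.0), "outlet"),
    )
    return build_junction(limbs=limbs)


def solve_tube(frac: int, resistance: float = 1e5, q: float = TUBE_Q,
               mu: float = TUBE_MU, tol: float = 1e-5):
    """Steady Newtonian tube solve at spacing D/frac."""
    grid = voxelize(straight_tube(TUBE_D, TUBE_L), TUBE_D / frac)
    sim = Simulation(grid, {"IN": q}, {"OUT": OutletModel(resistance)},
                     CarreauParams.newtonian(mu, RHO))
    field, mon = sim.solve_steady(tol=tol)
    return grid, sim, field, mon


@pytest.fixture(scope="session")
def tube_solves():
    """Poiseuille benchmark solves: the refinement ladder D/5, D/8, D/12
    plus the reference resolution D/10."""
    return {frac: solve_tube(frac) for frac in (5, 8, 10, 12)}


def tube_benchmark_errors(grid, sim, field):
    """Poiseuille benchmark errors of one tube solve.

    The analytic oracle uses the effective (resolved-area) diameter
    D_eff = 2 sqrt(A_voxel/pi) of the voxelized cross-section so the
    comparison isolates scheme error from geometric quantization.
    Returns (profile_rms_rel, dp_rel_err, tau_rel_err).
    """
    from fontanflow.metrics import wall_faces, wss_field
    dx = grid.dx
    kmid = grid.shape[2] // 2
    m = grid.fluid_mask[:, :, kmid]
    a_d = m.sum() * dx ** 2
    d_eff = 2 * np.sqrt(a_d / np.pi)
    q = -sim.port_flux(field, "IN")
    u_eff = q / a_d

    wc = 0.5 * (field.w[:, :, kmid] + field.w[:, :, kmid + 1])
    xs, ys, _ = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2)
    ana = 2 * u_eff * np.maximum(1 - (2 * r / d_eff) ** 2, 0)
    sel = m & (r < 0.45 * d_eff)
    prof_rms = float(np.sqrt(np.mean((wc[sel] - ana[sel]) ** 2)) / (2 * u_eff))

    n = grid.shape[2]
    k1, k2 = int(0.3 * n), int(0.7 * n)
    pbar = np.array([field.p[:, :, k][grid.fluid_mask[:, :, k]].mean()
                     for k in range(k1, k2)])
    slope = np.polyfit(np.arange(k1, k2) * dx, pbar, 1)[0]
    dp_err = float(slope / (-32 * TUBE_MU * u_eff / d_eff ** 2) - 1)

    walls = wall_faces(grid)
    tau = wss_field(field, grid, walls)
    zc = walls.cells[:, 2]
    msk = (zc > 0.25 * n) & (zc < 0.75 * n) & (walls.axis != 2)
    tau_err = float(tau[msk].mean() / (8 * TUBE_MU * u_eff / d_eff) - 1)
    return prof_rms, dp_err, tau_err


@pytest.fixture(scope="session")
def cross_grid():
    return voxelize(make_symmetric_cross(), CROSS_D / 6)


@pytest.fixture(scope="session")
def cross_symmetric(cross_grid):
    """Mirror-symmetric cross: equal inflows, equal outlet resistances."""
    sim = Simulation(cross_grid, {"IVC": CROSS_Q, "SVC": CROSS_Q},
                     {"LPA": OutletModel(CROSS_R), "RPA": OutletModel(CROSS_R)},
                     CarreauParams())
    field, mon = sim.solve_steady(tol=1e-5)
    conc, fluxes = sim.advect_hepatic_scalar(field, "IVC")
    return sim, field, mon, fluxes


@pytest.fixture(scope="session")
def glenn_report(tmp_path_factory):
    """Coarse steady Glenn demo executed through the full pipeline."""
    from fontanflow import make_case, run_case
    out = tmp_path_factory.mktemp("glenn_run")
    cfg = make_case("glenn", dx_fraction=0.125)
    report, artifacts = run_case(cfg, output_dir=str(out))
    return cfg, report, artifacts
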