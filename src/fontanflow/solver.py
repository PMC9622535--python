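"""Incompressible laminar flow on the voxel grid, plus hepatic tracking.

The solver is an explicit fractional-step (projection) method on a
staggered MAC grid: velocities live on cell faces, pressure at cell
centers, gauge-fixed by the zero-pressure atrial reservoir at the
outlets.  Convection is first-order upwind, diffusion central with the
generalized-Newtonian viscosity interpolated to faces/edges; the
pressure Poisson problem is assembled once per grid (and time step) and
prefactorized with a sparse LU.  Steady solutions are obtained by
pseudo-transient continuation until scaled residuals fall below the
tolerance and the monitored quantities are flat.

Outlet "porous baffles" are one marked face-layer per outlet limb, one
limb diameter upstream of the open port, carrying an implicit Darcy
drag whose integral across the layer reproduces the lumped law
dp = R_eff * F against the zero-pressure port.

Hepatic blood from the IVC is tracked as a passive scalar (pure
advection with the same upwind scheme; concentration 1 on the source
inlet, 0 on the others), from which per-outlet hepatic fluxes follow.

Everything is deterministic: initialization is quiescent and there is
no random number generation anywhere in the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .boundary_conditions import FlowWaveform, OutletModel
from .errors import (ConfigurationError, ConvergenceError, GeometryError,
                     TimeStepError)
from .geometry import Port, VoxelGrid
from .rheology import CarreauParams, carreau_viscosity, effective_viscosity_field

InletSpec = Union[float, FlowWaveform]

#: Laminar-regime advisory threshold on the inlet Reynolds number.
RE_LAMINAR_WARN = 2000.0


@dataclass
class FlowField:
    """MAC-grid flow state: face velocities, cell pressure/viscosity/scalar."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    eta: np.ndarray
    c: np.ndarray
    time: float = 0.0

    def copy(self) -> "FlowField":
        return FlowField(self.u.copy(), self.v.copy(), self.w.copy(),
                         self.p.copy(), self.eta.copy(), self.c.copy(),
                         self.time)

    def speed_cells(self) -> np.ndarray:
        """Velocity magnitude interpolated to cell centers."""
        uc = 0.5 * (self.u[1:, :, :] + self.u[:-1, :, :])
        vc = 0.5 * (self.v[:, 1:, :] + self.v[:, :-1, :])
        wc = 0.5 * (self.w[:, :, 1:] + self.w[:, :, :-1])
        return np.sqrt(uc**2 + vc**2 + wc**2)


@dataclass
class ConvergenceMonitor:
    """Residual and monitored-quantity histories of one solve."""

    tolerance: float
    steps: List[int] = dc_field(default_factory=list)
    residual_continuity: List[float] = dc_field(default_factory=list)
    residual_momentum: List[float] = dc_field(default_factory=list)
    monitors: Dict[str, List[float]] = dc_field(default_factory=dict)
    converged: bool = False
    n_steps: int = 0
    reynolds: Dict[str, float] = dc_field(default_factory=dict)
    cycle_history: Dict[str, List[float]] = dc_field(default_factory=dict)
    cycle_periodicity: Optional[float] = None

    def record(self, step: int, rc: float, rm: float,
               quantities: Dict[str, float]) -> None:
        self.steps.append(step)
        self.residual_continuity.append(rc)
        self.residual_momentum.append(rm)
        for k, val in quantities.items():
            self.monitors.setdefault(k, []).append(val)

    def monitored_flat(self, window: int, rel_tol: float = 1e-3) -> bool:
        """True when every monitor's span over the last ``window`` records
        is below ``rel_tol`` of its mean magnitude."""
        for vals in self.monitors.values():
            if len(vals) < window:
                return False
            tail = np.asarray(vals[-window:])
            scale = max(abs(tail.mean()), 1e-30)
            if (tail.max() - tail.min()) / scale > rel_tol:
                return False
        return True


def _perm(a: int) -> Tuple[int, int, int]:
    return (a, (a + 1) % 3, (a + 2) % 3)


def _t(arr: np.ndarray, a: int) -> np.ndarray:
    return np.transpose(arr, _perm(a))


def _ti(arr: np.ndarray, a: int) -> np.ndarray:
    return np.transpose(arr, np.argsort(_perm(a)))


def _upwind_derivative(q, adv, ax, dx, mirror_mask=None):
    """First-order upwind d(q)/dx_ax selected by the sign of ``adv``.

    ``mirror_mask`` (active-face mask) enables antisymmetric wall ghosts
    for tangential directions: an inactive neighbor value is replaced by
    ``-q`` so the no-slip plane sits halfway between the faces.
    """
    up = np.zeros_like(q)
    dn = np.zeros_like(q)
    sl_core = [slice(None)] * 3

    sl = list(sl_core); sl[ax] = slice(None, -1)
    sh = list(sl_core); sh[ax] = slice(1, None)
    nb_up = np.zeros_like(q)
    nb_up[tuple(sl)] = q[tuple(sh)]
    nb_dn = np.zeros_like(q)
    nb_dn[tuple(sh)] = q[tuple(sl)]
    if mirror_mask is not None:
        act_up = np.zeros_like(q, dtype=bool)
        act_up[tuple(sl)] = mirror_mask[tuple(sh)]
        act_dn = np.zeros_like(q, dtype=bool)
        act_dn[tuple(sh)] = mirror_mask[tuple(sl)]
        nb_up = np.where(act_up, nb_up, -q)
        nb_dn = np.where(act_dn, nb_dn, -q)
    up = (nb_up - q) / dx
    dn = (q - nb_dn) / dx
    return np.where(adv > 0.0, dn, up)


class Simulation:
    """One junction + boundary-condition setup, ready to solve.

    Parameters
    ----------
    grid : VoxelGrid
    inlets : mapping port name -> flow (m^3/s) or FlowWaveform
    outlets : mapping port name -> OutletModel
    fluid : CarreauParams
    baffle_diameters_upstream : float
        Distance of the resistance layer from the open port, in limb
        diameters.
    """

    def __init__(self, grid: VoxelGrid, inlets: Dict[str, InletSpec],
                 outlets: Dict[str, OutletModel], fluid: CarreauParams,
                 baffle_diameters_upstream: float = 1.0,
                 viscosity_update_every: int = 10):
        self.grid = grid
        self.fluid = fluid
        self.dx = grid.dx
        self.visc_every = viscosity_update_every
        self.F = grid.fluid_mask
        nx, ny, nz = self.F.shape
        self.shape = (nx, ny, nz)
        if grid.connected_components() != 1:
            raise GeometryError("fluid region must be a single connected component")

        for name in list(inlets) + list(outlets):
            if name not in grid.ports:
                raise ConfigurationError(
                    f"port {name!r} not in grid ports {sorted(grid.ports)}")
        for name, port in grid.ports.items():
            if port.role == "inlet" and name not in inlets:
                raise ConfigurationError(f"inlet port {name} has no flow assigned")
            if port.role == "outlet" and name not in outlets:
                raise ConfigurationError(f"outlet port {name} has no OutletModel")
        self.inlets = {k: (v if isinstance(v, FlowWaveform)
                           else FlowWaveform.constant(float(v)))
                       for k, v in inlets.items()}
        self.outlets = dict(outlets)

        total_in = sum(wf.q_avg for wf in self.inlets.values())
        if total_in <= 0:
            raise ConfigurationError("total mean inlet flow must be positive")
        self.u_ref = max(wf.q_avg / grid.port(k).area
                         for k, wf in self.inlets.items())
        self.u_peak = max(abs(wf.q_max) / grid.port(k).area
                          for k, wf in self.inlets.items())

        # face activity: both adjacent cells fluid
        F = self.F
        self.active = [
            np.zeros((nx + 1, ny, nz), bool),
            np.zeros((nx, ny + 1, nz), bool),
            np.zeros((nx, ny, nz + 1), bool),
        ]
        self.active[0][1:-1, :, :] = F[1:, :, :] & F[:-1, :, :]
        self.active[1][:, 1:-1, :] = F[:, 1:, :] & F[:, :-1, :]
        self.active[2][:, :, 1:-1] = F[:, :, 1:] & F[:, :, :-1]

        self._setup_ports(baffle_diameters_upstream)
        self._reynolds = self._compute_reynolds()
        for name, re in self._reynolds.items():
            if re > RE_LAMINAR_WARN:
                warnings.warn(
                    f"inlet {name}: Reynolds number {re:.0f} exceeds the "
                    f"laminar-regime assumption (~{RE_LAMINAR_WARN:.0f})",
                    stacklevel=2)

        # cell numbering for the Poisson system
        self.cell_id = -np.ones(self.shape, dtype=np.int64)
        self.cell_id[F] = np.arange(F.sum())
        self.n_cells = int(F.sum())
        self._dt = None
        self._lu = None

    # -- port/baffle bookkeeping -------------------------------------------

    def _face_tuple(self, port: Port, shift: int = 0):
        """(i,j,k) index arrays of a port's face layer shifted inward."""
        idx = port.face_index.copy()
        idx[:, port.axis] -= port.sign * shift
        return tuple(idx.T)

    def _setup_ports(self, baffle_diameters: float) -> None:
        self.inlet_faces = {}
        self.outlet_faces = {}
        self.outlet_interior = {}
        self.baffle_faces = {}
        self.baffle_beta = {}
        for name, wf in self.inlets.items():
            port = self.grid.port(name)
            self.inlet_faces[name] = (port.axis, port.sign,
                                      self._face_tuple(port), port.area)
        for name, model in self.outlets.items():
            port = self.grid.port(name)
            self.outlet_faces[name] = (port.axis, port.sign, self._face_tuple(port))
            self.outlet_interior[name] = self._face_tuple(port, shift=1)
            nb = max(1, int(round(baffle_diameters * port.diameter / self.dx)))
            bidx = port.face_index.copy()
            bidx[:, port.axis] -= port.sign * nb
            keep = self.active[port.axis][tuple(bidx.T)]
            bidx = bidx[keep]
            if bidx.shape[0] == 0:
                raise GeometryError(
                    f"baffle layer for outlet {name} found no interior faces; "
                    "limb too short for the configured baffle position")
            a_layer = bidx.shape[0] * self.dx ** 2
            beta = model.effective_resistance * a_layer / self.dx
            self.baffle_faces[name] = (port.axis, port.sign, tuple(bidx.T))
            self.baffle_beta[name] = beta

    def _compute_reynolds(self) -> Dict[str, float]:
        res = {}
        for name, wf in self.inlets.items():
            port = self.grid.port(name)
            u = abs(wf.q_avg) / port.area
            d = port.diameter
            gamma = 8.0 * u / d if d > 0 else 0.0
            eta = carreau_viscosity(gamma, self.fluid)
            res[name] = self.fluid.density * u * d / eta
        return res

    @property
    def reynolds(self) -> Dict[str, float]:
        """Inlet Reynolds numbers (density * U * D / eta(8U/D))."""
        return dict(self._reynolds)

    # -- time step and Poisson operator ------------------------------------

    def stable_dt(self, umax: float, cfl: float = 0.5) -> float:
        dt_conv = cfl * self.dx / max(umax, 1e-12)
        # explicit diffusion limit; the factor 12 (vs the nominal 6 of a
        # 7-point Laplacian) covers the doubled tangential gradients of
        # the mirror wall ghosts
        dt_visc = cfl * self.fluid.density * self.dx ** 2 / (12.0 * self.fluid.eta0)
        return min(dt_conv, dt_visc)

    def _theta_arrays(self, dt: float):
        """Per-face projection coefficient: 1, or 1/(1+dt*beta/rho) on baffles."""
        theta = [np.ones_like(a, dtype=float) for a in self.active]
        rho = self.fluid.density
        for name, (ax, sg, idx) in self.baffle_faces.items():
            theta[ax][idx] = 1.0 / (1.0 + dt * self.baffle_beta[name] / rho)
        return theta

    def _build_poisson(self, dt: float) -> None:
        nx, ny, nz = self.shape
        F = self.F
        cid = self.cell_id
        dx2 = self.dx ** 2
        theta = self._theta_arrays(dt)

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_cells)

        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            both = F[tuple(sl_lo)] & F[tuple(sl_hi)]
            il = cid[tuple(sl_lo)][both]
            ih = cid[tuple(sl_hi)][both]
            # interior faces between cell pairs are indices 1..n-1 on the
            # staggered axis
            sel = [slice(None)] * 3
            sel[ax] = slice(1, -1)
            th = theta[ax][tuple(sel)][both]
            coef = th / dx2
            rows.extend([il, ih])
            cols.extend([ih, il])
            vals.extend([coef, coef])
            np.add.at(diag, il, -coef)
            np.add.at(diag, ih, -coef)

        # outlet Dirichlet faces: p = 0 at the face (half-cell spacing)
        for name, (ax, sg, idx) in self.outlet_faces.items():
            cells = np.asarray(idx).T.copy()
            cells[:, ax] -= 1 if sg > 0 else 0
            cidx = cid[tuple(cells.T)]
            np.add.at(diag, cidx, -2.0 / dx2)

        rows.append(np.arange(self.n_cells))
        cols.append(np.arange(self.n_cells))
        vals.append(diag)
        A = csc_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(self.n_cells, self.n_cells))
        self._lu = splu(A)
        self._theta = theta
        self._dt = dt

    # -- state management ---------------------------------------------------

    def new_field(self) -> FlowField:
        nx, ny, nz = self.shape
        return FlowField(
            u=np.zeros((nx + 1, ny, nz)), v=np.zeros((nx, ny + 1, nz)),
            w=np.zeros((nx, ny, nz + 1)), p=np.zeros((nx, ny, nz)),
            eta=np.full((nx, ny, nz), carreau_viscosity(0.0, self.fluid)),
            c=np.zeros((nx, ny, nz)), time=0.0)

    def _apply_inlets(self, comps, t: float) -> None:
        for name, (ax, sg, idx, area) in self.inlet_faces.items():
            wf = self.inlets[name]
            # steady solves drive the time-averaged flow
            q = wf.q_avg if getattr(self, "_steady_mode", False) else wf.q(t)
            comps[ax][idx] = -sg * q / area  # inward

    def _apply_outlet_extrapolation(self, comps) -> None:
        for name, (ax, sg, idx) in self.outlet_faces.items():
            comps[ax][idx] = comps[ax][self.outlet_interior[name]]

    def _apply_baffle(self, comps, dt: float) -> None:
        rho = self.fluid.density
        for name, (ax, sg, idx) in self.baffle_faces.items():
            comps[ax][idx] /= (1.0 + dt * self.baffle_beta[name] / rho)

    def divergence(self, u, v, w) -> np.ndarray:
        d = ((u[1:, :, :] - u[:-1, :, :]) + (v[:, 1:, :] - v[:, :-1, :])
             + (w[:, :, 1:] - w[:, :, :-1])) / self.dx
        return np.where(self.F, d, 0.0)

    # -- spatial operators ---------------------------------------------------

    def _convection(self, comps) -> List[np.ndarray]:
        dx = self.dx
        out = []
        for a in range(3):
            q = _t(comps[a], a)
            r = _t(comps[(a + 1) % 3], a)
            s = _t(comps[(a + 2) % 3], a)
            act = _t(self.active[a], a)

            def _avg_to_q(other):
                # other staggered on (canonical) axis1 or axis2 -> q faces
                op = np.pad(other, ((1, 1), (0, 0), (0, 0)))
                if other.shape[1] == q.shape[1] + 1:   # staggered axis1
                    return 0.25 * (op[:-1, :-1, :] + op[1:, :-1, :]
                                   + op[:-1, 1:, :] + op[1:, 1:, :])
                return 0.25 * (op[:-1, :, :-1] + op[1:, :, :-1]
                               + op[:-1, :, 1:] + op[1:, :, 1:])

            r4 = _avg_to_q(r)
            s4 = _avg_to_q(s)
            d0 = _upwind_derivative(q, q, 0, dx)
            d1 = _upwind_derivative(q, r4, 1, dx, mirror_mask=act)
            d2 = _upwind_derivative(q, s4, 2, dx, mirror_mask=act)
            conv = q * d0 + r4 * d1 + s4 * d2
            out.append(_ti(conv, a))
        return out

    def _diffusion(self, comps, eta) -> List[np.ndarray]:
        dx = self.dx
        out = []
        etam = np.where(self.F, eta, 0.0)
        for a in range(3):
            q = _t(comps[a], a)
            act = _t(self.active[a], a)
            em = _t(etam, a)
            Fc = _t(self.F, a)

            lap = np.zeros_like(q)
            # normal direction: flux eta * dq/dx0 at cell centers
            gx = np.where(Fc, em * (q[1:, :, :] - q[:-1, :, :]) / dx, 0.0)
            gp = np.pad(gx, ((1, 1), (0, 0), (0, 0)))
            lap += (gp[1:, :, :] - gp[:-1, :, :]) / dx

            # tangential directions: flux at edges, mirror ghosts at walls
            ep = np.pad(em, ((1, 1), (0, 0), (0, 0)))
            cp = np.pad(Fc.astype(float), ((1, 1), (0, 0), (0, 0)))
            e_face = ep[:-1] + ep[1:]       # sums over the 2 cells of a q-face
            c_face = cp[:-1] + cp[1:]
            for tax in (1, 2):
                sl_lo = [slice(None)] * 3
                sl_hi = [slice(None)] * 3
                sl_lo[tax] = slice(None, -1)
                sl_hi[tax] = slice(1, None)
                e_edge = e_face[tuple(sl_lo)] + e_face[tuple(sl_hi)]
                c_edge = c_face[tuple(sl_lo)] + c_face[tuple(sl_hi)]
                eta_e = e_edge / np.maximum(c_edge, 1.0)
                q_lo = q[tuple(sl_lo)]
                q_hi = q[tuple(sl_hi)]
                a_lo = act[tuple(sl_lo)]
                a_hi = act[tuple(sl_hi)]
                q_hi_eff = np.where(a_hi, q_hi, -q_lo)
                q_lo_eff = np.where(a_lo, q_lo, -q_hi)
                flux = eta_e * (q_hi_eff - q_lo_eff) / dx
                pad_spec = [(0, 0)] * 3
                pad_spec[tax] = (1, 1)
                fp = np.pad(flux, pad_spec)
                lap += (fp[tuple(sl_hi)] - fp[tuple(sl_lo)]) / dx
            out.append(_ti(lap, a))
        return out

    # -- one projection step -------------------------------------------------

    def step(self, state: FlowField, dt: float, step_index: int = 0,
             advect_scalar: bool = False,
             scalar_source: Optional[str] = None) -> Tuple[float, float]:
        """Advance the state by ``dt``; returns scaled residuals."""
        if self._dt is None or self._lu is None or dt != self._dt:
            self._build_poisson(dt)
        rho = self.fluid.density
        comps = [state.u, state.v, state.w]
        if (not self.fluid.is_newtonian) and (step_index % self.visc_every == 0):
            state.eta = effective_viscosity_field(
                state.u, state.v, state.w, self.dx, self.fluid, self.F)

        conv = self._convection(comps)
        diff = self._diffusion(comps, state.eta)
        t_new = state.time + dt
        star = []
        old = [c.copy() for c in comps]
        for a in range(3):
            qs = comps[a] + dt * (-conv[a] + diff[a] / rho)
            qs *= self.active[a]
            star.append(qs)
        self._apply_inlets(star, t_new)
        self._apply_outlet_extrapolation(star)
        self._apply_baffle(star, dt)

        div = self.divergence(*star)
        rhs = (rho / dt) * div[self.F]
        p_vec = self._lu.solve(rhs)
        p = np.zeros(self.shape)
        p[self.F] = p_vec

        # correct interior faces
        scale = dt / (rho * self.dx)
        for ax in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[ax] = slice(None, -1)
            sl_hi[ax] = slice(1, None)
            dp = p[tuple(sl_hi)] - p[tuple(sl_lo)]
            sel = [slice(None)] * 3
            sel[ax] = slice(1, -1)
            faces = star[ax][tuple(sel)]
            mask = self.active[ax][tuple(sel)]
            th = self._theta[ax][tuple(sel)]
            faces -= np.where(mask, th * scale * dp, 0.0)
        # outlet Dirichlet faces: p_face = 0, half-cell gradient
        for name, (ax, sg, idx) in self.outlet_faces.items():
            cells = np.asarray(idx).T.copy()
            cells[:, ax] -= 1 if sg > 0 else 0
            pc = p[tuple(cells.T)]
            star[ax][idx] += -sg * (dt / rho) * (0.0 - pc) * 2.0 / self.dx

        state.u, state.v, state.w = star
        state.p = p
        state.time = t_new

        if advect_scalar:
            self._scalar_step(state, dt, scalar_source)

        umax = max(float(np.max(np.abs(c))) for c in star)
        if umax * dt / self.dx > 2.0:
            raise TimeStepError(
                f"CFL blow-up: |u|max dt/dx = {umax * dt / self.dx:.2f}",
                suggested_dt=0.5 * self.dx / umax)

        rc = float(np.max(np.abs(self.divergence(*star)))) * self.dx / self.u_ref
        rm = max(float(np.max(np.abs(star[a] - old[a]))) for a in range(3))
        rm = rm / dt * self.dx / self.u_ref ** 2
        return rc, rm

    # -- scalar transport ----------------------------------------------------

    def _scalar_step(self, state: FlowField, dt: float,
                     source: Optional[str]) -> None:
        """Conservative upwind advection of the hepatic marker."""
        c = state.c
        dx = self.dx
        comps = [state.u, state.v, state.w]
        dcdt = np.zeros(self.shape)
        for ax in range(3):
            vel = _t(comps[ax], ax)
            cc = _t(c, ax)
            cp = np.pad(cc, ((1, 1), (0, 0), (0, 0)))
            c_up = np.where(vel > 0.0, cp[:-1, :, :], cp[1:, :, :])
            flux = vel * c_up  # per unit face area
            dcdt -= _ti((flux[1:, :, :] - flux[:-1, :, :]) / dx, ax)
        c_new = c + dt * dcdt
        # inlet faces carry the prescribed concentration.  The generic
        # scheme above upwinded from the exterior (solid) cell, c = 0;
        # replace that flux with vel * c_in wherever flow enters.
        for name, (ax, sg, idx, area) in self.inlet_faces.items():
            cin = 1.0 if name == source else 0.0
            vel = comps[ax][idx]  # -sg * q/area when flowing inward
            cells = np.asarray(idx).T.copy()
            cells[:, ax] -= 1 if sg > 0 else 0
            cidx = tuple(cells.T)
            inflow = np.maximum(-sg * vel, 0.0)  # positive into the domain
            c_new[cidx] += dt * inflow * cin / dx
        c_new = np.where(self.F, c_new, 0.0)
        state.c = np.clip(c_new, 0.0, 1.0 + 1e-9)

    def advect_hepatic_scalar(self, flow, source_port: str = "IVC",
                              flux_tol: float = 1e-5,
                              max_transits: float = 60.0):
        """Steady (or cycle-replayed) passive-scalar transport.

        ``flow`` is a converged :class:`FlowField` (frozen velocities) or
        a sequence of ``(time, FlowField)`` snapshots spanning one cycle
        (replayed periodically).  Returns ``(concentration, fluxes)``
        where ``fluxes`` maps each outlet to the mean hepatic volume flux
        (m^3/s) leaving through it.
        """
        if source_port not in self.inlets:
            raise ConfigurationError(
                f"scalar source {source_port!r} must be an inlet port")
        seq = None
        if isinstance(flow, FlowField):
            state = flow.copy()
        else:
            seq = list(flow)
            state = seq[-1][1].copy()
        state.c = np.zeros(self.shape)

        umax = max(float(np.max(np.abs(a)))
                   for a in (state.u, state.v, state.w))
        if seq is not None:
            umax = max(umax, self.u_peak)
        dt = 0.8 * self.dx / max(umax, 1e-12)
        # transit time scale: domain extent / reference speed
        extent = max(self.shape) * self.dx
        transit = extent / max(self.u_ref, 1e-12)
        max_steps = int(max_transits * transit / dt) + 1

        def outlet_fluxes(st):
            return {name: self.scalar_flux_out(st, name) for name in self.outlets}

        if seq is None:
            # frozen steady field: march to a flux steady state
            prev = None
            hold = 0
            for it in range(max_steps):
                self._scalar_step(state, dt, source_port)
                if it % 25 == 24:
                    cur = outlet_fluxes(state)
                    tot = sum(cur.values())
                    if prev is not None and tot > 0:
                        change = max(abs(cur[k] - prev[k]) for k in cur) / tot
                        if change < flux_tol:
                            hold += 1
                            if hold >= 3:
                                break
                        else:
                            hold = 0
                    prev = cur
            return state.c, outlet_fluxes(state)

        # periodic replay of the snapshot cycle: report cycle-averaged
        # outlet scalar fluxes once they repeat cycle-to-cycle
        snap_times = np.array([t for t, _ in seq])
        period = self.inlets[next(iter(self.inlets))].period
        steps_per_cycle = max(1, int(round(period / dt)))
        dt = period / steps_per_cycle
        max_cycles = max(3, int(np.ceil(max_transits * transit / period)))
        prev_mean = None
        mean_fluxes = {n: 0.0 for n in self.outlets}
        for cyc in range(max_cycles):
            acc = {n: 0.0 for n in self.outlets}
            for k in range(steps_per_cycle):
                tau = (k * dt) % period
                j = int(np.argmin(np.abs(snap_times - snap_times[0] - tau)))
                snap = seq[j][1]
                state.u, state.v, state.w = snap.u, snap.v, snap.w
                self._scalar_step(state, dt, source_port)
                for n in self.outlets:
                    acc[n] += self.scalar_flux_out(state, n)
            mean_fluxes = {n: acc[n] / steps_per_cycle for n in self.outlets}
            tot = sum(mean_fluxes.values())
            if prev_mean is not None and tot > 0:
                change = max(abs(mean_fluxes[n] - prev_mean[n])
                             for n in mean_fluxes) / tot
                if change < max(flux_tol, 1e-4):
                    break
            prev_mean = mean_fluxes
        return state.c, mean_fluxes

    def scalar_flux_out(self, state: FlowField, outlet: str) -> float:
        """Hepatic volume flux (m^3/s) leaving through ``outlet``."""
        ax, sg, idx = self.outlet_faces[outlet]
        comps = [state.u, state.v, state.w]
        vel = comps[ax][idx]
        cells = np.asarray(idx).T.copy()
        cells[:, ax] -= 1 if sg > 0 else 0
        cup = state.c[tuple(cells.T)]
        return float(np.sum(sg * vel * cup) * self.dx ** 2)

    # -- flux / pressure measurement ----------------------------------------

    def port_flux(self, state: FlowField, name: str) -> float:
        """Signed volume flux through a port, positive outward."""
        port = self.grid.port(name)
        comps = [state.u, state.v, state.w]
        vel = comps[port.axis][self._face_tuple(port)]
        return float(port.sign * np.sum(vel) * self.dx ** 2)

    def inflow_total(self, t: float) -> float:
        return sum(wf.q(t) for wf in self.inlets.values())

    def mass_imbalance(self, state: FlowField) -> float:
        """|sum outflow - sum inflow| / sum inflow at the state's time."""
        q_in = sum(-self.port_flux(state, n) for n in self.inlets)
        q_out = sum(self.port_flux(state, n) for n in self.outlets)
        return abs(q_out - q_in) / max(abs(q_in), 1e-30)

    def baffle_pressure_jump(self, state: FlowField, outlet: str) -> float:
        """Area-averaged pressure drop across an outlet's baffle layer."""
        ax, sg, idx = self.baffle_faces[outlet]
        cells = np.asarray(idx).T
        up = cells.copy()
        up[:, ax] -= 1 if sg > 0 else 0       # upstream cell of the face
        dn = cells.copy()
        dn[:, ax] -= 0 if sg > 0 else 1       # downstream cell
        keep = self.F[tuple(up.T)] & self.F[tuple(dn.T)]
        pu = state.p[tuple(up[keep].T)]
        pd = state.p[tuple(dn[keep].T)]
        return float(np.mean(pu) - np.mean(pd))

    def baffle_flux(self, state: FlowField, outlet: str) -> float:
        ax, sg, idx = self.baffle_faces[outlet]
        comps = [state.u, state.v, state.w]
        return float(sg * np.sum(comps[ax][idx]) * self.dx ** 2)

    # -- steady solve --------------------------------------------------------

    def _monitor_quantities(self, state: FlowField) -> Dict[str, float]:
        from . import metrics as _metrics
        out = {}
        fluxes = {n: self.port_flux(state, n) for n in self.outlets}
        tot = sum(fluxes.values())
        for n, q in fluxes.items():
            out[f"flow_out_{n}"] = q
        if "LPA" in fluxes and tot != 0:
            out["pfd_lpa_pct"] = 100.0 * fluxes["LPA"] / tot
        out["e_loss_mw"] = _metrics.power_loss(state, self, self.fluid.density)
        return out

    def solve_steady(self, tol: float = 1e-5, cfl: float = 0.7,
                     max_steps: int = 40000, monitor_every: int = 10,
                     flat_window_iters: int = 100
                     ) -> Tuple[FlowField, ConvergenceMonitor]:
        """Pseudo-transient continuation to a steady solution.

        Converged when continuity and velocity-scaled residuals drop
        below ``tol`` and the monitored quantities (power loss, outlet
        flows) are flat to < 0.1 % over the final ``flat_window_iters``
        iterations.
        """
        state = self.new_field()
        mon = ConvergenceMonitor(tolerance=tol)
        mon.reynolds = self.reynolds
        self._steady_mode = True
        dt = self.stable_dt(1.5 * self.u_peak, cfl)
        window = max(2, flat_window_iters // monitor_every)
        rc = rm = np.inf
        for it in range(max_steps):
            try:
                rc, rm = self.step(state, dt, step_index=it)
            except TimeStepError as exc:
                dt = exc.suggested_dt if exc.suggested_dt else 0.5 * dt
                state = self.new_field()
                continue
            if it % monitor_every == monitor_every - 1:
                mon.record(it + 1, rc, rm, self._monitor_quantities(state))
                if (rc < tol and rm < tol
                        and mon.monitored_flat(window, 1e-3)):
                    mon.converged = True
                    mon.n_steps = it + 1
                    break
        self._steady_mode = False
        if not mon.converged:
            raise ConvergenceError(
                f"steady solve did not converge in {max_steps} steps "
                f"(residuals {rc:.2e}, {rm:.2e})", history=mon)
        return state, mon

    # -- pulsatile solve -----------------------------------------------------

    def solve_pulsatile(self, cycles: int, steps_per_cycle: int = 4000,
                        cfl_limit: float = 0.9,
                        snapshots_per_cycle: int = 32,
                        hepatic_source: Optional[str] = None,
                        tol: float = 1e-5
                        ) -> Tuple[List[Tuple[float, FlowField]], ConvergenceMonitor]:
        """Time-accurate pulsatile solve over ``cycles`` heartbeats.

        All inlet waveforms must share one period.  Snapshots of the
        final cycle are returned together with per-cycle summaries
        (%PFD, hepatic split, power loss) in ``monitor.cycle_history``
        and the cycle-periodicity metric (RMS velocity difference
        between the ends of the last two cycles over the velocity
        scale).
        """
        periods = {round(wf.period, 12) for wf in self.inlets.values()}
        if len(periods) != 1:
            raise ConfigurationError(
                f"all inlet waveforms must share one period, got {sorted(periods)}")
        T = next(iter(periods))
        dt = T / steps_per_cycle
        dt_ok = self.stable_dt(1.5 * self.u_peak, cfl_limit)
        if dt > dt_ok:
            raise TimeStepError(
                f"steps_per_cycle={steps_per_cycle} gives dt={dt:.3e} s above "
                f"the CFL bound {dt_ok:.3e} s; use >= {int(np.ceil(T / dt_ok))} "
                "steps per cycle", suggested_dt=dt_ok)
        track = hepatic_source is not None

        state = self.new_field()
        mon = ConvergenceMonitor(tolerance=tol)
        mon.reynolds = self.reynolds
        snap_every = max(1, steps_per_cycle // snapshots_per_cycle)
        snapshots: List[Tuple[float, FlowField]] = []
        prev_cycle_end: Optional[FlowField] = None
        hist = {"pfd_lpa_pct": [], "e_loss_mw": [], "hfd_lpa_pct": []}

        for cyc in range(cycles):
            q_acc = {n: 0.0 for n in self.outlets}
            h_acc = {n: 0.0 for n in self.outlets}
            e_acc = 0.0
            last = cyc == cycles - 1
            for k in range(steps_per_cycle):
                it = cyc * steps_per_cycle + k
                rc, rm = self.step(state, dt, step_index=it,
                                   advect_scalar=track,
                                   scalar_source=hepatic_source)
                for n in self.outlets:
                    q_acc[n] += self.port_flux(state, n)
                    if track:
                        h_acc[n] += self.scalar_flux_out(state, n)
                if k % monitor_stride(steps_per_cycle) == 0:
                    from . import metrics as _metrics
                    e_now = _metrics.power_loss(state, self, self.fluid.density)
                    e_acc += e_now
                    mon.record(it + 1, rc, rm, {"e_loss_mw": e_now})
                if last and (k % snap_every == snap_every - 1):
                    snapshots.append((state.time, state.copy()))
            tot = sum(q_acc.values())
            if "LPA" in q_acc and tot != 0:
                hist["pfd_lpa_pct"].append(100.0 * q_acc["LPA"] / tot)
            if track and "LPA" in h_acc:
                q_ivc = self.inlets[hepatic_source].q_avg * steps_per_cycle
                hist["hfd_lpa_pct"].append(100.0 * h_acc["LPA"] / q_ivc)
            nmon = max(1, steps_per_cycle // monitor_stride(steps_per_cycle))
            hist["e_loss_mw"].append(e_acc / nmon)
            if prev_cycle_end is not None and cyc == cycles - 1:
                num = 0.0
                den = 0.0
                for a, b in ((state.u, prev_cycle_end.u),
                             (state.v, prev_cycle_end.v),
                             (state.w, prev_cycle_end.w)):
                    num += float(np.sum((a - b) ** 2))
                    den += float(np.sum(a ** 2))
                mon.cycle_periodicity = float(np.sqrt(num / max(den, 1e-300)))
            if cyc == cycles - 2:
                prev_cycle_end = state.copy()
        mon.cycle_history = {k: v for k, v in hist.items() if v}
        mon.converged = True
        mon.n_steps = cycles * steps_per_cycle
        return snapshots, mon


def monitor_stride(steps_per_cycle: int) -> int:
    return max(1, steps_per_cycle // 50)


# ---------------------------------------------------------------------------
# Module-level convenience wrappers (the spec's operation surface)

def solve_steady(grid: VoxelGrid, inlets, outlets, fluid: CarreauParams,
                 tol: float = 1e-5, **kw):
    sim = Simulation(grid, inlets, outlets, fluid)
    field, mon = sim.solve_steady(tol=tol, **kw)
    return field, mon, sim


def solve_pulsatile(grid: VoxelGrid, inlets, outlets, fluid: CarreauParams,
                    cycles: int, steps_per_cycle: int = 4000, **kw):
    sim = Simulation(grid, inlets, outlets, fluid)
    snaps, mon = sim.solve_pulsatile(cycles, steps_per_cycle, **kw)
    return snaps, mon, sim


def run_case(config, output_dir: Optional[str] = None):
    """One-call pipeline: geometry -> voxelize -> solve -> scalar -> metrics.

    ``config`` is a :class:`fontanflow.io_cli.RunConfig` (or YAML dict
    accepted by it).  Returns ``(report, artifacts)`` where ``report``
    is the JSON-serializable metrics report.  Deterministic for a fixed
    config.
    """
    from . import io_cli
    return io_cli.execute_run(config, output_dir=output_dir)
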