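"""Hemodynamic parameters of the cavopulmonary connection.

Implements the standard Fontan metric suite: pulmonary and hepatic flow
distribution to the LPA, power loss (net total-pressure energy flux,
inlets minus outlets), wall shear stress and its time average over one
heartbeat, the low-WSS area fraction (threshold 0.4 Pa, the
atherosclerosis-prone regime), and the per-vessel / flow-weighted
pulsatility indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .boundary_conditions import FlowWaveform
from .errors import (ConfigurationError, GeometryError, InvalidInputError)
from .geometry import VoxelGrid

#: Low-shear threshold (Pa) for the normalized WSS area.
WSS_THRESHOLD_PA = 0.4


# ---------------------------------------------------------------------------
# Flow splits

def pfd_lpa(q_lpa: float, q_rpa: float) -> float:
    """% of total pulmonary flow reaching the LPA."""
    if q_lpa < 0 or q_rpa < 0:
        raise InvalidInputError("pulmonary flows must be nonnegative")
    tot = q_lpa + q_rpa
    if tot == 0:
        raise InvalidInputError("pulmonary split undefined: both flows zero")
    return 100.0 * q_lpa / tot


def hfd_lpa(scalar_flux_to_lpa: float, q_ivc: float) -> float:
    """% of IVC (hepatic) flow reaching the LPA."""
    if q_ivc <= 0:
        raise InvalidInputError(f"IVC flow must be positive, got {q_ivc}")
    return 100.0 * scalar_flux_to_lpa / q_ivc


# ---------------------------------------------------------------------------
# Power loss

def power_loss(field, sim, density: Optional[float] = None) -> float:
    """Net total-pressure energy flux in mW.

    E = sum_inlets int (p + rho v^2/2) v.dA  -  sum_outlets int (...) v.dA

    with discrete face quadrature over the port patches; the outlet
    integral is evaluated at the zero-pressure port downstream of the
    baffle, so baffle dissipation is included.  Pressure is taken from
    the port-adjacent cell, the kinetic term from the full velocity
    magnitude at the face.
    """
    rho = density if density is not None else sim.fluid.density
    comps = [field.u, field.v, field.w]
    dx = sim.dx
    speed = field.speed_cells()

    def port_energy_flux(ax, sg, idx, outward: bool) -> float:
        vn = comps[ax][idx]
        cells = np.asarray(idx).T.copy()
        cells[:, ax] -= 1 if sg > 0 else 0
        cid = tuple(cells.T)
        p = field.p[cid]
        # full velocity magnitude: tangential from the adjacent cell,
        # normal from the face itself
        sp2 = np.maximum(speed[cid] ** 2, vn ** 2)
        e = (p + 0.5 * rho * sp2) * (sg * vn if outward else -sg * vn)
        return float(np.sum(e) * dx ** 2)

    e_in = 0.0
    for name, (ax, sg, idx, area) in sim.inlet_faces.items():
        e_in += port_energy_flux(ax, sg, idx, outward=False)
    e_out = 0.0
    for name, (ax, sg, idx) in sim.outlet_faces.items():
        e_out += port_energy_flux(ax, sg, idx, outward=True)
    return (e_in - e_out) * 1e3  # W -> mW


# ---------------------------------------------------------------------------
# Wall shear stress

@dataclass
class WallFaces:
    """Enumerated stair-step wall faces (fluid cell, face axis, sign)."""

    cells: np.ndarray   # (M, 3) int
    axis: np.ndarray    # (M,)
    sign: np.ndarray    # (M,)
    dx: float

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    @property
    def areas(self) -> np.ndarray:
        """Per-face area: dx^2 per exposed stair-step face (first order)."""
        return np.full(self.n, self.dx ** 2)

    @property
    def total_area(self) -> float:
        return self.n * self.dx ** 2

    def centers(self, origin: np.ndarray) -> np.ndarray:
        c = (self.cells + 0.5) * self.dx + origin
        for m in range(self.n):
            c[m, self.axis[m]] += 0.5 * self.sign[m] * self.dx
        return c


def wall_faces(grid: VoxelGrid, exclude_ports: bool = True) -> WallFaces:
    """All fluid-solid face adjacencies that are not open ports."""
    F = grid.fluid_mask
    port_faces = set()
    if exclude_ports:
        for p in grid.ports.values():
            for row in p.face_index:
                port_faces.add((p.axis, tuple(row)))
    cells, axes, signs = [], [], []
    Fp = np.pad(F, 1)
    for ax in range(3):
        for sg in (1, -1):
            shifted = np.roll(Fp, -sg, axis=ax)[1:-1, 1:-1, 1:-1]
            wall = F & ~shifted
            ii = np.argwhere(wall)
            for c in ii:
                fidx = c.copy()
                if sg > 0:
                    fidx[ax] += 1
                if exclude_ports and (ax, tuple(fidx)) in port_faces:
                    continue
                cells.append(c)
                axes.append(ax)
                signs.append(sg)
    if not cells:
        raise GeometryError("no wall faces found (empty wall set)")
    return WallFaces(cells=np.asarray(cells, int), axis=np.asarray(axes, int),
                     sign=np.asarray(signs, int), dx=grid.dx)


def _cell_center_velocity(field) -> np.ndarray:
    uc = 0.5 * (field.u[1:, :, :] + field.u[:-1, :, :])
    vc = 0.5 * (field.v[:, 1:, :] + field.v[:, :-1, :])
    wc = 0.5 * (field.w[:, :, 1:] + field.w[:, :, :-1])
    return np.stack([uc, vc, wc], axis=-1)


def _fluid_trilinear(pts: np.ndarray, vel: np.ndarray, mask: np.ndarray,
                     origin: np.ndarray, dx: float):
    """Trilinear interpolation of cell-centered vectors, solid cells
    excluded from the stencil (weights renormalized)."""
    rel = (pts - origin) / dx - 0.5
    i0 = np.floor(rel).astype(int)
    f = rel - i0
    out = np.zeros((len(pts), 3))
    wsum = np.zeros(len(pts))
    nx, ny, nz = mask.shape
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                ii = np.clip(i0[:, 0] + di, 0, nx - 1)
                jj = np.clip(i0[:, 1] + dj, 0, ny - 1)
                kk = np.clip(i0[:, 2] + dk, 0, nz - 1)
                w = ((f[:, 0] if di else 1 - f[:, 0])
                     * (f[:, 1] if dj else 1 - f[:, 1])
                     * (f[:, 2] if dk else 1 - f[:, 2]))
                w = w * mask[ii, jj, kk]
                out += w[:, None] * vel[ii, jj, kk]
                wsum += w
    ok = wsum > 1e-9
    out[ok] /= wsum[ok, None]
    return out, ok


def wss_field(field, grid: VoxelGrid,
              walls: Optional[WallFaces] = None) -> np.ndarray:
    """Wall shear stress magnitude tau_w (Pa) per wall face.

    tau_w = eta * d|u_t|/dn at the wall.  On grids carrying the
    parametric solid, each wall face is projected onto the true surface
    along the signed-distance normal and the tangential speed is
    sampled at two probe heights (2 dx and 4 dx) along that normal; the
    wall gradient is the slope at 0 of the quadratic through the origin
    and both probes.  This keeps the estimate first-order accurate on
    stair-step boundaries.  Without a parametric solid (imported STL) a
    one-sided cell-center stencil over delta = dx/2 is used instead.
    """
    if walls is None:
        walls = wall_faces(grid)
    dx = grid.dx
    vel = _cell_center_velocity(field)
    cid = tuple(walls.cells.T)
    eta = field.eta[cid]

    # fallback: one-sided stencil from the wall-adjacent cell center
    v_cell = vel[cid]
    vt = v_cell.copy()
    vt[np.arange(walls.n), walls.axis] = 0.0
    ut = np.linalg.norm(vt, axis=1)
    tau_simple = eta * ut / (0.5 * dx)
    if grid.geometry is None:
        return tau_simple

    geo = grid.geometry
    origin = np.asarray(grid.origin)
    xc = origin + (walls.cells + 0.5) * dx
    eps = 0.05 * dx
    grad = np.zeros((walls.n, 3))
    for a in range(3):
        dp = xc.copy(); dp[:, a] += eps
        dm = xc.copy(); dm[:, a] -= eps
        grad[:, a] = (geo.sdf(dp) - geo.sdf(dm)) / (2 * eps)
    nrm = grad / np.maximum(np.linalg.norm(grad, axis=1, keepdims=True), 1e-12)
    xsurf = xc - geo.sdf(xc)[:, None] * nrm

    h1, h2 = 2.0 * dx, 4.0 * dx
    v1, ok1 = _fluid_trilinear(xsurf - h1 * nrm, vel, grid.fluid_mask,
                               origin, dx)
    v2, ok2 = _fluid_trilinear(xsurf - h2 * nrm, vel, grid.fluid_mask,
                               origin, dx)

    def _tangential_speed(v):
        return np.linalg.norm(v - np.sum(v * nrm, axis=1, keepdims=True) * nrm,
                              axis=1)

    u1 = _tangential_speed(v1)
    u2 = _tangential_speed(v2)
    slope = (u1 * h2 ** 2 - u2 * h1 ** 2) / (h1 * h2 * (h2 - h1))
    tau = eta * np.maximum(slope, 0.0)
    ok = ok1 & ok2
    tau[~ok] = tau_simple[~ok]
    return tau


def tawss(wss_snapshots: Sequence[np.ndarray], times: Sequence[float],
          period: float) -> np.ndarray:
    """Per-face time-averaged WSS, (1/T) int |tau_w| dt over one cycle.

    ``wss_snapshots[k]`` is the WSS array at ``times[k]``; the snapshots
    must span one full period (a single snapshot is interpreted as a
    steady field, whose TAWSS is itself).  Trapezoidal quadrature with
    periodic closure.
    """
    taus = [np.abs(np.asarray(s, float)) for s in wss_snapshots]
    if len(taus) == 0:
        raise InvalidInputError("no WSS snapshots given")
    if len(taus) == 1:
        return taus[0]
    t = np.asarray(times, float)
    if len(t) != len(taus):
        raise InvalidInputError("times and snapshots length mismatch")
    span = t[-1] - t[0]
    if span > period * (1 + 1e-9) or span < 0.8 * period:
        raise InvalidInputError(
            f"snapshots span {span:.4g} s; need one full period {period:.4g} s")
    # periodic closure: repeat the first snapshot at t0 + T
    t_ext = np.concatenate([t, [t[0] + period]])
    tau_ext = np.stack(taus + [taus[0]], axis=0)
    integral = np.trapezoid(tau_ext, t_ext, axis=0)
    return integral / period


def low_wss_area_fraction(tau: np.ndarray,
                          areas: Optional[np.ndarray] = None,
                          threshold: float = WSS_THRESHOLD_PA) -> float:
    """% of wall area with WSS (or TAWSS) below ``threshold`` Pa."""
    tau = np.asarray(tau, float)
    if tau.size == 0:
        raise GeometryError("empty wall set")
    if areas is None:
        areas = np.ones_like(tau)
    total = float(np.sum(areas))
    low = float(np.sum(areas[tau < threshold]))
    return 100.0 * low / total


# ---------------------------------------------------------------------------
# Pulsatility

def pulsatility_index(waveform_or_extrema) -> float:
    """PI = (Q_max - Q_min) / (2 Q_avg) * 100%."""
    if isinstance(waveform_or_extrema, FlowWaveform):
        q_max = waveform_or_extrema.q_max
        q_min = waveform_or_extrema.q_min
        q_avg = waveform_or_extrema.q_avg
    else:
        q_max, q_min, q_avg = waveform_or_extrema
    if q_avg == 0:
        raise InvalidInputError("PI undefined for zero-mean flow")
    return 100.0 * (q_max - q_min) / (2.0 * abs(q_avg))


def weighted_pi(pi_values: Sequence[float], flows: Sequence[float],
                normalized: bool = True) -> float:
    """Flow-weighted pulsatility wPI = sum_i PI_i * C_i (%).

    Weights default to the normalized relative splits
    C_i = Q_i / sum(Q); with ``normalized=False`` the raw
    C_i = Q_i / mean(Q) convention is used instead.
    """
    pi = np.asarray(pi_values, float)
    q = np.asarray(flows, float)
    if pi.size == 0 or pi.shape != q.shape:
        raise InvalidInputError("need matching, nonempty PI and flow sequences")
    if np.any(q <= 0):
        raise InvalidInputError("vessel flows must be positive")
    if normalized:
        c = q / q.sum()
    else:
        c = q / q.mean()
    return float(np.sum(pi * c))


# ---------------------------------------------------------------------------
# Aggregate report

@dataclass
class MetricsReport:
    """All hemodynamic parameters of one run, JSON/CSV-serializable."""

    mode: str
    pfd_lpa_pct: Optional[float] = None
    hfd_lpa_pct: Optional[float] = None
    power_loss_mw: Optional[float] = None
    low_wss_area_pct: Optional[float] = None
    wss_mean_pa: Optional[float] = None
    tawss_mean_pa: Optional[float] = None
    pi_pct: Dict[str, float] = dc_field(default_factory=dict)
    wpi_pct: Optional[float] = None
    wpi_raw_pct: Optional[float] = None
    port_flows_m3s: Dict[str, float] = dc_field(default_factory=dict)
    hepatic_flux_m3s: Dict[str, float] = dc_field(default_factory=dict)
    reynolds: Dict[str, float] = dc_field(default_factory=dict)
    mass_imbalance: Optional[float] = None
    wss_threshold_pa: float = WSS_THRESHOLD_PA
    extra: Dict[str, float] = dc_field(default_factory=dict)

    UNITS = {
        "pfd_lpa_pct": "%", "hfd_lpa_pct": "%", "power_loss_mw": "mW",
        "low_wss_area_pct": "%", "wss_mean_pa": "Pa", "tawss_mean_pa": "Pa",
        "wpi_pct": "%", "wpi_raw_pct": "%", "mass_imbalance": "fraction",
        "wss_threshold_pa": "Pa",
    }

    def to_dict(self) -> dict:
        out = {"mode": self.mode}
        for k, unit in self.UNITS.items():
            v = getattr(self, k)
            if v is not None:
                out[k] = {"value": float(v), "unit": unit}
        out["pi_pct"] = {k: float(v) for k, v in self.pi_pct.items()}
        out["port_flows_m3s"] = {k: float(v) for k, v in self.port_flows_m3s.items()}
        out["hepatic_flux_m3s"] = {k: float(v)
                                   for k, v in self.hepatic_flux_m3s.items()}
        out["reynolds"] = {k: float(v) for k, v in self.reynolds.items()}
        out["extra"] = {k: float(v) for k, v in self.extra.items()}
        return out

    def metric_value(self, name: str) -> float:
        d = self.to_dict()
        if name in d and isinstance(d[name], dict) and "value" in d[name]:
            return d[name]["value"]
        for sub in ("pi_pct", "port_flows_m3s", "hepatic_flux_m3s", "extra"):
            if name in d[sub]:
                return d[sub][name]
        raise ConfigurationError(
            f"metric {name!r} not in report; available: {self.available()}")

    def available(self) -> List[str]:
        d = self.to_dict()
        names = [k for k, v in d.items() if isinstance(v, dict) and "value" in v]
        for sub in ("pi_pct", "port_flows_m3s", "hepatic_flux_m3s", "extra"):
            names.extend(d[sub])
        return sorted(names)


def compute_report(sim, field_or_snaps, monitor=None,
                   hepatic_fluxes: Optional[Dict[str, float]] = None,
                   wss_threshold: float = WSS_THRESHOLD_PA,
                   mode: str = "steady") -> MetricsReport:
    """Assemble the full metric suite from a solve.

    For steady runs pass the converged :class:`FlowField`; for pulsatile
    runs pass the final-cycle snapshot list, in which case flows are
    cycle-averaged and the low-WSS area uses TAWSS.
    """
    grid = sim.grid
    walls = wall_faces(grid)
    rep = MetricsReport(mode=mode, wss_threshold_pa=wss_threshold)
    rep.reynolds = sim.reynolds

    if mode == "steady":
        field = field_or_snaps
        flows = {n: sim.port_flux(field, n) for n in sim.outlets}
        tau = wss_field(field, grid, walls)
        rep.wss_mean_pa = float(np.average(tau, weights=walls.areas))
        rep.low_wss_area_pct = low_wss_area_fraction(tau, walls.areas,
                                                     wss_threshold)
        rep.power_loss_mw = power_loss(field, sim)
        rep.mass_imbalance = sim.mass_imbalance(field)
        for n in sim.inlets:
            flows[n] = sim.port_flux(field, n)
    else:
        snaps = field_or_snaps
        times = [t for t, _ in snaps]
        period = next(iter(sim.inlets.values())).period
        taus = [wss_field(f, grid, walls) for _, f in snaps]
        ta = tawss(taus, times, period)
        rep.tawss_mean_pa = float(np.average(ta, weights=walls.areas))
        rep.low_wss_area_pct = low_wss_area_fraction(ta, walls.areas,
                                                     wss_threshold)
        flows = {}
        for n in list(sim.outlets) + list(sim.inlets):
            vals = [sim.port_flux(f, n) for _, f in snaps]
            flows[n] = float(np.mean(vals))
        e_vals = [power_loss(f, sim) for _, f in snaps]
        rep.power_loss_mw = float(np.mean(e_vals))
        rep.mass_imbalance = abs(
            sum(flows[n] for n in sim.outlets)
            + sum(flows[n] for n in sim.inlets)
        ) / max(abs(sum(flows[n] for n in sim.inlets)), 1e-30)

    rep.port_flows_m3s = flows
    if "LPA" in sim.outlets and "RPA" in sim.outlets:
        rep.pfd_lpa_pct = pfd_lpa(max(flows["LPA"], 0.0), max(flows["RPA"], 0.0))
    if hepatic_fluxes:
        rep.hepatic_flux_m3s = dict(hepatic_fluxes)
        src = [n for n in sim.inlets if n == "IVC"]
        q_src = sim.inlets[src[0]].q_avg if src else \
            next(iter(sim.inlets.values())).q_avg
        if "LPA" in hepatic_fluxes:
            rep.hfd_lpa_pct = hfd_lpa(hepatic_fluxes["LPA"], q_src)

    # pulsatility of the prescribed inlet waveforms (plus outlet flows in
    # pulsatile mode, from their cycle traces, would need per-step data;
    # the inlet-side indices are always well defined)
    pis, qs = [], []
    for n, wf in sim.inlets.items():
        try:
            pi = pulsatility_index(wf)
        except InvalidInputError:
            continue
        rep.pi_pct[n] = pi
        pis.append(pi)
        qs.append(abs(wf.q_avg))
    if pis:
        rep.wpi_pct = weighted_pi(pis, qs, normalized=True)
        rep.wpi_raw_pct = weighted_pi(pis, qs, normalized=False)
    if monitor is not None and monitor.cycle_periodicity is not None:
        rep.extra["cycle_periodicity"] = monitor.cycle_periodicity
    return rep
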