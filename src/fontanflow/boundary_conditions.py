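"""Inlet waveforms, harmonic decomposition and lumped outlet resistances.

Pulsatile venous inflows are periodic flow-rate signals Q(t) carried as a
mean plus up to 15 complex harmonics (the decomposition used to drive the
pulsatile solver).  Inlets are plug profiles: the instantaneous flow is
spread uniformly over the discrete port faces, so the integrated flux
equals Q(t) exactly.

Each outlet lumps the downstream pulmonary vascular bed into a linear
resistance ("porous baffle") satisfying dp = R_eff * F against a shared
zero-pressure reservoir (the atrium).  Aortopulmonary collateral flow is
folded in through the factor k = (pulmonary vein flow)/(pulmonary artery
flow), which scales the resistance: R_eff = R * k.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidInputError, SamplingError

DEFAULT_N_HARMONICS = 15

LMIN_TO_M3S = 1.0 / 60000.0  # liters per minute -> m^3/s


# ---------------------------------------------------------------------------
# Harmonic decomposition

def _uniform_resample(times: np.ndarray, flows: np.ndarray, period: float,
                      n: int) -> np.ndarray:
    """Periodic linear interpolation onto n uniform phases in [0, T)."""
    t = np.mod(times - times[0], period)
    order = np.argsort(t)
    t = t[order]
    q = flows[order]
    tt = np.concatenate([t, [t[0] + period]])
    qq = np.concatenate([q, [q[0]]])
    phases = np.arange(n) * period / n
    return np.interp(phases, tt, qq)


def fourier_decompose(samples: Sequence[Tuple[float, float]],
                      period: Optional[float] = None,
                      n_harmonics: int = DEFAULT_N_HARMONICS):
    """Decompose one period of (time, flow) samples into harmonics.

    Returns ``(mean, harmonics, rms_error)`` where ``harmonics`` is a
    complex array of length ``n_harmonics`` and the signal is

        Q(t) = mean + sum_m Re( 2 * harmonics[m-1] * exp(2j*pi*m*t/T) ).

    Samples may be non-uniform; they are resampled to a uniform grid by
    periodic linear interpolation first.  Uniform samples are
    transformed directly, so signals band-limited to ``<= n_harmonics``
    modes round-trip exactly.  ``rms_error`` is the RMS misfit of the
    truncated reconstruction at the (resampled) grid.
    """
    arr = np.asarray(samples, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidInputError("samples must be a sequence of (time, flow) pairs")
    times, flows = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("waveform samples must be finite")
    if period is None:
        # infer: duplicated endpoint, else uniform extrapolation
        if len(times) >= 2 and np.isclose(flows[0], flows[-1], rtol=1e-6, atol=0):
            period = times[-1] - times[0]
        else:
            period = (times[-1] - times[0]) * len(times) / (len(times) - 1)
    if period <= 0:
        raise InvalidInputError(f"period must be positive, got {period}")
    # drop a duplicated endpoint at t0 + T
    if len(times) >= 2 and np.isclose(times[-1] - times[0], period, rtol=1e-9):
        times, flows = times[:-1], flows[:-1]
    if len(times) < 2 * n_harmonics + 1:
        raise SamplingError(
            f"{len(times)} samples cannot resolve {n_harmonics} harmonics; "
            f"need >= {2 * n_harmonics + 1} per period"
        )
    dt = np.diff(times)
    uniform = np.allclose(dt, dt[0], rtol=1e-8, atol=period * 1e-12)
    if uniform:
        q = flows
    else:
        q = _uniform_resample(times, flows, period, max(256, 4 * len(times)))
    spec = np.fft.rfft(q) / len(q)
    mean = float(spec[0].real)
    harmonics = np.asarray(spec[1:n_harmonics + 1], complex)
    if len(harmonics) < n_harmonics:
        harmonics = np.pad(harmonics, (0, n_harmonics - len(harmonics)))
    # truncation misfit on the uniform grid
    tgrid = np.arange(len(q)) * period / len(q)
    recon = reconstruct_flow(mean, harmonics, tgrid, period)
    rms_error = float(np.sqrt(np.mean((recon - q) ** 2)))
    return mean, harmonics, rms_error


def reconstruct_flow(mean: float, harmonics: np.ndarray, t, period: float):
    """Evaluate the harmonic series at time(s) t (periodic in T)."""
    t = np.asarray(t, float)
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("time must be finite")
    m = np.arange(1, len(harmonics) + 1)
    phase = np.exp(2j * np.pi * np.multiply.outer(t, m) / period)
    q = mean + 2.0 * np.real(phase @ np.asarray(harmonics, complex))
    return float(q) if t.ndim == 0 else q


@dataclass
class FlowWaveform:
    """Periodic flow-rate signal with its harmonic representation.

    ``mean`` is the exact time-average; ``q(t)`` evaluates the
    band-limited reconstruction, periodic in ``period``.
    """

    period: float
    mean: float
    harmonics: np.ndarray
    samples: Optional[np.ndarray] = None
    reconstruction_rms: float = 0.0

    @classmethod
    def from_samples(cls, samples, period: Optional[float] = None,
                     n_harmonics: int = DEFAULT_N_HARMONICS) -> "FlowWaveform":
        mean, harm, rms = fourier_decompose(samples, period, n_harmonics)
        arr = np.asarray(samples, float)
        if period is None:
            times = arr[:, 0]
            if np.isclose(arr[0, 1], arr[-1, 1], rtol=1e-6, atol=0):
                period = times[-1] - times[0]
            else:
                period = (times[-1] - times[0]) * len(times) / (len(times) - 1)
        return cls(period=float(period), mean=mean, harmonics=harm,
                   samples=arr, reconstruction_rms=rms)

    @classmethod
    def constant(cls, q: float, period: float = 1.0) -> "FlowWaveform":
        return cls(period=period, mean=float(q),
                   harmonics=np.zeros(DEFAULT_N_HARMONICS, complex))

    @classmethod
    def from_harmonics(cls, mean: float, harmonics, period: float) -> "FlowWaveform":
        return cls(period=float(period), mean=float(mean),
                   harmonics=np.asarray(harmonics, complex))

    def __post_init__(self):
        if self.period <= 0:
            raise InvalidInputError(f"period must be positive, got {self.period}")

    def q(self, t) -> float:
        return reconstruct_flow(self.mean, self.harmonics, t, self.period)

    @property
    def is_constant(self) -> bool:
        return bool(np.all(np.abs(self.harmonics) == 0.0))

    @property
    def q_avg(self) -> float:
        return self.mean

    def _dense(self, n: int = 4096) -> np.ndarray:
        t = np.arange(n) * self.period / n
        return self.q(t)

    @property
    def q_max(self) -> float:
        return float(self._dense().max())

    @property
    def q_min(self) -> float:
        return float(self._dense().min())


# ---------------------------------------------------------------------------
# Plug inlets

def plug_inlet_velocity(waveform_or_q, port, t: float = 0.0) -> float:
    """Uniform inward normal velocity Q(t)/A over the discrete port.

    ``port`` is a :class:`~fontanflow.geometry.Port`; by construction
    the summed face flux ``velocity * n_faces * dx^2`` equals Q(t)
    exactly.
    """
    if port is None:
        raise ConfigurationError("port not found")
    area = port.area
    if area <= 0:
        raise ConfigurationError(f"port {port.name} has zero area")
    if isinstance(waveform_or_q, FlowWaveform):
        qt = waveform_or_q.q(t)
    else:
        qt = float(waveform_or_q)
    return qt / area


# ---------------------------------------------------------------------------
# Outlet resistances

@dataclass(frozen=True)
class OutletModel:
    """Linear pulmonary resistance with APC scaling at one outlet.

    ``resistance`` in Pa s/m^3; ``apc_factor`` k is dimensionless
    (>= 1 when collaterals add pulmonary flow); downstream reference is
    the common atrial pressure, fixed at 0 Pa.
    """

    resistance: float
    apc_factor: float = 1.0
    downstream_pressure: float = 0.0

    def __post_init__(self):
        if self.resistance <= 0:
            raise InvalidInputError(f"resistance must be > 0, got {self.resistance}")
        if self.apc_factor <= 0:
            raise InvalidInputError(f"APC factor must be > 0, got {self.apc_factor}")

    @property
    def effective_resistance(self) -> float:
        return self.resistance * self.apc_factor


def apc_factor(pulmonary_vein_flow: float, pulmonary_artery_flow: float) -> float:
    """k = vein flow / artery flow (any consistent units)."""
    if pulmonary_artery_flow <= 0:
        raise InvalidInputError(
            f"pulmonary artery flow must be > 0, got {pulmonary_artery_flow}"
        )
    return pulmonary_vein_flow / pulmonary_artery_flow


def baffle_pressure_drop(r_eff: float, flow: float) -> float:
    """Transpulmonary gradient dp = R_eff * F (sign follows F)."""
    return r_eff * flow


def predict_split_0d(r_left_eff: float, r_right_eff: float) -> float:
    """Two-resistor divider: % of total flow through the left outlet.

    Lumped-network consequence of dp = R*F with a shared zero-pressure
    sink; independent of total flow and of common resistance scaling.
    """
    if r_left_eff <= 0 or r_right_eff <= 0:
        raise InvalidInputError("resistances must be positive")
    return 100.0 * r_right_eff / (r_left_eff + r_right_eff)


# ---------------------------------------------------------------------------
# Waveform CSV I/O

def read_waveform_csv(path: str, period: Optional[float] = None,
                      n_harmonics: int = DEFAULT_N_HARMONICS) -> FlowWaveform:
    """Read (time, flow) samples from CSV.

    Header must name ``time_s`` and either ``flow_m3s`` or ``flow_lmin``
    (converted to m^3/s).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InvalidInputError(f"{path}: empty waveform CSV")
        cols = [c.strip() for c in reader.fieldnames]
        if "time_s" not in cols:
            raise InvalidInputError(f"{path}: missing required column time_s")
        if "flow_m3s" in cols:
            fcol, scale = "flow_m3s", 1.0
        elif "flow_lmin" in cols:
            fcol, scale = "flow_lmin", LMIN_TO_M3S
        else:
            raise InvalidInputError(
                f"{path}: need a flow_m3s or flow_lmin column, got {cols}"
            )
        samples = [(float(row["time_s"]), float(row[fcol]) * scale)
                   for row in reader]
    return FlowWaveform.from_samples(samples, period=period,
                                     n_harmonics=n_harmonics)


def write_waveform_csv(path: str, waveform: FlowWaveform, n: int = 64) -> None:
    t = np.arange(n) * waveform.period / n
    q = waveform.q(t)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "flow_m3s"])
        for ti, qi in zip(t, q):
            writer.writerow([f"{ti:.9g}", f"{qi:.9g}"])
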