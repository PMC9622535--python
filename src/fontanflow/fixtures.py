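"""Synthetic inputs: venous-like waveforms and complete demo cases.

Fontan/Glenn venous flow is only mildly pulsatile (weighted pulsatility
index roughly 30-70 % in patients, versus arterial pulses well above
100 %), so the waveform generator builds a biphasic signal from 2-3 low
harmonics with seed-controlled phases, scaled to hit a target
pulsatility index exactly while keeping the prescribed mean.  Complete
run configurations ("cases") span the physiologic ranges of
BSA-indexed caval flows around 0.5-2 L/min/m^2.

Every fixture is reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .boundary_conditions import LMIN_TO_M3S, FlowWaveform
from .errors import InvalidInputError

#: Default relative harmonic amplitudes of the biphasic venous shape.
VENOUS_HARMONIC_AMPLITUDES = (1.0, 0.45, 0.2)


@dataclass(frozen=True)
class WaveformSpec:
    """Target description of one synthetic venous waveform.

    ``mean_flow`` in m^3/s, ``period`` in s, ``target_pi`` in percent.
    ``harmonic_amplitudes`` are relative weights of the low harmonics
    (absolute scale is set by the PI target).
    """

    mean_flow: float
    period: float = 0.6
    target_pi: float = 45.0
    harmonic_amplitudes: Tuple[float, ...] = VENOUS_HARMONIC_AMPLITUDES

    def __post_init__(self):
        if self.mean_flow <= 0:
            raise InvalidInputError(f"mean flow must be positive, got {self.mean_flow}")
        if self.period <= 0:
            raise InvalidInputError(f"period must be positive, got {self.period}")
        if self.target_pi < 0:
            raise InvalidInputError(f"target PI must be >= 0, got {self.target_pi}")
        if self.target_pi > 100:
            raise InvalidInputError(
                f"target PI {self.target_pi}% would drive the venous flow "
                "negative; unreachable with a positive waveform")
        if len(self.harmonic_amplitudes) == 0 or len(self.harmonic_amplitudes) > 15:
            raise InvalidInputError("need 1..15 harmonic amplitudes")


def make_waveform(spec: WaveformSpec, seed: int = 0) -> FlowWaveform:
    """Deterministic venous waveform matching the spec.

    The harmonic mixture is scaled so the computed pulsatility index
    (Q_max - Q_min)/(2 Q_avg) equals ``target_pi`` and the time-mean is
    exactly ``mean_flow``; phases are drawn from ``seed``.
    """
    if spec.target_pi == 0:
        return FlowWaveform.constant(spec.mean_flow, spec.period)
    rng = np.random.default_rng(seed)
    amps = np.asarray(spec.harmonic_amplitudes, float)
    phases = rng.uniform(0, 2 * np.pi, size=len(amps))
    if len(amps) == 1:
        phases[:] = -np.pi / 2  # pure sinusoid: Q0(1 + a sin)

    # dense shape evaluation to normalize the swing
    t = np.arange(8192) / 8192 * spec.period
    m = np.arange(1, len(amps) + 1)
    shape = np.sum(amps[None, :] * np.cos(
        2 * np.pi * np.outer(t, m) / spec.period + phases[None, :]), axis=1)
    half_swing = 0.5 * (shape.max() - shape.min())
    scale = (spec.target_pi / 100.0) * spec.mean_flow / half_swing
    # reconstruction convention: Q = mean + sum 2 Re(c_m e^{i w m t})
    coeff = 0.5 * scale * amps * np.exp(1j * phases)
    harmonics = np.zeros(15, complex)
    harmonics[:len(coeff)] = coeff
    return FlowWaveform.from_harmonics(spec.mean_flow, harmonics, spec.period)


#: Physiologic defaults per preset: BSA-indexed mean flows (L/min/m^2),
#: body surface area (m^2), pulsatility and cycle length typical of the
#: respective palliation stages.
CASE_DEFAULTS = {
    "glenn": {
        "bsa_m2": 0.56,
        "flows_lmin_m2": {"SVC": 1.5},
        "pi_pct": {"SVC": 48.0},
        "period_s": 0.55,
        "resistance": {"LPA": 2.4e7, "RPA": 2.4e7},
        "apc_k": {"LPA": 1.2, "RPA": 1.2},
        "cycles": 3,
        "hepatic_source": None,
    },
    "tcpc": {
        "bsa_m2": 1.1,
        "flows_lmin_m2": {"IVC": 1.2, "SVC": 0.82},
        "pi_pct": {"IVC": 46.0, "SVC": 46.0},
        "period_s": 0.6,
        "resistance": {"LPA": 2.4e7, "RPA": 2.4e7},
        "apc_k": {"LPA": 1.2, "RPA": 1.2},
        "cycles": 6,
        "hepatic_source": "IVC",
    },
}


def make_case(preset: str, physiology: Optional[dict] = None,
              mode: str = "steady", dx_fraction: float = 0.10,
              caval_offset: float = 0.0, seed: int = 0,
              output_dir: Optional[str] = None):
    """Complete, validated run configuration for a preset junction.

    ``physiology`` may override any of: ``flows_lmin_m2`` (per inlet),
    ``bsa_m2``, ``pi_pct`` (per inlet), ``period_s``, ``resistance``
    and ``apc_k`` (per outlet).  Returns a
    :class:`fontanflow.io_cli.RunConfig`.
    """
    from .io_cli import RunConfig  # deferred: io_cli imports the solver

    if preset not in CASE_DEFAULTS:
        raise InvalidInputError(
            f"unknown preset {preset!r}; choose from {sorted(CASE_DEFAULTS)}")
    base = {k: (dict(v) if isinstance(v, dict) else v)
            for k, v in CASE_DEFAULTS[preset].items()}
    phys = physiology or {}
    for key, val in phys.items():
        if key not in base:
            raise InvalidInputError(
                f"unknown physiology key {key!r}; allowed: {sorted(base)}")
        if isinstance(base[key], dict):
            base[key].update(val)
        else:
            base[key] = val
    _sanity_check_physiology(base)

    bsa = base["bsa_m2"]
    inlets = {}
    for name, f_idx in base["flows_lmin_m2"].items():
        inlets[name] = {
            "mean_lmin": f_idx * bsa,
            "pi_pct": base["pi_pct"].get(name, 45.0),
            "period_s": base["period_s"],
            "seed": seed,
        }
    outlets = {name: {"R": base["resistance"][name],
                      "k": base["apc_k"].get(name, 1.0)}
               for name in base["resistance"]}
    raw = {
        "geometry": {"preset": preset, "dx_fraction": dx_fraction,
                     "caval_offset": caval_offset},
        "fluid": {},
        "inlets": inlets,
        "outlets": outlets,
        "solver": {"mode": mode, "cycles": base["cycles"],
                   "steps_per_cycle": "auto"},
        "metrics": {"hepatic_source": base["hepatic_source"]},
        "output": {"dir": output_dir},
    }
    return RunConfig.from_dict(raw)


def _sanity_check_physiology(base: dict) -> None:
    import warnings
    for name, f in base["flows_lmin_m2"].items():
        if not 0.1 <= f <= 4.0:
            warnings.warn(
                f"inlet {name}: BSA-indexed flow {f} L/min/m^2 is outside the "
                "physiologic 0.1-4 range", stacklevel=3)
    for name, pi in base["pi_pct"].items():
        if pi > 100:
            raise InvalidInputError(f"inlet {name}: PI {pi}% unreachable")
    for name, r in base["resistance"].items():
        if r <= 0:
            raise InvalidInputError(f"outlet {name}: resistance must be > 0")
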