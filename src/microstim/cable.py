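"""Backward-Euler integration of the MRG double-cable fiber.

This module turns a :class:`~microstim.mrg.FiberGeometry` into the
electrical arrays of the double-cable discretization (axolemma and myelin
layers, intracellular and periaxonal axial pathways), maintains a cache of
relaxed resting states, and runs stimulations under a prescribed
extracellular potential series.

The axoplasmic and periaxonal resistivity is 70 Ω·cm; the myelin sheath
contributes 0.1 µF/cm² and 0.001 S/cm² per lamella membrane (two membranes
per lamella); nodes face the extracellular medium through a negligible
resistance, implemented as a 10¹⁰ S/cm² shunt in place of myelin, exactly
as in the reference double-cable parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .fields import Electrode, Resistivities, StimulusWaveform, waveform_current
from .mrg import NODE, FiberGeometry, build_axon, place_axon

__all__ = [
    "SimulationConfig",
    "MembraneTrace",
    "CableSystem",
    "simulate",
    "detect_activation",
    "NumericalInstabilityError",
]

RHO_AXIAL = 70.0          # Ω·cm, axoplasm and periaxonal space
MYELIN_CM_LAMELLA = 0.1   # µF/cm² per lamella membrane
MYELIN_GM_LAMELLA = 0.001  # S/cm² per lamella membrane
NODE_SHUNT_G = 1e10       # S/cm², node "myelin" layer (direct contact)
CM_MEMBRANE = 2.0         # µF/cm², axolemma everywhere
GPAS_MYSA = 0.001         # S/cm²
GPAS_FLUT = 0.0001
GPAS_STIN = 0.0001
EPAS = -80.0              # mV
SPACE_WIDTH = {0: 0.002, 1: 0.002, 2: 0.004, 3: 0.004}  # µm, by comp type


class NumericalInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Solver settings: fixed step ``dt`` (µs), quiescent tail after the
    stimulus (µs), temperature (°C), and the propagation criterion (mV at
    the last node of Ranvier)."""

    dt: float = 5.0
    post_stimulus_time: float = 400.0
    temperature: float = 36.0
    spike_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.post_stimulus_time < 0:
            raise ValueError("post_stimulus_time must be >= 0")

    @property
    def q10(self) -> tuple[float, float, float]:
        t = self.temperature
        return (2.2 ** ((t - 20.0) / 10.0),
                2.9 ** ((t - 20.0) / 10.0),
                3.0 ** ((t - 36.0) / 10.0))


@dataclass
class MembraneTrace:
    """Per-node membrane potential (mV) on the solver time grid."""

    times: np.ndarray        # (n_steps+1,) µs
    node_vm: np.ndarray      # (n_steps+1, 21) mV
    activated: bool
    spike_threshold: float

    @property
    def last_node_peak(self) -> float:
        return float(self.node_vm[:, -1].max())

    def save_text(self, path) -> None:
        """Columnar debug dump: time (µs) then Vm (mV) per node."""
        header = "time_us " + " ".join(f"node{j:02d}" for j in
                                       range(self.node_vm.shape[1]))
        np.savetxt(path, np.column_stack([self.times, self.node_vm]),
                   fmt="%.6g", header=header)


def detect_activation(trace: MembraneTrace, config: SimulationConfig | None = None) -> bool:
    """True iff the last node's potential exceeded the spike criterion at
    any time step (strict comparison)."""
    thr = config.spike_threshold if config is not None else trace.spike_threshold
    return bool(np.any(trace.node_vm[:, -1] > thr))


class CableSystem:
    """Electrical discretization of one fiber geometry.

    Precomputes capacitances (nF), conductances (µS) and axial couplings
    so repeated simulations only pay for time stepping.  Also owns the
    relaxed resting state for each (dt, temperature) pair.
    """

    def __init__(self, geometry: FiberGeometry):
        self.geometry = geometry
        g = geometry
        n = g.n_compartments
        area = np.pi * g.diameters * g.lengths * 1e-8            # cm², axolemma
        myelin_area = np.pi * g.fiber_diameter * g.lengths * 1e-8  # cm², sheath

        self.cm = CM_MEMBRANE * area * 1e3                        # nF
        gpas_map = {NODE: 0.0, 1: GPAS_MYSA, 2: GPAS_FLUT, 3: GPAS_STIN}
        gpas_cm2 = np.array([gpas_map[int(t)] for t in g.comp_types])
        self.gpas = gpas_cm2 * area * 1e6                         # µS
        self.ipas = self.gpas * EPAS                              # nA

        nl2 = 2.0 * g.n_lamellae
        self.cmy = np.where(g.comp_types == NODE, 0.0,
                            (MYELIN_CM_LAMELLA / nl2) * myelin_area * 1e3)
        node_area = area
        self.gmy = np.where(g.comp_types == NODE,
                            NODE_SHUNT_G * node_area * 1e6,
                            (MYELIN_GM_LAMELLA / nl2) * myelin_area * 1e6)

        # axial pathways: half-compartment resistances in Ω
        half_ri = RHO_AXIAL * (g.lengths / 2.0) / (np.pi * (g.diameters / 2.0) ** 2) * 1e4
        space = np.array([SPACE_WIDTH[int(t)] for t in g.comp_types])
        annulus = np.pi * ((g.diameters / 2.0 + space) ** 2 - (g.diameters / 2.0) ** 2)
        half_rp = RHO_AXIAL * (g.lengths / 2.0) / annulus * 1e4
        self.ga = 1e6 / (half_ri[:-1] + half_ri[1:])              # µS
        self.gp = 1e6 / (half_rp[:-1] + half_rp[1:])              # µS
        self.sum_ga = np.zeros(n)
        self.sum_ga[:-1] += self.ga
        self.sum_ga[1:] += self.ga
        self.sum_gp = np.zeros(n)
        self.sum_gp[:-1] += self.gp
        self.sum_gp[1:] += self.gp

        self.node_idx = g.node_indices.astype(np.int64)
        narea = area[self.node_idx][0]
        self.gna_us = _kernels.GNABAR * narea * 1e6
        self.gnap_us = _kernels.GNAPBAR * narea * 1e6
        self.gk_us = _kernels.GKBAR * narea * 1e6
        self.gl_us = _kernels.GL * narea * 1e6

        self._rest_cache: dict[tuple[float, float], tuple[np.ndarray, ...]] = {}
        self._factor_cache: dict[float, tuple[np.ndarray, ...]] = {}

    def _factors(self, dt_ms: float) -> tuple[np.ndarray, ...]:
        """LU factors of the gate-independent pentadiagonal system matrix
        (interleaved intracellular/periaxonal ordering), cached per dt."""
        if dt_ms not in self._factor_cache:
            n = self.geometry.n_compartments
            n2 = 2 * n
            cm_dt = self.cm / dt_ms
            cmy_dt = self.cmy / dt_ms
            d0 = np.empty(n2)
            d1u = np.zeros(n2 - 1)
            d1l = np.zeros(n2 - 1)
            d2u = np.zeros(n2 - 2)
            d2l = np.zeros(n2 - 2)
            for k in range(n):
                gm = cm_dt[k] + self.gpas[k]
                d0[2 * k] = gm + self.sum_ga[k]
                d0[2 * k + 1] = cmy_dt[k] + self.gmy[k] + self.sum_gp[k] + gm
                d1u[2 * k] = -gm
                d1l[2 * k] = -gm
                if k < n - 1:
                    d2u[2 * k] = -self.ga[k]
                    d2u[2 * k + 1] = -self.gp[k]
                    d2l[2 * k] = -self.ga[k]
                    d2l[2 * k + 1] = -self.gp[k]
            fac = _kernels.factor_penta(d0, d1u, d2u, d1l, d2l)
            Z, S0 = _kernels.woodbury_precompute(*fac, self.node_idx)
            self._factor_cache[dt_ms] = (*fac, Z, S0)
        return self._factor_cache[dt_ms]

    # -- resting state ----------------------------------------------------
    def resting_state(self, config: SimulationConfig,
                      settle_ms: float = 50.0) -> tuple[np.ndarray, ...]:
        """Steady state of the unstimulated fiber, computed once by
        relaxing from a uniform −80 mV start and cached."""
        key = (config.dt, config.temperature)
        if key not in self._rest_cache:
            n = self.geometry.n_compartments
            q1, q2, q3 = config.q10
            a = np.full(n, -80.0)
            b = np.zeros(n)
            m0, h0, p0, s0 = _kernels.gate_steady_state(-80.0, q1, q2, q3)
            nn = self.node_idx.size
            m = np.full(nn, m0)
            h = np.full(nn, h0)
            p = np.full(nn, p0)
            s = np.full(nn, s0)
            dt_ms = config.dt * 1e-3
            n_steps = int(round(settle_ms / dt_ms))
            trace = np.empty((n_steps + 1, nn))
            flag = self._run(dt_ms, n_steps, np.zeros(n), np.zeros(n_steps), None,
                             a, b, m, h, p, s, config, trace, early_exit=False,
                             abort_step=n_steps + 1)
            if flag < 0:
                raise NumericalInstabilityError("resting relaxation diverged")
            self._rest_cache[key] = (a, b, m, h, p, s)
        return tuple(arr.copy() for arr in self._rest_cache[key])

    def resting_potential(self, config: SimulationConfig) -> float:
        a, b, *_ = self.resting_state(config)
        i = self.node_idx[len(self.node_idx) // 2]
        return float(a[i] - b[i])

    # -- integration ------------------------------------------------------
    ABORT_MV = -60.0          # all-nodes-below ⇒ no spike can still emerge
    ABORT_MARGIN_US = 120.0   # wait this long past stimulus end first

    def _run(self, dt_ms, n_steps, profile, schedule, ve_full,
             a, b, m, h, p, s, config, trace, early_exit, abort_step):
        q1, q2, q3 = config.q10
        use_full = ve_full is not None
        if not use_full:
            ve_full = np.zeros((1, 1))
        inv0, u1, u2, l1, l2, Z, S0 = self._factors(dt_ms)
        return _kernels.run_cable(
            dt_ms, n_steps, np.ascontiguousarray(profile),
            np.ascontiguousarray(schedule), np.ascontiguousarray(ve_full),
            use_full, inv0, u1, u2, l1, l2, Z, S0,
            self.cm / dt_ms, self.gpas, self.ipas, self.cmy / dt_ms, self.gmy,
            self.node_idx, self.gna_us, self.gnap_us, self.gk_us, self.gl_us,
            q1, q2, q3, a, b, m, h, p, s,
            config.spike_threshold, trace, early_exit, abort_step, self.ABORT_MV)

    def run_profile(self, profile: np.ndarray, schedule: np.ndarray,
                    config: SimulationConfig, early_exit: bool = True,
                    keep_trace: bool = False):
        """Hot path: extracellular potential at step j is
        ``schedule[j] * profile``.  Returns (activated, trace|None)."""
        a, b, m, h, p, s = self.resting_state(config)
        n_steps = schedule.size
        trace = np.empty((n_steps + 1, self.node_idx.size))
        dt_ms = config.dt * 1e-3
        if keep_trace:
            abort_step = n_steps + 1   # full trace requested: never truncate
        else:
            nz = np.flatnonzero(schedule)
            stim_end = int(nz[-1]) + 1 if nz.size else 0
            abort_step = stim_end + int(round(self.ABORT_MARGIN_US / config.dt))
        flag = self._run(dt_ms, n_steps, profile, schedule, None,
                         a, b, m, h, p, s, config, trace, early_exit, abort_step)
        if flag < 0:
            raise NumericalInstabilityError("membrane potential diverged")
        return bool(flag), (trace if keep_trace else None)

    def run_series(self, ve_series: np.ndarray, config: SimulationConfig):
        """General path: full (n_steps, n_comp) extracellular series."""
        a, b, m, h, p, s = self.resting_state(config)
        n_steps = ve_series.shape[0]
        trace = np.empty((n_steps + 1, self.node_idx.size))
        dt_ms = config.dt * 1e-3
        flag = self._run(dt_ms, n_steps, np.zeros(self.geometry.n_compartments),
                         np.zeros(0), ve_series, a, b, m, h, p, s, config,
                         trace, early_exit=False, abort_step=n_steps + 1)
        if flag < 0:
            raise NumericalInstabilityError("membrane potential diverged")
        times = np.arange(n_steps + 1) * config.dt
        return MembraneTrace(times, trace, bool(flag), config.spike_threshold)


_system_cache: dict[float, CableSystem] = {}


def get_system(fiber_diameter: float) -> CableSystem:
    """Shared, memoized CableSystem per fiber diameter."""
    if fiber_diameter not in _system_cache:
        _system_cache[fiber_diameter] = CableSystem(build_axon(fiber_diameter))
    return _system_cache[fiber_diameter]


def stimulus_schedule(waveform: StimulusWaveform, config: SimulationConfig) -> np.ndarray:
    """Per-step signed current multipliers (µA) on the solver grid, from
    stimulus onset through the post-stimulus window."""
    dt = config.dt
    for name, w in (("cathodic_width", waveform.cathodic_width),
                    ("onset_time", waveform.onset_time)):
        if abs(round(w / dt) * dt - w) > 1e-9:
            raise ValueError(f"{name}={w} µs must be a multiple of dt={dt} µs")
    t_end = waveform.end_time + config.post_stimulus_time
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps) * dt
    return np.asarray(waveform_current(waveform, times), dtype=float)


def simulate(geometry: FiberGeometry, center_node_position,
             electrodes: Sequence[Electrode],
             waveforms: Sequence[StimulusWaveform],
             rho: Resistivities,
             config: SimulationConfig | None = None) -> MembraneTrace:
    """Simulate one fiber under point-source stimulation.

    The extracellular potential is evaluated at every compartment center
    and applied as the potential outside the myelin (double-cable
    coupling).  Returns the per-node membrane trace; activation means a
    propagating spike exceeded the criterion at the last node.
    """
    from .fields import field_timeseries

    config = config or SimulationConfig()
    coords = place_axon(geometry, center_node_position)
    t_end = max(w.end_time for w in waveforms) + config.post_stimulus_time
    ve = field_timeseries(coords, electrodes, waveforms, rho, config.dt, t_end)
    system = get_system(geometry.fiber_diameter)
    return system.run_series(ve, config)
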