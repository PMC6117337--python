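"""Extracellular potentials of point-source electrodes and stimulus waveforms.

The tissue is an infinite, homogeneous, anisotropic volume conductor.  A
point source carrying current ``I`` (µA) produces, at displacement
``(Δx, Δy, Δz)`` (µm) from the electrode, the potential

    V(mV) = 10 · sqrt(ρx ρy ρz) · I / (4π · sqrt(ρx Δx² + ρy Δy² + ρz Δz²))

with resistivities in Ω·cm.  The factor 10 converts the µA/µm/Ω·cm unit
system to mV.  Axes follow the nerve convention used throughout this
package: x = transverse, y = depth, z = longitudinal (axons run along z).

Stimuli are charge-balanced biphasic pulses: a cathodic (negative) phase
followed immediately by an anodic phase of half the amplitude and twice the
duration.  Reported amplitudes are always the cathodic magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Resistivities",
    "Electrode",
    "StimulusWaveform",
    "potential_at",
    "superpose",
    "waveform_current",
    "field_timeseries",
]


@dataclass(frozen=True)
class Resistivities:
    """Tissue resistivities in Ω·cm along the transverse (x), depth (y) and
    longitudinal (z) axes.  Defaults are the dorsal-column-derived values
    used for peripheral nerve: 1211 Ω·cm transverse/depth, 175 Ω·cm
    longitudinal."""

    rho_x: float = 1211.0
    rho_y: float = 1211.0
    rho_z: float = 175.0

    def __post_init__(self) -> None:
        for name in ("rho_x", "rho_y", "rho_z"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_x, self.rho_y, self.rho_z], dtype=float)


@dataclass(frozen=True)
class Electrode:
    """Point-source electrode at ``position`` (µm, lab frame)."""

    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        pos = tuple(float(c) for c in self.position)
        if len(pos) != 3 or not all(np.isfinite(pos)):
            raise ValueError(f"electrode position must be 3 finite coords, got {self.position}")
        object.__setattr__(self, "position", pos)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class StimulusWaveform:
    """Charge-balanced biphasic pulse.

    ``cathodic_amplitude`` is the magnitude (µA, > 0) of the leading
    cathodic phase of width ``cathodic_width`` (µs).  The anodic phase has
    half the amplitude and twice the width and starts exactly when the
    cathodic phase ends, so the net charge is zero.  ``onset_time`` shifts
    the whole pulse (µs); phases are half-open ``[start, end)`` intervals.
    """

    cathodic_amplitude: float
    cathodic_width: float = 200.0
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.cathodic_amplitude < 0:
            raise ValueError("cathodic_amplitude is a magnitude and must be >= 0")
        if self.cathodic_width <= 0:
            raise ValueError("cathodic_width must be positive")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")

    @property
    def anodic_amplitude(self) -> float:
        return self.cathodic_amplitude / 2.0

    @property
    def anodic_width(self) -> float:
        return 2.0 * self.cathodic_width

    @property
    def end_time(self) -> float:
        """Time (µs) at which the anodic phase ends."""
        return self.onset_time + self.cathodic_width + self.anodic_width

    def total_charge(self) -> float:
        """Net delivered charge in µA·µs (zero by construction)."""
        return (-self.cathodic_amplitude * self.cathodic_width
                + self.anodic_amplitude * self.anodic_width)

    def with_amplitude(self, amplitude: float) -> "StimulusWaveform":
        return StimulusWaveform(amplitude, self.cathodic_width, self.onset_time)


def _check_rho(rho: Resistivities) -> Resistivities:
    if not isinstance(rho, Resistivities):
        rho = Resistivities(*rho)
    return rho


def potential_at(point, electrode: Electrode, i_stim: float,
                 rho: Resistivities) -> float | np.ndarray:
    """Potential (mV) at ``point`` (µm) from a point source carrying signed
    current ``i_stim`` (µA; cathodic phases are negative).

    ``point`` may be a single 3-vector or an (N, 3) array.  Raises
    ``ZeroDivisionError`` if a point coincides with the electrode.
    """
    rho = _check_rho(rho)
    p = np.asarray(point, dtype=float)
    d = p - electrode.as_array()
    w = rho.as_array()
    denom_sq = (w * d * d).sum(axis=-1)
    if np.any(denom_sq == 0.0):
        raise ZeroDivisionError("potential requested at the electrode position (zero distance)")
    num = 10.0 * np.sqrt(rho.rho_x * rho.rho_y * rho.rho_z) * i_stim
    out = num / (4.0 * np.pi * np.sqrt(denom_sq))
    return float(out) if out.ndim == 0 else out


def superpose(point, electrodes_with_currents: Sequence[tuple[Electrode, float]],
              rho: Resistivities) -> float | np.ndarray:
    """Summed potential (mV) from several point sources (linear medium)."""
    if len(electrodes_with_currents) == 0:
        raise ValueError("need at least one electrode")
    total = None
    for elec, cur in electrodes_with_currents:
        v = potential_at(point, elec, cur, rho)
        total = v if total is None else total + v
    return total


def waveform_current(waveform: StimulusWaveform, t) -> float | np.ndarray:
    """Signed current (µA) of ``waveform`` at time(s) ``t`` (µs).

    Negative during the cathodic phase, +amplitude/2 during the anodic
    phase, zero elsewhere; phase membership uses half-open intervals.
    """
    t = np.asarray(t, dtype=float)
    c0 = waveform.onset_time
    c1 = c0 + waveform.cathodic_width
    a1 = c1 + waveform.anodic_width
    out = np.zeros_like(t)
    out = np.where((t >= c0) & (t < c1), -waveform.cathodic_amplitude, out)
    out = np.where((t >= c1) & (t < a1), waveform.anodic_amplitude, out)
    return float(out) if out.ndim == 0 else out


def field_timeseries(points, electrodes: Sequence[Electrode],
                     waveforms: Sequence[StimulusWaveform],
                     rho: Resistivities, dt: float, t_end: float) -> np.ndarray:
    """Extracellular potential (mV) at each point for each solver step.

    Returns an array of shape ``(n_steps, n_points)`` where row ``i`` holds
    the potentials during ``[i·dt, (i+1)·dt)``; the piecewise-constant
    stimulus is sampled at the left edge of each step.  One waveform per
    electrode is required.
    """
    if len(electrodes) != len(waveforms):
        raise ValueError("need exactly one waveform per electrode")
    if dt <= 0:
        raise ValueError("dt must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    times = np.arange(0.0, t_end, dt)
    out = np.zeros((times.size, pts.shape[0]))
    # spatial pattern per electrode is fixed; time course scales it linearly
    for elec, wf in zip(electrodes, waveforms):
        unit = potential_at(pts, elec, 1.0, rho)          # mV per µA
        cur = waveform_current(wf, times)                  # µA, signed
        out += np.outer(np.atleast_1d(cur), unit)
    return out
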