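"""Threshold search and 3D threshold maps.

The recruitment threshold of a fiber at a given center-node location is
the smallest cathodic amplitude that elicits a propagating action
potential.  Thresholds are quantized to the search accuracy (0.1 µA by
default) and found by bisection on that integer lattice, which makes the
result a canonical quantity — the smallest activating multiple of the
accuracy — independent of how the bracket was initialized.  Grids of
thresholds over center-node positions form :class:`ThresholdField` objects
consumed by the activation-volume and population stages.

Two exact accelerations are used (both correctness-neutral and covered by
tests):

* **Field-equivalence memoization.**  The extracellular drive along the
  fiber depends on each electrode only through (q, Δz) with
  q = ρx·Δx² + ρy·Δy², so positions sharing that multiset share one
  simulation.  A mirror-symmetric fiber makes the z-reflected multiset
  equivalent as well.
* **Warm starting.**  Neighboring grid points predict a narrow bracket;
  the bracket ends are verified by simulation and the search falls back
  to the full range whenever the prediction is wrong.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .cable import CableSystem, SimulationConfig, get_system, stimulus_schedule
from .fields import Electrode, Resistivities, StimulusWaveform

__all__ = [
    "SearchSettings",
    "ThresholdField",
    "ThresholdEngine",
    "find_threshold",
    "asynchronous_threshold",
    "compute_threshold_grid",
    "NOT_RECRUITED",
]

NOT_RECRUITED = np.nan   # sentinel for "no activation within the bracket"


class BracketAnomalyError(RuntimeError):
    """Activation at the low bracket but not the high one — signals a
    non-monotone response (solver instability)."""


@dataclass(frozen=True)
class SearchSettings:
    """Bisection settings: thresholds are resolved to ``accuracy`` (µA)
    within [amplitude_min, amplitude_max]."""

    accuracy: float = 0.1
    amplitude_min: float = 0.0
    amplitude_max: float = 30.0
    warm_margin: float = 0.6     # µA half-width of warm-started brackets

    def __post_init__(self) -> None:
        if self.accuracy <= 0:
            raise ValueError("accuracy must be positive")
        if not self.amplitude_min < self.amplitude_max:
            raise ValueError("amplitude bracket must have min < max")

    @property
    def max_units(self) -> int:
        return int(round(self.amplitude_max / self.accuracy))


@dataclass
class ThresholdField:
    """Thresholds (µA) on a uniform 3D grid of center-node positions.

    ``values[i, j, k]`` corresponds to position ``origin + step*(i, j, k)``
    (x, y, z order).  ``NaN`` marks positions not recruited within the
    searched amplitude range.  ``z_period`` is set when the grid's z knots
    cover exactly one internodal length half-open (interpolation wraps
    across the seam), in which case the field is its own longitudinal fold.
    """

    origin: np.ndarray            # (3,) µm
    step: np.ndarray              # (3,) µm
    values: np.ndarray            # (nx, ny, nz) µA
    condition: str                # "single:<k>" or "sync:<i>,<j>,…"
    fiber_diameter: float
    cathodic_width: float         # µs
    rho: Resistivities
    electrodes: tuple[tuple[float, float, float], ...] = ()
    z_period: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.step = np.broadcast_to(np.asarray(self.step, dtype=float), (3,)).copy()
        if np.any(self.step <= 0):
            raise ValueError("grid step must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[i] + self.step[i] * np.arange(self.values.shape[i])
                     for i in range(3))

    def compatible(self, other: "ThresholdField") -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.origin, other.origin)
                and np.allclose(self.step, other.step)
                and self.fiber_diameter == other.fiber_diameter
                and self.cathodic_width == other.cathodic_width)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write values to ``<path>.npz`` with a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values)
        meta = dict(origin=self.origin.tolist(), step=self.step.tolist(),
                    condition=self.condition, fiber_diameter=self.fiber_diameter,
                    cathodic_width=self.cathodic_width,
                    rho=[self.rho.rho_x, self.rho.rho_y, self.rho.rho_z],
                    electrodes=[list(e) for e in self.electrodes],
                    z_period=self.z_period)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ThresholdField":
        path = Path(path)
        values = np.load(path.with_suffix(".npz"))["values"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(origin=np.array(meta["origin"]), step=np.array(meta["step"]),
                   values=values, condition=meta["condition"],
                   fiber_diameter=meta["fiber_diameter"],
                   cathodic_width=meta["cathodic_width"],
                   rho=Resistivities(*meta["rho"]),
                   electrodes=tuple(tuple(e) for e in meta["electrodes"]),
                   z_period=meta["z_period"])


def asynchronous_threshold(fields: Sequence[ThresholdField]) -> ThresholdField:
    """Pointwise minimum over single-electrode fields: the asynchronous
    threshold at a location is the lower of the per-electrode thresholds.
    NaN (not recruited) survives only where every input is NaN."""
    if len(fields) == 0:
        raise ValueError("need at least one field")
    first = fields[0]
    for f in fields[1:]:
        if not first.compatible(f):
            raise ValueError("threshold fields are on different grids")
    stack = np.stack([f.values for f in fields])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        vals = np.nanmin(stack, axis=0)
    elecs = tuple(e for f in fields for e in f.electrodes)
    labels = ",".join(f.condition.split(":", 1)[1] for f in fields)
    return replace(first, values=vals, condition=f"async:{labels}",
                   electrodes=elecs)


class ThresholdEngine:
    """Bisection threshold solver for one (fiber, waveform, tissue)
    configuration, with exact memoization across equivalent geometries."""

    def __init__(self, fiber_diameter: float,
                 waveform: StimulusWaveform | None = None,
                 rho: Resistivities | None = None,
                 config: SimulationConfig | None = None,
                 settings: SearchSettings | None = None,
                 use_z_reflection: bool = True,
                 use_memo: bool = True):
        self.system: CableSystem = get_system(fiber_diameter)
        self.waveform = (waveform or StimulusWaveform(1.0)).with_amplitude(1.0)
        self.rho = rho or Resistivities()
        self.config = config or SimulationConfig()
        self.settings = settings or SearchSettings()
        self.use_z_reflection = use_z_reflection
        self.use_memo = use_memo
        self._schedule = stimulus_schedule(self.waveform, self.config)
        self._memo: dict[tuple, float] = {}
        self.n_simulations = 0
        # constants of the potential formula
        r = self.rho
        self._vnum = 10.0 * np.sqrt(r.rho_x * r.rho_y * r.rho_z) / (4.0 * np.pi)

    # -- geometry canonicalization ---------------------------------------
    def _key(self, position, electrodes: Sequence[Electrode]) -> tuple:
        """Canonical invariant of the extracellular drive: sorted multiset
        of per-electrode (q, Δz), reduced under z-reflection."""
        p = np.asarray(position, dtype=float)
        r = self.rho
        items = []
        for e in electrodes:
            d = p - e.as_array()
            q = r.rho_x * d[0] ** 2 + r.rho_y * d[1] ** 2
            items.append((round(q, 3), round(d[2], 6)))
        fwd = tuple(sorted(items))
        if not self.use_z_reflection:
            return fwd
        rev = tuple(sorted((q, -dz) for q, dz in items))
        return min(fwd, rev)

    def _profile(self, key: tuple) -> np.ndarray:
        """Unit-current extracellular potential (mV/µA) at each compartment
        for the canonical geometry ``key``."""
        zoff = self.system.geometry.z_offsets
        prof = np.zeros_like(zoff)
        rz = self.rho.rho_z
        # sub-µm electrode–compartment distances are clamped to a 1 µm
        # electrical distance: the point-source potential is singular there
        # and such positions are recruited at the lowest amplitudes anyway
        eps = min(self.rho.rho_x, self.rho.rho_y, rz) * 1.0
        for q, dz in key:
            d2 = q + rz * (zoff + dz) ** 2
            prof += self._vnum / np.sqrt(np.maximum(d2, eps))
        return prof

    def _activates(self, profile: np.ndarray, amplitude: float) -> bool:
        self.n_simulations += 1
        act, _ = self.system.run_profile(profile, amplitude * self._schedule,
                                         self.config)
        return act

    # -- search ------------------------------------------------------------
    def threshold_at(self, position, electrodes: Sequence[Electrode],
                     predicted: float | None = None) -> float:
        """Threshold (µA) at ``position`` for the active electrode set (all
        driven by the same waveform at equal amplitude).  Returns NaN when
        the top of the amplitude bracket fails to recruit."""
        key = self._key(position, electrodes)
        if self.use_memo and key in self._memo:
            return self._memo[key]
        out = self._search(self._profile(key), predicted)
        if self.use_memo:
            self._memo[key] = out
        return out

    def _search(self, profile: np.ndarray, predicted: float | None) -> float:
        acc = self.settings.accuracy
        hi_max = self.settings.max_units
        lo, hi = 0, None            # lo always inactive; amplitude 0 never fires

        if predicted is not None and np.isfinite(predicted):
            m = self.settings.warm_margin
            lo_w = max(0, int(np.floor((predicted - m) / acc)))
            hi_w = min(hi_max, int(np.ceil((predicted + m) / acc)))
            if hi_w > lo_w:
                if self._activates(profile, hi_w * acc):
                    hi = hi_w
                    if lo_w > 0:
                        if self._activates(profile, lo_w * acc):
                            hi, lo = lo_w, 0   # prediction high; keep verified top
                        else:
                            lo = lo_w
                else:
                    lo = hi_w               # prediction low; verified inactive
        if hi is None:
            if not self._activates(profile, hi_max * acc):
                return NOT_RECRUITED
            hi = hi_max
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if self._activates(profile, mid * acc):
                hi = mid
            else:
                lo = mid
        return hi * acc

    # -- grids --------------------------------------------------------------
    def grid(self, origin, shape, step, electrodes: Sequence[Electrode],
             condition: str | None = None, warm_start: bool = True,
             z_period: float | None = None,
             progress: bool = False) -> ThresholdField:
        """Threshold field over ``shape`` grid points from ``origin`` with
        spacing ``step``.  Warm starts use the previously solved z-neighbor
        (then y-, then x-neighbor); results are identical with warm start
        on or off because the bisection lattice is absolute."""
        origin = np.asarray(origin, dtype=float)
        step_a = np.broadcast_to(np.asarray(step, dtype=float), (3,))
        nx, ny, nz = shape
        vals = np.full((nx, ny, nz), np.nan)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    pred = None
                    if warm_start:
                        if k > 0:
                            pred = vals[i, j, k - 1]
                        if (pred is None or not np.isfinite(pred)) and j > 0:
                            pred = vals[i, j - 1, k]
                        if (pred is None or not np.isfinite(pred)) and i > 0:
                            pred = vals[i - 1, j, k]
                    pos = origin + step_a * (i, j, k)
                    vals[i, j, k] = self.threshold_at(pos, electrodes, pred)
            if progress:
                print(f"  grid row {i + 1}/{nx} "
                      f"({self.n_simulations} simulations)", flush=True)
        if condition is None:
            idx = ",".join(str(t) for t in range(len(electrodes)))
            condition = f"sync:{idx}" if len(electrodes) > 1 else "single:0"
        return ThresholdField(
            origin=origin, step=step_a.copy(), values=vals, condition=condition,
            fiber_diameter=self.system.geometry.fiber_diameter,
            cathodic_width=self.waveform.cathodic_width, rho=self.rho,
            electrodes=tuple(e.position for e in electrodes),
            z_period=z_period)


def find_threshold(center_node_position, electrodes: Sequence[Electrode],
                   waveform: StimulusWaveform, fiber_diameter: float,
                   rho: Resistivities | None = None,
                   settings: SearchSettings | None = None,
                   config: SimulationConfig | None = None) -> float:
    """One-off threshold search (µA); NaN if not recruited in the bracket."""
    eng = ThresholdEngine(fiber_diameter, waveform, rho, config, settings)
    return eng.threshold_at(center_node_position, electrodes)


def compute_threshold_grid(origin, shape, step,
                           electrodes: Sequence[Electrode],
                           fiber_diameter: float,
                           waveform: StimulusWaveform | None = None,
                           rho: Resistivities | None = None,
                           settings: SearchSettings | None = None,
                           config: SimulationConfig | None = None,
                           condition: str | None = None,
                           warm_start: bool = True,
                           z_period: float | None = None) -> ThresholdField:
    """Convenience wrapper building a fresh engine and computing one grid."""
    eng = ThresholdEngine(fiber_diameter, waveform, rho, config, settings)
    return eng.grid(origin, shape, step, electrodes, condition=condition,
                    warm_start=warm_start, z_period=z_period)
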