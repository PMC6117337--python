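"""Parameter sweeps over electrode-pair stimulation configurations.

Each study builds threshold grids for a pair of point-source electrodes
(each electrode alone, and both driven synchronously at equal amplitude),
converts them to activation volumes, and reports the volume ratio
sync/async as a function of stimulus amplitude.  Sweeps vary fiber
diameter, cathodic pulse width, pair spacing/orientation, or tissue
resistivity around that core.

Grid regions are sized automatically: the longitudinal window spans
exactly one internodal length (the field is periodic in the center-node
z to within end effects, and the activation volume is folded to one
period), while transverse/depth extents are grown outward until the
synchronous threshold exceeds the amplitude bracket, guaranteeing
unclipped volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cable import SimulationConfig
from .fields import Electrode, Resistivities, StimulusWaveform
from .mrg import build_axon
from .thresholds import (SearchSettings, ThresholdEngine, ThresholdField,
                         asynchronous_threshold)
from .vta import VolumeRatioCurve, volume_ratio

__all__ = [
    "electrode_pair",
    "pair_study",
    "PairStudy",
    "threshold_reduction_study",
    "ThresholdReductionResult",
    "run_diameter_sweep",
    "run_pulse_width_sweep",
    "run_spacing_sweep",
    "run_resistivity_sensitivity",
    "run_branner_prediction",
    "ratio_at_async_volume",
    "period_z_step",
    "get_engine",
    "GridCache",
]

SLANT_DEPTH_RATIO = 0.25   # depth offset per unit longitudinal offset

_engine_cache: dict[tuple, ThresholdEngine] = {}


def get_engine(fiber_diameter: float, cathodic_width: float = 200.0,
               rho: Resistivities | None = None,
               settings: SearchSettings | None = None,
               config: SimulationConfig | None = None) -> ThresholdEngine:
    """Shared engines so studies with common configurations reuse every
    previously solved threshold (exact memoization)."""
    rho = rho or Resistivities()
    settings = settings or SearchSettings()
    config = config or SimulationConfig()
    key = (fiber_diameter, cathodic_width, rho.rho_x, rho.rho_y, rho.rho_z,
           settings.accuracy, settings.amplitude_max, config.dt,
           config.temperature)
    if key not in _engine_cache:
        _engine_cache[key] = ThresholdEngine(
            fiber_diameter, StimulusWaveform(1.0, cathodic_width), rho,
            config, settings)
    return _engine_cache[key]


def electrode_pair(axis: str, spacing: float,
                   slant_depth_ratio: float = SLANT_DEPTH_RATIO
                   ) -> tuple[Electrode, Electrode]:
    """Electrode pair with the first at the origin and the second offset
    ``spacing`` µm along ``axis`` ('longitudinal', 'transverse', or
    'slant': a combined depth+longitudinal offset mimicking a slanted
    penetrating array, depth = slant_depth_ratio × longitudinal)."""
    if axis == "longitudinal":
        off = (0.0, 0.0, spacing)
    elif axis == "transverse":
        off = (spacing, 0.0, 0.0)
    elif axis == "slant":
        off = (0.0, slant_depth_ratio * spacing, spacing)
    else:
        raise ValueError(f"unknown pairing axis {axis!r}")
    return Electrode((0.0, 0.0, 0.0)), Electrode(off)


def period_z_step(L: float, target: float) -> float:
    """Integer-µm divisor of the internodal length closest to the
    requested step, so one period is an integer number of integer-µm
    cells and 1 µm upsampling stays exact."""
    best = None
    for n in range(1, int(L) + 1):
        s = L / n
        if abs(s - round(s)) < 1e-9:
            s = round(s)
            if best is None or abs(s - target) < abs(best - target):
                best = s
    return float(best)


@dataclass
class PairStudy:
    """Threshold fields and volume-ratio curve for one electrode pair."""

    fields: dict[str, ThresholdField]
    curve: VolumeRatioCurve | None
    electrodes: tuple[tuple[float, float, float], ...]
    fiber_diameter: float
    cathodic_width: float
    internodal_length: float
    n_simulations: int
    config_hash: str


def _config_hash(payload: dict) -> str:
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class GridCache:
    """Versioned on-disk store for threshold grids, keyed by a hash of the
    full configuration."""

    VERSION = 1

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    def get_or_compute(self, key: dict, compute) -> ThresholdField:
        h = _config_hash({**key, "version": self.VERSION})
        base = self.dir / f"grid_{h}"
        if base.with_suffix(".npz").exists():
            return ThresholdField.load(base)
        f = compute()
        f.save(base)
        return f


def _snap_out(value: float, origin: float, step: float, up: bool) -> float:
    k = (value - origin) / step
    k = np.ceil(k) if up else np.floor(k)
    return origin + k * step


def _transverse_extent(engine: ThresholdEngine, electrodes, axis: int,
                       probe_step: float, margin: float) -> tuple[float, float]:
    """Grow the grid along transverse/depth ``axis`` (0=x, 1=y) until the
    synchronous threshold leaves the amplitude bracket."""
    los, his = [], []
    for e in electrodes:
        base = np.asarray(e.position, dtype=float)
        for sign in (-1.0, 1.0):
            d = probe_step
            while True:
                p = base.copy()
                p[axis] += sign * d
                th = engine.threshold_at(p, list(electrodes))
                if np.isnan(th):
                    break
                d += probe_step
                if d > 20000:
                    raise RuntimeError("activation region exceeds 2 cm; "
                                       "check configuration")
            (los if sign < 0 else his).append(base[axis] + sign * (d + margin))
    return min(los), max(his)


def pair_study(fiber_diameter: float, offset, *,
               cathodic_width: float = 200.0,
               rho: Resistivities | None = None,
               step: float = 40.0,
               amplitudes=None,
               settings: SearchSettings | None = None,
               config: SimulationConfig | None = None,
               slice_2d: bool = False,
               probe_step: float = 100.0,
               engine: ThresholdEngine | None = None,
               cache: GridCache | None = None,
               progress: bool = False) -> PairStudy:
    """Full sync/async comparison for a pair of electrodes: one at the
    origin, the second displaced by ``offset`` (µm).

    ``slice_2d`` restricts the grid to the electrode depth plane (y of
    both electrodes, which must agree) — used for threshold-reduction maps
    and quick looks; volume curves require the full 3D grid.
    """
    offset = tuple(float(v) for v in offset)
    e1 = Electrode((0.0, 0.0, 0.0))
    e2 = Electrode(offset)
    rho = rho or Resistivities()
    settings = settings or SearchSettings()
    config = config or SimulationConfig()
    if amplitudes is None:
        amplitudes = np.arange(1.0, settings.amplitude_max + 0.5, 1.0)
    eng = engine or get_engine(fiber_diameter, cathodic_width, rho, settings, config)
    geom = build_axon(fiber_diameter)
    L = geom.internodal_length
    stepz = period_z_step(L, step)
    nz = int(round(L / stepz))
    zmid = (e1.position[2] + e2.position[2]) / 2.0
    z0 = zmid - L / 2.0

    margin = step
    xlo, xhi = _transverse_extent(eng, (e1, e2), 0, probe_step, margin)
    xlo = _snap_out(xlo, 0.0, step, up=False)
    xhi = _snap_out(xhi, 0.0, step, up=True)
    nx = int(round((xhi - xlo) / step)) + 1
    if slice_2d:
        if abs(e1.position[1] - e2.position[1]) > 1e-9:
            raise ValueError("2D slice mode needs both electrodes at one depth")
        ylo, ny = e1.position[1], 1
    else:
        ylo, yhi = _transverse_extent(eng, (e1, e2), 1, probe_step, margin)
        ylo = _snap_out(ylo, 0.0, step, up=False)
        yhi = _snap_out(yhi, 0.0, step, up=True)
        ny = int(round((yhi - ylo) / step)) + 1

    origin = (xlo, ylo, z0)
    shape = (nx, ny, nz)
    gstep = (step, step, stepz)
    meta = dict(fiber=fiber_diameter, width=cathodic_width,
                rho=[rho.rho_x, rho.rho_y, rho.rho_z], offset=list(offset),
                origin=[float(v) for v in origin], shape=list(shape),
                step=list(gstep), accuracy=settings.accuracy,
                amax=settings.amplitude_max, dt=config.dt, slice2d=slice_2d)
    h = _config_hash(meta)

    def build(cond_name, elecs, cond_label):
        def compute():
            if progress:
                print(f"[{h}] grid {cond_name} shape={shape}", flush=True)
            return eng.grid(origin, shape, gstep, elecs, condition=cond_label,
                            z_period=L, progress=progress)
        if cache is not None:
            return cache.get_or_compute({**meta, "cond": cond_name}, compute)
        return compute()

    f1 = build("single0", [e1], "single:0")
    f2 = build("single1", [e2], "single:1")
    fsync = build("sync", [e1, e2], "sync:0,1")
    fasync = asynchronous_threshold([f1, f2])
    fields = {"single0": f1, "single1": f2, "sync": fsync, "async": fasync}
    curve = None
    if not slice_2d:
        curve = volume_ratio(fsync, [f1, f2], amplitudes, L=L)
    return PairStudy(fields=fields, curve=curve,
                     electrodes=(e1.position, e2.position),
                     fiber_diameter=fiber_diameter,
                     cathodic_width=cathodic_width, internodal_length=L,
                     n_simulations=eng.n_simulations, config_hash=h)


@dataclass
class ThresholdReductionResult:
    """Percent threshold reduction sync vs async over the mapped plane."""

    median_pct: float
    reductions_pct: np.ndarray
    study: PairStudy


def threshold_reduction_study(fiber_diameter: float = 10.0,
                              axis: str = "longitudinal",
                              spacing: float = 400.0,
                              step: float = 40.0,
                              **kwargs) -> ThresholdReductionResult:
    """Median percent reduction in threshold, 100·(async − sync)/async,
    over the 2D slice at electrode depth (mapped points: positions
    recruited asynchronously within the amplitude bracket)."""
    _, e2 = electrode_pair(axis, spacing)
    st = pair_study(fiber_diameter, e2.position, step=step, slice_2d=True,
                    **kwargs)
    a = st.fields["async"].values
    s = st.fields["sync"].values
    # sync dominance makes sync finite wherever async is; the joint mask
    # guards the median against any stray sentinel
    mask = np.isfinite(a) & np.isfinite(s)
    red = 100.0 * (a[mask] - s[mask]) / a[mask]
    return ThresholdReductionResult(float(np.median(red)), red, st)


def _records(study: PairStudy, **extra) -> list[dict]:
    c = study.curve
    rows = []
    for i, a in enumerate(c.amplitudes):
        rows.append(dict(amplitude=float(a),
                         sync_volume=float(c.sync_volumes[i]),
                         async_volume=float(c.async_volumes[i]),
                         ratio=float(c.ratios[i]),
                         fiber_diameter=study.fiber_diameter,
                         cathodic_width=study.cathodic_width,
                         config_hash=study.config_hash, **extra))
    return rows


def run_diameter_sweep(diameters: Sequence[float] = (5.7, 10.0, 15.0),
                       pairings: Sequence[str] = ("longitudinal", "transverse"),
                       spacing: float = 400.0, **kwargs) -> pd.DataFrame:
    """Volume-ratio curves per fiber diameter and pairing orientation."""
    rows = []
    for axis in pairings:
        _, e2 = electrode_pair(axis, spacing)
        for d in diameters:
            st = pair_study(d, e2.position, **kwargs)
            rows += _records(st, varied="diameter", value=d, pairing=axis,
                             spacing=spacing)
    return pd.DataFrame(rows)


def run_pulse_width_sweep(widths: Sequence[float] = (50.0, 100.0, 200.0, 400.0),
                          fiber_diameter: float = 15.0,
                          pairings: Sequence[str] = ("longitudinal", "transverse"),
                          spacing: float = 400.0, **kwargs) -> pd.DataFrame:
    """Volume-ratio curves per cathodic pulse width.  Ratios should be
    compared at matched asynchronous volume (the stimulation-strength
    proxy), not at matched amplitude — see :func:`ratio_at_async_volume`."""
    rows = []
    for axis in pairings:
        _, e2 = electrode_pair(axis, spacing)
        for w in widths:
            st = pair_study(fiber_diameter, e2.position, cathodic_width=w,
                            **kwargs)
            rows += _records(st, varied="pulse_width", value=w, pairing=axis,
                             spacing=spacing)
    return pd.DataFrame(rows)


def ratio_at_async_volume(curve: VolumeRatioCurve, volumes) -> np.ndarray:
    """Interpolate the volume ratio as a function of asynchronous volume
    (the async volume grows monotonically with amplitude)."""
    ok = (curve.async_volumes > 0) & np.isfinite(curve.ratios)
    v = curve.async_volumes[ok]
    r = curve.ratios[ok]
    order = np.argsort(v)
    return np.interp(np.asarray(volumes, dtype=float), v[order], r[order],
                     left=np.nan, right=np.nan)


def run_spacing_sweep(axis: str = "longitudinal",
                      spacings: Sequence[float] = tuple(range(200, 1601, 200)),
                      fiber_diameter: float = 15.0, **kwargs) -> pd.DataFrame:
    """Volume-ratio curves vs pair spacing along one axis."""
    rows = []
    for s in spacings:
        _, e2 = electrode_pair(axis, float(s))
        st = pair_study(fiber_diameter, e2.position, **kwargs)
        rows += _records(st, varied="spacing", value=float(s), pairing=axis,
                         spacing=float(s))
    return pd.DataFrame(rows)


def run_resistivity_sensitivity(delta: float = 100.0,
                                fiber_diameter: float = 15.0,
                                pairings: Sequence[str] = ("longitudinal", "transverse"),
                                spacing: float = 400.0, **kwargs) -> pd.DataFrame:
    """Ratio curves under ±delta Ω·cm perturbations of the longitudinal or
    transverse resistivity (the other held at its default)."""
    base = Resistivities()
    variants = {
        "default": base,
        "rho_z-": Resistivities(base.rho_x, base.rho_y, base.rho_z - delta),
        "rho_z+": Resistivities(base.rho_x, base.rho_y, base.rho_z + delta),
        "rho_t-": Resistivities(base.rho_x - delta, base.rho_y - delta, base.rho_z),
        "rho_t+": Resistivities(base.rho_x + delta, base.rho_y + delta, base.rho_z),
    }
    rows = []
    for axis in pairings:
        _, e2 = electrode_pair(axis, spacing)
        for name, rho in variants.items():
            st = pair_study(fiber_diameter, e2.position, rho=rho, **kwargs)
            rows += _records(st, varied="resistivity", value=name, pairing=axis,
                             spacing=spacing)
    return pd.DataFrame(rows)


def grid_interpolation_error(fiber_diameter: float = 10.0,
                             grid_step: float = 20.0,
                             n_points: int = 30,
                             seed: int = 0,
                             region=((60.0, 280.0), (-100.0, 100.0), (-200.0, 200.0)),
                             cathodic_width: float = 200.0,
                             rho: Resistivities | None = None,
                             settings: SearchSettings | None = None,
                             config: SimulationConfig | None = None) -> dict:
    """Accuracy of the threshold lookup table: build a grid at
    ``grid_step`` near a single electrode at the origin, then compare
    trilinear interpolation against directly simulated thresholds at
    random off-grid positions.  Returns the mean/max absolute error (µA).
    """
    from scipy.interpolate import RegularGridInterpolator

    eng = get_engine(fiber_diameter, cathodic_width, rho, settings, config)
    e = Electrode((0.0, 0.0, 0.0))
    region = np.asarray(region, dtype=float)
    origin = region[:, 0]
    shape = tuple(int(round((hi - lo) / grid_step)) + 1 for lo, hi in region)
    f = eng.grid(origin, shape, grid_step, [e])
    if np.isnan(f.values).any():
        raise RuntimeError("lookup-table region contains unrecruited points; "
                           "shrink the region or raise the amplitude bracket")
    interp = RegularGridInterpolator(f.axes(), f.values)

    rng = np.random.default_rng(seed)
    pts = rng.uniform(region[:, 0], region[:, 1], size=(n_points, 3))
    direct = np.array([eng.threshold_at(p, [e]) for p in pts])
    predicted = interp(pts)
    err = np.abs(predicted - direct)
    return {"mean_abs_error": float(err.mean()),
            "max_abs_error": float(err.max()),
            "n_points": n_points,
            "direct": direct, "interpolated": predicted, "points": pts}


def run_branner_prediction(step: float = 40.0, amplitudes=None,
                           **kwargs) -> dict:
    """Volume-ratio curve for 14 µm fibers and electrodes offset by
    (400, 200, 800) µm along (transverse, depth, longitudinal) — the
    published microelectrode-array geometry — and its maximum."""
    st = pair_study(14.0, (400.0, 200.0, 800.0), step=step,
                    amplitudes=amplitudes, **kwargs)
    return {"study": st, "curve": st.curve, "max_ratio": st.curve.max_ratio()}
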