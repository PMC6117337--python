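"""Randomly placed axon populations and neuron-recruitment ratios.

The geometric volume ratio has a population counterpart: place identical
fibers uniformly at random in a box around the electrodes, mark each as
recruited when the (folded) threshold field at its center-node position
does not exceed the stimulus amplitude, and form the ratio of counts
recruited synchronously vs asynchronously.  Across many random
populations the mean neuron ratio estimates the volume ratio until
saturation (every fiber recruited) pulls it down.

The default configuration is 2038 fibers of 14 µm diameter in an
800 × 800 × 1400 µm box (one internodal length along z, so each axon
contributes exactly one center-node per period); the population count is
configurable, and statistical tests run at a few hundred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mrg import internodal_length
from .thresholds import ThresholdField, asynchronous_threshold

__all__ = [
    "NeuronPopulation",
    "RecruitmentSummary",
    "generate_population",
    "recruited",
    "neuron_ratio_distribution",
    "DEFAULT_BOX",
    "DEFAULT_N_AXONS",
]

DEFAULT_BOX = (800.0, 800.0, 1400.0)   # µm (transverse, depth, longitudinal)
DEFAULT_N_AXONS = 2038


@dataclass
class NeuronPopulation:
    """Center-node positions (n, 3) µm of identical-diameter fibers placed
    uniformly in a box centered on ``center``."""

    positions: np.ndarray
    fiber_diameter: float
    box: tuple[float, float, float]
    seed: int
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n(self) -> int:
        return self.positions.shape[0]


def generate_population(n: int, box, fiber_diameter: float, seed: int,
                        center=(0.0, 0.0, 0.0)) -> NeuronPopulation:
    """Uniform random center-node positions in ``center ± box/2``."""
    if n <= 0:
        raise ValueError("population size must be positive")
    box = tuple(float(b) for b in box)
    if any(b <= 0 for b in box):
        raise ValueError("box extents must be positive")
    rng = np.random.default_rng(seed)
    half = np.asarray(box) / 2.0
    c = np.asarray(center, dtype=float)
    pos = rng.uniform(c - half, c + half, size=(n, 3))
    return NeuronPopulation(pos, fiber_diameter, box, seed, tuple(c))


def _interpolate_folded(field: ThresholdField, positions: np.ndarray,
                        L: float) -> np.ndarray:
    """Trilinear interpolation of the folded field at (x, y, z mod L).

    z wraps periodically for one-period fields; x/y outside the grid raise
    a coverage error.  NaN cells (not recruited) propagate."""
    v = field.values
    nx, ny, nz = v.shape
    o, s = field.origin, field.step
    fx = (positions[:, 0] - o[0]) / s[0]
    fy = (positions[:, 1] - o[1]) / s[1]
    if np.any(fx < -1e-9) or np.any(fx > nx - 1 + 1e-9) \
            or np.any(fy < -1e-9) or np.any(fy > ny - 1 + 1e-9):
        raise ValueError("positions fall outside the folded field coverage")
    if field.z_period is not None:
        if abs(field.z_period - L) > 1e-9:
            raise ValueError("field period disagrees with requested fold length")
        fz = np.mod(positions[:, 2] - o[2], L) / s[2]
        periodic = True
    else:
        extent = s[2] * (nz - 1)
        fz = np.mod(positions[:, 2] - o[2], L) / s[2]
        if np.any(fz > (extent / s[2]) + 1e-9):
            raise ValueError("positions fall outside the folded field coverage")
        periodic = False

    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 2 if nx > 1 else 0)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2 if ny > 1 else 0)
    k0 = np.floor(fz).astype(int)
    tx = fx - i0
    ty = fy - j0
    tz = fz - k0
    if periodic:
        k0 = np.mod(k0, nz)
        k1 = np.mod(k0 + 1, nz)
    else:
        k0 = np.clip(k0, 0, nz - 2 if nz > 1 else 0)
        k1 = np.minimum(k0 + 1, nz - 1)
        tz = fz - k0
    i1 = np.minimum(i0 + 1, nx - 1)
    j1 = np.minimum(j0 + 1, ny - 1)
    if nx == 1:
        tx = np.zeros_like(tx)
    if ny == 1:
        ty = np.zeros_like(ty)

    out = np.zeros(positions.shape[0])
    for di, wi in ((i0, 1 - tx), (i1, tx)):
        for dj, wj in ((j0, 1 - ty), (j1, ty)):
            for dk, wk in ((k0, 1 - tz), (k1, tz)):
                out = out + wi * wj * wk * v[di, dj, dk]
    return out


def recruited(population: NeuronPopulation, field: ThresholdField,
              amplitude: float, L: float | None = None) -> np.ndarray:
    """Boolean per neuron: the folded-field threshold at the neuron's
    center-node position (z taken mod L) is at or below ``amplitude``."""
    if L is None:
        L = internodal_length(population.fiber_diameter)
    th = _interpolate_folded(field, population.positions, L)
    with np.errstate(invalid="ignore"):
        return th <= amplitude


@dataclass
class RecruitmentSummary:
    """Monte-Carlo neuron-ratio statistics across random populations."""

    amplitudes: np.ndarray          # (n_amp,)
    deciles: np.ndarray             # (n_amp, 9): 10%…90% of neuron ratios
    mean_ratio: np.ndarray          # (n_amp,)
    mean_sync_count: np.ndarray
    mean_async_count: np.ndarray
    n_populations: int
    n_excluded: np.ndarray          # per amplitude: populations with async count 0


def neuron_ratio_distribution(n_populations: int, n: int, box,
                              sync_field: ThresholdField,
                              single_fields, amplitudes, seed: int,
                              center=(0.0, 0.0, 0.0),
                              fiber_diameter: float | None = None,
                              L: float | None = None) -> RecruitmentSummary:
    """Deciles and mean of sync/async recruitment-count ratios.

    One top-level ``seed`` deterministically spawns per-population seeds,
    so any single population can be regenerated in isolation.  Amplitude
    cells where a population recruits nothing asynchronously are excluded
    from that amplitude's statistics and reported in ``n_excluded``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    fiber_diameter = fiber_diameter or sync_field.fiber_diameter
    if L is None:
        L = internodal_length(fiber_diameter)
    async_field = asynchronous_threshold(list(single_fields))
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(seed).spawn(n_populations)]

    sync_counts = np.empty((n_populations, amplitudes.size))
    async_counts = np.empty_like(sync_counts)
    for i, cs in enumerate(child_seeds):
        pop = generate_population(n, box, fiber_diameter, cs, center)
        th_sync = _interpolate_folded(sync_field, pop.positions, L)
        th_async = _interpolate_folded(async_field, pop.positions, L)
        with np.errstate(invalid="ignore"):
            sync_counts[i] = (th_sync[:, None] <= amplitudes).sum(axis=0)
            async_counts[i] = (th_async[:, None] <= amplitudes).sum(axis=0)

    ok = async_counts > 0
    ratios = np.where(ok, sync_counts / np.where(ok, async_counts, 1), np.nan)
    qs = np.arange(10, 100, 10)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN amplitude cells
        deciles = np.nanpercentile(ratios, qs, axis=0).T
        mean_ratio = np.nanmean(ratios, axis=0)
    return RecruitmentSummary(
        amplitudes=amplitudes, deciles=deciles, mean_ratio=mean_ratio,
        mean_sync_count=sync_counts.mean(axis=0),
        mean_async_count=async_counts.mean(axis=0),
        n_populations=n_populations,
        n_excluded=(~ok).sum(axis=0))
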