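"""Analytic surrogate threshold fields.

A fast stand-in for the cable model used to exercise the geometry and
statistics stages exhaustively: single-electrode thresholds follow a
classical current–distance law, quadratic in an anisotropy-weighted
distance, so iso-threshold surfaces are ellipsoids and activation volumes
have closed forms.  The synchronous combination adds the reciprocal
"drives" of the electrodes, which keeps the two-electrode condition
analytically tractable.  This is a test fixture with no biophysical
claim; it simply honors the same field contract as simulated grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import Resistivities
from .thresholds import ThresholdField

__all__ = ["SurrogateModel", "surrogate_threshold", "surrogate_grid"]


@dataclass(frozen=True)
class SurrogateModel:
    """Current–distance surrogate: single-electrode threshold
    t_j(p) = offset + k · Σ_axis w_axis (p − e_j)²_axis  (µA, µm²).

    Synchronous thresholds combine reciprocally:
    1/t_sync = Σ_j 1/t_j, so co-located electrodes halve the threshold and
    an infinitely remote second electrode leaves it unchanged.
    """

    k: float = 1e-4                       # µA/µm²
    offset: float = 1.0                   # µA
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    electrodes: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.offset < 0 or any(w <= 0 for w in self.weights):
            raise ValueError("k and anisotropy weights must be positive, offset >= 0")

    def single_threshold(self, points, j: int) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p - np.asarray(self.electrodes[j])
        q = (np.asarray(self.weights) * d * d).sum(axis=-1)
        return self.offset + self.k * q

    def threshold(self, points, condition: str = "async") -> np.ndarray:
        """Threshold (µA) at points for ``condition``: "single:<j>",
        "async" (nearest electrode, i.e. pointwise min) or "sync"."""
        singles = np.stack([self.single_threshold(points, j)
                            for j in range(len(self.electrodes))])
        if condition.startswith("single:"):
            return singles[int(condition.split(":")[1])]
        if condition == "async":
            return singles.min(axis=0)
        if condition == "sync":
            return 1.0 / (1.0 / singles).sum(axis=0)
        raise ValueError(f"unknown condition {condition!r}")


def surrogate_threshold(point, model: SurrogateModel, condition: str = "async") -> float:
    """Scalar surrogate threshold (µA) at one point."""
    return float(model.threshold(np.asarray(point, dtype=float)[None, :], condition)[0])


def surrogate_grid(model: SurrogateModel, origin, shape, step,
                   condition: str = "async", fiber_diameter: float = 14.0,
                   cathodic_width: float = 200.0,
                   rho: Resistivities | None = None,
                   z_period: float | None = None) -> ThresholdField:
    """Exact evaluation of the surrogate on a grid, packaged as a
    :class:`ThresholdField` interchangeable with simulated fields."""
    origin = np.asarray(origin, dtype=float)
    step_a = np.broadcast_to(np.asarray(step, dtype=float), (3,))
    axes = [origin[i] + step_a[i] * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = model.threshold(pts, condition).reshape(shape)
    cond_label = condition if ":" in condition else (
        "sync:" + ",".join(str(i) for i in range(len(model.electrodes)))
        if condition == "sync" else
        "async:" + ",".join(str(i) for i in range(len(model.electrodes))))
    return ThresholdField(origin=origin, step=step_a.copy(), values=vals,
                          condition=cond_label, fiber_diameter=fiber_diameter,
                          cathodic_width=cathodic_width,
                          rho=rho or Resistivities(),
                          electrodes=tuple(model.electrodes),
                          z_period=z_period)
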