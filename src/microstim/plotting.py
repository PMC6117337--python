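"""Plotting helpers: threshold maps, iso-threshold contours, ratio curves."""

from __future__ import annotations

import numpy as np

from .thresholds import ThresholdField

__all__ = ["plot_threshold_slice", "iso_threshold_contours", "plot_ratio_curves"]


def _slice_at_depth(field: ThresholdField, depth: float | None):
    y = field.axes()[1]
    j = 0 if y.size == 1 else int(np.argmin(np.abs(y - (depth or 0.0))))
    return field.values[:, j, :], y[j]


def plot_threshold_slice(field: ThresholdField, depth: float | None = None,
                         ax=None, vmax: float = 25.0, **imshow_kw):
    """Threshold map on the x–z plane at the given depth (color saturated
    above ``vmax`` µA for display, matching common practice)."""
    import matplotlib.pyplot as plt

    sl, y0 = _slice_at_depth(field, depth)
    x, _, z = field.axes()
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(sl, origin="lower", aspect="equal",
                   extent=(z[0], z[-1], x[0], x[-1]), vmin=0.0, vmax=vmax,
                   **imshow_kw)
    ax.set_xlabel("longitudinal z (µm)")
    ax.set_ylabel("transverse x (µm)")
    ax.set_title(f"{field.condition} threshold (µA), depth y={y0:g} µm")
    for ex, ey, ez in field.electrodes:
        if abs(ey - y0) < max(field.step[1], 1.0):
            ax.plot(ez, ex, "wo", mec="k", ms=5)
    plt.colorbar(im, ax=ax, label="threshold (µA)")
    return ax


def iso_threshold_contours(fields, amplitudes=(5.0, 10.0, 15.0),
                           depth: float | None = None, ax=None,
                           linestyles=("solid", "dotted")):
    """Iso-threshold contours at the electrode depth for one or more
    fields (e.g. synchronous solid vs asynchronous dotted)."""
    import matplotlib.pyplot as plt

    if isinstance(fields, ThresholdField):
        fields = [fields]
    if ax is None:
        _, ax = plt.subplots()
    for f, ls in zip(fields, linestyles):
        sl, _ = _slice_at_depth(f, depth)
        x, _, z = f.axes()
        ax.contour(z, x, sl, levels=sorted(amplitudes), linestyles=ls)
    ax.set_xlabel("longitudinal z (µm)")
    ax.set_ylabel("transverse x (µm)")
    return ax


def plot_ratio_curves(df, by: str = "value", ax=None):
    """Volume ratio vs amplitude, one line per swept value, from a sweep
    DataFrame in long format."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for val, grp in df.groupby(by):
        ax.plot(grp["amplitude"], grp["ratio"], label=f"{by}={val}")
    ax.axhline(1.0, color="gray", lw=0.5)
    ax.set_xlabel("amplitude (µA)")
    ax.set_ylabel("volume ratio (sync/async)")
    ax.legend(fontsize="small")
    return ax
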