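"""Quick-look plots for the main result objects (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_trace(trace, ax=None, **kw):
    """Membrane-potential or current trace vs time."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(trace.times, trace.values, lw=0.6, **kw)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(trace.units)
    return ax


def plot_segmentation(trace, seg, ax=None):
    """Trace with nonfiring episodes shaded."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    plot_trace(trace, ax=ax, color="k")
    for ep in seg.nonfiring_episodes:
        ax.axvspan(ep.start, ep.end, color="tab:orange", alpha=0.25, lw=0)
    ax.set_title(f"{seg.cell_class}: {seg.pct_nonfiring:.1f}% nonfiring")
    return ax


def plot_activation_curve(fit, points=None, ax=None):
    """Boltzmann fit with optional data points."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    if points is not None:
        ax.plot(points.iloc[:, 0], points.iloc[:, 1], "o", ms=4, color="k")
    vm = np.linspace(-150.0, -20.0, 300)
    ax.plot(vm, fit.predict(vm), color="tab:red",
            label=f"V0.5 = {fit.v05:.1f} mV, k = {fit.k:.1f} mV")
    ax.set_xlabel("membrane potential (mV)")
    ax.set_ylabel("normalized current")
    ax.legend(frameon=False)
    return ax


def plot_psd(res, ax=None):
    """One-sided RR power spectral density with murine band boundaries."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(res.freq, res.power, color="k", lw=0.8)
    for edge in (0.4, 1.5, 4.0):
        ax.axvline(edge, color="0.7", ls=":", lw=0.8)
    ax.set_xlim(0, 4.5)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD (ms$^2$/Hz)")
    return ax


def plot_poincare(pairs, ax=None):
    """Poincare scatter of (RR_n, RR_n+1)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(pairs.rr_n, pairs.rr_n1, ".", ms=2, alpha=0.4)
    lim = (min(pairs.rr_n.min(), pairs.rr_n1.min()),
           max(pairs.rr_n.max(), pairs.rr_n1.max()))
    ax.plot(lim, lim, color="0.6", lw=0.8)
    ax.set_xlabel("RR$_n$ (ms)")
    ax.set_ylabel("RR$_{n+1}$ (ms)")
    return ax


def plot_activation_map(amap, ax=None):
    """Isochronal activation map (ms after earliest activation)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    im = ax.imshow(amap.times_ms, cmap="viridis", origin="upper")
    plt.colorbar(im, ax=ax, label="activation time (ms)")
    r, c = amap.leading_site
    ax.plot(c, r, "w*", ms=10)
    return ax
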