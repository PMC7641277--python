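"""Voltage-clamp curve fitting.

Steady-state activation curves are fitted with a Boltzmann sigmoid in the
hyperpolarization-activated orientation (activation grows as the membrane is
hyperpolarized), current time-courses with single or double exponentials
after an initial delay, and current densities and calcium-current
decomposition are simple normalized quotients/differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import FitError, UniformTrace


def boltzmann(vm, v05, k, imin, imax):
    """Hyperpolarization-activated Boltzmann sigmoid.

    Equals ``imax`` at very negative potentials, ``imin`` at depolarized ones
    and the midpoint (half-maximal activation) at ``v05``; ``k`` (mV, > 0) is
    the slope factor.
    """
    vm = np.asarray(vm, dtype=float)
    return imin + (imax - imin) / (1.0 + np.exp((vm - v05) / k))


@dataclass
class ActivationCurveFit:
    """Boltzmann fit of a steady-state activation curve."""

    v05: float
    k: float
    imin: float
    imax: float
    rss: float
    n_points: int

    def predict(self, vm):
        return boltzmann(vm, self.v05, self.k, self.imin, self.imax)

    def summary(self) -> str:
        return (
            "Boltzmann activation fit\n"
            f"  V0.5 : {self.v05:10.2f} mV\n"
            f"  k    : {self.k:10.2f} mV\n"
            f"  Imin : {self.imin:10.4f}\n"
            f"  Imax : {self.imax:10.4f}\n"
            f"  RSS  : {self.rss:10.3e}  (n = {self.n_points})"
        )


@dataclass
class ExpFitResult:
    """Exponential fit I(t) = Iss + sum_j A_j exp(-(t - delay)/tau_j).

    For order 2 the convention is tau1 >= tau2. ``degenerate`` flags an
    order-2 fit whose two time constants collapsed onto each other.
    """

    iss: float
    amplitudes: tuple
    taus: tuple
    delay: float
    rss: float
    degenerate: bool = False

    @property
    def order(self) -> int:
        return len(self.taus)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        tp = np.maximum(t - self.delay, 0.0)
        out = np.full(t.shape, self.iss)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-tp / tau)
        return out

    def summary(self) -> str:
        lines = ["Exponential fit", f"  Iss   : {self.iss:10.4g}"]
        for j, (a, tau) in enumerate(zip(self.amplitudes, self.taus), 1):
            lines.append(f"  A{j}    : {a:10.4g}")
            lines.append(f"  tau{j}  : {tau:10.4g} s")
        lines.append(f"  delay : {self.delay:10.4g} s")
        lines.append(f"  RSS   : {self.rss:10.3e}")
        if self.degenerate:
            lines.append("  [degenerate: tau2 ~= tau1]")
        return "\n".join(lines)


def fit_boltzmann(points, normalize: bool = False) -> ActivationCurveFit:
    """Least-squares Boltzmann fit of (V_m, current) points.

    Parameters
    ----------
    points : DataFrame with columns (vm_mv, current) or 2-column array.
    normalize : bool
        Scale currents by the maximum before fitting, as is done for tail
        currents referenced to the largest response.
    """
    if isinstance(points, pd.DataFrame):
        vm = points.iloc[:, 0].to_numpy(dtype=float)
        cur = points.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        vm, cur = arr[:, 0], arr[:, 1]
    if np.unique(vm).size < 5:
        raise FitError("need at least 5 distinct test potentials")
    if not np.all(np.isfinite(cur)):
        raise FitError("currents must be finite")
    if normalize:
        m = np.max(np.abs(cur))
        if m == 0:
            raise FitError("cannot normalize an all-zero dataset")
        cur = cur / m

    span = cur.max() - cur.min()
    scale = max(abs(cur).max(), 1.0)
    if span < 1e-6 * scale:
        raise FitError("no sigmoid structure: currents are flat over the voltage range")

    # initial guesses: midpoint of the half-range crossing, k = 10 mV
    order = np.argsort(vm)
    half = cur.min() + span / 2.0
    crossing = vm[order][np.argmin(np.abs(cur[order] - half))]
    p0 = (crossing, 10.0, cur.min(), cur.max())
    lb = (vm.min() - 50.0, 1e-3, cur.min() - span, cur.min())
    ub = (vm.max() + 50.0, 200.0, cur.max(), cur.max() + span)
    try:
        popt, _ = curve_fit(boltzmann, vm, cur, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError as exc:
        resid = cur - boltzmann(vm, *p0)
        raise FitError(
            f"Boltzmann fit did not converge (initial RSS {float(resid @ resid):.3g})"
        ) from exc
    v05, k, imin, imax = (float(x) for x in popt)
    resid = cur - boltzmann(vm, v05, k, imin, imax)
    rss = float(resid @ resid)
    if imax - imin < 1e-6 * scale:
        raise FitError("no sigmoid structure: fitted amplitude is zero")
    return ActivationCurveFit(v05=v05, k=k, imin=imin, imax=imax, rss=rss,
                              n_points=vm.size)


def _estimate_delay(t, y):
    """Delay = time at which 10% of the total amplitude change has occurred."""
    y0, y_end = y[0], y[-1]
    total = y_end - y0
    if total == 0:
        return float(t[0])
    frac = (y - y0) / total
    idx = np.argmax(frac >= 0.10)
    return float(t[idx])


def fit_exponential(
    trace: UniformTrace,
    order: int = 1,
    fit_window: tuple | None = None,
    delay: float | None = None,
) -> ExpFitResult:
    """Fit a single or double exponential to a current trace.

    The fit uses samples after the initial delay; if ``delay`` is not given
    it is estimated as the time at which 10% of the total amplitude change
    has occurred. An order-2 fit of genuinely single-exponential data returns
    a result flagged ``degenerate`` rather than raising.
    """
    if order not in (1, 2):
        raise FitError("order must be 1 or 2")
    if fit_window is not None:
        sub = trace.slice(*fit_window)
    else:
        sub = trace
    t = sub.times
    y = sub.values
    if t.size < 8 * order:
        raise FitError("fit window contains too few samples")

    span = np.ptp(y)
    if span < 1e-12 * max(np.abs(y).max(), 1.0):
        raise FitError("no exponential decay: trace is constant")
    if delay is None:
        delay = _estimate_delay(t, y)
    m = t >= delay
    tt, yy = t[m] - delay, y[m]

    amp0 = yy[0] - yy[-1]
    tau0 = max((tt[-1] - tt[0]) / 5.0, 1e-6)
    try:
        if order == 1:
            def model(x, iss, a, tau):
                return iss + a * np.exp(-x / tau)
            p0 = (yy[-1], amp0, tau0)
            popt, _ = curve_fit(model, tt, yy, p0=p0, maxfev=20000)
            iss, a, tau = popt
            amps, taus = (float(a),), (float(tau),)
        else:
            def model(x, iss, a1, tau1, a2, tau2):
                return iss + a1 * np.exp(-x / tau1) + a2 * np.exp(-x / tau2)
            p0 = (yy[-1], 0.6 * amp0, tau0 * 2.0, 0.4 * amp0, tau0 / 4.0)
            popt, _ = curve_fit(model, tt, yy, p0=p0, maxfev=40000)
            iss, a1, tau1, a2, tau2 = popt
            if tau1 >= tau2:
                amps, taus = (float(a1), float(a2)), (float(tau1), float(tau2))
            else:
                amps, taus = (float(a2), float(a1)), (float(tau2), float(tau1))
    except RuntimeError as exc:
        raise FitError("exponential fit did not converge") from exc

    iss = float(iss)
    resid = yy - (iss + sum(a * np.exp(-tt / tau) for a, tau in zip(amps, taus)))
    if any(tau <= 0 for tau in taus):
        raise FitError("exponential fit returned a non-positive time constant")
    degenerate = order == 2 and taus[1] / taus[0] > 0.8
    return ExpFitResult(
        iss=iss, amplitudes=amps, taus=taus, delay=float(delay),
        rss=float(resid @ resid), degenerate=degenerate,
    )


def current_density(steady_current_pa: float, capacitance_pf: float) -> float:
    """Current density in pA/pF: steady-state current / cell capacitance."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return steady_current_pa / capacitance_pf


def ica_decompose(i_tl_peak: float, i_l_peak: float) -> float:
    """T-type calcium current: peak I_Ca,T+L minus peak I_Ca,L (pA/pF)."""
    return i_tl_peak - i_l_peak


def subtract_leak(points: pd.DataFrame) -> pd.DataFrame:
    """Subtract a linear leak estimated from the two most depolarized points.

    Fits a line through the currents at the two most positive test potentials
    (where the conductance of interest is closed) and removes it from every
    point.
    """
    vm = points.iloc[:, 0].to_numpy(dtype=float)
    cur = points.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(vm)
    v2, i2 = vm[order][-2:], cur[order][-2:]
    slope = (i2[1] - i2[0]) / (v2[1] - v2[0])
    intercept = i2[0] - slope * v2[0]
    out = points.copy()
    out.iloc[:, 1] = cur - (slope * vm + intercept)
    return out
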