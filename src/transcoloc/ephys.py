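"""Whole-cell voltage-clamp analysis.

Covers the workflow used for cardiac I_Kr / I_Na / I_to families: drug-
sensitive subtraction, steady-state and tail-current measurement, Boltzmann
fits of activation and availability (inactivation), conductance-voltage
curves, and the late-sodium-current integral.

Model equations
---------------
Activation (current-voltage form)::

    I(V) = (V - V_rev) * G_max / (1 + exp((V - V_half) / k))

With the exponent written this way, activation that increases with
depolarization corresponds to a *negative* slope factor ``k``.

Availability / inactivation::

    I(V) = (I_min - I_max) + I_max / (1 + exp((V - V_max) / k))

Both are fitted exactly in these forms; ``slope_magnitude`` on the results
reports |k| together with a direction flag to sidestep sign-convention
ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


class ProtocolMismatchError(ValueError):
    """Two sweep sets do not share protocol/sampling and cannot be combined."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepProtocol:
    """A step protocol: hold, depolarizing step, optional tail epoch."""

    step_voltages_mV: tuple
    hold_mV: float = -50.0
    pre_s: float = 0.05
    step_s: float = 3.0
    tail_mV: float | None = -40.0
    tail_s: float = 1.0
    sample_rate_hz: float = 1000.0

    def __post_init__(self):
        v = tuple(float(x) for x in self.step_voltages_mV)
        if not np.all(np.isfinite(v)):
            raise ValueError("protocol voltages must be finite")
        object.__setattr__(self, "step_voltages_mV", v)

    @property
    def total_s(self) -> float:
        return self.pre_s + self.step_s + (self.tail_s if self.tail_mV is not None else 0.0)


@dataclass
class SweepSet:
    """A family of current sweeps on a shared time base.

    ``epochs`` maps epoch names (``"pre"``, ``"step"``, ``"tail"``) to
    ``(t_start_s, t_end_s)`` half-open intervals.
    """

    time_s: np.ndarray
    currents_pA: np.ndarray  # (n_sweeps, n_samples)
    step_voltages_mV: np.ndarray
    epochs: dict = field(default_factory=dict)
    sample_rate_hz: float = 1000.0
    capacitance_pF: float | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.currents_pA = np.atleast_2d(np.asarray(self.currents_pA, dtype=float))
        self.step_voltages_mV = np.asarray(self.step_voltages_mV, dtype=float)
        if self.currents_pA.shape[0] != self.step_voltages_mV.size:
            raise ValueError("one step voltage per sweep required")
        if self.currents_pA.shape[1] != self.time_s.size:
            raise ValueError("time base and traces disagree in length")
        if not np.all(np.isfinite(self.step_voltages_mV)):
            raise ValueError("sweep voltages must be finite")

    @property
    def n_sweeps(self) -> int:
        return self.currents_pA.shape[0]

    def epoch_slice(self, name: str) -> slice:
        t0, t1 = self.epochs[name]
        i0, i1 = np.searchsorted(self.time_s, [t0, t1])
        return slice(int(i0), int(i1))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sweep_id, time_s, voltage_mV, current_pA."""
        n, m = self.currents_pA.shape
        return pd.DataFrame(
            {
                "sweep_id": np.repeat(np.arange(n), m),
                "time_s": np.tile(self.time_s, n),
                "voltage_mV": np.repeat(self.step_voltages_mV, m),
                "current_pA": self.currents_pA.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, epochs: dict | None = None) -> "SweepSet":
        frame = frame.sort_values(["sweep_id", "time_s"])
        ids = frame["sweep_id"].unique()
        first = frame[frame["sweep_id"] == ids[0]]
        time_s = first["time_s"].to_numpy()
        currents = np.vstack(
            [frame.loc[frame["sweep_id"] == i, "current_pA"].to_numpy() for i in ids]
        )
        volts = np.array(
            [frame.loc[frame["sweep_id"] == i, "voltage_mV"].iloc[0] for i in ids]
        )
        dt = np.median(np.diff(time_s)) if time_s.size > 1 else 1.0
        return cls(time_s, currents, volts, epochs=epochs or {}, sample_rate_hz=1.0 / dt)


# ---------------------------------------------------------------------------
# Model equations
# ---------------------------------------------------------------------------


def boltzmann_iv(v, g_max, v_rev, v_half, k):
    """Activation I-V: ``(V - V_rev) * G_max / (1 + exp((V - V_half)/k))``."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        return (v - v_rev) * g_max / (1.0 + np.exp((v - v_half) / k))


def boltzmann_g(v, g_max, v_half, k):
    """Logistic conductance (or normalized tail) curve."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        return g_max / (1.0 + np.exp((v - v_half) / k))


def boltzmann_inactivation(v, i_min, i_max, v_max, k):
    """Availability curve: ``(I_min - I_max) + I_max / (1 + exp((V - V_max)/k))``."""
    v = np.asarray(v, dtype=float)
    with np.errstate(over="ignore"):
        return (i_min - i_max) + i_max / (1.0 + np.exp((v - v_max) / k))


@dataclass
class BoltzmannFit:
    """Activation-fit parameters."""

    g_max: float
    v_rev: float
    v_half: float
    k: float
    residual: float = np.nan

    @property
    def slope_magnitude(self) -> float:
        return abs(self.k)

    @property
    def direction(self) -> str:
        """'activating' when the curve rises with depolarization (k < 0)."""
        return "activating" if self.k < 0 else "deactivating"

    def predict(self, v):
        return boltzmann_iv(v, self.g_max, self.v_rev, self.v_half, self.k)


@dataclass
class InactivationFit:
    i_min: float
    i_max: float
    v_max: float
    k: float
    residual: float = np.nan

    @property
    def slope_magnitude(self) -> float:
        return abs(self.k)

    def predict(self, v):
        return boltzmann_inactivation(v, self.i_min, self.i_max, self.v_max, self.k)


# ---------------------------------------------------------------------------
# Measurements on sweeps
# ---------------------------------------------------------------------------


def subtract_sensitive(sweeps_pre: SweepSet, sweeps_drug: SweepSet) -> SweepSet:
    """Drug-sensitive component: pointwise (pre - drug) difference traces.

    Emulates isolating I_Kr as the E-4031-sensitive current.  Protocols and
    sampling must match exactly.
    """
    if sweeps_pre.currents_pA.shape != sweeps_drug.currents_pA.shape:
        raise ProtocolMismatchError("sweep sets differ in shape")
    if not np.allclose(sweeps_pre.step_voltages_mV, sweeps_drug.step_voltages_mV):
        raise ProtocolMismatchError("sweep sets differ in step voltages")
    if not np.allclose(sweeps_pre.time_s, sweeps_drug.time_s):
        raise ProtocolMismatchError("sweep sets differ in time base")
    return SweepSet(
        time_s=sweeps_pre.time_s.copy(),
        currents_pA=sweeps_pre.currents_pA - sweeps_drug.currents_pA,
        step_voltages_mV=sweeps_pre.step_voltages_mV.copy(),
        epochs=dict(sweeps_pre.epochs),
        sample_rate_hz=sweeps_pre.sample_rate_hz,
        capacitance_pF=sweeps_pre.capacitance_pF,
    )


def measure_steady_state(
    sweeps: SweepSet, window_ms: float = 5.0, epoch: str = "step"
) -> pd.DataFrame:
    """Mean current over the final ``window_ms`` of the step, per sweep.

    Returns a frame with columns ``voltage_mV`` and ``current_pA``.
    """
    t0, t1 = sweeps.epochs[epoch]
    if window_ms <= 0 or window_ms / 1000.0 > (t1 - t0):
        raise ValueError("window must be positive and shorter than the step epoch")
    mask = (sweeps.time_s >= t1 - window_ms / 1000.0) & (sweeps.time_s < t1)
    return pd.DataFrame(
        {
            "voltage_mV": sweeps.step_voltages_mV,
            "current_pA": sweeps.currents_pA[:, mask].mean(axis=1),
        }
    )


def measure_tail_peak(
    sweeps: SweepSet, epoch: str = "tail", polarity: str = "auto"
) -> pd.DataFrame:
    """Signed extremum of the tail current per sweep, vs. prepulse voltage.

    ``polarity``: ``"positive"`` takes the maximum, ``"negative"`` the
    minimum, ``"auto"`` whichever has the larger magnitude per sweep.
    """
    sl = sweeps.epoch_slice(epoch)
    seg = sweeps.currents_pA[:, sl]
    if seg.shape[1] == 0:
        raise ValueError(f"epoch {epoch!r} contains no samples")
    hi = seg.max(axis=1)
    lo = seg.min(axis=1)
    if polarity == "positive":
        peak = hi
    elif polarity == "negative":
        peak = lo
    elif polarity == "auto":
        peak = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return pd.DataFrame({"voltage_mV": sweeps.step_voltages_mV, "current_pA": peak})


def measure_peak(
    sweeps: SweepSet, t0_ms: float = 1.0, t1_ms: float = 10.0, epoch: str = "step"
) -> pd.DataFrame:
    """Signed extremum within [t0, t1] ms of step onset (peak I_Na style)."""
    e0, _ = sweeps.epochs[epoch]
    mask = (sweeps.time_s >= e0 + t0_ms / 1000.0) & (sweeps.time_s < e0 + t1_ms / 1000.0)
    if not mask.any():
        raise ValueError("peak search window contains no samples")
    seg = sweeps.currents_pA[:, mask]
    hi, lo = seg.max(axis=1), seg.min(axis=1)
    peak = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
    return pd.DataFrame({"voltage_mV": sweeps.step_voltages_mV, "current_pA": peak})


def late_current_integral(
    time_s,
    current_pA,
    *,
    t0_ms: float = 50.0,
    t1_ms: float = 800.0,
    pulse_start_s: float = 0.0,
    baseline="prepulse",
    pre_window_ms: float = 10.0,
) -> float:
    """Trapezoidal charge integral over [t0, t1] ms from pulse onset, in pA*ms.

    ``baseline`` is the zero-current policy: ``"prepulse"`` uses the mean
    current over the ``pre_window_ms`` immediately before the pulse,
    ``"none"`` uses 0, or pass a number directly.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(current_pA, dtype=float)
    ta = pulse_start_s + t0_ms / 1000.0
    tb = pulse_start_s + t1_ms / 1000.0
    if ta < t[0] - 1e-12 or tb > t[-1] + 1e-12:
        raise ValueError("integration window extends outside the trace")
    if baseline == "prepulse":
        pre = (t >= pulse_start_s - pre_window_ms / 1000.0) & (t < pulse_start_s)
        if not pre.any():
            raise ValueError("no samples available for the prepulse baseline")
        b = float(y[pre].mean())
    elif baseline == "none":
        b = 0.0
    else:
        b = float(baseline)
    inner = (t > ta) & (t < tb)
    grid = np.concatenate(([ta], t[inner], [tb]))
    vals = np.interp(grid, t, y) - b
    return float(np.trapezoid(vals, grid) * 1000.0)  # pA*s -> pA*ms


def conductance_curve(
    voltages_mV, currents_pA, v_rev_mV, *, normalize: bool = False, tol_mV: float = 1e-9
):
    """Chord conductance G(V) = I / (V - V_rev) and its logistic G_max.

    Points at the reversal potential are excluded with a warning.  Returns
    ``(frame, g_max)``; with ``normalize=True`` the frame's conductance
    column is divided by the fitted G_max.
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(currents_pA, dtype=float)
    keep = np.abs(v - v_rev_mV) > tol_mV
    if not keep.all():
        warnings.warn(
            "excluding point(s) at the reversal potential from the G-V curve",
            stacklevel=2,
        )
    g = i[keep] / (v[keep] - v_rev_mV)
    res = _fit_logistic(v[keep], g)
    g_max = res.fit.g_max
    out = pd.DataFrame(
        {"voltage_mV": v[keep], "conductance_nS": g / g_max if normalize else g}
    )
    return out, g_max


# ---------------------------------------------------------------------------
# Boltzmann model objects
# ---------------------------------------------------------------------------

_K_STARTS = (-3.0, -7.0, -15.0, 3.0, 7.0, 15.0)


def _half_amplitude_voltage(v, y):
    """Voltage at which |y| first crosses half its maximum (fit seed)."""
    a = np.abs(np.asarray(y, dtype=float))
    if a.max() == 0:
        return float(np.median(v))
    idx = int(np.argmin(np.abs(a - a.max() / 2.0)))
    return float(np.asarray(v)[idx])


def _multistart_curve_fit(fun, v, y, starts, bounds=None):
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        return _multistart_inner(fun, v, y, starts, bounds)


def _multistart_inner(fun, v, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            kw = {"p0": p0, "maxfev": 20000}
            if bounds is not None:
                kw["bounds"] = bounds
                kw.pop("maxfev")
                kw["max_nfev"] = 20000
            popt, pcov = optimize.curve_fit(fun, v, y, **kw)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((fun(v, *popt) - y) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    if best is None:
        raise FitError("Boltzmann fit failed to converge from every start")
    return best


def _fit_logistic(v, g):
    v = np.asarray(v, dtype=float)
    g = np.asarray(g, dtype=float)
    amp0 = g[np.argmax(np.abs(g))]
    vh0 = _half_amplitude_voltage(v, g)
    starts = [(amp0, vh0, k0) for k0 in _K_STARTS]
    popt, pcov, ss = _multistart_curve_fit(boltzmann_g, v, g, starts)
    return _ActivationResult(
        fit=BoltzmannFit(g_max=popt[0], v_rev=np.nan, v_half=popt[1], k=popt[2], residual=ss),
        pcov=pcov,
        mode="normalized_g",
        voltages_mV=v,
        data=g,
    )


@dataclass
class _ActivationResult:
    """Results of a Boltzmann activation fit."""

    fit: BoltzmannFit
    pcov: np.ndarray
    mode: str
    voltages_mV: np.ndarray
    data: np.ndarray

    @property
    def params(self):
        return self.fit

    @property
    def stderr(self) -> dict:
        se = np.sqrt(np.diag(self.pcov)) if self.pcov is not None else []
        if self.mode == "full_iv":
            names = (
                ["g_max", "v_rev", "v_half", "k"]
                if len(se) == 4
                else ["g_max", "v_half", "k"]
            )
        else:
            names = ["g_max", "v_half", "k"]
        return dict(zip(names, se))

    def predict(self, v):
        if self.mode == "full_iv":
            return self.fit.predict(v)
        return boltzmann_g(v, self.fit.g_max, self.fit.v_half, self.fit.k)

    def summary(self) -> str:
        f = self.fit
        lines = [
            f"Boltzmann activation fit ({self.mode}), n={len(self.voltages_mV)} points",
            f"  G_max  = {f.g_max:.4g}",
            f"  V_half = {f.v_half:.3f} mV",
            f"  k      = {f.k:.3f} mV (|k| = {f.slope_magnitude:.3f}, {f.direction})",
        ]
        if np.isfinite(f.v_rev):
            lines.insert(2, f"  V_rev  = {f.v_rev:.3f} mV")
        lines.append(f"  residual SS = {f.residual:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - visual aid
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.voltages_mV, self.data, "o", label="data")
        vv = np.linspace(self.voltages_mV.min(), self.voltages_mV.max(), 200)
        ax.plot(vv, self.predict(vv), "-", label="fit")
        ax.set_xlabel("voltage (mV)")
        ax.set_ylabel("current / conductance")
        ax.legend()
        return ax


@dataclass
class _InactivationResult:
    fit: InactivationFit
    pcov: np.ndarray
    voltages_mV: np.ndarray
    data: np.ndarray

    @property
    def params(self):
        return self.fit

    @property
    def stderr(self) -> dict:
        se = np.sqrt(np.diag(self.pcov)) if self.pcov is not None else []
        return dict(zip(["i_min", "i_max", "v_max", "k"], se))

    def predict(self, v):
        return self.fit.predict(v)

    def summary(self) -> str:
        f = self.fit
        return "\n".join(
            [
                f"Boltzmann availability fit, n={len(self.voltages_mV)} points",
                f"  I_min = {f.i_min:.4g}",
                f"  I_max = {f.i_max:.4g}",
                f"  V_max = {f.v_max:.3f} mV",
                f"  k     = {f.k:.3f} mV (|k| = {f.slope_magnitude:.3f})",
                f"  residual SS = {f.residual:.4g}",
            ]
        )


class BoltzmannActivation:
    """Boltzmann activation model for I-V or G-V/tail data.

    Parameters
    ----------
    voltages_mV, data :
        Step (or prepulse) voltages and the corresponding measurement:
        current for ``mode="full_iv"``, conductance or peak tail current for
        ``mode="normalized_g"``.
    mode : {"full_iv", "normalized_g"}
        ``full_iv`` fits ``I(V) = (V - V_rev) G_max / (1 + exp((V-V_half)/k))``;
        ``normalized_g`` fits the plain logistic ``G_max / (1 + exp(...))``.
    v_rev_mV : float, optional
        Fix the reversal potential instead of fitting it (full_iv only).
    """

    def __init__(self, voltages_mV, data, *, mode: str = "full_iv", v_rev_mV=None):
        self.v = np.asarray(voltages_mV, dtype=float)
        self.y = np.asarray(data, dtype=float)
        if self.v.size != self.y.size:
            raise ValueError("voltages and data differ in length")
        if self.v.size < 5:
            raise ValueError("at least 5 voltage points are required")
        if mode not in ("full_iv", "normalized_g"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.v_rev_fixed = v_rev_mV

    def fit(self) -> _ActivationResult:
        v, y = self.v, self.y
        if self.mode == "normalized_g":
            return _fit_logistic(v, y)
        vh0 = _half_amplitude_voltage(v, y)
        amp = y[np.argmax(np.abs(y))]
        if self.v_rev_fixed is not None:
            vr = float(self.v_rev_fixed)
            g0 = amp / (v[np.argmax(np.abs(y))] - vr + 1e-9)

            def fun(vv, g_max, v_half, k):
                return boltzmann_iv(vv, g_max, vr, v_half, k)

            starts = [(g0, vh0, k0) for k0 in _K_STARTS]
            popt, pcov, ss = _multistart_curve_fit(fun, v, y, starts)
            fitres = BoltzmannFit(popt[0], vr, popt[1], popt[2], residual=ss)
        else:
            vr0_candidates = (v.min() - 40.0, v.min() - 5.0, 0.0)
            starts = []
            for vr0 in vr0_candidates:
                g0 = amp / (v[np.argmax(np.abs(y))] - vr0 + 1e-9)
                starts += [(g0, vr0, vh0, k0) for k0 in _K_STARTS]
            popt, pcov, ss = _multistart_curve_fit(boltzmann_iv, v, y, starts)
            fitres = BoltzmannFit(*popt, residual=ss)
        return _ActivationResult(fit=fitres, pcov=pcov, mode="full_iv", voltages_mV=v, data=y)


class BoltzmannInactivation:
    """Availability model fitted exactly as printed (see module docstring)."""

    def __init__(self, voltages_mV, currents):
        self.v = np.asarray(voltages_mV, dtype=float)
        self.y = np.asarray(currents, dtype=float)
        if self.v.size != self.y.size:
            raise ValueError("voltages and data differ in length")
        if self.v.size < 5:
            raise ValueError("at least 5 voltage points are required")

    def fit(self) -> _InactivationResult:
        v, y = self.v, self.y
        vh0 = _half_amplitude_voltage(v, y - y.min())
        starts = []
        for k0 in _K_STARTS:
            starts.append((y.min(), y.max() - y.min(), vh0, k0))
            starts.append((y.max(), y.max() - y.min(), vh0, k0))
        popt, pcov, ss = _multistart_curve_fit(boltzmann_inactivation, v, y, starts)
        return _InactivationResult(
            fit=InactivationFit(*popt, residual=ss), pcov=pcov, voltages_mV=v, data=y
        )


def fit_activation(voltages_mV, data, *, mode: str = "full_iv", v_rev_mV=None):
    """Functional wrapper around :class:`BoltzmannActivation`."""
    return BoltzmannActivation(voltages_mV, data, mode=mode, v_rev_mV=v_rev_mV).fit()


def fit_inactivation(voltages_mV, currents):
    """Functional wrapper around :class:`BoltzmannInactivation`."""
    return BoltzmannInactivation(voltages_mV, currents).fit()
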