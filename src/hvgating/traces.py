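"""Gating-current sweep analytics.

Operates on recorded or simulated sweeps: charge integration over ON/OFF
windows, OFF-peak amplitudes, Q_OFF/Q_ON trapping time courses, and the
exponential models used throughout — single/double decaying and
saturating exponentials, plus the double-pulse recovery fit.

Sign conventions: the ON transient is positive (outward), the OFF
transient negative.  Integrated charges are reported as magnitudes so
that Q_OFF/Q_ON is directly the fraction of charge recovered on
repolarization; the signed integral remains available for linearity-
sensitive uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Parameters, minimize
from numpy.polynomial import polynomial as P
from scipy.integrate import trapezoid

from .errors import FitFailureError, InvalidInputError, InvalidWindowError

__all__ = [
    "Sweep",
    "ChargePair",
    "ExponentialFit",
    "RecoveryResult",
    "MODEL_IDS",
    "evaluate_model",
    "integrate_charge",
    "off_peak_amplitude",
    "fit_exponential_model",
    "charge_pair",
    "charge_ratio_timecourse",
    "recovery_analysis",
]

#: Default OFF-charge integration window after repolarization, ms.
DEFAULT_OFF_WINDOW_MS = 20.0
#: Default OFF-peak search window after repolarization, ms.
DEFAULT_PEAK_SEARCH_MS = 5.0

MODEL_IDS = ("single_decay", "single_saturating", "double_decay", "double_saturating")


@dataclass
class Sweep:
    """One time/current trace with protocol annotations.

    ``annotations`` may carry ``depol_start_ms``, ``depol_end_ms``,
    ``repol_start_ms`` and ``duration_ms`` for the standard
    hold/step/tail protocol family.
    """

    times: np.ndarray
    current: np.ndarray
    voltage: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not (len(self.times) == len(self.current) == len(self.voltage)):
            raise InvalidInputError("times, current and voltage must share length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass(frozen=True)
class ChargePair:
    """ON/OFF charge magnitudes for one depolarization duration."""

    q_on: float       # fC
    q_off: float      # fC
    duration: float   # ms

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidInputError("duration must be positive")


@dataclass
class ExponentialFit:
    """Result of an exponential-model fit.

    For double models the components are canonically ordered so that
    ``tau1 <= tau2`` (amplitudes permuted accordingly).
    """

    model_id: str
    a: float
    tau1: float
    b: float | None = None
    tau2: float | None = None
    offset: float = 0.0
    rss: float = np.nan
    success: bool = True
    stderr: dict = field(default_factory=dict)

    @property
    def tau_slow(self) -> float:
        return self.tau1 if self.tau2 is None else self.tau2

    @property
    def tau_fast(self) -> float:
        return self.tau1


@dataclass(frozen=True)
class RecoveryResult:
    """Fit of the double-pulse recovery curve Q_max (1 - exp(-t/tau))."""

    q_max: float   # fC
    tau: float     # ms
    q_max_stderr: float | None = None
    tau_stderr: float | None = None
    rss: float = np.nan


# ---------------------------------------------------------------------------
# charge integration


def _window_mask(
    sweep: Sweep, window: tuple[float, float], include_end: bool = True
) -> np.ndarray:
    w0, w1 = window
    if w1 <= w0:
        raise InvalidWindowError(f"empty window {window}")
    eps = 1e-9
    if w0 < sweep.times[0] - eps or w1 > sweep.times[-1] + eps:
        raise InvalidWindowError(
            f"window {window} outside sweep range "
            f"[{sweep.times[0]}, {sweep.times[-1]}] ms"
        )
    mask = (sweep.times >= w0 - eps) & (
        sweep.times <= w1 + eps if include_end else sweep.times < w1 - eps
    )
    if mask.sum() < 2:
        raise InvalidWindowError(f"window {window} contains fewer than 2 samples")
    return mask


def integrate_charge(
    sweep: Sweep,
    window: tuple[float, float],
    baseline: float = 0.0,
    signed: bool = False,
    include_end: bool = True,
) -> float:
    """Trapezoidal integral of (current - baseline) over a time window, fC.

    By default the magnitude is returned so ON and OFF charges are both
    positive; pass ``signed=True`` for the raw signed integral.  With
    ``include_end=False`` the window is right-open, which keeps a
    voltage-step sample sitting exactly on the window edge (it belongs
    to the next protocol segment) out of the integral.
    """
    if not np.isfinite(baseline):
        raise InvalidInputError("baseline must be finite")
    mask = _window_mask(sweep, window, include_end=include_end)
    q = trapezoid(sweep.current[mask] - baseline, sweep.times[mask])
    return float(q) if signed else float(abs(q))


def _tail_mean(
    sweep: Sweep,
    window: tuple[float, float],
    fraction: float = 0.1,
    include_end: bool = True,
) -> float:
    """Mean current over the final ``fraction`` of a window (baseline estimate)."""
    w0, w1 = window
    tail = (w1 - fraction * (w1 - w0), w1)
    return float(np.mean(sweep.current[_window_mask(sweep, tail, include_end=include_end)]))


def _require_annotation(sweep: Sweep, key: str) -> float:
    if key not in sweep.annotations:
        raise InvalidInputError(f"sweep annotation '{key}' is required")
    return float(sweep.annotations[key])


def charge_pair(
    sweep: Sweep,
    off_window_ms: float = DEFAULT_OFF_WINDOW_MS,
    on_baseline: str = "hold",
) -> ChargePair:
    """Q_ON / Q_OFF for an annotated hold/step/tail sweep.

    The OFF charge integrates the first ``off_window_ms`` after
    repolarization against the mean of that window's final 10%.  The ON
    baseline is selectable:

    ``"hold"`` (default)
        mean current over the last 10% of the pre-pulse holding segment
        — robust for short depolarizations, where the gating transient
        is still decaying at the pulse end;
    ``"depol_tail"``
        mean over the last 10% of the depolarization itself, which also
        removes a steady residual macroscopic current but requires the
        pulse to outlast the gating transient.
    """
    d0 = _require_annotation(sweep, "depol_start_ms")
    d1 = _require_annotation(sweep, "depol_end_ms")
    r0 = _require_annotation(sweep, "repol_start_ms")
    off_window = (r0, min(r0 + off_window_ms, float(sweep.times[-1])))
    if on_baseline == "hold" and d0 > sweep.times[0]:
        base_on = _tail_mean(sweep, (float(sweep.times[0]), d0), include_end=False)
    elif on_baseline in ("hold", "depol_tail"):
        base_on = _tail_mean(sweep, (d0, d1), include_end=False)
    else:
        raise InvalidInputError(f"unknown on_baseline mode {on_baseline!r}")
    q_on = integrate_charge(sweep, (d0, d1), baseline=base_on, include_end=False)
    q_off = integrate_charge(sweep, off_window, baseline=_tail_mean(sweep, off_window))
    return ChargePair(q_on=q_on, q_off=q_off, duration=d1 - d0)


def off_peak_amplitude(
    sweep: Sweep, search_ms: float = DEFAULT_PEAK_SEARCH_MS
) -> float:
    """Magnitude of the fast OFF-transient peak.

    Searches the first ``search_ms`` after repolarization for the
    extremum of the baseline-subtracted current; the baseline is the
    mean over the final 10% of the repolarization tail.
    """
    r0 = _require_annotation(sweep, "repol_start_ms")
    t_end = float(sweep.times[-1])
    if r0 >= t_end:
        raise InvalidWindowError("repolarization window is empty")
    baseline = _tail_mean(sweep, (r0, t_end))
    mask = _window_mask(sweep, (r0, min(r0 + search_ms, t_end)))
    return float(np.max(np.abs(sweep.current[mask] - baseline)))


# ---------------------------------------------------------------------------
# exponential models


def evaluate_model(model_id: str, t: np.ndarray, params: dict) -> np.ndarray:
    """Evaluate one of the four exponential models at times ``t``.

    ``params`` uses keys a, tau1 (and b, tau2 for double models) plus an
    optional offset.
    """
    t = np.asarray(t, dtype=float)
    a = params["a"]
    tau1 = params["tau1"]
    off = params.get("offset", 0.0)
    if model_id == "single_decay":
        return a * np.exp(-t / tau1) + off
    if model_id == "single_saturating":
        return a * (1.0 - np.exp(-t / tau1)) + off
    b = params["b"]
    tau2 = params["tau2"]
    if model_id == "double_decay":
        return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + off
    if model_id == "double_saturating":
        return a * (1.0 - np.exp(-t / tau1)) + b * (1.0 - np.exp(-t / tau2)) + off
    raise InvalidInputError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _n_params(model_id: str, fit_offset: bool) -> int:
    base = 2 if model_id.startswith("single") else 4
    return base + int(fit_offset)


def _seed_tau(t: np.ndarray, y: np.ndarray, decay: bool) -> float:
    """Log-linear tail regression for a starting time constant."""
    span = t[-1] - t[0]
    resid = y - y[-1] if decay else y[-1] - y
    resid = np.abs(resid)
    tail = slice(len(t) // 2, None)
    good = resid[tail] > 1e-12 * max(resid.max(), 1e-300)
    if good.sum() >= 2:
        coeffs = P.polyfit(t[tail][good], np.log(resid[tail][good]), 1)
        if coeffs[1] < -1e-12:
            tau = -1.0 / coeffs[1]
            if 1e-4 * span < tau < 1e4 * span:
                return float(tau)
    return float(span / 3.0)


def _residual(params: Parameters, t, y, model_id):
    p = {k: params[k].value for k in params}
    return evaluate_model(model_id, t, p) - y


def fit_exponential_model(
    t: Sequence[float],
    y: Sequence[float],
    model_id: str,
    init: dict | None = None,
    fit_offset: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> ExponentialFit:
    """Nonlinear least-squares fit of an exponential model.

    Initialization combines a log-linear tail regression for the time
    constant with jittered multi-starts; the lowest-residual converged
    solution wins.  Raises :class:`FitFailureError` (carrying the best
    candidate) if no start converges.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if model_id not in MODEL_IDS:
        raise InvalidInputError(f"unknown model_id {model_id!r}")
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidInputError("t and y must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("t must be strictly increasing")
    if len(t) < 3 * _n_params(model_id, fit_offset):
        warnings.warn(
            f"only {len(t)} points for {_n_params(model_id, fit_offset)} parameters; "
            "fit may be poorly determined",
            RuntimeWarning,
        )

    decay = model_id.endswith("decay")
    scale = float(np.max(np.abs(y))) or 1.0
    tau_seed = _seed_tau(t, y, decay)
    single = model_id.startswith("single")
    span = t[-1] - t[0]

    base: dict = {"a": y[0] - y[-1] if decay else y[-1] - y[0], "tau1": tau_seed}
    if not single:
        base = {
            "a": base["a"] / 2,
            "tau1": max(span / 20.0, 10 * np.min(np.diff(t)) / 10),
            "b": base["a"] / 2,
            "tau2": tau_seed,
        }
    if fit_offset:
        base["offset"] = float(y[-1] if decay else y[0])
    if init:
        base.update(init)

    rng = np.random.default_rng(seed)
    best = None
    best_rss = np.inf
    converged = False
    for k in range(n_restarts):
        params = Parameters()
        for name, val in base.items():
            jitter = 1.0 if k == 0 else float(np.exp(rng.normal(0.0, 0.7)))
            if name.startswith("tau"):
                params.add(name, value=max(val * jitter, 1e-6), min=1e-9)
            elif name == "offset":
                params.add(name, value=val)
            else:
                params.add(name, value=val * (jitter if val != 0 else 1.0) or 0.1 * scale)
        try:
            out = minimize(_residual, params, args=(t, y, model_id), method="leastsq")
        except Exception:
            continue
        rss = float(np.sum(out.residual**2))
        if rss < best_rss:
            best_rss = rss
            best = out
            converged = converged or bool(out.success)
        if out.success and rss < (1e-3 * scale) ** 2 * len(t):
            break

    if best is None:
        raise FitFailureError(f"{model_id} fit failed on all starts")

    vals = {k: best.params[k].value for k in best.params}
    errs = {
        k: best.params[k].stderr
        for k in best.params
        if best.params[k].stderr is not None
    }
    result = ExponentialFit(
        model_id=model_id,
        a=vals["a"],
        tau1=vals["tau1"],
        b=vals.get("b"),
        tau2=vals.get("tau2"),
        offset=vals.get("offset", 0.0),
        rss=best_rss,
        success=bool(best.success),
        stderr=errs,
    )
    if result.tau2 is not None and result.tau1 > result.tau2:
        result.a, result.b = result.b, result.a
        result.tau1, result.tau2 = result.tau2, result.tau1
        for pair in (("a", "b"), ("tau1", "tau2")):
            if pair[0] in result.stderr or pair[1] in result.stderr:
                result.stderr[pair[0]], result.stderr[pair[1]] = (
                    result.stderr.get(pair[1]),
                    result.stderr.get(pair[0]),
                )
    if not converged:
        raise FitFailureError(
            f"{model_id} fit did not converge after {n_restarts} starts", best=result
        )
    return result


# ---------------------------------------------------------------------------
# trapping time course and recovery


def charge_ratio_timecourse(
    sweeps: Sequence[Sweep],
    off_window_ms: float = DEFAULT_OFF_WINDOW_MS,
    noise_floor: float = 0.0,
    on_baseline: str = "hold",
) -> list[tuple[float, float]]:
    """Q_OFF/Q_ON per depolarization duration, sorted by duration.

    A ratio is reported as NaN when Q_ON does not exceed ``noise_floor``.
    """
    out = []
    for sweep in sweeps:
        pair = charge_pair(sweep, off_window_ms=off_window_ms, on_baseline=on_baseline)
        ratio = pair.q_off / pair.q_on if pair.q_on > noise_floor else np.nan
        if not np.isfinite(ratio) and pair.q_on <= noise_floor:
            warnings.warn(
                f"Q_ON below noise floor at duration {pair.duration} ms; "
                "ratio flagged undefined",
                RuntimeWarning,
            )
        out.append((pair.duration, float(ratio)))
    return sorted(out, key=lambda x: x[0])


def recovery_analysis(
    intervals: Sequence[float], second_pulse_charges: Sequence[float]
) -> RecoveryResult:
    """Fit Q_max (1 - exp(-t/tau)) to recovered charge vs interpulse interval."""
    t = np.asarray(intervals, dtype=float)
    q = np.asarray(second_pulse_charges, dtype=float)
    if len(t) < 4:
        raise InvalidInputError("need at least 4 interval points")
    if t.shape != q.shape:
        raise InvalidInputError("intervals and charges must share length")
    order = np.argsort(t)
    t, q = t[order], q[order]
    noise = np.std(np.diff(q)) / np.sqrt(2.0)
    if np.any(np.diff(q) < -3.0 * max(noise, 1e-12)):
        warnings.warn("recovery data non-monotone beyond noise", RuntimeWarning)

    fit = fit_exponential_model(t, q, "single_saturating")
    return RecoveryResult(
        q_max=fit.a,
        tau=fit.tau1,
        q_max_stderr=fit.stderr.get("a"),
        tau_stderr=fit.stderr.get("tau1"),
        rss=fit.rss,
    )
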