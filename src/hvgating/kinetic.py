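"""Voltage-dependent Markov model of gating currents.

The voltage sensor is modelled as a linear chain of N kinetic states
(default five, labelled A1-A3, B1-B2) connected by voltage-dependent
transitions obeying Eyring-type rate laws

    alpha(V) = alpha0 * exp( x * z_delta * e0 * V / kT)
    beta(V)  = beta0  * exp((x - 1) * z_delta * e0 * V / kT)

where ``z_delta`` is the gating charge moved across a transition and
``x`` the fraction of that charge moved in the forward direction.  The
master equation dp/dt = p G (row-vector convention, G the generator
matrix) is solved exactly by eigendecomposition; the macroscopic gating
current is the rate of change of the mean gating charge,

    I_g(t) = N * e0 * sum_i z_i dp_i/dt ,

with z_i the cumulative charge of state i relative to the first state.
Outward (ON) current is positive, so the OFF transient after
repolarization is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

from .errors import DegenerateSchemeError, InvalidInputError
from .traces import Sweep
from .units import E0_FC, ROOM_TEMPERATURE_K, thermal_voltage_mv

__all__ = [
    "TransitionParams",
    "KineticScheme",
    "VoltageProtocol",
    "OccupancyTrajectory",
    "transition_rates",
    "build_generator",
    "equilibrium_occupancy",
    "solve_occupancies",
    "gating_current",
    "simulate_protocol",
    "example_scheme",
    "step_protocol",
    "scheme_from_dict",
    "protocol_from_dict",
]


@dataclass(frozen=True)
class TransitionParams:
    """Rate-law parameters of one forward/backward transition pair.

    alpha0, beta0 : forward/backward rate at 0 mV, 1/ms
    x             : forward charge fraction, dimensionless in [0, 1]
    z_delta       : gating charge moved across the transition, e0
    """

    alpha0: float
    beta0: float
    x: float
    z_delta: float

    def __post_init__(self):
        if not (self.alpha0 > 0 and self.beta0 > 0):
            raise InvalidInputError("alpha0 and beta0 must be positive")
        if not 0.0 <= self.x <= 1.0:
            raise InvalidInputError(f"x must lie in [0, 1], got {self.x}")
        if self.z_delta < 0:
            raise InvalidInputError("z_delta must be non-negative")


@dataclass(frozen=True)
class KineticScheme:
    """Linear-chain kinetic scheme for the voltage sensor.

    ``transitions[j]`` connects ``state_names[j]`` to ``state_names[j+1]``.
    ``n_channels`` scales the single-sensor current to the macroscopic
    ensemble current.
    """

    state_names: tuple[str, ...]
    transitions: tuple[TransitionParams, ...]
    n_channels: float = 1.0e8
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self):
        object.__setattr__(self, "state_names", tuple(self.state_names))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        if self.n_states < 2:
            raise InvalidInputError("need at least two states")
        if len(self.transitions) != self.n_states - 1:
            raise InvalidInputError(
                f"linear chain with {self.n_states} states needs "
                f"{self.n_states - 1} transitions, got {len(self.transitions)}"
            )
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be positive")
        if not self.n_channels > 0:
            raise InvalidInputError("n_channels must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def state_charges(self) -> np.ndarray:
        """Cumulative gating charge of each state relative to the first (e0)."""
        dz = np.array([t.z_delta for t in self.transitions])
        return np.concatenate([[0.0], np.cumsum(dz)])


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant voltage-clamp protocol.

    segments        : sequence of (duration_ms, voltage_mV)
    sample_interval : output sampling step, ms
    """

    segments: tuple[tuple[float, float], ...]
    sample_interval: float = 0.05

    def __post_init__(self):
        object.__setattr__(
            self, "segments", tuple((float(d), float(v)) for d, v in self.segments)
        )
        if len(self.segments) == 0:
            raise InvalidInputError("protocol must contain at least one segment")
        if any(d <= 0 for d, _ in self.segments):
            raise InvalidInputError("all segment durations must be positive")
        if not self.sample_interval > 0:
            raise InvalidInputError("sample_interval must be positive")


@dataclass
class OccupancyTrajectory:
    """Time-resolved state probabilities under a (piecewise) voltage."""

    times: np.ndarray       # ms
    occupancy: np.ndarray   # (n_times, n_states)
    voltage: np.ndarray     # mV per sample

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)


def transition_rates(
    params: TransitionParams, v_mv: float, temperature_k: float
) -> tuple[float, float]:
    """Forward/backward rates (1/ms) at voltage ``v_mv`` and temperature ``temperature_k``."""
    if not np.isfinite(v_mv):
        raise InvalidInputError(f"voltage must be finite, got {v_mv}")
    if not temperature_k > 0:
        raise InvalidInputError("temperature must be positive")
    vt = thermal_voltage_mv(temperature_k)
    u = params.z_delta * v_mv / vt
    alpha = params.alpha0 * np.exp(params.x * u)
    beta = params.beta0 * np.exp((params.x - 1.0) * u)
    return float(alpha), float(beta)


def build_generator(scheme: KineticScheme, v_mv: float) -> np.ndarray:
    """Generator matrix G (1/ms) at voltage ``v_mv``; dp/dt = p G, rows sum to zero."""
    n = scheme.n_states
    g = np.zeros((n, n))
    for j, tr in enumerate(scheme.transitions):
        alpha, beta = transition_rates(tr, v_mv, scheme.temperature)
        g[j, j + 1] = alpha
        g[j + 1, j] = beta
    g[np.diag_indices(n)] = -g.sum(axis=1)
    return g


def equilibrium_occupancy(scheme: KineticScheme, v_mv: float) -> np.ndarray:
    """Stationary distribution of the chain at a holding voltage.

    Computed from the null space of G^T; for an irreducible nearest-
    neighbour chain this coincides with the product of Boltzmann factors
    along the chain (detailed balance).
    """
    g = build_generator(scheme, v_mv)
    ns = null_space(g.T, rcond=1e-12)
    if ns.shape[1] != 1:
        raise DegenerateSchemeError(
            f"stationary distribution is not unique (null space dim {ns.shape[1]})"
        )
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise DegenerateSchemeError("stationary vector has negative entries")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def _propagate(g: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """p(t) = p0 expm(G t), spectral solve with matrix-exponential fallback."""
    w, v = np.linalg.eig(g)
    # Reciprocal condition of the eigenvector matrix gauges diagonalizability.
    sv = np.linalg.svd(v, compute_uv=False)
    rcond = sv[-1] / sv[0]
    if rcond < 1e-10:
        warnings.warn(
            "generator is (nearly) defective; falling back to dense matrix exponential",
            RuntimeWarning,
        )
        return np.stack([p0 @ expm(g * t) for t in times]).real
    # p(t) = p0 V e^{wt} V^{-1}; project once, then scale modes per time point
    c = p0 @ v
    vinv = np.linalg.inv(v)
    e = np.exp(np.outer(times, w))
    return ((e * c) @ vinv).real


def solve_occupancies(
    scheme: KineticScheme,
    v_mv: float,
    p0: Sequence[float],
    times: Sequence[float],
) -> OccupancyTrajectory:
    """Exact relaxation of the master equation at constant voltage."""
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (scheme.n_states,):
        raise InvalidInputError("p0 length must equal the number of states")
    if abs(p0.sum() - 1.0) > 1e-8:
        raise InvalidInputError("p0 must sum to 1")
    times = np.asarray(times, dtype=float)
    g = build_generator(scheme, v_mv)
    occ = _propagate(g, p0, times)
    return OccupancyTrajectory(
        times=times, occupancy=occ, voltage=np.full_like(times, v_mv)
    )


def gating_current(
    traj: OccupancyTrajectory,
    z: Sequence[float],
    n_channels: float,
    scheme: KineticScheme | None = None,
) -> np.ndarray:
    """Macroscopic gating current I_g(t) = N e0 sum_i z_i dp_i/dt, in fC/ms.

    If ``scheme`` is supplied, dp/dt is evaluated exactly as p G(V(t));
    otherwise a central finite difference of the occupancies is used.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != traj.occupancy.shape[1]:
        raise InvalidInputError("charge vector length must equal the number of states")
    if scheme is not None:
        dpdt = np.empty_like(traj.occupancy)
        for v in np.unique(traj.voltage):
            mask = traj.voltage == v
            dpdt[mask] = traj.occupancy[mask] @ build_generator(scheme, v)
    else:
        dpdt = np.gradient(traj.occupancy, traj.times, axis=0)
    return n_channels * E0_FC * (dpdt @ z)


def simulate_protocol(scheme: KineticScheme, protocol: VoltageProtocol) -> Sweep:
    """Simulate a voltage-clamp protocol and return the gating-current sweep.

    The initial condition is the stationary distribution at the first
    segment's (holding) voltage; occupancy is continuous across segment
    boundaries while the current jumps with the driving force.  Each
    boundary sample is attributed to the incoming segment, so the
    instantaneous post-step current (the OFF peak) is captured.
    """
    z = scheme.state_charges
    dt = protocol.sample_interval
    p = equilibrium_occupancy(scheme, protocol.segments[0][1])

    all_t, all_i, all_v = [], [], []
    t_offset = 0.0
    for k, (dur, v) in enumerate(protocol.segments):
        n_steps = max(int(round(dur / dt)), 1)
        local = np.arange(0, n_steps + 1) * dt
        local = local[local <= dur + 1e-12]
        if local[-1] < dur - 1e-12:
            local = np.append(local, dur)
        g = build_generator(scheme, v)
        occ = _propagate(g, p, local)
        i_seg = scheme.n_channels * E0_FC * ((occ @ g) @ z)
        # Keep both sides of each internal voltage step: the end-of-segment
        # sample is time-stamped 1 ns early so the next segment can own the
        # boundary instant (times stay strictly increasing, the pre- and
        # post-step currents are both recorded).
        t_out = local.copy()
        if k < len(protocol.segments) - 1:
            t_out[-1] -= 1e-6
        all_t.append(t_out + t_offset)
        all_i.append(i_seg)
        all_v.append(np.full(local.shape, v))
        p = occ[-1]
        t_offset += dur

    times = np.concatenate(all_t)
    annotations: dict = {
        "segments": [list(s) for s in protocol.segments],
        "sample_interval_ms": dt,
    }
    if len(protocol.segments) >= 3:
        d0 = protocol.segments[0][0]
        d1 = protocol.segments[1][0]
        annotations.update(
            depol_start_ms=d0,
            depol_end_ms=d0 + d1,
            repol_start_ms=d0 + d1,
            duration_ms=d1,
        )
    return Sweep(
        times=times,
        current=np.concatenate(all_i),
        voltage=np.concatenate(all_v),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Example configurations and config plumbing


def example_scheme(
    trapping: bool = True,
    n_channels: float = 1.0e8,
    temperature: float = ROOM_TEMPERATURE_K,
) -> KineticScheme:
    """A documented example 5-state scheme (A1-A3, B1-B2).

    Total gating charge 2 e0 split evenly over four transitions.  In the
    trapping variant the backward rate out of B1 (the A3 <-> B1 step) is
    two orders of magnitude slower than the other backward rates, so the
    sensor stalls in the activated well after repolarization; the
    non-trapping variant uses uniform backward rates and conserves
    charge on the tens-of-milliseconds scale.  These values are an
    illustrative parameterization, not a fitted ground truth.
    """
    if trapping:
        # slow entry into the trapped well (alpha0 of the A3->B1 step) and a
        # deep escape barrier (its beta0), so Q_OFF/Q_ON keeps falling over
        # tens of milliseconds of depolarization
        barrier = TransitionParams(alpha0=0.02, beta0=0.004, x=0.5, z_delta=0.5)
    else:
        barrier = TransitionParams(alpha0=0.35, beta0=1.2, x=0.5, z_delta=0.5)
    transitions = (
        TransitionParams(alpha0=0.25, beta0=1.2, x=0.5, z_delta=0.5),
        TransitionParams(alpha0=0.30, beta0=1.2, x=0.5, z_delta=0.5),
        barrier,
        TransitionParams(alpha0=0.30, beta0=1.2, x=0.5, z_delta=0.5),
    )
    return KineticScheme(
        state_names=("A1", "A2", "A3", "B1", "B2"),
        transitions=transitions,
        n_channels=n_channels,
        temperature=temperature,
    )


def step_protocol(
    hold_mv: float = -90.0,
    step_mv: float = 150.0,
    tail_mv: float = 0.0,
    hold_ms: float = 5.0,
    step_ms: float = 50.0,
    tail_ms: float = 50.0,
    sample_interval: float = 0.05,
) -> VoltageProtocol:
    """hold -> depolarizing step -> repolarization tail."""
    return VoltageProtocol(
        segments=((hold_ms, hold_mv), (step_ms, step_mv), (tail_ms, tail_mv)),
        sample_interval=sample_interval,
    )


def scheme_from_dict(cfg: dict) -> KineticScheme:
    """Build a scheme from the JSON config dialect.

    Expected keys: ``states`` (list of labels), ``transitions`` (list of
    {alpha0, beta0, x, z_delta}), optional ``n_channels`` and
    ``temperature_K``.
    """
    try:
        transitions = tuple(
            TransitionParams(
                alpha0=t["alpha0"], beta0=t["beta0"], x=t["x"], z_delta=t["z_delta"]
            )
            for t in cfg["transitions"]
        )
        return KineticScheme(
            state_names=tuple(cfg["states"]),
            transitions=transitions,
            n_channels=cfg.get("n_channels", 1.0e8),
            temperature=cfg.get("temperature_K", ROOM_TEMPERATURE_K),
        )
    except KeyError as exc:
        raise InvalidInputError(f"scheme config missing key {exc}") from exc


def protocol_from_dict(cfg: dict) -> VoltageProtocol:
    """Expected keys: ``segments`` ([[duration_ms, voltage_mV], ...]), ``sample_interval_ms``."""
    try:
        return VoltageProtocol(
            segments=tuple((s[0], s[1]) for s in cfg["segments"]),
            sample_interval=cfg.get("sample_interval_ms", 0.05),
        )
    except KeyError as exc:
        raise InvalidInputError(f"protocol config missing key {exc}") from exc


def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "states": list(scheme.state_names),
        "transitions": [
            {"alpha0": t.alpha0, "beta0": t.beta0, "x": t.x, "z_delta": t.z_delta}
            for t in scheme.transitions
        ],
        "n_channels": scheme.n_channels,
        "temperature_K": scheme.temperature,
    }
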