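"""Synthetic-data generators with serialized ground truth.

Every generator in this module produces inputs in exactly the dialects
the analysis modules consume — noisy Q(V) points, simulated gating-
current sweep families, exponential time courses, and toy coordinate
trajectories with prescribed salt-bridge distance dynamics — and returns
a :class:`GroundTruth` record (generator name, parameter map, seed) so
parameter-recovery tests can compare estimates against the truth.

Noise model: additive Gaussian scaled to the signal peak for current
traces and time courses, multiplicative Gaussian for Q(V) points.  All
randomness derives from a single integer seed via numpy's SeedSequence
spawning, so datasets are bit-reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import kinetic
from .equilibrium import BoltzmannParams, QVCurve, boltzmann
from .errors import GenerationError, InvalidInputError
from .md import (
    ARG_GUANIDINIUM_ATOMS,
    ASP_CARBOXYLATE_ATOMS,
    FrameSeries,
)
from .traces import Sweep, evaluate_model
from .units import ROOM_TEMPERATURE_K

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "DistanceSpec",
    "DURATION_FAMILY_MS",
    "gen_qv_points",
    "gen_gating_sweeps",
    "gen_recovery_sweeps",
    "gen_timecourse_series",
    "gen_toy_trajectory",
]

#: The eleven depolarization durations of the time-varying protocol, ms.
DURATION_FAMILY_MS = tuple(range(2, 53, 5))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise magnitudes and the seed controlling all draws.

    relative_sigma : Gaussian sigma as a fraction of the signal peak
    additive_sigma : Gaussian sigma in absolute signal units
    """

    relative_sigma: float = 0.0
    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.relative_sigma < 0 or self.additive_sigma < 0:
            raise InvalidInputError("noise sigmas must be non-negative")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Provenance sidecar serialized alongside every generated dataset."""

    generator: str
    params: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Q(V) points


def gen_qv_points(
    params: BoltzmannParams,
    voltages: Sequence[float],
    noise: NoiseSpec,
    n_replicates: int = 1,
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> tuple[list[QVCurve], GroundTruth]:
    """Replicate Q(V) curves from the ascending two-state Boltzmann.

    Noise is multiplicative (relative_sigma) plus optional additive
    Gaussian, mimicking per-patch charge-measurement scatter.
    """
    v = np.asarray(voltages, dtype=float)
    if not (v.min() < params.v_half < v.max()):
        raise InvalidInputError("voltages must span v_half")
    clean = boltzmann(
        v, params.v_half, params.z_delta, params.q_max, temperature_k=temperature_k
    )
    curves = []
    for r in range(n_replicates):
        rng = noise.rng(stream=r)
        q = clean * (1.0 + noise.relative_sigma * rng.standard_normal(v.shape))
        q = q + noise.additive_sigma * rng.standard_normal(v.shape)
        curves.append(QVCurve(voltages=v, charges=q, replicate_id=f"rep{r}"))
    truth = GroundTruth(
        generator="gen_qv_points",
        params={
            "v_half": params.v_half,
            "z_delta": params.z_delta,
            "q_max": params.q_max,
            "temperature_K": temperature_k,
            "voltages": v,
            "n_replicates": n_replicates,
            "relative_sigma": noise.relative_sigma,
            "additive_sigma": noise.additive_sigma,
        },
        seed=noise.seed,
    )
    return curves, truth


# ---------------------------------------------------------------------------
# gating-current sweep families


def _add_current_noise(sweep: Sweep, noise: NoiseSpec, rng: np.random.Generator) -> Sweep:
    peak = float(np.max(np.abs(sweep.current))) or 1.0
    sigma = noise.relative_sigma * peak + noise.additive_sigma
    current = sweep.current + sigma * rng.standard_normal(sweep.current.shape)
    return Sweep(
        times=sweep.times,
        current=current,
        voltage=sweep.voltage,
        annotations=dict(sweep.annotations),
    )


def gen_gating_sweeps(
    scheme: kinetic.KineticScheme,
    noise: NoiseSpec,
    durations_ms: Sequence[float] = DURATION_FAMILY_MS,
    hold_mv: float = -90.0,
    step_mv: float = 150.0,
    tail_mv: float = 0.0,
    hold_ms: float = 5.0,
    tail_ms: float = 50.0,
    sample_interval: float = 0.05,
) -> tuple[list[Sweep], GroundTruth]:
    """The time-varying depolarization family: one sweep per duration.

    Defaults reproduce the standard protocol: hold at -90 mV, step to a
    strong depolarization for each of eleven durations (2-52 ms in 5 ms
    increments), then repolarize to 0 mV (the proton reversal potential
    at symmetric pH).
    """
    sweeps = []
    for k, dur in enumerate(durations_ms):
        protocol = kinetic.step_protocol(
            hold_mv=hold_mv,
            step_mv=step_mv,
            tail_mv=tail_mv,
            hold_ms=hold_ms,
            step_ms=float(dur),
            tail_ms=tail_ms,
            sample_interval=sample_interval,
        )
        sweep = kinetic.simulate_protocol(scheme, protocol)
        sweeps.append(_add_current_noise(sweep, noise, noise.rng(stream=k)))
    truth = GroundTruth(
        generator="gen_gating_sweeps",
        params={
            "scheme": kinetic.scheme_to_dict(scheme),
            "durations_ms": list(durations_ms),
            "hold_mV": hold_mv,
            "step_mV": step_mv,
            "tail_mV": tail_mv,
            "relative_sigma": noise.relative_sigma,
            "additive_sigma": noise.additive_sigma,
        },
        seed=noise.seed,
    )
    return sweeps, truth


def gen_recovery_sweeps(
    scheme: kinetic.KineticScheme,
    noise: NoiseSpec,
    intervals_ms: Sequence[float] = tuple(range(5, 151, 5)),
    hold_mv: float = -90.0,
    pulse_mv: float = 200.0,
    pulse_ms: float = 30.0,
    hold_ms: float = 5.0,
    tail_ms: float = 30.0,
    sample_interval: float = 0.05,
) -> tuple[list[Sweep], GroundTruth]:
    """The double-pulse recovery family: interpulse interval grows 5 ms per trace.

    Each sweep holds at -90 mV, steps to +200 mV, returns to the holding
    potential for the interpulse interval, then applies an identical
    second pulse.  Annotations mark the second-pulse window so the
    recovered charge can be integrated downstream.
    """
    sweeps = []
    for k, gap in enumerate(intervals_ms):
        protocol = kinetic.VoltageProtocol(
            segments=(
                (hold_ms, hold_mv),
                (pulse_ms, pulse_mv),
                (float(gap), hold_mv),
                (pulse_ms, pulse_mv),
                (tail_ms, hold_mv),
            ),
            sample_interval=sample_interval,
        )
        sweep = kinetic.simulate_protocol(scheme, protocol)
        p2_start = hold_ms + pulse_ms + gap
        sweep.annotations.update(
            interval_ms=float(gap),
            pulse2_start_ms=p2_start,
            pulse2_end_ms=p2_start + pulse_ms,
        )
        sweeps.append(_add_current_noise(sweep, noise, noise.rng(stream=k)))
    truth = GroundTruth(
        generator="gen_recovery_sweeps",
        params={
            "scheme": kinetic.scheme_to_dict(scheme),
            "intervals_ms": list(intervals_ms),
            "pulse_mV": pulse_mv,
            "pulse_ms": pulse_ms,
            "relative_sigma": noise.relative_sigma,
            "additive_sigma": noise.additive_sigma,
        },
        seed=noise.seed,
    )
    return sweeps, truth


# ---------------------------------------------------------------------------
# exponential time courses


def gen_timecourse_series(
    model_id: str,
    params: dict,
    x: Sequence[float],
    noise: NoiseSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Evaluate an exponential model on a grid and add peak-scaled noise."""
    x = np.asarray(x, dtype=float)
    y = evaluate_model(model_id, x, params)
    rng = noise.rng()
    sigma = noise.relative_sigma * (float(np.max(np.abs(y))) or 1.0) + noise.additive_sigma
    y = y + sigma * rng.standard_normal(y.shape)
    truth = GroundTruth(
        generator="gen_timecourse_series",
        params={
            "model_id": model_id,
            **params,
            "x": x,
            "relative_sigma": noise.relative_sigma,
            "additive_sigma": noise.additive_sigma,
        },
        seed=noise.seed,
    )
    return x, y, truth


# ---------------------------------------------------------------------------
# toy trajectories

# Idealized rigid side-chain group templates (local coordinates, Angstrom);
# unit-mass COM at the origin.  Bond geometry is approximate — these are
# synthetic stand-ins for charged moieties, not force-field structures.
_ASP_TEMPLATE = np.array(
    [[0.0, -0.42, 0.0], [1.14, 0.21, 0.0], [-1.14, 0.21, 0.0]]
)  # CG, OD1, OD2
_ARG_TEMPLATE = np.array(
    [[0.0, -1.3325, 0.0], [0.0, -0.0025, 0.0], [1.15, 0.6675, 0.0], [-1.15, 0.6675, 0.0]]
)  # NE, CZ, NH1, NH2

_GROUP_AXES = {"R258": np.array([1.0, 0.0, 0.0]),
               "R261": np.array([0.0, 1.0, 0.0]),
               "R255": np.array([0.0, 0.0, 1.0])}


@dataclass(frozen=True)
class DistanceSpec:
    """Target distance process of one D160-arginine pair.

    With ``bound_fraction`` set, the pair switches between a bound state
    (mean ``mean``) and an unbound state (mean ``unbound_mean``) via a
    two-state Markov process with stationary bound probability
    ``bound_fraction`` and mean dwell ``mean_dwell_frames``; otherwise
    the distance fluctuates around ``mean`` alone.
    """

    mean: float = 4.0
    sigma: float = 0.2
    bound_fraction: float | None = None
    unbound_mean: float = 8.0
    mean_dwell_frames: int = 20

    def __post_init__(self):
        if self.mean <= 0 or self.unbound_mean <= 0 or self.sigma < 0:
            raise InvalidInputError("distances must be positive, sigma non-negative")
        if self.bound_fraction is not None and not 0.0 <= self.bound_fraction <= 1.0:
            raise InvalidInputError("bound_fraction must lie in [0, 1]")


def _two_state_path(spec: DistanceSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Markov telegraph with stationary bound probability f."""
    f = spec.bound_fraction
    if f in (0.0, 1.0):
        return np.where(np.full(n, bool(f)), spec.mean, spec.unbound_mean)
    # per-frame exit probabilities: bound dwell = mean_dwell_frames, and
    # detailed balance f * q_bu = (1 - f) * q_ub fixes the stationary fraction
    q_bu = min(1.0, 1.0 / spec.mean_dwell_frames)
    q_ub = min(1.0, q_bu * f / (1.0 - f))
    state = rng.random() < f
    path = np.empty(n, dtype=bool)
    draws = rng.random(n)
    for i in range(n):
        path[i] = state
        if state and draws[i] < q_bu:
            state = False
        elif not state and draws[i] < q_ub:
            state = True
    return np.where(path, spec.mean, spec.unbound_mean)


def gen_toy_trajectory(
    pair_specs: dict[str, DistanceSpec],
    n_frames: int = 500,
    seed: int = 0,
    frame_interval_ns: float = 0.1,
    pdb_path: str | Path | None = None,
) -> tuple[FrameSeries, GroundTruth]:
    """Toy trajectory of mock D160/R255/R258/R261 charged groups.

    The aspartate carboxylate sits at the origin; each arginine
    guanidinium is placed along its own fixed axis at the per-frame
    distance drawn from its :class:`DistanceSpec`, so the D160-arginine
    COM distances follow the requested process exactly (arginine-
    arginine distances are a geometric consequence).  With
    ``pdb_path`` set, a valid multi-model PDB is also written.
    """
    if n_frames < 100:
        raise InvalidInputError("need at least 100 frames")
    unknown = set(pair_specs) - set(_GROUP_AXES)
    if unknown:
        raise GenerationError(f"unknown group labels {sorted(unknown)}; "
                              f"expected subset of {sorted(_GROUP_AXES)}")
    if not pair_specs:
        raise GenerationError("pair_specs must name at least one arginine group")

    rng_root = np.random.SeedSequence(seed)
    streams = rng_root.spawn(len(pair_specs))

    groups = [("D160", "ASP", 160, ASP_CARBOXYLATE_ATOMS, _ASP_TEMPLATE)]
    distances: dict[str, np.ndarray] = {}
    for (label, spec), ss in zip(sorted(pair_specs.items()), streams):
        rng = np.random.default_rng(ss)
        if spec.bound_fraction is not None:
            base = _two_state_path(spec, n_frames, rng)
        else:
            base = np.full(n_frames, spec.mean)
        d = base + spec.sigma * rng.standard_normal(n_frames)
        d = np.clip(d, 0.5, None)
        distances[label] = d
        resid = int(label[1:])
        groups.append((label, "ARG", resid, ARG_GUANIDINIUM_ATOMS, _ARG_TEMPLATE))

    n_atoms = sum(len(g[3]) for g in groups)
    coords = np.empty((n_frames, n_atoms, 3))
    rows = []
    offset = 0
    selections: dict[str, np.ndarray] = {}
    for label, resname, resid, names, template in groups:
        idx = np.arange(offset, offset + len(names))
        selections[label] = idx
        for name in names:
            rows.append({"resid": resid, "name": name, "resname": resname, "chain": "A"})
        if label == "D160":
            coords[:, idx, :] = template[None, :, :]
        else:
            com = distances[label][:, None] * _GROUP_AXES[label][None, :]
            coords[:, idx, :] = template[None, :, :] + com[:, None, :]
        offset += len(names)

    import pandas as pd

    traj = FrameSeries(
        coords=coords,
        atoms=pd.DataFrame(rows),
        frame_interval_ns=frame_interval_ns,
        selections=selections,
    )
    truth = GroundTruth(
        generator="gen_toy_trajectory",
        params={
            label: dataclasses.asdict(spec) for label, spec in pair_specs.items()
        }
        | {"n_frames": n_frames, "frame_interval_ns": frame_interval_ns},
        seed=seed,
    )
    if pdb_path is not None:
        from .io import write_structure_frames

        write_structure_frames(traj, pdb_path)
    return traj, truth
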