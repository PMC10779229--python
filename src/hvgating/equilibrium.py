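"""Two-state Boltzmann analysis of Q(V) curves and activation energetics.

The total gating charge moved by a voltage step is fitted with the
ascending two-state Boltzmann

    Q(V)/Q_max = 1 / (1 + exp(-z_delta F (V - V_0.5) / RT))

where ``z_delta`` is the effective gating charge (e0) and ``V_0.5`` the
half-activation voltage.  The chemical free energy of the resting ->
active transition at 0 mV follows the standard two-state convention
dG = z_delta * F * V_0.5, reported in kcal/mol; per-mutant ddG values
can then be regressed against a residue hydrophobicity scale.

The descending orientation (positive exponent) is available behind the
``descending`` flag for completeness; activation data ascend with V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from .errors import FitFailureError, InvalidInputError
from .units import FARADAY, GAS_CONSTANT, J_PER_KCAL, ROOM_TEMPERATURE_K

__all__ = [
    "QVCurve",
    "BoltzmannParams",
    "FreeEnergyRecord",
    "build_qv",
    "merge_replicates",
    "boltzmann",
    "fit_boltzmann",
    "activation_free_energy",
    "ddg_hydrophobicity_correlation",
    "KYTE_DOOLITTLE",
    "WIMLEY_WHITE_INTERFACE",
]


@dataclass
class QVCurve:
    """Charge-vs-voltage points for one patch (or a pooled average)."""

    voltages: np.ndarray            # mV
    charges: np.ndarray             # fC (or normalized)
    replicate_id: str | None = None
    sem: np.ndarray | None = None   # per-voltage SEM when pooled

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.voltages.shape != self.charges.shape:
            raise InvalidInputError("voltages and charges must share length")
        if len(self.voltages) < 5:
            raise InvalidInputError("a Q(V) curve needs at least 5 points")
        if not np.all(np.isfinite(self.charges)):
            raise InvalidInputError("charges must be finite")


@dataclass(frozen=True)
class BoltzmannParams:
    """Two-state Boltzmann fit parameters."""

    v_half: float          # mV
    z_delta: float         # e0
    q_max: float           # fC (or 1 for normalized data)
    v_half_stderr: float | None = None
    z_delta_stderr: float | None = None
    q_max_stderr: float | None = None

    def __post_init__(self):
        if self.z_delta <= 0 or self.q_max <= 0:
            raise InvalidInputError("z_delta and q_max must be positive")


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Activation free energy of one variant plus its hydrophobicity index."""

    label: str
    delta_g: float                  # kcal/mol
    ddg_vs_reference: float         # kcal/mol
    hydrophobicity: float           # kcal/mol (scale value for the filter residue)


def build_qv(
    charge_by_voltage: Iterable[tuple[float, float]],
    normalize: bool = False,
    replicate_id: str | None = None,
) -> QVCurve:
    """Assemble a sorted Q(V) curve; duplicate voltages are averaged."""
    pts = np.asarray(list(charge_by_voltage), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("expected an iterable of (voltage, charge) pairs")
    v, q = pts[:, 0], pts[:, 1]
    uniq, inverse, counts = np.unique(v, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn("duplicate voltages averaged", RuntimeWarning)
        q = np.bincount(inverse, weights=q) / counts
        v = uniq
    order = np.argsort(v)
    v, q = v[order], q[order]
    if normalize:
        qmax = np.max(np.abs(q))
        if qmax == 0:
            raise InvalidInputError("cannot normalize an all-zero curve")
        q = q / qmax
    return QVCurve(voltages=v, charges=q, replicate_id=replicate_id)


def merge_replicates(curves: Sequence[QVCurve]) -> QVCurve:
    """Per-voltage mean and SEM across replicate patches (shared voltage grid)."""
    if len(curves) == 0:
        raise InvalidInputError("no curves to merge")
    v0 = curves[0].voltages
    for c in curves[1:]:
        if not np.array_equal(c.voltages, v0):
            raise InvalidInputError("replicates must share the voltage grid")
    q = np.stack([c.charges for c in curves])
    sem = q.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    return QVCurve(voltages=v0, charges=q.mean(axis=0), replicate_id="pooled", sem=sem)


def boltzmann(
    v_mv: np.ndarray,
    v_half: float,
    z_delta: float,
    q_max: float = 1.0,
    temperature_k: float = ROOM_TEMPERATURE_K,
    descending: bool = False,
) -> np.ndarray:
    """Two-state Boltzmann Q(V); ascending in V unless ``descending``."""
    v_mv = np.asarray(v_mv, dtype=float)
    u = z_delta * FARADAY * (v_mv - v_half) * 1e-3 / (GAS_CONSTANT * temperature_k)
    sign = 1.0 if descending else -1.0
    return q_max / (1.0 + np.exp(sign * u))


def fit_boltzmann(
    curve: QVCurve,
    temperature_k: float = ROOM_TEMPERATURE_K,
    descending: bool = False,
) -> BoltzmannParams:
    """Least-squares fit of the two-state Boltzmann to a Q(V) curve.

    The curve should span both sides of the inflection; a curve that is
    flat to within numerical noise raises :class:`FitFailureError`.
    """
    v, q = curve.voltages, curve.charges
    qspan = np.ptp(q)
    if qspan <= 1e-12 * max(np.max(np.abs(q)), 1.0):
        raise FitFailureError("curve is flat; no inflection to fit")

    qmax0 = float(np.max(q))
    vhalf0 = float(v[np.argmin(np.abs(q - qmax0 / 2.0))])

    params = Parameters()
    params.add("v_half", value=vhalf0)
    params.add("z_delta", value=1.0, min=1e-4)
    params.add("q_max", value=qmax0 if qmax0 > 0 else 1.0, min=1e-12)

    def resid(p):
        return (
            boltzmann(
                v,
                p["v_half"].value,
                p["z_delta"].value,
                p["q_max"].value,
                temperature_k=temperature_k,
                descending=descending,
            )
            - q
        )

    out = minimize(resid, params, method="leastsq")
    if not out.success:
        raise FitFailureError("Boltzmann fit did not converge", best=out)
    pv = out.params
    return BoltzmannParams(
        v_half=pv["v_half"].value,
        z_delta=pv["z_delta"].value,
        q_max=pv["q_max"].value,
        v_half_stderr=pv["v_half"].stderr,
        z_delta_stderr=pv["z_delta"].stderr,
        q_max_stderr=pv["q_max"].stderr,
    )


def activation_free_energy(params: BoltzmannParams) -> float:
    """dG (kcal/mol) of the resting -> active transition at 0 mV: z_delta F V_0.5."""
    return params.z_delta * FARADAY * params.v_half * 1e-3 / J_PER_KCAL


def ddg_vs_reference(params: BoltzmannParams, reference: BoltzmannParams) -> float:
    """ddG (kcal/mol) of a variant relative to a reference construct."""
    return activation_free_energy(params) - activation_free_energy(reference)


def ddg_hydrophobicity_correlation(
    records: Sequence[FreeEnergyRecord],
) -> tuple[float, float, float]:
    """OLS line (slope, intercept) and Pearson r of ddG vs hydrophobicity."""
    if len(records) < 3:
        raise InvalidInputError("need at least 3 records for a correlation")
    x = np.array([r.hydrophobicity for r in records], dtype=float)
    y = np.array([r.ddg_vs_reference for r in records], dtype=float)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# Hydrophobicity scales (kcal/mol per residue), offered as documented options;
# any residue -> value table of the same shape is accepted by callers.

#: Kyte & Doolittle hydropathy index (dimensionless, used as kcal/mol proxy).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Wimley-White interface transfer free energies (kcal/mol; negative = favorable).
WIMLEY_WHITE_INTERFACE: dict[str, float] = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}
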