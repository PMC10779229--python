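"""Trajectory post-processing: salt-bridge geometry, densities, energetics.

Works on :class:`FrameSeries`, an ordered stack of coordinate frames with
per-atom metadata and named atom-group selections.  Provides distance
series between charged-group centers of mass, distance distributions and
salt-bridge occupancy (threshold 4 Angstrom by convention), z-axis
density profiles, point-charge Coulomb energies of the selectivity-
filter/arginine triad with the fully-active -> intermediate-active
thermodynamic cycle, Kabsch superposition and k-means conformational
clustering.

A minimal selection language is supported: clauses joined by ``and``,
each clause being a keyword (``resid``, ``name``, ``resname``,
``chain``) followed by one or more values OR-ed together, e.g.
``"resid 160 and name OD1 OD2 CG"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import (
    DegenerateGeometryError,
    InvalidInputError,
    SelectionError,
)
from .units import COULOMB_KCAL_A

__all__ = [
    "FrameSeries",
    "ChargedGroupPair",
    "TriadEnergy",
    "CycleResult",
    "SALT_BRIDGE_THRESHOLD_A",
    "ASP_CARBOXYLATE_ATOMS",
    "ARG_GUANIDINIUM_ATOMS",
    "select_atoms",
    "group_distance_series",
    "distance_distribution",
    "salt_bridge_occupancy",
    "z_density_profile",
    "coulomb_energy",
    "cycle_energy",
    "kabsch_superpose",
    "cluster_frames",
]

#: Conventional salt-bridge distance cut-off between charged-group COMs, Angstrom.
SALT_BRIDGE_THRESHOLD_A = 4.0

#: Side-chain atoms defining the charged moieties used for COM distances.
ASP_CARBOXYLATE_ATOMS = ("CG", "OD1", "OD2")
ARG_GUANIDINIUM_ATOMS = ("NE", "CZ", "NH1", "NH2")


@dataclass
class FrameSeries:
    """Ordered coordinate frames plus atom metadata and named selections.

    coords : (n_frames, n_atoms, 3) array, Angstrom
    atoms  : DataFrame with columns resid, name, resname, chain
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_interval_ns: float = 1.0
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise InvalidInputError("atom metadata length must match coords")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidInputError("coordinates must be finite")
        for col in ("resid", "name"):
            if col not in self.atoms.columns:
                raise InvalidInputError(f"atom table missing column '{col}'")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def add_selection(self, label: str, expr: str) -> np.ndarray:
        idx = select_atoms(self.atoms, expr)
        self.selections[label] = idx
        return idx

    def resolve(self, selection: str | Sequence[int]) -> np.ndarray:
        """Resolve a selection label, expression or explicit index list."""
        if isinstance(selection, str):
            if selection in self.selections:
                return np.asarray(self.selections[selection], dtype=int)
            return select_atoms(self.atoms, selection)
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise SelectionError("empty explicit selection")
        return idx

    def discard_initial(self, fraction: float) -> "FrameSeries":
        """Drop the leading ``fraction`` of frames (equilibration burn-in)."""
        if not 0.0 <= fraction < 1.0:
            raise InvalidInputError("fraction must lie in [0, 1)")
        start = int(round(fraction * self.n_frames))
        return FrameSeries(
            coords=self.coords[start:],
            atoms=self.atoms,
            frame_interval_ns=self.frame_interval_ns,
            selections=dict(self.selections),
        )


_SELECTION_KEYWORDS = ("resid", "name", "resname", "chain")


def select_atoms(atoms: pd.DataFrame, expr: str) -> np.ndarray:
    """Indices matching a mini-language expression like ``"resid 258 and name NE CZ"``."""
    mask = np.ones(len(atoms), dtype=bool)
    for clause in expr.split(" and "):
        tokens = clause.split()
        if len(tokens) < 2 or tokens[0] not in _SELECTION_KEYWORDS:
            raise SelectionError(
                f"bad clause {clause!r}; expected '<keyword> value ...' with keyword "
                f"in {_SELECTION_KEYWORDS}"
            )
        key, values = tokens[0], tokens[1:]
        if key == "resid":
            try:
                vals = [int(v) for v in values]
            except ValueError as exc:
                raise SelectionError(f"non-integer resid in {clause!r}") from exc
            mask &= atoms["resid"].isin(vals).to_numpy()
        else:
            mask &= atoms[key].isin(values).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return idx


@dataclass
class ChargedGroupPair:
    """A pair of charged groups with their per-frame COM distance series."""

    group_a: str
    group_b: str
    q_a: float                  # e0
    q_b: float                  # e0
    distance_series: np.ndarray  # Angstrom per frame

    def __post_init__(self):
        self.distance_series = np.asarray(self.distance_series, dtype=float)
        if np.any(self.distance_series <= 0):
            raise InvalidInputError("distances must be positive")


@dataclass(frozen=True)
class TriadEnergy:
    """Time-averaged pair energies of the D160/R258/R261 triad (kcal/mol)."""

    pair_energies: tuple[tuple[str, float], ...]
    state: str      # "A_I" or "A_F"
    variant: str

    @property
    def total(self) -> float:
        return float(sum(e for _, e in self.pair_energies))


@dataclass(frozen=True)
class CycleResult:
    """Thermodynamic-cycle energies for the A_F -> A_I transition (kcal/mol)."""

    delta_e_variant: float
    delta_e_reference: float
    variant: str
    reference: str

    @property
    def ddelta_e(self) -> float:
        return self.delta_e_variant - self.delta_e_reference


# ---------------------------------------------------------------------------
# geometry


def _com_series(
    traj: FrameSeries, idx: np.ndarray, masses: np.ndarray | None
) -> np.ndarray:
    xyz = traj.coords[:, idx, :]
    if masses is None:
        return xyz.mean(axis=1)
    m = np.asarray(masses, dtype=float)
    if m.shape != (len(idx),):
        raise InvalidInputError("masses must match the selection size")
    return (xyz * m[None, :, None]).sum(axis=1) / m.sum()


def group_distance_series(
    traj: FrameSeries,
    sel_a: str | Sequence[int],
    sel_b: str | Sequence[int],
    masses_a: np.ndarray | None = None,
    masses_b: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame distance between the centers of mass of two atom groups.

    Unit masses are used unless explicit masses are given, matching the
    convention of COM distances between charged side-chain moieties.
    """
    ia = traj.resolve(sel_a)
    ib = traj.resolve(sel_b)
    com_a = _com_series(traj, ia, masses_a)
    com_b = _com_series(traj, ib, masses_b)
    return np.linalg.norm(com_a - com_b, axis=1)


def distance_distribution(
    series: Sequence[float], bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized distance histogram: (bin_edges, probability mass per bin)."""
    d = np.asarray(series, dtype=float)
    if len(d) < 10:
        raise InvalidInputError("need at least 10 samples for a distribution")
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    return edges, counts / counts.sum()


def salt_bridge_occupancy(
    series: Sequence[float], threshold: float = SALT_BRIDGE_THRESHOLD_A
) -> float:
    """Fraction of frames with COM distance at or below the threshold."""
    d = np.asarray(series, dtype=float)
    if d.size == 0:
        raise InvalidInputError("empty distance series")
    return float(np.mean(d <= threshold))


def z_density_profile(
    traj: FrameSeries,
    selection: str | Sequence[int],
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged density of a selection along the membrane normal (z).

    Returns (bin_centers, density) with the profile normalized so its
    peak equals 1.
    """
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    idx = traj.resolve(selection)
    zs = traj.coords[:, idx, 2].ravel()
    lo = np.floor(zs.min() / bin_width) * bin_width
    hi = np.ceil(zs.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(zs, bins=edges)
    dens = counts.astype(float)
    dens /= dens.max()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


# ---------------------------------------------------------------------------
# energetics


def coulomb_energy(pair: ChargedGroupPair, epsilon_r: float) -> float:
    """Time-averaged screened point-charge Coulomb energy, kcal/mol.

    E = <k_C q_a q_b / (epsilon_r r)> over frames, k_C ~ 332.06
    kcal Angstrom / (mol e0^2).  The relative permittivity ``epsilon_r``
    is a modelling choice and must be given explicitly.
    """
    if not epsilon_r > 0:
        raise InvalidInputError("epsilon_r must be positive")
    r = pair.distance_series
    if np.any(r == 0):
        raise InvalidInputError("zero distance encountered; Coulomb energy singular")
    return float(np.mean(COULOMB_KCAL_A * pair.q_a * pair.q_b / (epsilon_r * r)))


def triad_energy(
    pairs: Sequence[ChargedGroupPair],
    epsilon_r: float,
    state: str,
    variant: str,
) -> TriadEnergy:
    """Sum of time-averaged pair Coulomb energies for one state/variant."""
    terms = tuple(
        (f"{p.group_a}-{p.group_b}", coulomb_energy(p, epsilon_r)) for p in pairs
    )
    return TriadEnergy(pair_energies=terms, state=state, variant=variant)


def cycle_energy(
    triads: Sequence[TriadEnergy], variant: str, reference: str
) -> CycleResult:
    """Thermodynamic cycle over {A_I, A_F} x {variant, reference}.

    dE = E(A_I) - E(A_F) per construct; ddE = dE_variant - dE_reference.
    """
    table: dict[tuple[str, str], float] = {}
    for tr in triads:
        table[(tr.variant, tr.state)] = tr.total
    needed = [(lbl, st) for lbl in (variant, reference) for st in ("A_I", "A_F")]
    missing = [k for k in needed if k not in table]
    if missing:
        raise InvalidInputError(f"missing triad energies for {missing}")
    de_var = table[(variant, "A_I")] - table[(variant, "A_F")]
    de_ref = table[(reference, "A_I")] - table[(reference, "A_F")]
    return CycleResult(
        delta_e_variant=de_var,
        delta_e_reference=de_ref,
        variant=variant,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# superposition and clustering


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of frame b onto frame a.

    Returns (rotation, translation, rmsd) such that
    ``coords_b @ rotation.T + translation`` minimizes the RMSD to
    ``coords_a`` over all proper rigid motions (SVD solution with
    reflection correction).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise InvalidInputError("coordinate arrays must share shape (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-9) < 2 or np.linalg.matrix_rank(b0, tol=1e-9) < 2:
        raise DegenerateGeometryError("atoms are collinear; rotation underdetermined")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    trans = ca - cb @ rot.T
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd


def cluster_frames(
    traj: FrameSeries,
    k: int,
    seed: int = 0,
    selection: str | Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means clustering of superposed frames; returns (labels, centroid frame indices).

    Frames are first rigid-body superposed onto the first frame on the
    clustering selection (Calpha atoms when present, else all atoms),
    then k-means is run on the flattened coordinates — equivalent to an
    RMSD metric up to a constant factor.  The per-cluster representative
    is the frame nearest its cluster mean.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > traj.n_frames:
        raise InvalidInputError(f"k={k} exceeds the {traj.n_frames} available frames")
    if selection is None:
        try:
            idx = traj.resolve("name CA")
        except SelectionError:
            idx = np.arange(traj.n_atoms)
    else:
        idx = traj.resolve(selection)

    ref = traj.coords[0, idx, :]
    flat = np.empty((traj.n_frames, idx.size * 3))
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(ref, traj.coords[f, idx, :])
        flat[f] = (traj.coords[f, idx, :] @ rot.T + trans).ravel()

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(flat)
    centroids = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        dist = np.linalg.norm(flat[members] - km.cluster_centers_[c], axis=1)
        centroids[c] = members[np.argmin(dist)]
    return labels, centroids
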