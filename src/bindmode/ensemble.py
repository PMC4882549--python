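"""Snapshot-ensemble statistics, geometry monitors and profile comparison.

An :class:`Ensemble` is a molecular system plus an ordered stack of coordinate
frames (e.g. the equilibrated tail of an MD trajectory).  Energies are
averaged over frames with the standard error of the mean (sample SD divided by
sqrt(n)); geometry monitors cover superposed RMSD, pocket membership,
atom-atom distances and hydrogen-bond occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .ff_energy import (
    EnergyBreakdown,
    MolecularSystem,
    ResidueProfile,
    SelectionError,
    SolventModelParams,
    decompose_snapshot,
    mmgbsa_snapshot,
)

#: default geometric criteria for a hydrogen bond (distance in A, angle in deg)
HBOND_DISTANCE_MAX = 3.5
HBOND_ANGLE_MIN = 135.0
#: default N...O distance for a salt-bridge contact (A)
SALT_BRIDGE_DISTANCE_MAX = 4.0


@dataclass
class Ensemble:
    """A system with >= 1 coordinate frames of identical atom count."""

    system: MolecularSystem
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise SelectionError("frames must be a non-empty (n, atoms, 3) stack")
        if self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise SelectionError("frame atom count does not match system")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class EnergyStats:
    """Frame-averaged binding energy with per-term SEM.

    ``sem`` maps each term name (and ``"total"``) to its own standard error
    over frames — the total's SEM comes from the per-frame totals, since the
    terms are correlated.  Entries are NaN when only one frame is available.
    """

    mean: EnergyBreakdown
    sem: dict[str, float]
    n_frames: int

    def format_total(self) -> str:
        """Render the total as the conventional two-decimal 'mean ± sem'."""
        return f"{self.mean.total:.2f} ± {self.sem['total']:.2f}"


@dataclass
class GeometrySeries:
    """A per-frame scalar (distance or RMSD, in A) with summary statistics."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


def _per_term(values: list[EnergyBreakdown], fn) -> EnergyBreakdown:
    arr = np.array([[eb.e_vdw, eb.e_ele, eb.g_pol, eb.g_nonpol] for eb in values])
    out = fn(arr)
    return EnergyBreakdown(*out)


def ensemble_energy_stats(ensemble: Ensemble, params: SolventModelParams) -> EnergyStats:
    """Mean and SEM of the snapshot binding energy over all frames.

    SEM uses the sample standard deviation (n-1 denominator) over sqrt(n); a
    single-frame ensemble reports NaN SEMs.
    """
    per_frame = [mmgbsa_snapshot(ensemble.system, f, params) for f in ensemble.frames]
    mean = _per_term(per_frame, lambda a: a.mean(axis=0))
    names = ("e_vdw", "e_ele", "g_pol", "g_nonpol", "total")
    if len(per_frame) > 1:
        arr = np.array([[getattr(eb, t) for t in names] for eb in per_frame])
        sems = arr.std(axis=0, ddof=1) / math.sqrt(len(per_frame))
        sem = dict(zip(names, sems.tolist()))
    else:
        sem = {t: math.nan for t in names}
    return EnergyStats(mean=mean, sem=sem, n_frames=len(per_frame))


def ensemble_decomposition(
    ensemble: Ensemble, params: SolventModelParams, icosa_depth: int = 3
) -> ResidueProfile:
    """Arithmetic frame average of the per-residue decomposition.

    Averaging is linear per term, so the pairwise-term conservation invariant
    of the single-snapshot decomposition is preserved.
    """
    profiles = [
        decompose_snapshot(ensemble.system, f, params, icosa_depth=icosa_depth)
        for f in ensemble.frames
    ]
    first = profiles[0]
    averaged: dict[int, EnergyBreakdown] = {}
    for idx in first.contributions:
        terms = [p.contributions[idx] for p in profiles]
        averaged[idx] = _per_term(terms, lambda a: a.mean(axis=0))
    return ResidueProfile(averaged, dict(first.residue_names))


# ---------------------------------------------------------------------------
# Geometry monitors
# ---------------------------------------------------------------------------


def _resolve_selection(
    system: MolecularSystem, selection: Callable | Sequence[int] | np.ndarray
) -> np.ndarray:
    if callable(selection):
        idx = np.array([i for i, a in enumerate(system.atoms) if selection(a)], dtype=int)
    else:
        idx = np.asarray(selection, dtype=int)
    if len(idx) == 0:
        raise SelectionError("selection matched no atoms")
    return idx


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation of ``mobile`` onto ``ref`` (least squares).

    Uses the SVD of the covariance matrix with the determinant correction that
    guarantees a proper rotation.
    """
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    return rot, rc - rot @ mc


def superpose_rmsd(
    ensemble: Ensemble,
    selection: Callable | Sequence[int] | np.ndarray,
    reference: int = 0,
    label: str = "rmsd",
) -> GeometrySeries:
    """Per-frame RMSD over a selection after least-squares superposition.

    Each frame is rigidly fitted onto the reference frame over the selected
    atoms before the RMSD is evaluated on those same atoms.
    """
    idx = _resolve_selection(ensemble.system, selection)
    if len(idx) < 3:
        raise SelectionError("superposition needs >= 3 selected atoms")
    ref = ensemble.frames[reference][idx]
    out = np.empty(ensemble.n_frames)
    for f, frame in enumerate(ensemble.frames):
        rot, trans = _kabsch(frame[idx], ref)
        moved = frame[idx] @ rot.T + trans
        out[f] = math.sqrt(((moved - ref) ** 2).sum(axis=1).mean())
    return GeometrySeries(out, label)


def pocket_residues(
    system: MolecularSystem, frame: np.ndarray, cutoff: float = 5.0
) -> set[int]:
    """Receptor residues with a heavy atom within ``cutoff`` of a ligand heavy atom."""
    if cutoff <= 0:
        raise SelectionError("cutoff must be > 0")
    frame = system.check_frame(frame)
    heavy = np.array([not a.element_is_hydrogen for a in system.atoms])
    lig = system.ligand_idx[heavy[system.ligand_idx]]
    found: set[int] = set()
    for res_idx, _, span in system.residues:
        atoms = np.arange(span.start, span.stop)
        if system.atoms[span.start].segment != "receptor":
            continue
        atoms = atoms[heavy[atoms]]
        if len(atoms) == 0 or len(lig) == 0:
            continue
        d = np.linalg.norm(frame[atoms][:, None] - frame[lig][None, :], axis=-1)
        if d.min() <= cutoff:
            found.add(res_idx)
    return found


def _resolve_single(system: MolecularSystem, selector) -> int:
    idx = _resolve_selection(system, selector) if not isinstance(selector, (int, np.integer)) \
        else np.array([selector])
    if len(idx) != 1:
        raise SelectionError(f"selector resolved to {len(idx)} atoms, expected 1")
    return int(idx[0])


def distance_series(
    ensemble: Ensemble, atom_a, atom_b, label: str = "distance"
) -> GeometrySeries:
    """Euclidean distance between two atoms in every frame."""
    ia = _resolve_single(ensemble.system, atom_a)
    ib = _resolve_single(ensemble.system, atom_b)
    vals = np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib], axis=1)
    return GeometrySeries(vals, label)


def hbond_occupancy(
    ensemble: Ensemble,
    donor,
    hydrogen,
    acceptor,
    distance_max: float = HBOND_DISTANCE_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> float:
    """Fraction of frames with a donor-H...acceptor hydrogen bond.

    The bond is counted when the heavy-atom distance D...A is at most
    ``distance_max`` and the D-H...A angle is at least ``angle_min`` degrees.
    """
    i_d = _resolve_single(ensemble.system, donor)
    i_h = _resolve_single(ensemble.system, hydrogen)
    i_a = _resolve_single(ensemble.system, acceptor)
    d_vec = ensemble.frames[:, i_a] - ensemble.frames[:, i_d]
    da = np.linalg.norm(d_vec, axis=1)
    hd = ensemble.frames[:, i_d] - ensemble.frames[:, i_h]
    ha = ensemble.frames[:, i_a] - ensemble.frames[:, i_h]
    cosang = (hd * ha).sum(axis=1) / (
        np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(((da <= distance_max) & (angle >= angle_min)).mean())


def differential_residues(
    profile_a: ResidueProfile,
    profile_b: ResidueProfile,
    threshold: float = 0.5,
) -> list[tuple[int, float]]:
    """Residues whose total contribution differs by >= ``threshold`` kcal/mol.

    Returns ``(residue_index, total_a - total_b)`` sorted by decreasing
    absolute difference — the rule used to contrast enantiomer binding modes.
    """
    keys_a, keys_b = set(profile_a.contributions), set(profile_b.contributions)
    shared = keys_a & keys_b
    if not shared:
        raise SelectionError("profiles share no residues")
    deltas = [
        (idx, profile_a.contributions[idx].total - profile_b.contributions[idx].total)
        for idx in shared
    ]
    flagged = [(i, d) for i, d in deltas if abs(d) >= threshold]
    return sorted(flagged, key=lambda t: (-abs(t[1]), t[0]))
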