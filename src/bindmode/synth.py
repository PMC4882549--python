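"""Synthetic pocket-ligand complexes, jittered ensembles and planted matrices.

The generators let every pipeline stage run and be tested without any
simulation output: a toy binding pocket with physically plausible force-field
parameters stands in for an equilibrated complex, Gaussian coordinate jitter
stands in for a snapshot ensemble, and a planted-group residue-energy matrix
mimics the statistical shape of real per-residue decompositions — one
strongly favorable group shared across ligands, weaker groups, a few weakly
unfavorable residues, and a large block of exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .ff_energy import AtomRecord, MolecularSystem, R_KCAL
from .thermo import T_CONVERSION

# element-wise plausible parameters: (lj_rmin_half, lj_epsilon, gb_radius,
# gb_screen, sasa_radius); values are in the range of common biomolecular
# force fields for heavy atoms
_ELEMENT_PARAMS = {
    "C": (1.908, 0.1094, 1.70, 0.72, 1.70),
    "N": (1.824, 0.1700, 1.55, 0.79, 1.55),
    "O": (1.661, 0.2100, 1.50, 0.85, 1.50),
}

# neutral LCPO weights: exact in the two-sphere truncation, adequate for the
# sparsely overlapping toy geometries generated here
_LCPO_NEUTRAL = (1.0, -1.0, 0.0, 0.0)

_RESIDUE_NAMES = ("ALA", "VAL", "TYR", "SER", "PHE", "MET", "GLY")


def _place_points(rng: np.random.Generator, n: int, center: np.ndarray,
                  spread: float, min_sep: float = 1.2) -> np.ndarray:
    """Rejection-sample n points around a center with a minimum separation."""
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = center + rng.uniform(-spread, spread, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts)


def build_toy_complex(
    n_pocket_residues: int,
    n_ligand_atoms: int,
    seed: int,
) -> tuple[MolecularSystem, np.ndarray]:
    """A small pocket-plus-ligand complex with plausible parameters.

    Ligand atoms sit near the origin; each pocket residue contributes three
    heavy atoms centered on a sphere of radius 6-10 A.  Partial charges are
    drawn in [-0.5, 0.5] e except for a designated salt-bridge pair: the first
    ligand atom (an amine-like nitrogen, +1 e) and the first atom of residue 1
    (a carboxylate-like oxygen, -1 e).  Deterministic under ``seed``.
    """
    if n_pocket_residues < 1 or n_ligand_atoms < 1:
        raise ValueError("need >= 1 pocket residue and >= 1 ligand atom")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    serial = 1

    def make_atom(element: str, name: str, res_idx: int, res_name: str,
                  segment: str, xyz: np.ndarray, charge: float) -> AtomRecord:
        nonlocal serial
        rmh, eps, gbr, scr, sr = _ELEMENT_PARAMS[element]
        rec = AtomRecord(
            serial=serial, name=name, residue_index=res_idx,
            residue_name=res_name, segment=segment,
            coords=tuple(float(v) for v in xyz), charge=float(charge),
            lj_rmin_half=rmh, lj_epsilon=eps, gb_radius=gbr, gb_screen=scr,
            sasa_radius=sr, lcpo_p=_LCPO_NEUTRAL,
        )
        serial += 1
        return rec

    # pocket residues on a 6-10 A shell around the ligand
    elements = ("C", "N", "O")
    for r in range(1, n_pocket_residues + 1):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = direction * rng.uniform(6.0, 10.0)
        res_name = "ASP" if r == 1 else _RESIDUE_NAMES[rng.integers(len(_RESIDUE_NAMES))]
        xyz = _place_points(rng, 3, center, spread=0.9)
        for a in range(3):
            element = "O" if (r == 1 and a == 0) else elements[rng.integers(3)]
            charge = -1.0 if (r == 1 and a == 0) else rng.uniform(-0.5, 0.5)
            name = f"{'OD' if (r == 1 and a == 0) else element}{a + 1}"
            atoms.append(make_atom(element, name, r, res_name, "receptor", xyz[a], charge))

    lig_idx = n_pocket_residues + 1
    lig_xyz = _place_points(rng, n_ligand_atoms, np.zeros(3), spread=1.6)
    for a in range(n_ligand_atoms):
        element = "N" if a == 0 else elements[rng.integers(3)]
        charge = 1.0 if a == 0 else rng.uniform(-0.5, 0.5)
        name = f"{'N' if a == 0 else element}{a + 1}"
        atoms.append(make_atom(element, name, lig_idx, "LIG", "ligand", lig_xyz[a], charge))

    system = MolecularSystem(atoms, ligand_label="LIG")
    return system, system.base_coordinates()


def jitter_ensemble(
    system: MolecularSystem,
    frame: np.ndarray,
    n_frames: int,
    sigma: float = 0.3,
    seed: int = 0,
) -> Ensemble:
    """Gaussian-jittered snapshot stack around a base frame.

    Displacements are i.i.d. normal per atom, per frame, per axis with
    standard deviation ``sigma`` (A); sigma = 0 replicates the base frame.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    frame = system.check_frame(frame)
    if sigma > 0:
        frames = frame[None] + rng.normal(0.0, sigma, size=(n_frames, system.n_atoms, 3))
    else:
        frames = np.repeat(frame[None], n_frames, axis=0)
    return Ensemble(system=system, frames=frames)


@dataclass(frozen=True)
class PlantedMatrixSpec:
    """Ground-truth design of a synthetic residue x ligand energy matrix.

    Defaults emulate the shape of a transporter-wide per-residue
    decomposition for four ligands: an 11-residue strongly favorable shared
    group, two progressively weaker groups, a small weakly unfavorable group
    (238 contributing residues in total), and enough exact-zero residues to
    bring the full matrix to 538 rows.
    """

    group_sizes: tuple[int, ...] = (11, 47, 90, 90)
    group_means: tuple[float, ...] = (-2.5, -0.8, -0.2, 0.1)
    within_sd: float = 0.1
    n_ligands: int = 4
    zero_fraction: float = 300.0 / 538.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_means):
            raise ValueError("group_sizes and group_means must align")
        if len(self.group_sizes) < 2:
            raise ValueError("need >= 2 groups")
        if self.within_sd < 0 or not (0 <= self.zero_fraction < 1):
            raise ValueError("invalid noise or zero fraction")


def planted_matrix(spec: PlantedMatrixSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Residue-energy matrix with planted group structure and true labels.

    Each residue's ligand vector is drawn around its group mean; exact-zero
    residues (label -1) are appended to exercise the nonzero-row filter.
    Rows are shuffled deterministically so group order carries no signal.
    """
    rng = np.random.default_rng(spec.seed)
    n_signal = sum(spec.group_sizes)
    n_zero = round(n_signal * spec.zero_fraction / (1.0 - spec.zero_fraction))

    rows, labels = [], []
    for g, (size, mean) in enumerate(zip(spec.group_sizes, spec.group_means)):
        vecs = mean + rng.normal(0.0, spec.within_sd, size=(size, spec.n_ligands)) \
            if spec.within_sd > 0 else np.full((size, spec.n_ligands), mean)
        rows.append(vecs)
        labels.extend([g] * size)
    if n_zero:
        rows.append(np.zeros((n_zero, spec.n_ligands)))
        labels.extend([-1] * n_zero)

    data = np.vstack(rows)
    labels = np.array(labels)
    order = rng.permutation(len(labels))
    data, labels = data[order], labels[order]
    index = [f"RES{i + 1}" for i in range(len(labels))]
    columns = [f"lig{j + 1}" for j in range(spec.n_ligands)]
    return pd.DataFrame(data, index=index, columns=columns), labels


def ki_from_dg(dg: float, temperature: float = T_CONVERSION) -> float:
    """Inhibition constant in nM from a binding free energy (kcal/mol).

    Exact inverse of the dG = RT ln(K_i) conversion.
    """
    return math.exp(dg / (R_KCAL * temperature)) * 1e9
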