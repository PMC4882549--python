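"""Molecular-mechanics / Generalized-Born energy engine for single snapshots.

Implements the single-trajectory MM/GBSA binding energy

    dG_bind = dE_vdw + dE_ele + dG_pol + dG_nonpol

and its per-residue decomposition for a receptor-ligand complex evaluated on
complex coordinates.  The gas-phase terms are complete pairwise sums (no
cutoff); the polar solvation term uses Hawkins-Cramer-Truhlar (HCT) pairwise
descreening for the effective Born radii together with the Still interpolation
function; the nonpolar term is a surface-area model, with an analytic LCPO
surface for system totals and a recursive-icosahedron surface for the
per-residue split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("bindmode")

#: Coulomb constant in kcal * Angstrom / (mol * e^2).
COULOMB_CONST = 332.0636

#: Gas constant in kcal / (mol * K).
R_KCAL = 1.9872e-3

#: Minimum receptor-ligand separation before geometry is declared degenerate (A).
MIN_PAIR_DISTANCE = 1e-6


class DegenerateGeometryError(ValueError):
    """Two interacting atoms (near-)coincide, so pair energies diverge."""


class ParameterError(ValueError):
    """An atomic parameter violates a physical precondition."""


class SelectionError(ValueError):
    """An atom/residue selection is empty, ambiguous, or misaligned."""


# ---------------------------------------------------------------------------
# Parameters and system containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolventModelParams:
    """Implicit-solvent and electrostatics settings.

    Parameters
    ----------
    eps_in
        Solute interior dielectric constant (dimensionless, >= 1).
    eps_out
        Solvent dielectric constant (dimensionless, > ``eps_in``).
    salt_conc
        Monovalent salt concentration in mol/L; enters through a Debye
        screening factor on the solvent part of the GB energy.
    probe_radius
        Solvent probe radius in Angstrom used by both surface models.
    gb_offset
        Offset subtracted from intrinsic Born radii before descreening (A).
    gamma_nonpolar
        Surface-tension coefficient of the nonpolar term, kcal/mol/A^2.
    coulomb_const
        Electrostatic constant, kcal*A/mol/e^2.
    temperature
        Temperature in kelvin used for thermodynamic conversions.
    """

    eps_in: float = 1.0
    eps_out: float = 80.0
    salt_conc: float = 0.15
    probe_radius: float = 1.4
    gb_offset: float = 0.09
    gamma_nonpolar: float = 0.0072
    coulomb_const: float = COULOMB_CONST
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.eps_out > self.eps_in >= 1.0):
            raise ParameterError("require eps_out > eps_in >= 1")
        if self.probe_radius < 0:
            raise ParameterError("probe_radius must be >= 0")
        if self.gamma_nonpolar <= 0:
            raise ParameterError("gamma_nonpolar must be > 0")
        if self.salt_conc < 0:
            raise ParameterError("salt_conc must be >= 0")

    @property
    def kappa(self) -> float:
        """Debye screening constant in 1/A: 0.329 * sqrt(I[mol/L])."""
        return 0.329 * math.sqrt(self.salt_conc)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates-independent force-field parameters.

    ``lcpo_p`` holds the four LCPO weights (P1..P4); ``gb_screen`` is the HCT
    descreening scale factor S.
    """

    serial: int
    name: str
    residue_index: int
    residue_name: str
    segment: str  # "receptor" | "ligand"
    coords: tuple[float, float, float]
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    gb_radius: float
    gb_screen: float
    sasa_radius: float
    lcpo_p: tuple[float, float, float, float] = (1.0, -1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.segment not in ("receptor", "ligand"):
            raise ParameterError(f"atom {self.serial}: segment must be receptor|ligand")
        if self.lj_epsilon < 0:
            raise ParameterError(f"atom {self.serial}: lj_epsilon must be >= 0")
        if self.gb_radius <= 0:
            raise ParameterError(f"atom {self.serial}: gb_radius must be > 0")
        if self.sasa_radius < 0:
            raise ParameterError(f"atom {self.serial}: sasa_radius must be >= 0")

    @property
    def element_is_hydrogen(self) -> bool:
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper() == "H"


class MolecularSystem:
    """An ordered atom list partitioned into receptor and ligand segments.

    Residues are contiguous runs of atoms sharing ``residue_index``; the
    ligand is treated as a single unit in all decompositions.
    """

    def __init__(self, atoms: Sequence[AtomRecord], ligand_label: str = "LIG"):
        atoms = list(atoms)
        if not atoms:
            raise SelectionError("system needs at least one atom")
        self.atoms = atoms
        self.ligand_label = ligand_label

        seg = np.array([a.segment for a in atoms])
        self.receptor_idx = np.flatnonzero(seg == "receptor")
        self.ligand_idx = np.flatnonzero(seg == "ligand")
        if len(self.receptor_idx) == 0 or len(self.ligand_idx) == 0:
            raise SelectionError("system needs >=1 receptor and >=1 ligand atom")

        self.serials = np.array([a.serial for a in atoms], dtype=int)
        self.charges = np.array([a.charge for a in atoms])
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in atoms])
        self.lj_epsilon = np.array([a.lj_epsilon for a in atoms])
        self.gb_radius = np.array([a.gb_radius for a in atoms])
        self.gb_screen = np.array([a.gb_screen for a in atoms])
        self.sasa_radius = np.array([a.sasa_radius for a in atoms])
        self.lcpo = np.array([a.lcpo_p for a in atoms])
        self.residue_of_atom = np.array([a.residue_index for a in atoms], dtype=int)

        # contiguous residue spans; every atom belongs to exactly one residue
        self.residues: list[tuple[int, str, slice]] = []
        start = 0
        for i in range(1, len(atoms) + 1):
            if i == len(atoms) or atoms[i].residue_index != atoms[start].residue_index:
                self.residues.append(
                    (atoms[start].residue_index, atoms[start].residue_name, slice(start, i))
                )
                start = i
        seen = [r[0] for r in self.residues]
        if len(set(seen)) != len(seen):
            raise SelectionError("residue indices must form contiguous atom runs")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def receptor_residue_indices(self) -> list[int]:
        return [idx for idx, _, span in self.residues
                if self.atoms[span.start].segment == "receptor"]

    def base_coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def check_frame(self, frame: np.ndarray) -> np.ndarray:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (self.n_atoms, 3):
            raise SelectionError(
                f"frame shape {frame.shape} does not match {self.n_atoms} atoms"
            )
        return frame


@dataclass(frozen=True)
class EnergyBreakdown:
    """The four MM/GBSA terms and their sum, all in kcal/mol."""

    e_vdw: float
    e_ele: float
    g_pol: float
    g_nonpol: float

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_ele + self.g_pol + self.g_nonpol

    def as_dict(self) -> dict[str, float]:
        return {
            "e_vdw": self.e_vdw,
            "e_ele": self.e_ele,
            "g_pol": self.g_pol,
            "g_nonpol": self.g_nonpol,
            "total": self.total,
        }


@dataclass
class ResidueProfile:
    """Per-residue energy contributions of receptor residues to binding."""

    contributions: dict[int, EnergyBreakdown]
    residue_names: dict[int, str] = field(default_factory=dict)

    def totals(self) -> dict[int, float]:
        return {idx: eb.total for idx, eb in self.contributions.items()}

    def term_sum(self, term: str) -> float:
        return float(sum(getattr(eb, term) for eb in self.contributions.values()))

    def __iter__(self):
        return iter(self.contributions.items())

    def __len__(self) -> int:
        return len(self.contributions)


# ---------------------------------------------------------------------------
# Gas-phase pairwise terms
# ---------------------------------------------------------------------------


def pairwise_interaction_energies(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
) -> tuple[float, float, dict[int, tuple[float, float]]]:
    """Intermolecular Lennard-Jones and Coulomb energies with a residue split.

    Sums run over every receptor-ligand atom pair with no cutoff.  LJ uses the
    rmin/2 + geometric-epsilon combining rules; Coulomb is screened only by
    ``eps_in``.  Each pair's energy is assigned wholly to the receptor residue
    (the ligand is one unit), so the per-residue values sum exactly to the
    totals.

    Returns ``(e_vdw, e_ele, {residue_index: (e_vdw, e_ele)})``.
    """
    frame = system.check_frame(frame)
    ri, li = system.receptor_idx, system.ligand_idx
    d = cdist(frame[ri], frame[li])

    if d.min() < MIN_PAIR_DISTANCE:
        a, b = np.unravel_index(np.argmin(d), d.shape)
        raise DegenerateGeometryError(
            f"atoms with serials {system.serials[ri[a]]} and "
            f"{system.serials[li[b]]} overlap (r={d[a, b]:.2e} A)"
        )

    rmin = system.lj_rmin_half[ri][:, None] + system.lj_rmin_half[li][None, :]
    eps_ij = np.sqrt(system.lj_epsilon[ri][:, None] * system.lj_epsilon[li][None, :])
    s6 = (rmin / d) ** 6
    vdw_pairs = eps_ij * (s6 * s6 - 2.0 * s6)

    qq = system.charges[ri][:, None] * system.charges[li][None, :]
    ele_pairs = params.coulomb_const * qq / (params.eps_in * d)

    per_atom_vdw = vdw_pairs.sum(axis=1)
    per_atom_ele = ele_pairs.sum(axis=1)
    res_ids = system.residue_of_atom[ri]
    per_residue: dict[int, tuple[float, float]] = {}
    for idx in system.receptor_residue_indices:
        mask = res_ids == idx
        per_residue[idx] = (float(per_atom_vdw[mask].sum()), float(per_atom_ele[mask].sum()))

    return float(vdw_pairs.sum()), float(ele_pairs.sum()), per_residue


# ---------------------------------------------------------------------------
# Generalized Born: HCT effective radii and polar energy
# ---------------------------------------------------------------------------


def effective_born_radii(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii for ``subset`` atoms.

    ``1/R_i = 1/rho_i - sum_j H(r_ij, S_j * rho_j)`` with ``rho = gb_radius -
    gb_offset`` and H the analytic integral of 1/r^4 over the scaled neighbor
    sphere outside atom i's own sphere.  Radii are clamped to a small positive
    floor if descreening overshoots (logged); by construction R_i >= rho_i is
    not required.
    """
    frame = system.check_frame(frame)
    idx = np.arange(system.n_atoms) if subset is None else np.asarray(subset)
    rho = system.gb_radius[idx] - params.gb_offset
    if np.any(rho <= 0):
        bad = system.serials[idx[rho <= 0]]
        raise ParameterError(f"non-positive reduced Born radius for serials {bad.tolist()}")

    x = frame[idx]
    r = cdist(x, x)
    s = system.gb_screen[idx] * rho  # scaled descreening radii of neighbors j
    n = len(idx)
    if n == 1:
        return rho.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        rho_i = rho[:, None]
        s_j = s[None, :]
        U = r + s_j
        L = np.maximum(rho_i, np.abs(r - s_j))
        inv_l, inv_u = 1.0 / L, 1.0 / U
        H = 0.5 * (
            inv_l - inv_u
            + 0.25 * (r - s_j**2 / r) * (inv_u**2 - inv_l**2)
            + 0.5 * np.log(L / U) / r
        )
        # atom i fully engulfed by neighbor j's scaled sphere
        engulfed = rho_i < (s_j - r)
        H = np.where(engulfed, H + 2.0 * (1.0 / rho_i - inv_l), H)

    H = np.where(np.eye(n, dtype=bool) | (rho_i >= U), 0.0, H)
    inv_r = 1.0 / rho - H.sum(axis=1)

    floor = 1e-3
    if np.any(inv_r <= 0):
        over = system.serials[idx[inv_r <= 0]]
        logger.warning("Born radii clamped for serials %s", over.tolist())
        inv_r = np.where(inv_r <= 0, 1.0 / floor, inv_r)
    return 1.0 / inv_r


def gb_polar_energy(
    system: MolecularSystem,
    frame: np.ndarray,
    radii: np.ndarray,
    params: SolventModelParams,
    subset: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """GB polar solvation energy and its full atom-pair matrix.

    Uses the Still interpolation ``f = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i
    R_j))`` (the i = j limit gives f = R_i, so self energies need no special
    case) and Debye screening of the solvent term:

        G_pol = -(C/2) * sum_ij (1/eps_in - exp(-kappa f)/eps_out) q_i q_j / f

    The returned matrix M satisfies ``M.sum() == G_pol`` with M[i, j] the
    ordered-pair term, which supports residue-level decomposition.
    """
    frame = system.check_frame(frame)
    idx = np.arange(system.n_atoms) if subset is None else np.asarray(subset)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ParameterError("Born radii must be positive")
    if len(radii) != len(idx):
        raise SelectionError("radii length does not match subset")

    x = frame[idx]
    q = system.charges[idx]
    r2 = cdist(x, x) ** 2
    rr = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    tau = 1.0 / params.eps_in - np.exp(-params.kappa * f) / params.eps_out
    pair_matrix = -(params.coulomb_const / 2.0) * tau * (q[:, None] * q[None, :]) / f
    return float(pair_matrix.sum()), pair_matrix


def gb_binding_polar(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
) -> tuple[float, np.ndarray]:
    """Single-trajectory binding dG_pol = GB(complex) - GB(receptor) - GB(ligand).

    All three species are evaluated on identical (complex) coordinates; radii
    are recomputed for each species, so the difference also captures the
    descreening change on binding.  Also returns the complex pair matrix for
    decomposition.
    """
    radii_c = effective_born_radii(system, frame, params)
    g_c, m_c = gb_polar_energy(system, frame, radii_c, params)
    out = []
    for sub in (system.receptor_idx, system.ligand_idx):
        radii = effective_born_radii(system, frame, params, subset=sub)
        g, _ = gb_polar_energy(system, frame, radii, params, subset=sub)
        out.append(g)
    return g_c - out[0] - out[1], m_c


# ---------------------------------------------------------------------------
# Surface areas: LCPO and recursive-icosahedron
# ---------------------------------------------------------------------------


def _inflated_radii(system: MolecularSystem, params: SolventModelParams,
                    idx: np.ndarray) -> np.ndarray:
    r = system.sasa_radius[idx]
    return np.where(r > 0, r + params.probe_radius, 0.0)


def _overlap_area(r_i: float, r_j: float, d: float) -> float:
    """Area of sphere i's surface buried inside sphere j (two-sphere lens)."""
    if d >= r_i + r_j or r_i == 0.0 or r_j == 0.0:
        return 0.0
    if d + r_i <= r_j:
        return 4.0 * math.pi * r_i**2
    if d + r_j <= r_i:
        return 0.0
    a = 2.0 * math.pi * r_i * (r_i - d / 2.0 - (r_i**2 - r_j**2) / (2.0 * d))
    return min(max(a, 0.0), 4.0 * math.pi * r_i**2)


def sasa_lcpo(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by LCPO (A^2).

    S_i = P1*S1 + P2*sum_j A_ij + P3*sum_{j,k} A_jk + P4*sum_j A_ij*sum_k A_jk
    with S1 the full inflated-sphere area, A_ij the analytic two-sphere buried
    area, j running over i's overlapping neighbors and k over the mutual
    neighbors of i and j.  Negative per-atom areas are clamped to zero and
    logged.
    """
    frame = system.check_frame(frame)
    idx = np.arange(system.n_atoms) if subset is None else np.asarray(subset)
    radii = _inflated_radii(system, params, idx)
    x = frame[idx]
    p = system.lcpo[idx]
    n = len(idx)
    d = cdist(x, x)

    neighbors: list[list[int]] = []
    for i in range(n):
        if radii[i] == 0.0:
            neighbors.append([])
            continue
        nb = [j for j in range(n)
              if j != i and radii[j] > 0 and d[i, j] < radii[i] + radii[j]]
        neighbors.append(nb)

    sasa = np.zeros(n)
    for i in range(n):
        if radii[i] == 0.0:
            continue
        s1 = 4.0 * math.pi * radii[i] ** 2
        sum_aij = 0.0
        sum_ajk = 0.0
        sum_aij_ajk = 0.0
        for j in neighbors[i]:
            a_ij = _overlap_area(radii[i], radii[j], d[i, j])
            sum_aij += a_ij
            ajk = 0.0
            for k in neighbors[i]:
                if k != j and d[j, k] < radii[j] + radii[k]:
                    ajk += _overlap_area(radii[j], radii[k], d[j, k])
            sum_ajk += ajk
            sum_aij_ajk += a_ij * ajk
        val = p[i, 0] * s1 + p[i, 1] * sum_aij + p[i, 2] * sum_ajk + p[i, 3] * sum_aij_ajk
        if val < 0:
            logger.warning("LCPO area clamped to 0 for serial %d (%.3f A^2)",
                           system.serials[idx[i]], val)
            val = 0.0
        sasa[i] = val
    return sasa


@lru_cache(maxsize=8)
def _icosphere(depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere face centroids and area weights from a subdivided icosahedron.

    Weights are planar triangle areas normalized to sum to 4*pi, so the
    tessellation integrates the full sphere exactly at every depth.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    tri = verts[np.array(faces)]
    for _ in range(depth):
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        ab = (a + b) / 2.0
        bc = (b + c) / 2.0
        ca = (c + a) / 2.0
        for m in (ab, bc, ca):
            m /= np.linalg.norm(m, axis=1, keepdims=True)
        tri = np.concatenate([
            np.stack([a, ab, ca], axis=1),
            np.stack([ab, b, bc], axis=1),
            np.stack([ca, bc, c], axis=1),
            np.stack([ab, bc, ca], axis=1),
        ])
    centroids = tri.mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    weights = areas * (4.0 * math.pi / areas.sum())
    return centroids, weights


def sasa_icosa(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
    depth: int = 3,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA from recursive icosahedron subdivision of each sphere.

    Each atom's inflated sphere is tessellated into 20*4^depth triangular
    faces; a face is exposed if its centroid (projected on the sphere) lies
    outside every other inflated sphere, and the SASA is the exposed area sum.
    """
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    frame = system.check_frame(frame)
    idx = np.arange(system.n_atoms) if subset is None else np.asarray(subset)
    radii = _inflated_radii(system, params, idx)
    x = frame[idx]
    centroids, weights = _icosphere(depth)

    sasa = np.zeros(len(idx))
    for i in range(len(idx)):
        if radii[i] == 0.0:
            continue
        pts = x[i] + radii[i] * centroids
        exposed = np.ones(len(pts), dtype=bool)
        for j in range(len(idx)):
            if j == i or radii[j] == 0.0:
                continue
            if np.linalg.norm(x[j] - x[i]) >= radii[i] + radii[j]:
                continue
            exposed &= np.linalg.norm(pts - x[j], axis=1) >= radii[j]
        sasa[i] = radii[i] ** 2 * weights[exposed].sum()
    return sasa


# ---------------------------------------------------------------------------
# Snapshot-level binding energy and per-residue decomposition
# ---------------------------------------------------------------------------


def _delta_sasa(system: MolecularSystem, frame: np.ndarray,
                params: SolventModelParams, method, **kw) -> tuple[float, np.ndarray]:
    """Binding SASA change and the per-atom complex-minus-isolated areas."""
    s_complex = method(system, frame, params, **kw)
    per_atom = s_complex.copy()
    for sub in (system.receptor_idx, system.ligand_idx):
        s_alone = method(system, frame, params, subset=sub, **kw)
        per_atom[sub] -= s_alone
    return float(per_atom.sum()), per_atom


def mmgbsa_snapshot(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
) -> EnergyBreakdown:
    """Single-snapshot, single-trajectory MM/GBSA binding energy.

    Bonded/internal terms cancel identically between complex and isolated
    species evaluated on the same coordinates, so only the intermolecular
    gas-phase terms and the solvation differences are computed.
    """
    e_vdw, e_ele, _ = pairwise_interaction_energies(system, frame, params)
    g_pol, _ = gb_binding_polar(system, frame, params)
    d_sasa, _ = _delta_sasa(system, frame, params, sasa_lcpo)
    return EnergyBreakdown(
        e_vdw=e_vdw,
        e_ele=e_ele,
        g_pol=g_pol,
        g_nonpol=params.gamma_nonpolar * d_sasa,
    )


def decompose_snapshot(
    system: MolecularSystem,
    frame: np.ndarray,
    params: SolventModelParams,
    icosa_depth: int = 3,
) -> ResidueProfile:
    """Per-residue contributions of receptor residues to the binding energy.

    vdW/electrostatic terms come from the intermolecular pair sums; the GB
    term is the residue<->ligand cross block of the complex pair matrix (the
    self and receptor-internal parts cancel in the single-trajectory
    difference and are not attributed); the nonpolar term is gamma times the
    residue's share of the binding SASA change computed with the icosahedral
    surface.
    """
    _, _, per_res_pair = pairwise_interaction_energies(system, frame, params)
    radii_c = effective_born_radii(system, frame, params)
    _, m_c = gb_polar_energy(system, frame, radii_c, params)
    _, per_atom_dsasa = _delta_sasa(
        system, frame, params, sasa_icosa, depth=icosa_depth
    )

    li = system.ligand_idx
    contributions: dict[int, EnergyBreakdown] = {}
    names: dict[int, str] = {}
    for res_idx, res_name, span in system.residues:
        atoms = np.arange(span.start, span.stop)
        if system.atoms[span.start].segment != "receptor":
            continue
        e_vdw, e_ele = per_res_pair[res_idx]
        # symmetric cross block: both (i in res, j in lig) and transpose
        g_pol = 2.0 * float(m_c[np.ix_(atoms, li)].sum())
        g_nonpol = params.gamma_nonpolar * float(per_atom_dsasa[atoms].sum())
        contributions[res_idx] = EnergyBreakdown(e_vdw, e_ele, g_pol, g_nonpol)
        names[res_idx] = res_name
    return ResidueProfile(contributions, names)
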