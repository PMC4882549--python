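"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the library's vectorized code paths:
explicit Python double loops for pair sums, a golden-spiral Shrake-Rupley
surface sampler, and a volume-grid quadrature of the Born descreening
integral.
"""

from __future__ import annotations

import numpy as np
import pytest

from bindmode import AtomRecord, MolecularSystem, SolventModelParams


@pytest.fixture
def params() -> SolventModelParams:
    return SolventModelParams()


@pytest.fixture
def params_nosalt() -> SolventModelParams:
    return SolventModelParams(salt_conc=0.0)


def make_atom(
    serial: int,
    xyz,
    segment: str = "receptor",
    residue_index: int | None = None,
    charge: float = 0.0,
    lj_rmin_half: float = 1.9,
    lj_epsilon: float = 0.1,
    gb_radius: float = 1.7,
    gb_screen: float = 0.72,
    sasa_radius: float = 1.7,
    name: str | None = None,
    residue_name: str | None = None,
    lcpo_p: tuple = (1.0, -1.0, 0.0, 0.0),
) -> AtomRecord:
    return AtomRecord(
        serial=serial,
        name=name or f"C{serial}",
        residue_index=residue_index if residue_index is not None else serial,
        residue_name=residue_name or ("LIG" if segment == "ligand" else "RES"),
        segment=segment,
        coords=tuple(float(v) for v in xyz),
        charge=charge,
        lj_rmin_half=lj_rmin_half,
        lj_epsilon=lj_epsilon,
        gb_radius=gb_radius,
        gb_screen=gb_screen,
        sasa_radius=sasa_radius,
        lcpo_p=lcpo_p,
    )


def random_system(seed: int, n_receptor: int = 9, n_ligand: int = 3,
                  n_residues: int = 3) -> tuple[MolecularSystem, np.ndarray]:
    """A random non-overlapping system with varied parameters."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 1
    pts: list[np.ndarray] = []

    def place(center, spread):
        while True:
            cand = center + rng.uniform(-spread, spread, 3)
            if all(np.linalg.norm(cand - p) > 1.5 for p in pts):
                pts.append(cand)
                return cand

    for i in range(n_receptor):
        res = i % n_residues
        xyz = place(np.array([6.0 + 2.0 * res, 0.0, 0.0]), 3.0)
        atoms.append(make_atom(
            serial, xyz, "receptor", residue_index=res + 1,
            charge=rng.uniform(-0.6, 0.6),
            lj_rmin_half=rng.uniform(1.5, 2.1), lj_epsilon=rng.uniform(0.02, 0.25),
            gb_radius=rng.uniform(1.3, 2.1), gb_screen=rng.uniform(0.6, 0.9),
            sasa_radius=rng.uniform(1.4, 1.9),
        ))
        serial += 1
    atoms.sort(key=lambda a: a.residue_index)
    atoms = [
        AtomRecord(**{**a.__dict__, "serial": i + 1}) for i, a in enumerate(atoms)
    ]
    serial = n_receptor + 1
    for _ in range(n_ligand):
        xyz = place(np.zeros(3), 2.0)
        atoms.append(make_atom(
            serial, xyz, "ligand", residue_index=n_residues + 1,
            charge=rng.uniform(-0.6, 0.6),
            lj_rmin_half=rng.uniform(1.5, 2.1), lj_epsilon=rng.uniform(0.02, 0.25),
            gb_radius=rng.uniform(1.3, 2.1), gb_screen=rng.uniform(0.6, 0.9),
            sasa_radius=rng.uniform(1.4, 1.9),
        ))
        serial += 1
    system = MolecularSystem(atoms)
    return system, system.base_coordinates()


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_pair_energies(system: MolecularSystem, frame: np.ndarray,
                              params: SolventModelParams):
    """Explicit double loop over receptor-ligand pairs (vdW and Coulomb)."""
    e_vdw = e_ele = 0.0
    per_res: dict[int, list[float]] = {}
    for i in system.receptor_idx:
        for j in system.ligand_idx:
            ai, aj = system.atoms[i], system.atoms[j]
            r = float(np.linalg.norm(frame[i] - frame[j]))
            rmin = ai.lj_rmin_half + aj.lj_rmin_half
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            vdw = eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
            ele = params.coulomb_const * ai.charge * aj.charge / (params.eps_in * r)
            e_vdw += vdw
            e_ele += ele
            acc = per_res.setdefault(ai.residue_index, [0.0, 0.0])
            acc[0] += vdw
            acc[1] += ele
    return e_vdw, e_ele, {k: tuple(v) for k, v in per_res.items()}


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, n_pts: int = 960) -> np.ndarray:
    """Numerical per-atom SASA from golden-spiral surface points."""
    k = np.arange(n_pts)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_pts
    rho = np.sqrt(1.0 - z * z)
    unit = np.stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z], axis=1)
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        if radii[i] == 0:
            continue
        pts = coords[i] + radii[i] * unit
        ok = np.ones(n_pts, dtype=bool)
        for j in range(len(coords)):
            if j == i or radii[j] == 0:
                continue
            ok &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        out[i] = 4.0 * np.pi * radii[i] ** 2 * ok.mean()
    return out


def descreen_quadrature(rho_i: float, s_j: float, d: float, n: int = 160) -> float:
    """Grid quadrature of (1/4pi) * integral of dV/r^4 over the scaled
    neighbor sphere, excluding atom i's own sphere."""
    g = (np.arange(n) + 0.5) / n * 2.0 - 1.0
    xs = s_j * g
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    inside_j = X**2 + Y**2 + Z**2 <= s_j**2
    r2 = (X + d) ** 2 + Y**2 + Z**2
    sel = inside_j & (r2 > rho_i**2)
    dv = (2.0 * s_j / n) ** 3
    return float((1.0 / (4.0 * np.pi)) * np.sum(dv / r2[sel] ** 2))


def chain_system(spacings, sasa_radius: float = 1.7) -> tuple[MolecularSystem, np.ndarray]:
    """Atoms along the x axis at cumulative spacings; last atom is the ligand."""
    xs = np.concatenate([[0.0], np.cumsum(spacings)])
    atoms = [
        make_atom(i + 1, (x, 0.0, 0.0),
                  "ligand" if i == len(xs) - 1 else "receptor",
                  sasa_radius=sasa_radius)
        for i, x in enumerate(xs)
    ]
    system = MolecularSystem(atoms)
    return system, system.base_coordinates()
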