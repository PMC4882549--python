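"""Unit tests for the pairwise, GB and surface-area energy engine."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindmode import (
    DegenerateGeometryError,
    MolecularSystem,
    SolventModelParams,
    decompose_snapshot,
    effective_born_radii,
    gb_binding_polar,
    gb_polar_energy,
    mmgbsa_snapshot,
    pairwise_interaction_energies,
    sasa_icosa,
    sasa_lcpo,
)

from conftest import (
    brute_force_pair_energies,
    chain_system,
    descreen_quadrature,
    make_atom,
    random_system,
    shrake_rupley,
)


# ---------------------------------------------------------------------------
# gas-phase pair energies
# ---------------------------------------------------------------------------


def test_null_interaction_ligand(params):
    """A ligand with zero charges and zero LJ depth contributes nothing."""
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", charge=0.4),
        make_atom(2, (4, 0, 0), "ligand", charge=0.0, lj_epsilon=0.0),
        make_atom(3, (5, 1, 0), "ligand", charge=0.0, lj_epsilon=0.0),
    ]
    system = MolecularSystem(atoms)
    e_vdw, e_ele, _ = pairwise_interaction_energies(
        system, system.base_coordinates(), params
    )
    assert e_vdw == 0.0
    assert e_ele == 0.0


def test_coulomb_two_atoms(params):
    """Opposite half charges 3 A apart give the closed-form Coulomb energy."""
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", charge=0.5, lj_epsilon=0.0),
        make_atom(2, (3, 0, 0), "ligand", charge=-0.5, lj_epsilon=0.0),
    ]
    system = MolecularSystem(atoms)
    _, e_ele, _ = pairwise_interaction_energies(system, system.base_coordinates(), params)
    assert e_ele == pytest.approx(332.0636 * 0.25 * (-1.0) / 3.0, abs=1e-9)
    assert e_ele == pytest.approx(-27.67, abs=0.01)


@pytest.mark.parametrize("seed", range(5))
def test_pair_energies_match_brute_force(seed, params):
    """Vectorized totals and residue split equal an explicit double loop."""
    system, frame = random_system(seed)
    e_vdw, e_ele, per_res = pairwise_interaction_energies(system, frame, params)
    o_vdw, o_ele, o_res = brute_force_pair_energies(system, frame, params)
    assert e_vdw == pytest.approx(o_vdw, abs=1e-10)
    assert e_ele == pytest.approx(o_ele, abs=1e-10)
    for idx, (v, e) in per_res.items():
        assert v == pytest.approx(o_res[idx][0], abs=1e-10)
        assert e == pytest.approx(o_res[idx][1], abs=1e-10)


def test_overlapping_atoms_raise_named_error(params):
    atoms = [
        make_atom(7, (0, 0, 0), "receptor"),
        make_atom(9, (0, 0, 0), "ligand"),
    ]
    system = MolecularSystem(atoms)
    with pytest.raises(DegenerateGeometryError, match="7.*9"):
        pairwise_interaction_energies(system, system.base_coordinates(), params)


def test_energies_invariant_under_rigid_motion(params):
    """All four MM/GBSA terms are unchanged by a global rotation+translation."""
    system, frame = random_system(3)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = frame @ rot.T + np.array([5.0, -3.0, 12.0])
    a = mmgbsa_snapshot(system, frame, params)
    b = mmgbsa_snapshot(system, moved, params)
    for term in ("e_vdw", "e_ele", "g_pol", "g_nonpol"):
        assert getattr(a, term) == pytest.approx(getattr(b, term), abs=1e-8)


# ---------------------------------------------------------------------------
# effective Born radii
# ---------------------------------------------------------------------------


def test_isolated_atom_radius_is_reduced_radius(params):
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", gb_radius=1.5),
        make_atom(2, (500, 0, 0), "ligand"),
    ]
    system = MolecularSystem(atoms)
    r = effective_born_radii(system, system.base_coordinates(), params,
                             subset=np.array([0]))
    assert r[0] == pytest.approx(1.5 - 0.09, abs=1e-12)


def test_symmetric_pair_has_equal_radii(params):
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", gb_radius=1.7),
        make_atom(2, (2.5, 0, 0), "ligand", gb_radius=1.7),
    ]
    system = MolecularSystem(atoms)
    r = effective_born_radii(system, system.base_coordinates(), params)
    assert r[0] == pytest.approx(r[1], abs=1e-12)
    assert r[0] > 1.7 - 0.09  # descreening enlarges the effective radius


@pytest.mark.parametrize("d", [2.2, 3.0, 4.5])
def test_born_radius_matches_quadrature(d, params):
    """Two-atom HCT radius within 2% of a volume-grid descreening integral."""
    rho_i, rho_j, screen = 1.41, 1.61, 0.8
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", gb_radius=rho_i + 0.09, gb_screen=0.5),
        make_atom(2, (d, 0, 0), "ligand", gb_radius=rho_j + 0.09, gb_screen=screen),
    ]
    system = MolecularSystem(atoms)
    r = effective_born_radii(system, system.base_coordinates(), params)
    h_num = descreen_quadrature(rho_i, screen * rho_j, d)
    r_oracle = 1.0 / (1.0 / rho_i - h_num)
    assert r[0] == pytest.approx(r_oracle, rel=0.02)


# ---------------------------------------------------------------------------
# GB polar energy
# ---------------------------------------------------------------------------


def test_single_ion_born_closed_form(params_nosalt):
    """A unit charge with R = 2 A reproduces the Born solvation energy."""
    atoms = [
        make_atom(1, (0, 0, 0), "ligand", charge=1.0),
        make_atom(2, (999, 0, 0), "receptor", charge=0.0),
    ]
    system = MolecularSystem(atoms)
    g, _ = gb_polar_energy(
        system, system.base_coordinates(), np.array([2.0]), params_nosalt,
        subset=np.array([0]),
    )
    expected = -(1.0 - 1.0 / 80.0) * 332.0636 / (2.0 * 2.0)
    assert g == pytest.approx(expected, abs=1e-6)
    assert g == pytest.approx(-81.98, abs=0.01)


@pytest.mark.parametrize("salt", [0.0, 0.15])
def test_gb_interaction_far_limit_is_screened_coulomb(salt):
    """At large separation the cross term approaches the screened Coulomb."""
    p = SolventModelParams(salt_conc=salt)
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", charge=0.8),
        make_atom(2, (60.0, 0, 0), "ligand", charge=-0.5),
    ]
    system = MolecularSystem(atoms)
    radii = np.array([1.6, 1.8])
    _, m = gb_polar_energy(system, system.base_coordinates(), radii, p)
    cross = 2.0 * m[0, 1]
    r = 60.0
    expected = -(1.0 / p.eps_in - math.exp(-p.kappa * r) / p.eps_out) \
        * p.coulomb_const * 0.8 * (-0.5) / r
    assert cross == pytest.approx(expected, rel=0.01)


def test_pair_matrix_sums_to_total(params):
    system, frame = random_system(11, n_receptor=6, n_ligand=2)
    radii = effective_born_radii(system, frame, params)
    total, m = gb_polar_energy(system, frame, radii, params)
    assert total == pytest.approx(m.sum(), abs=1e-10)
    assert np.allclose(m, m.T, atol=1e-12)


# ---------------------------------------------------------------------------
# surface areas
# ---------------------------------------------------------------------------


def test_isolated_sphere_areas(params):
    """Both surface models give the full inflated-sphere area when alone."""
    system, frame = chain_system([40.0])
    full = 4.0 * math.pi * (1.7 + 1.4) ** 2
    assert sasa_lcpo(system, frame, params) == pytest.approx([full, full])
    assert sasa_icosa(system, frame, params, depth=3) == pytest.approx([full, full])


def test_disjoint_spheres_additive(params):
    system, frame = chain_system([2 * (1.7 + 1.4) + 0.1])
    full = 4.0 * math.pi * (1.7 + 1.4) ** 2
    assert sasa_lcpo(system, frame, params).sum() == pytest.approx(2 * full)


@pytest.mark.parametrize(
    "spacings",
    [
        [7.0],                       # disjoint pair
        [3.0, 3.0],                  # overlapping 3-atom chain
        [3.0, 3.0, 3.0, 3.0],        # 5-atom chain
        [2.6, 3.4],                  # asymmetric chain
    ],
    ids=["pair", "chain3", "chain5", "chain3-asym"],
)
def test_sasa_methods_match_shrake_rupley(spacings, params):
    """LCPO and icosahedral SASA within 5% of a 960-point numerical surface."""
    system, frame = chain_system(spacings)
    oracle = shrake_rupley(frame, system.sasa_radius + params.probe_radius)
    for method, kw in ((sasa_lcpo, {}), (sasa_icosa, {"depth": 3})):
        total = method(system, frame, params, **kw).sum()
        assert total == pytest.approx(oracle.sum(), rel=0.05)


def test_wide_triangle_matches_oracle(params):
    """A spread 3-atom cluster (disjoint buried caps) matches the oracle."""
    atoms = [
        make_atom(1, (0, 0, 0), "receptor"),
        make_atom(2, (5.5, 0, 0), "receptor", residue_index=1),
        make_atom(3, (2.75, 4.76, 0), "ligand"),
    ]
    system = MolecularSystem(atoms)
    frame = system.base_coordinates()
    oracle = shrake_rupley(frame, system.sasa_radius + params.probe_radius)
    assert sasa_lcpo(system, frame, params).sum() == pytest.approx(oracle.sum(), rel=0.05)
    assert sasa_icosa(system, frame, params, 3).sum() == pytest.approx(oracle.sum(), rel=0.05)


def test_icosa_buried_atom_is_zero(params):
    atoms = [
        make_atom(1, (0, 0, 0), "ligand", sasa_radius=0.5),
        make_atom(2, (0.2, 0, 0), "receptor", sasa_radius=3.0),
    ]
    system = MolecularSystem(atoms)
    s = sasa_icosa(system, system.base_coordinates(), params, depth=2)
    assert s[0] == 0.0


@pytest.mark.parametrize("depth", [0, 1, 2, 4])
def test_icosa_isolated_atom_area_exact_at_any_depth(depth, params):
    """The normalized tessellation integrates the full sphere at every depth."""
    system, frame = chain_system([50.0])
    area = sasa_icosa(system, frame, params, depth=depth)[0]
    assert area == pytest.approx(4.0 * math.pi * 3.1**2, rel=1e-12)


# ---------------------------------------------------------------------------
# snapshot assembly and decomposition
# ---------------------------------------------------------------------------


def test_ghost_ligand_binds_with_zero_energy(params):
    """Zero charge, LJ depth, surface radius and screening: total is zero."""
    atoms = [
        make_atom(1, (0, 0, 0), "receptor", charge=0.3),
        make_atom(2, (2.0, 0, 0), "receptor", residue_index=1, charge=-0.3),
        make_atom(3, (4.0, 0, 0), "ligand", charge=0.0, lj_epsilon=0.0,
                  sasa_radius=0.0, gb_radius=0.5, gb_screen=0.0),
    ]
    system = MolecularSystem(atoms)
    eb = mmgbsa_snapshot(system, system.base_coordinates(), params)
    assert eb.total == pytest.approx(0.0, abs=1e-10)


def test_snapshot_equals_assembled_components(params):
    """mmgbsa_snapshot is exactly the sum of its four component operations."""
    system, frame = random_system(21, n_receptor=3, n_ligand=2, n_residues=1)
    eb = mmgbsa_snapshot(system, frame, params)

    e_vdw, e_ele, _ = pairwise_interaction_energies(system, frame, params)
    g_pol, _ = gb_binding_polar(system, frame, params)
    d_sasa = sasa_lcpo(system, frame, params).sum()
    for sub in (system.receptor_idx, system.ligand_idx):
        d_sasa -= sasa_lcpo(system, frame, params, subset=sub).sum()

    assert eb.e_vdw == pytest.approx(e_vdw, abs=1e-12)
    assert eb.e_ele == pytest.approx(e_ele, abs=1e-12)
    assert eb.g_pol == pytest.approx(g_pol, abs=1e-12)
    assert eb.g_nonpol == pytest.approx(0.0072 * d_sasa, abs=1e-12)
    assert eb.total == pytest.approx(
        eb.e_vdw + eb.e_ele + eb.g_pol + eb.g_nonpol, abs=1e-9
    )


@pytest.mark.parametrize("seed", range(10))
def test_decomposition_conserves_pairwise_terms(seed, params):
    """Summed per-residue vdW/ele/GB-cross terms equal the system totals."""
    system, frame = random_system(seed)
    profile = decompose_snapshot(system, frame, params, icosa_depth=2)
    e_vdw, e_ele, _ = pairwise_interaction_energies(system, frame, params)
    radii = effective_born_radii(system, frame, params)
    _, m = gb_polar_energy(system, frame, radii, params)
    cross = 2.0 * m[np.ix_(system.receptor_idx, system.ligand_idx)].sum()
    assert profile.term_sum("e_vdw") == pytest.approx(e_vdw, abs=1e-6)
    assert profile.term_sum("e_ele") == pytest.approx(e_ele, abs=1e-6)
    assert profile.term_sum("g_pol") == pytest.approx(cross, abs=1e-6)


def test_distant_neutral_residue_contributes_nothing(params):
    """A neutral residue 10+ A from the ligand has a negligible total."""
    atoms = [
        make_atom(1, (4.0, 0, 0), "receptor", residue_index=1, charge=-0.5),
        make_atom(2, (15.0, 0, 0), "receptor", residue_index=2, charge=0.0),
        make_atom(3, (16.5, 0, 0), "receptor", residue_index=2, charge=0.0),
        make_atom(4, (0, 0, 0), "ligand", residue_index=3, charge=0.5),
    ]
    system = MolecularSystem(atoms)
    profile = decompose_snapshot(system, system.base_coordinates(), params)
    assert abs(profile.contributions[2].total) < 0.01
    assert abs(profile.contributions[1].total) > 0.1


def test_decomposition_matches_per_pair_bookkeeping(params):
    """Three-residue pocket: residue terms equal explicit per-pair assignment."""
    system, frame = random_system(31)
    profile = decompose_snapshot(system, frame, params, icosa_depth=2)
    _, _, oracle_pairs = brute_force_pair_energies(system, frame, params)
    radii = effective_born_radii(system, frame, params)
    _, m = gb_polar_energy(system, frame, radii, params)
    for res_idx, eb in profile:
        atoms = [i for i, a in enumerate(system.atoms) if a.residue_index == res_idx]
        gb_cross = 2.0 * sum(m[i, j] for i in atoms for j in system.ligand_idx)
        assert eb.e_vdw == pytest.approx(oracle_pairs[res_idx][0], abs=1e-10)
        assert eb.e_ele == pytest.approx(oracle_pairs[res_idx][1], abs=1e-10)
        assert eb.g_pol == pytest.approx(gb_cross, abs=1e-10)
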