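# Methods

## Scope and assumptions

`bindmode` evaluates binding energetics of a receptor–ligand complex on
pre-computed snapshot ensembles; it contains no MD integrator and no bonded
terms. Everything rests on the single-trajectory approximation: complex,
receptor and ligand are evaluated on identical (complex) coordinates, so
internal bonded contributions cancel identically and are never computed.
Entropic terms (normal-mode or quasiharmonic) are deliberately out of scope —
the method is used for ranking structurally similar ligands, where they
largely cancel.

## Energy model

**Gas phase.** Lennard-Jones uses `E = ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶]`
with `r_min,ij = r_i/2 + r_j/2` (arithmetic) and `ε_ij = √(ε_i ε_j)`
(geometric). Coulomb is `C·q_i q_j/(ε_in r)` with
C = 332.0636 kcal·Å/mol/e². No distance cutoff anywhere: both gas-phase and
GB sums run over all pairs, so decomposition identities hold exactly.

**Polar solvation.** Effective Born radii follow the HCT pairwise-descreening
scheme: `1/R_i = 1/ρ̃_i − Σ_j H(r_ij, S_j ρ̃_j)` with `ρ̃ = ρ − 0.09 Å` and H
the analytic integral of 1/r⁴ over the scaled neighbor sphere outside atom
i's own sphere (including the engulfed-atom correction). The GB variant is a
declared default, not something the energy model can infer from data; HCT
with the Still function `f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j))` was chosen
as the long-standing default of mainstream MM/GBSA implementations. The i = j
limit of f_GB is R_i, so self-energies need no special case. Salt enters as
`exp(−κ f_GB)` on the solvent term with κ = 0.329·√(I/mol L⁻¹) Å⁻¹; defaults
are ε_in = 1, ε_out = 80, I = 0.15 M (a physiological simulation
environment), all configurable. Descreening can push 1/R below zero for
pathological parameter sets; radii are clamped to a 10⁻³ Å floor with a log
warning rather than propagating a negative radius into f_GB.

**Nonpolar solvation.** `ΔG_nonpol = γ·ΔSASA` with γ = 0.0072 kcal/mol/Å² and
a 1.4 Å probe. System totals use LCPO — per-atom
`P1·S1 + P2·ΣA_ij + P3·ΣΣA_jk + P4·Σ(A_ij·ΣA_jk)` with analytic two-sphere
buried areas; negative per-atom values are clamped to zero and logged. The
per-residue split instead uses a recursive-icosahedron surface: each inflated
sphere is tessellated into 20·4^depth triangles (planar face areas normalized
so the full tessellation integrates to exactly 4πr² at every depth), and a
face counts as exposed when its centroid lies outside every other inflated
sphere. Depth 3 (1280 faces) keeps the discretization error of a buried-atom
surface well under the 5% band of the numerical-oracle tests while staying
fast; it is a parameter.

## Per-residue decomposition

vdW and electrostatic terms are assigned per receptor residue by summing that
residue's pairs with the ligand (the ligand is one unit); this makes the
residue sums conserve the system totals exactly, which the tests assert at
1e-6 kcal/mol. The GB term credited to a residue is twice its cross block of
the complex pair matrix (both orderings of each pair); self and
receptor-internal contributions cancel in the single-trajectory difference
and are not attributed to residues. Whether such cross-assignment or
half-splitting between residue pairs better mirrors any particular published
decomposition is ambiguous in general; residue-vs-ligand assignment was
chosen because the downstream analyses all contrast residues against one
ligand at a time. The nonpolar residue term is γ times the residue's share of
the complex-minus-isolated per-atom SASA change.

## Ensemble statistics and geometry

Energies are averaged over frames; the SEM is the sample SD (n−1) over √n,
computed per term *and* for the total from the per-frame totals (the terms
are strongly anticorrelated, so summing per-term SEMs would overstate the
total's error). A single frame reports NaN. RMSD monitors superpose each
frame on a reference (frame 0 by default) by the SVD construction with the
proper-rotation determinant correction, over a configurable selection.
Pocket membership uses heavy atoms within 5.0 Å of any ligand heavy atom
(hydrogen detection by atom-name convention: leading H after digits).
Hydrogen bonds use D···A ≤ 3.5 Å and ∠D–H···A ≥ 135°; salt-bridge contacts
N···O ≤ 4.0 Å — standard geometric criteria, configurable. Differential
residue comparison between two systems flags |ΔE_total| ≥ 0.5 kcal/mol,
sorted by magnitude; it is antisymmetric by construction.

## Clustering and hot spots

Rows with |E| < 0.005 kcal/mol in every column (half the two-decimal printing
precision) are dropped before clustering. Ward linkage is implemented
directly via the Lance–Williams recurrence
`d(k, i∪j) = [(n_i+n_k)d(k,i) + (n_j+n_k)d(k,j) − n_k d(i,j)]/(n_i+n_j+n_k)`
applied to the *unsquared* Manhattan distances — the behavior of R's
`hclust(…, "ward.D")` on a precomputed Manhattan matrix, which the tests
cross-check against R directly. SciPy's `ward` operates on squared
distances (`ward.D2`) and is therefore not a drop-in substitute. Ward's
coefficients satisfy α_i+α_j+β = 1, so merge heights are monotone
(no inversions), which is asserted as a property. Ties are broken by the
smallest (min leaf id, max leaf id) pair, making the tree deterministic.

Cutting at k undoes the last k−1 merges; groups are labeled A, B, … by
descending mean |energy| across ligands. The strongest group is split into
subgroups A1/A2 by undoing the top merge of its own subtree. Hot spots are
residues with |E| ≥ 0.5 kcal/mol (inclusive). Group fractions are
100·(group sum)/(reference total) with the ligand's total binding free energy
as the default reference; an alternative denominator (sum of per-residue
terms) is available by passing different reference totals. Heat-map
intensities map favorable energies linearly to [−1, 0) (red) and unfavorable
to (0, 1] (blue) between configurable anchors, clamping beyond. Dendrograms
export as ultrametric Newick (each child branch gets half the height drop),
round-tripped through Bio.Phylo in tests.

## Thermodynamic conversions

`ΔG = RT ln(K_i[M])`, `ΔΔG = RT ln FC`, R = 1.9872×10⁻³ kcal/(mol·K),
T = 298.15 K by default: this is the convention under which the two-decimal
cells of published hNET affinity tables reproduce exactly, although such
simulations are typically run at 310 K; both temperatures are plain
parameters. Two cells of the six-ligand reference table (atomoxetine −11.33,
(S,S)-reboxetine −13.78) sit 0.005–0.01 kcal/mol off the 298.15 K
recomputation — an upstream rounding-path ambiguity; constants were not
adjusted to chase them and the tests exclude those two cells. Rounding for
table display is half-away-from-zero at two decimals, applied only at report
time. Sensitivity uses max(FC, 1/FC) ≥ 5 so gain-of-potency mutations
classify as sensitive, boundary inclusive.

## Synthetic data

`build_toy_complex` places a ligand (≲2 Å spread, first atom an amine-like
nitrogen at +1 e) inside a shell of three-atom residues at 6–10 Å, with a
carboxylate-like −1 e oxygen on residue 1 forming a salt bridge; other
charges are uniform in [−0.5, 0.5] e and LJ/GB/SASA parameters come from a
small built-in C/N/O table in the range of common biomolecular force fields.
`jitter_ensemble` adds i.i.d. Gaussian noise (default σ = 0.3 Å) per atom and
frame — a stand-in for an equilibrated snapshot window that deliberately has
no correlated motions, so SEM scaling tests behave ideally here in a way real
trajectories (autocorrelated) would not. `planted_matrix` defaults to the
statistical shape of a transporter-wide decomposition for four ligands: group
sizes (11, 47, 90, 90) with means (−2.5, −0.8, −0.2, +0.1) kcal/mol, σ = 0.1
within groups, plus 300 exact-zero residues for a 538-row matrix of which 238
pass the nonzero filter. The synthetic LCPO weights are the neutral
truncation (P1 = 1, P2 = −1, P3 = P4 = 0), exact when no two buried caps on a
sphere overlap; the numerical-surface comparisons therefore use sparse
chain/triangle geometries, while crowded toy complexes exercise the clamping
path instead. Passing tests on these generators demonstrates algorithmic
correctness, not force-field accuracy on real complexes.

## Problem sizes and numerical choices

Tests and the acceptance script run on toy systems of 8–20 atoms, ensembles
of 2–48 frames, and matrices of 40–538 rows; the clustering recovery check
uses 100 seeded 40-residue matrices with group separation ten times the
within-group noise, where the adjusted Rand index is 1 on every seed. Pair
energies are validated against explicit double loops at 1e-10 kcal/mol;
effective radii against a volume-grid quadrature of the descreening integral
at 2%; both surface models against a 960-point golden-spiral numerical
surface at 5%; the GB self term against the Born closed form at 1e-6.
Energies are invariant under rigid motions to 1e-8. Degenerate geometry
(receptor–ligand pair closer than 1e-6 Å) raises an error naming the serial
pair rather than returning a divergent energy.

## Known limitations

* No Poisson–Boltzmann reference, no entropy, no explicit-solvent terms.
* The per-residue nonpolar split does not attribute the ligand's own SASA
  change to any residue, so only the pairwise terms obey the conservation
  identity.
* Error bars are plain SEMs; no autocorrelation correction, so real
  trajectory SEMs would be underestimated at this package's level.
* LCPO accuracy depends entirely on the supplied P weights; the built-in
  neutral weights are not a fitted parameterization.
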