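"""Hot-spot identification by clustering per-residue energies across ligands.

Each residue's contributions to several ligands form an energy vector; rows
with no contribution to any ligand are dropped, the remaining vectors are
compared by Manhattan distance, and agglomerative clustering with the classic
Ward minimum-variance update (Lance-Williams recurrence applied to the
distances as given, i.e. R's ``ward.D`` behavior) builds the residue tree.
Cutting it yields energy groups, hot spots, per-ligand group fractions and
heat-map color intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ff_energy import ResidueProfile, SelectionError

#: residues below this absolute energy (kcal/mol) count as "no contribution";
#: chosen as half the printing precision of a two-decimal report
DEFAULT_EPS = 0.005

#: hot-spot threshold on the absolute per-residue contribution (kcal/mol)
HOTSPOT_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# Matrix construction and distances
# ---------------------------------------------------------------------------


def build_matrix(
    profiles: list[tuple[str, ResidueProfile]],
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Residue x ligand matrix of total contributions, nonzero rows only.

    A residue is kept if its absolute energy is >= ``eps`` for at least one
    ligand.  Rows are labeled ``NAME<index>`` when the profile carries residue
    names, else ``RES<index>``; columns follow the given ligand order.
    """
    labels = [lab for lab, _ in profiles]
    if len(set(labels)) != len(labels):
        raise SelectionError("duplicate ligand labels")
    all_res = sorted({idx for _, p in profiles for idx in p.contributions})
    names: dict[int, str] = {}
    for _, p in profiles:
        names.update(p.residue_names)
    data = np.zeros((len(all_res), len(labels)))
    for j, (_, p) in enumerate(profiles):
        totals = p.totals()
        for i, idx in enumerate(all_res):
            data[i, j] = totals.get(idx, 0.0)
    rows = [f"{names.get(idx, 'RES')}{idx}" for idx in all_res]
    mat = pd.DataFrame(data, index=rows, columns=labels)
    keep = (mat.abs() >= eps).any(axis=1)
    return mat.loc[keep]


def manhattan_distance(a: np.ndarray, b: np.ndarray) -> float:
    """City-block distance between two residue energy vectors (kcal/mol)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SelectionError("energy vectors differ in length")
    return float(np.abs(a - b).sum())


# ---------------------------------------------------------------------------
# Ward clustering on Manhattan distances
# ---------------------------------------------------------------------------


@dataclass
class ClusterTree:
    """Agglomerative merge history.

    Leaves are numbered ``0..n_leaves-1``; the i-th merge creates node
    ``n_leaves + i``.  ``merges`` rows are (left id, right id, height, size)
    in merge order, matching the SciPy linkage convention.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise SelectionError("a full tree has exactly n_leaves - 1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def leaves_under(self, node: int) -> list[int]:
        if node < self.n_leaves:
            return [node]
        left, right, _, _ = self.merges[node - self.n_leaves]
        return self.leaves_under(left) + self.leaves_under(right)

    def to_linkage(self) -> np.ndarray:
        return np.array([[l, r, h, s] for l, r, h, s in self.merges], dtype=float)


def ward_tree(matrix: pd.DataFrame) -> ClusterTree:
    """Ward agglomeration of matrix rows on their Manhattan distance matrix.

    Implements the Lance-Williams recurrence

        d(k, i+j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)]
                    / (n_i + n_j + n_k)

    on the unsquared distances.  Equal candidate distances are broken
    deterministically by the smallest (min leaf id, max leaf id) of the pair,
    so the tree does not depend on dictionary order.
    """
    values = np.asarray(matrix, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise SelectionError("clustering needs >= 2 rows")
    d = squareform(pdist(values, metric="cityblock"))

    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    max_leaf = {i: i for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []

    for step in range(n - 1):
        best = None
        for pair, val in dist.items():
            i, j = sorted(pair)
            key = (val, min(min_leaf[i], min_leaf[j]), max(max_leaf[i], max_leaf[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        (height, _, _), i, j = best
        new = n + step
        merges.append((i, j, height, size[i] + size[j]))

        for k in active - {i, j}:
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dij = dist[frozenset((i, j))]
            ni, nj, nk = size[i], size[j], size[k]
            dist[frozenset((new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        del dist[frozenset((i, j))]
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
        min_leaf[new] = min(min_leaf[i], min_leaf[j])
        max_leaf[new] = max(max_leaf[i], max_leaf[j])

    return ClusterTree(n_leaves=n, merges=merges, labels=list(matrix.index))


def _cut_roots(tree: ClusterTree, k: int) -> set[int]:
    """Node ids of the k clusters obtained by undoing the last k-1 merges."""
    if not (1 <= k <= tree.n_leaves):
        raise SelectionError(f"k={k} out of range 1..{tree.n_leaves}")
    roots = {2 * tree.n_leaves - 2} if tree.n_leaves > 1 else {0}
    for merge_id in range(tree.n_leaves - 2, tree.n_leaves - 1 - k, -1):
        node = tree.n_leaves + merge_id
        left, right, _, _ = tree.merges[merge_id]
        roots.remove(node)
        roots.update((left, right))
    return roots


def cut_groups(
    tree: ClusterTree, k: int, matrix: pd.DataFrame | None = None
) -> dict[str, str]:
    """Partition leaves into k groups by undoing the last k-1 merges.

    Groups are labeled A, B, ... in descending order of the group's mean
    absolute energy across ligands when ``matrix`` is supplied (the strongest
    contributors come first); otherwise by decreasing size then leaf order.
    Returns ``{row label: group label}``.
    """
    clusters = [sorted(tree.leaves_under(r)) for r in sorted(_cut_roots(tree, k))]

    def strength(leaves: list[int]) -> float:
        if matrix is None:
            return float(len(leaves))
        rows = [tree.labels[i] for i in leaves]
        return float(matrix.loc[rows].abs().values.mean())

    ordered = sorted(clusters, key=lambda c: (-strength(c), c[0]))
    assignment: dict[str, str] = {}
    for rank, leaves in enumerate(ordered):
        label = _group_label(rank)
        for leaf in leaves:
            assignment[tree.labels[leaf] if tree.labels else str(leaf)] = label
    return assignment


def _group_label(rank: int) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = ""
    rank += 1
    while rank:
        rank, rem = divmod(rank - 1, 26)
        out = letters[rem] + out
    return out


# ---------------------------------------------------------------------------
# Hot spots, fractions, colors, export
# ---------------------------------------------------------------------------


def hotspot_filter(
    data: ResidueProfile | pd.DataFrame, threshold: float = HOTSPOT_THRESHOLD
) -> dict[str, set]:
    """Residues with absolute contribution >= threshold, per ligand (inclusive)."""
    if threshold <= 0:
        raise SelectionError("threshold must be > 0")
    if isinstance(data, ResidueProfile):
        frame = pd.DataFrame({"profile": pd.Series(data.totals())})
    else:
        frame = data
    return {
        str(col): set(frame.index[frame[col].abs() >= threshold])
        for col in frame.columns
    }


def group_fraction(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    reference_totals: dict[str, float],
) -> dict[str, dict[str, float]]:
    """Percent of each ligand's reference total carried by each group.

    ``fraction = 100 * sum(group energies) / reference_total``; the reference
    is normally the ligand's total binding free energy, so the fractions of a
    full partition sum to (sum of all rows)/(reference) per ligand.
    """
    out: dict[str, dict[str, float]] = {}
    for lig in matrix.columns:
        ref = reference_totals[str(lig)]
        if ref == 0:
            raise ZeroDivisionError(f"reference total for {lig} is zero")
        per_group: dict[str, float] = {}
        for row, grp in groups.items():
            per_group[grp] = per_group.get(grp, 0.0) + float(matrix.at[row, lig])
        out[str(lig)] = {g: 100.0 * v / ref for g, v in sorted(per_group.items())}
    return out


def color_values(
    matrix: pd.DataFrame,
    red_anchor: float | None = None,
    blue_anchor: float | None = None,
) -> pd.DataFrame:
    """Signed heat-map intensities in [-1, 1] for a residue-energy matrix.

    Favorable (negative) energies map linearly onto [-1, 0) — full red at
    ``red_anchor`` — and unfavorable ones onto (0, 1] — full blue at
    ``blue_anchor``; zero is white.  Values beyond an anchor clamp to +/-1.
    Anchors default to the matrix extremes.
    """
    vals = matrix.to_numpy(dtype=float)
    if red_anchor is None:
        red_anchor = float(min(vals.min(), -1e-12))
    if blue_anchor is None:
        blue_anchor = float(max(vals.max(), 1e-12))
    if not (red_anchor < 0 < blue_anchor):
        raise SelectionError("need red_anchor < 0 < blue_anchor")
    out = np.where(
        vals < 0,
        -np.clip(vals / red_anchor, 0.0, 1.0),
        np.clip(vals / blue_anchor, 0.0, 1.0),
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def tree_to_newick(tree: ClusterTree, labels: list[str] | None = None) -> str:
    """Newick text for a merge tree, ultrametric by construction.

    Each child branch gets half the height drop from its parent merge, so a
    two-leaf tree at height h reads ``(A:h/2,B:h/2);``.
    """
    labels = labels if labels is not None else tree.labels
    if len(labels) != tree.n_leaves:
        raise SelectionError("label count must equal leaf count")

    def height(node: int) -> float:
        return 0.0 if node < tree.n_leaves else tree.merges[node - tree.n_leaves][2]

    def render(node: int, parent_height: float) -> str:
        bl = (parent_height - height(node)) / 2.0
        if node < tree.n_leaves:
            return f"{labels[node]}:{bl:.10g}"
        left, right, h, _ = tree.merges[node - tree.n_leaves]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = 2 * tree.n_leaves - 2
    left, right, h, _ = tree.merges[root - tree.n_leaves]
    return f"({render(left, h)},{render(right, h)});"


@dataclass
class HotspotReport:
    """Groups, hot spots, fractions and subgroup split for one energy matrix."""

    groups: dict[str, str]
    hotspots: dict[str, set]
    fractions: dict[str, dict[str, float]]
    subgroups: dict[str, str]
    tree: ClusterTree

    def as_dict(self) -> dict:
        return {
            "groups": self.groups,
            "hotspots": {k: sorted(v) for k, v in self.hotspots.items()},
            "fractions": self.fractions,
            "subgroups": self.subgroups,
        }


def hotspot_report(
    matrix: pd.DataFrame,
    reference_totals: dict[str, float],
    k: int = 4,
    hotspot_threshold: float = HOTSPOT_THRESHOLD,
) -> HotspotReport:
    """Cluster, cut into k groups, and derive the shared-binding-mode summary.

    The strongest group (label A) is split into two subgroups (A1 "strong",
    A2 "relatively strong") by undoing the top merge of its own subtree,
    mirroring the usual presentation of a shared hot-spot core.
    """
    tree = ward_tree(matrix)
    groups = cut_groups(tree, k, matrix)
    top_rows = {r for r, g in groups.items() if g == "A"}

    subgroups: dict[str, str] = {}
    a_root = next(
        r for r in _cut_roots(tree, k)
        if {tree.labels[i] for i in tree.leaves_under(r)} == top_rows
    )
    if a_root < tree.n_leaves:
        subgroups = {tree.labels[a_root]: "A1"}
    else:
        left, right, _, _ = tree.merges[a_root - tree.n_leaves]
        halves = [
            [tree.labels[i] for i in tree.leaves_under(child)]
            for child in (left, right)
        ]
        halves.sort(key=lambda rows: -float(matrix.loc[rows].abs().values.mean()))
        for tag, rows in zip(("A1", "A2"), halves):
            for row in rows:
                subgroups[row] = tag

    return HotspotReport(
        groups=groups,
        hotspots=hotspot_filter(matrix, hotspot_threshold),
        fractions=group_fraction(matrix, groups, reference_totals),
        subgroups=subgroups,
        tree=tree,
    )
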