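"""Distance-based gene trees and two-species gain/loss reconciliation.

Trees are ``skbio.TreeNode`` objects whose leaves are labeled
``<species>|<gene>``. Neighbor joining is implemented here (deterministic
tie-break, negative branches clamped); reconciliation labels each internal
node by species overlap of its children and the gain/loss accounting solves
``extant = mrca_units - losses + gains`` per lineage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import leaf_species

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self):
        return len(self.labels)


def protein_distance(a: str, b: str, model: str = "poisson") -> float:
    """Distance between two aligned strings (dual-gap columns dropped).

    ``p`` is the mismatch proportion over gap-free columns; ``poisson``
    applies d = -ln(1 - p).
    """
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    pairs = [(x, y) for x, y in zip(a.upper(), b.upper()) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no gap-free columns to compare")
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if model == "p":
        return p
    if model == "poisson":
        if p >= 1.0:
            raise ValueError("p = 1: Poisson distance saturated")
        return -math.log(1.0 - p)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix_from_sequences(
    named_seqs: Sequence[tuple[str, str]], model: str = "poisson"
) -> DistanceMatrix:
    """Pairwise global alignment of proteins -> corrected distance matrix."""
    from . import align  # local import keeps module deps one-way

    labels = [name for name, _ in named_seqs]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align.global_align(named_seqs[i][1], named_seqs[j][1])
            mat[i, j] = mat[j, i] = protein_distance(
                aln.aligned_a, aln.aligned_b, model
            )
    return DistanceMatrix(labels, mat)


def build_nj_tree(
    dm: DistanceMatrix,
    root: str = "midpoint",
) -> TreeNode:
    """Saitou-Nei neighbor joining, then rooting.

    Ties in the Q criterion break on the lexicographically smallest label
    pair; negative branch lengths are clamped to zero with a warning.
    ``root`` is "midpoint", "none" (unrooted trifurcation kept) or an
    outgroup leaf label.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    labels = list(dm.labels)
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # smallest leaf label under each working node

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tiebreak = tuple(sorted((keys[i], keys[j])))
                cand = (q, tiebreak, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = _clamp(vi), _clamp(vj)
        parent = TreeNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])
        new_row = np.array(
            [0.5 * (d[i, k] + d[j, k] - d[i, j]) for k in range(m) if k not in (i, j)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # final trifurcation
    r = d.sum(axis=1)
    lengths = [
        _clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2])),
        _clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2])),
        _clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1])),
    ]
    center = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = length
        center.append(node)

    if root == "none":
        return center
    if root == "midpoint":
        rooted = center.root_at_midpoint()
    else:
        leaf = center.find(root)
        rooted = center.root_at(leaf.parent)
    return rooted


def _clamp(length: float) -> float:
    if length < 0:
        logger.warning("negative branch length %.4f clamped to 0", length)
        return 0.0
    return length


def robinson_foulds(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Symmetric bipartition distance between two trees on the same leaves."""
    return int(tree_a.compare_rfd(tree_b))


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            parts.add(min(side, all_leaves - side, key=sorted))
    return parts


def bootstrap_support(
    named_rows: Sequence[tuple[str, str]],
    reps: int,
    seed: int,
    model: str = "poisson",
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support for NJ bipartitions.

    ``named_rows`` are (label, aligned string) with equal lengths. Returns
    support percentage per bipartition of the full-data tree.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = [name for name, _ in named_rows]
    rows = [seq for _, seq in named_rows]
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("aligned rows must have equal length")
    full_tree = build_nj_tree(_dm_from_rows(labels, rows, model))
    targets = _bipartitions(full_tree)
    counts = {part: 0 for part in targets}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = ["".join(row[c] for c in cols) for row in rows]
        try:
            rep_tree = build_nj_tree(_dm_from_rows(labels, resampled, model))
        except ValueError:
            continue  # saturated replicate
        rep_parts = _bipartitions(rep_tree)
        for part in targets:
            if part in rep_parts:
                counts[part] += 1
    return {part: 100.0 * k / reps for part, k in counts.items()}


def _dm_from_rows(labels, rows, model):
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = protein_distance(rows[i], rows[j], model)
    return DistanceMatrix(labels, mat)


# ---------------------------------------------------------------------------
# reconciliation

def _species_below(node: TreeNode) -> frozenset:
    return frozenset(leaf_species(leaf.name) for leaf in node.tips(include_self=True))


def resolve_polytomies(tree: TreeNode) -> TreeNode:
    """Deterministic left-branching resolution of polytomies (with warning)."""
    if any(len(node.children) > 2 for node in tree.non_tips(include_self=True)):
        logger.warning("polytomies resolved arbitrarily (left-branching)")
        tree = tree.copy()
        for node in list(tree.non_tips(include_self=True)):
            while len(node.children) > 2:
                a, b = node.children[0], node.children[1]
                node.remove(a)
                node.remove(b)
                merged = TreeNode(length=0.0)
                merged.extend([a, b])
                rest = list(node.children)
                for child in rest:
                    node.remove(child)
                node.extend([merged] + rest)
    return tree


def reconcile_species_overlap(
    tree: TreeNode, species_pair: tuple[str, str]
) -> TreeNode:
    """Label internal nodes speciation/duplication by child species overlap.

    A node is a duplication iff its children's species sets intersect;
    duplications are ``duplication_ancestral`` when the node's subtree holds
    both species, else ``duplication_lineage``. Labels are stored on
    ``node.event``.
    """
    species = set(species_pair)
    tree = resolve_polytomies(tree)
    observed = {leaf_species(leaf.name) for leaf in tree.tips()}
    extra = observed - species
    if extra:
        raise ValueError(f"tree contains species outside the pair: {sorted(extra)}")
    for node in tree.postorder():
        if node.is_tip():
            leaf_species(node.name)  # validates the label
            continue
        if len(node.children) != 2:
            raise ValueError("reconciliation requires a rooted binary tree")
        left, right = node.children
        overlap = _species_below(left) & _species_below(right)
        if not overlap:
            node.event = "speciation"
        elif len(_species_below(node)) == 2:
            node.event = "duplication_ancestral"
        else:
            node.event = "duplication_lineage"
    return tree


@dataclass
class GainLossSummary:
    """Per-class ancestral-unit count and per-species gain/loss tallies."""

    mrca_units: int
    extant: dict[str, int]
    gains: dict[str, int]
    losses: dict[str, int]
    class_label: Optional[str] = None

    def check_identity(self):
        for sp in self.extant:
            if self.extant[sp] != self.mrca_units - self.losses[sp] + self.gains[sp]:
                raise AssertionError(
                    f"accounting identity violated for species {sp!r}: "
                    f"{self.extant[sp]} != {self.mrca_units} - {self.losses[sp]}"
                    f" + {self.gains[sp]}"
                )


def infer_gain_loss(
    labeled_tree: TreeNode,
    species_pair: tuple[str, str],
    class_label: Optional[str] = None,
) -> GainLossSummary:
    """Count ancestral units and per-species gains/losses on a reconciled tree.

    Units partition the leaves: descending from the root through ancestral
    duplications, a unit is opened at every speciation node and at every
    maximal single-species clade. A unit missing one species is a loss in
    that species; extra leaves of a species within a unit are gains.
    """
    units: list[frozenset] = []

    def descend(node: TreeNode):
        if node.is_tip():
            units.append(frozenset([leaf_species(node.name)]))
            return
        event = getattr(node, "event", None)
        if event is None:
            raise ValueError("tree is not reconciled: run reconcile_species_overlap")
        if event == "speciation" or event == "duplication_lineage":
            units.append(_species_below(node))
            return
        for child in node.children:
            descend(child)

    if labeled_tree.is_tip():
        units.append(frozenset([leaf_species(labeled_tree.name)]))
    else:
        descend(labeled_tree)

    leaf_count = {sp: 0 for sp in species_pair}
    for leaf in labeled_tree.tips(include_self=True):
        leaf_count[leaf_species(leaf.name)] += 1

    mrca_units = len(units)
    extant, gains, losses = {}, {}, {}
    for sp in species_pair:
        units_with = sum(1 for u in units if sp in u)
        extant[sp] = leaf_count[sp]
        losses[sp] = mrca_units - units_with
        gains[sp] = leaf_count[sp] - units_with
    summary = GainLossSummary(mrca_units, extant, gains, losses, class_label)
    summary.check_identity()
    return summary


def gainloss_from_counts(
    mrca: Optional[int] = None,
    losses: Optional[int] = None,
    gains: Optional[int] = None,
    extant: Optional[int] = None,
) -> dict[str, int]:
    """Solve ``extant = mrca - losses + gains`` for the one missing quantity."""
    values = {"mrca": mrca, "losses": losses, "gains": gains, "extant": extant}
    missing = [k for k, v in values.items() if v is None]
    if len(missing) != 1:
        raise ValueError("exactly one of mrca/losses/gains/extant must be None")
    for k, v in values.items():
        if v is not None and v < 0:
            raise ValueError(f"{k} must be non-negative")
    key = missing[0]
    if key == "gains":
        values["gains"] = extant - mrca + losses
    elif key == "extant":
        values["extant"] = mrca - losses + gains
    elif key == "mrca":
        values["mrca"] = extant - gains + losses
    else:
        values["losses"] = mrca + gains - extant
    if values[key] < 0:
        raise ValueError(
            f"inconsistent counts: solved {key} = {values[key]} is negative"
        )
    return values
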