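"""16S rRNA distance phylogenetics: pairwise distances, neighbor joining,
bootstrap supports.

Distances come from closed-form models on an existing alignment:
``p`` (mismatch fraction), ``jc69`` (Jukes-Cantor,
d = -3/4 ln(1 - 4p/3)) and ``k2p`` (Kimura two-parameter, separating
transitions from transversions).  Sites where either sequence has a gap or
ambiguity are excluded per pair (pairwise deletion) by default.

Tree building is the Saitou-Nei neighbor-joining agglomeration with the
standard Q-criterion; it is exact on additive distance matrices, which the
test suite exploits as an oracle.  Q-ties break on the smallest pair of
cluster keys (a cluster's key is its smallest leaf label) so runs are
reproducible.  Negative branch-length estimates are clamped to zero with
the clamped total recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import DistanceMatrix

__all__ = [
    "Alignment",
    "PhyloTree",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "tree_bipartitions",
]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


@dataclass
class Alignment:
    """Aligned sequences over {A, C, G, T, N, -}; equal lengths, unique ids."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("one id per sequence required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        if not self.sequences or len(self.sequences[0]) < 1:
            raise ValueError("alignment must be non-empty")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix: A,C,G,T -> 0..3; gap/ambiguity -> 4."""
        return _CODE[
            np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8).reshape(
                len(self), self.n_sites
            )
        ]

    @classmethod
    def read_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences")
        return cls([r.id for r in records], [str(r.seq).upper() for r in records])

    def write_fasta(self, path) -> None:
        SeqIO.write(
            [SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.sequences)],
            str(path),
            "fasta",
        )


def _pair_counts(codes: np.ndarray, weights: np.ndarray | None = None):
    """Per-pair counts of comparable sites, mismatches and transitions,
    optionally weighting alignment columns (for bootstrap resampling)."""
    valid = codes < 4
    w = np.ones(codes.shape[1]) if weights is None else np.asarray(weights, float)
    Vw = valid * w
    comparable = Vw @ valid.T
    match = np.zeros_like(comparable)
    onehot = [(codes == c) & valid for c in range(4)]
    for E in onehot:
        match += (E * w) @ E.T
    A, C, G, T = onehot
    transitions = (A * w) @ G.T + (G * w) @ A.T + (C * w) @ T.T + (T * w) @ C.T
    return comparable, comparable - match, transitions


def _distances_from_counts(
    comparable: np.ndarray,
    mismatch: np.ndarray,
    transitions: np.ndarray,
    ids: list[str],
    model: str,
) -> np.ndarray:
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    if np.any(comparable[iu] == 0):
        i, j = _first_bad(comparable == 0, iu)
        raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
        if model == "p":
            d = p
        elif model == "jc69":
            arg = 1.0 - 4.0 * p / 3.0
            if np.any(arg[iu] <= 0):
                i, j = _first_bad(arg <= 0, iu)
                raise ValueError(
                    f"jc69 undefined (p >= 3/4) between {ids[i]!r} and {ids[j]!r}"
                )
            d = -0.75 * np.log(arg)
        elif model == "k2p":
            P = np.where(comparable > 0, transitions / np.maximum(comparable, 1), 0.0)
            Q = p - P
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            if np.any(a1[iu] <= 0) or np.any(a2[iu] <= 0):
                i, j = _first_bad((a1 <= 0) | (a2 <= 0), iu)
                raise ValueError(f"k2p log-domain violation between {ids[i]!r} and {ids[j]!r}")
            d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
        else:
            raise ValueError(f"unknown model {model!r}; use p, jc69 or k2p")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _first_bad(mask: np.ndarray, iu) -> tuple[int, int]:
    flat = np.flatnonzero(mask[iu])[0]
    return int(iu[0][flat]), int(iu[1][flat])


def pairwise_distance(
    a: Alignment, model: str = "jc69", complete_deletion: bool = False
) -> DistanceMatrix:
    codes = a.codes()
    if complete_deletion:
        codes = codes[:, (codes < 4).all(axis=0)]
        if codes.shape[1] == 0:
            raise ValueError("no site is unambiguous in every sequence")
    comparable, mismatch, transitions = _pair_counts(codes)
    return DistanceMatrix(a.ids, _distances_from_counts(comparable, mismatch, transitions, a.ids, model))


@dataclass
class PhyloTree:
    """Unrooted branch-length tree (dendropy-backed) with optional
    bipartition supports (fraction of bootstrap replicates)."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] | None = None
    clamped_negative_total: float = 0.0
    n_bootstrap: int = 0
    n_skipped_replicates: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def total_length(self) -> float:
        return float(sum(e.length or 0.0 for e in self.tree.edges() if e.length is not None))

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            ).strip()
        )

    def midpoint_rooted(self) -> dendropy.Tree:
        clone = self.tree.clone(depth=1)
        clone.reroot_at_midpoint(update_bipartitions=False)
        clone.is_rooted = True
        return clone

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits as frozensets of leaf labels, each canonicalised to
    the side *not* containing the smallest leaf label."""
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            splits.add(side)
    return splits


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices."""
    if np.any(np.isnan(d.values)):
        raise ValueError("distance matrix contains NaN")
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least two taxa")

    taxa = dendropy.TaxonNamespace(list(d.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    clamped = 0.0

    def make_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        return node

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    nodes = [make_leaf(l) for l in d.labels]
    keys = list(d.labels)
    D = d.values.astype(float).copy()

    if n == 2:
        root = dendropy.Node()
        half = D[0, 1] / 2.0
        for node in nodes:
            node.edge.length = half
            root.add_child(node)
        tree.seed_node = root
        tree.is_rooted = False
        return PhyloTree(tree, clamped_negative_total=clamped, provenance={"method": "nj"})

    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        Q = (Q + Q.T) / 2.0  # exact symmetry despite float summation order
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = [(i, j) for i, j in np.argwhere(Q == qmin) if i < j]
        i, j = min(ties, key=lambda p: tuple(sorted((keys[p[0]], keys[p[1]]))))
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        nodes[i].edge.length = clamp(li)
        nodes[j].edge.length = clamp(lj)
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        newrow = 0.5 * (D[i] + D[j] - D[i, j])
        newrow = np.delete(newrow, [i, j])
        D = np.delete(np.delete(D, [i, j], axis=0), [i, j], axis=1)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow
        D[:-1, -1] = newrow
        new_key = min(keys[i], keys[j])
        for idx in sorted((i, j), reverse=True):
            del nodes[idx]
            del keys[idx]
        nodes.append(u)
        keys.append(new_key)

    root = dendropy.Node()
    if len(nodes) == 3:
        la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        for node, length in zip(nodes, (la, lb, lc)):
            node.edge.length = clamp(length)
            root.add_child(node)
    else:  # exactly two clusters remain (possible only when n == 2, handled above)
        raise AssertionError("unreachable")
    tree.seed_node = root
    tree.is_rooted = False
    if clamped > 0:
        logger.info("neighbor joining clamped %.3g of negative branch length", clamped)
    return PhyloTree(tree, clamped_negative_total=clamped, provenance={"method": "nj"})


def bootstrap_support(
    a: Alignment,
    model: str = "jc69",
    n_reps: int = 1000,
    seed: int = 0,
    complete_deletion: bool = False,
) -> PhyloTree:
    """NJ tree with bipartition supports from column-resampled replicates.

    Each replicate resamples alignment columns with replacement; a
    replicate whose resampled distances are undefined (saturated or
    incomparable pair) is skipped and counted.  Supports are fractions of
    successful replicates; more than 50% skipped is an error.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = a.codes()
    if complete_deletion:
        codes = codes[:, (codes < 4).all(axis=0)]
    L = codes.shape[1]
    base = neighbor_joining(pairwise_distance(a, model, complete_deletion))
    original_splits = base.bipartitions()
    counts = {s: 0 for s in original_splits}
    rng = np.random.default_rng(seed)
    skipped = 0
    done = 0
    for _ in range(n_reps):
        weights = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        comparable, mismatch, transitions = _pair_counts(codes, weights)
        try:
            dvals = _distances_from_counts(comparable, mismatch, transitions, a.ids, model)
        except ValueError:
            skipped += 1
            continue
        rep_tree = neighbor_joining(DistanceMatrix(a.ids, dvals))
        rep_splits = rep_tree.bipartitions()
        for s in original_splits:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    if skipped > n_reps / 2:
        raise ValueError(f"{skipped}/{n_reps} bootstrap replicates undefined")
    supports = {s: counts[s] / done for s in original_splits} if done else {}
    _annotate_supports(base.tree, supports)
    base.supports = supports
    base.n_bootstrap = done
    base.n_skipped_replicates = skipped
    return base


def _annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if side in supports:
            node.label = f"{supports[side]:.3f}"
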