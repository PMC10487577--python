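"""Dendrogram-versus-phylogeny grouping concordance.

Two rooted trees over the same strains (the mass-profile dendrogram and
the midpoint-rooted 16S NJ tree) are compared at the species level.  For
each species the *spanning clade* — the smallest clade containing all of
that species' strains — is located in each tree, and its *co-group set* is
the set of species with at least one strain inside that clade.  A species
whose strains are cleanly separated co-groups only with itself; two
species whose strains interleave each list the other.  A species is
*consistent* when its co-group set is identical in both trees, and the
grouping similarity is the consistent fraction of species.  A contingency
(Sankey) table between any two flat groupings is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .clustering import Dendrogram, Grouping
from .phylo import PhyloTree, tree_bipartitions
from .spectra import StrainManifest

__all__ = [
    "ConcordanceReport",
    "species_cogroup_sets",
    "grouping_similarity",
    "sankey_table",
    "robinson_foulds",
    "cut_rooted_tree",
    "as_rooted_tree",
]


def as_rooted_tree(tree) -> dendropy.Tree:
    """Coerce a Dendrogram (already rooted) or an unrooted PhyloTree
    (midpoint-rooted) to a rooted dendropy tree."""
    if isinstance(tree, dendropy.Tree):
        return tree
    if isinstance(tree, Dendrogram):
        t = tree.to_dendropy()
        t.is_rooted = True
        return t
    if isinstance(tree, PhyloTree):
        return tree.midpoint_rooted()
    raise TypeError(f"cannot interpret {type(tree).__name__} as a rooted tree")


def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {l.taxon.label for l in tree.leaf_node_iter()}


def species_cogroup_sets(
    tree, manifest: StrainManifest
) -> dict[str, frozenset]:
    """Map each species to the species sharing its spanning clade."""
    t = as_rooted_tree(tree)
    leaves = _leaf_labels(t)
    strains = set(manifest.strain_ids)
    if leaves != strains:
        raise ValueError(
            f"tree/manifest mismatch; only in tree: {sorted(leaves - strains)}, "
            f"only in manifest: {sorted(strains - leaves)}"
        )
    species_map = manifest.species_map
    out: dict[str, frozenset] = {}
    for species in manifest.species_list:
        members = set(manifest.strains_of_species(species))
        taxa = [tax for tax in t.taxon_namespace if tax.label in members]
        if len(taxa) == 1:
            out[species] = frozenset([species])
            continue
        mrca = t.mrca(taxa=taxa)
        inside = {l.taxon.label for l in mrca.leaf_iter()}
        out[species] = frozenset(species_map[s] for s in inside)
    return out


@dataclass
class ConcordanceReport:
    per_species: pd.DataFrame  # species, cogroup_a, cogroup_b, consistent
    grouping_similarity: float
    sankey_edges: pd.DataFrame | None = None

    @property
    def n_consistent(self) -> int:
        return int(self.per_species["consistent"].sum())

    @property
    def n_species(self) -> int:
        return len(self.per_species)

    def to_csv(self, path) -> None:
        self.per_species.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_consistent": self.n_consistent,
            "grouping_similarity": self.grouping_similarity,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def grouping_similarity(
    tree_a,
    tree_b,
    manifest: StrainManifest,
    method: str = "cogroup",
    k: int | None = None,
) -> ConcordanceReport:
    """Fraction of species with identical co-group sets in the two trees.

    ``method="cogroup"`` (default) uses spanning-clade co-group sets;
    ``method="cut"`` cuts both rooted trees into ``k`` groups and compares
    species co-membership patterns instead.
    """
    if method == "cogroup":
        sets_a = species_cogroup_sets(tree_a, manifest)
        sets_b = species_cogroup_sets(tree_b, manifest)
    elif method == "cut":
        if k is None:
            raise ValueError("method='cut' requires k")
        sets_a = _cut_cogroup_sets(tree_a, manifest, k)
        sets_b = _cut_cogroup_sets(tree_b, manifest, k)
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for species in manifest.species_list:
        a, b = sets_a[species], sets_b[species]
        rows.append(
            {
                "species": species,
                "cogroup_a": ";".join(sorted(a)),
                "cogroup_b": ";".join(sorted(b)),
                "consistent": a == b,
            }
        )
    table = pd.DataFrame(rows)
    similarity = float(table["consistent"].mean())
    return ConcordanceReport(per_species=table, grouping_similarity=similarity)


def _cut_cogroup_sets(tree, manifest: StrainManifest, k: int) -> dict[str, frozenset]:
    grouping = cut_rooted_tree(tree, k)
    species_map = manifest.species_map
    by_group: dict[str, set] = {}
    for strain, gid in grouping.assignment.items():
        by_group.setdefault(gid, set()).add(species_map[strain])
    out: dict[str, frozenset] = {}
    for species in manifest.species_list:
        covered: set = set()
        for strain in manifest.strains_of_species(species):
            covered |= by_group[grouping.assignment[strain]]
        out[species] = frozenset(covered)
    return out


def cut_rooted_tree(tree, k: int) -> Grouping:
    """Cut a rooted tree into k groups by repeatedly splitting the
    shallowest remaining subtree root (ties to the smallest leaf label).

    On an ultrametric dendrogram this removes the k-1 highest merges, so
    it generalises the dendrogram cut to arbitrary rooted trees."""
    t = as_rooted_tree(tree)
    n = sum(1 for _ in t.leaf_node_iter())
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    depth: dict[dendropy.Node, float] = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        depth[node] = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)

    def min_leaf(node: dendropy.Node) -> str:
        return min(l.taxon.label for l in node.leaf_iter())

    subtrees = [t.seed_node]
    while len(subtrees) < k:
        splittable = [s for s in subtrees if not s.is_leaf()]
        target = min(splittable, key=lambda s: (depth[s], min_leaf(s)))
        subtrees.remove(target)
        subtrees.extend(target.child_nodes())
    assignment = {}
    for root in subtrees:
        gid = min_leaf(root)
        for leaf in root.leaf_iter():
            assignment[leaf.taxon.label] = gid
    return Grouping(assignment, provenance=f"rooted tree cut k={k}")


def sankey_table(g_a: Grouping, g_b: Grouping) -> pd.DataFrame:
    """Contingency edges between two partitions: one row per nonempty
    (group_a, group_b) pair with the shared-strain count."""
    if set(g_a.assignment) != set(g_b.assignment):
        raise ValueError("groupings cover different strain sets")
    rows: dict[tuple[str, str], int] = {}
    for strain in g_a.assignment:
        key = (g_a.assignment[strain], g_b.assignment[strain])
        rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [(a, b, c) for (a, b), c in rows.items()], columns=["source", "target", "count"]
    )
    return table.sort_values(["source", "target"]).reset_index(drop=True)


def robinson_foulds(t1, t2) -> int:
    """Symmetric difference of non-trivial bipartitions of two unrooted trees."""
    a = t1.tree if isinstance(t1, PhyloTree) else t1
    b = t2.tree if isinstance(t2, PhyloTree) else t2
    la, lb = _leaf_labels(a), _leaf_labels(b)
    if la != lb:
        raise ValueError(
            f"leaf sets differ; only in first: {sorted(la - lb)}, "
            f"only in second: {sorted(lb - la)}"
        )
    return len(tree_bipartitions(a) ^ tree_bipartitions(b))
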