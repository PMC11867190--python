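"""Tree containers and Newick I/O.

Two tree representations are used:

- :class:`FullTree` — the complete event history of a PBD simulation, as a
  flat table of lineage records (birth / completion / death times and the
  species each lineage belongs to).  Forward time runs from 0 (origin) to
  ``T`` (the present).
- :class:`ReconstructedTree` — a rooted, binary, ultrametric tree of extant
  species with branch lengths in Myr, wrapping a :class:`dendropy.Tree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


class NewickError(ValueError):
    """Raised for malformed Newick input or trees unfit for analysis."""


@dataclass
class LineageRecord:
    """One lineage of a PBD simulation.

    ``species`` is the label of the species the lineage belongs to: a new
    label is minted when a lineage completes speciation (or for the root,
    which starts good); an incipient lineage inherits its parent's label at
    the moment of initiation.
    """

    id: int
    parent: Optional[int]
    birth: float
    species: int
    completion: Optional[float] = None
    death: Optional[float] = None

    def alive_at(self, t: float) -> bool:
        return self.birth <= t and (self.death is None or self.death > t)

    def good_at(self, t: float) -> bool:
        return self.alive_at(t) and self.completion is not None and self.completion <= t


@dataclass
class FullTree:
    """Complete PBD event history up to the present ``T``."""

    T: float
    lineages: list[LineageRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lineages:
            roots = [rec for rec in self.lineages if rec.parent is None]
            if len(roots) != 1 or roots[0].birth != 0.0:
                raise ValueError("FullTree requires exactly one root lineage born at 0")

    @property
    def root(self) -> LineageRecord:
        return next(rec for rec in self.lineages if rec.parent is None)

    def alive(self, t: Optional[float] = None) -> list[LineageRecord]:
        t = self.T if t is None else t
        return [rec for rec in self.lineages if rec.alive_at(t)]

    def extant_species(self, require_good_alive: bool = False) -> dict[int, list[LineageRecord]]:
        """Extant species at the present, as ``{label: member lineages alive at T}``.

        A species is extant if any member lineage (the completed founder or a
        conspecific incipient descendant) is alive at ``T``; with
        ``require_good_alive`` only species whose good (completed) lineage
        itself survives are counted.
        """
        members: dict[int, list[LineageRecord]] = {}
        for rec in self.alive(self.T):
            members.setdefault(rec.species, []).append(rec)
        if require_good_alive:
            members = {
                label: recs
                for label, recs in members.items()
                if any(rec.good_at(self.T) for rec in recs)
            }
        return members

    def children_of(self, lineage_id: int) -> list[LineageRecord]:
        return [rec for rec in self.lineages if rec.parent == lineage_id]


class ReconstructedTree:
    """Rooted binary ultrametric tree of extant species (branch lengths in Myr).

    Thin wrapper around :class:`dendropy.Tree` adding height/age helpers and
    the validity checks the downstream statistics rely on.  The optional
    ``stem_length`` records the edge from the process origin to the crown.
    """

    def __init__(self, tree: dendropy.Tree, stem_length: float = 0.0):
        self._tree = tree
        self.stem_length = float(stem_length)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "ReconstructedTree":
        return read_newick(text)

    # -- basic structure ----------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label if leaf.taxon else "" for leaf in self._tree.leaf_node_iter()]

    def leaf_iter(self) -> Iterator[dendropy.Node]:
        return self._tree.leaf_node_iter()

    @property
    def height(self) -> float:
        """Maximum root-to-tip path length (crown age for ultrametric trees)."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return max(leaf.root_distance for leaf in self._tree.leaf_node_iter())

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age before present of every node (tips at ~0 when ultrametric)."""
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        h = max(leaf.root_distance for leaf in self._tree.leaf_node_iter())
        return {nd: h - nd.root_distance for nd in self._tree.preorder_node_iter()}

    def branching_ages(self) -> list[float]:
        """Ages of the internal nodes (including the root), sorted descending."""
        ages = self.node_ages()
        out = [age for nd, age in ages.items() if not nd.is_leaf()]
        return sorted(out, reverse=True)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        dists = [leaf.root_distance for leaf in self._tree.leaf_node_iter()]
        h = max(dists)
        if h == 0:
            return True
        return max(dists) - min(dists) <= rel_tol * h

    def is_binary(self) -> bool:
        for nd in self._tree.preorder_node_iter():
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                return False
        return True

    # -- I/O ----------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def clone(self) -> "ReconstructedTree":
        return ReconstructedTree(self._tree.clone(depth=1), self.stem_length)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<ReconstructedTree n_tips={self.n_tips} height={self.height:.4g}>"


def read_newick(text: str) -> ReconstructedTree:
    """Parse a Newick string with branch lengths into a :class:`ReconstructedTree`.

    Raises :class:`NewickError` for malformed input (reporting the position
    the parser stopped at) and for trees with missing branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise NewickError("empty Newick tree")
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        if nd.edge.length is None:
            label = nd.taxon.label if nd.taxon else "<internal>"
            raise NewickError(f"missing branch length on edge above {label}")
    stem = tree.seed_node.edge.length or 0.0
    tree.seed_node.edge.length = None
    return ReconstructedTree(tree, stem_length=stem)


def write_newick(tree: ReconstructedTree) -> str:
    """Serialise to Newick with >= 10 significant digits on branch lengths."""
    leaves = list(tree.dendropy_tree.leaf_node_iter())
    if not leaves or all(lf.taxon is None for lf in leaves):
        raise NewickError("cannot serialise an empty tree")
    s = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    return s.strip()
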