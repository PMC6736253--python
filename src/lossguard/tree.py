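"""Rooted binary species trees with supergroup and root-side leaf annotations.

The species tree is the scaffold for all ancestral-content reconstruction:
every leaf is a sequenced species assigned to a eukaryotic supergroup
(e.g. Opisthokonta, Amoebozoa, SAR) and to one of the two clades hanging
off the root ("left"/"right").  Ancestral-content criteria such as
"present in at least three supergroups and on both sides of the root"
are evaluated against these annotations.

Newick parsing is delegated to :mod:`dendropy`; annotations travel in a
sidecar TSV (``species_id, supergroup, phylum, root_side``) or, as a
convenience, inline NHX-style comments.  Trees with polytomies are
rejected: the reconstruction logic assumes strictly bifurcating trees.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy
import pandas as pd

__all__ = ["Node", "SpeciesTree", "read_newick", "write_newick"]

_NHX_RE = re.compile(r"&&NHX:(.*)")


@dataclass
class Node:
    """One node of a rooted binary tree.

    Leaves carry the species annotations; internal nodes only have ids.
    """

    id: str
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    species_id: Optional[str] = None
    supergroup: Optional[str] = None
    phylum: Optional[str] = None
    root_side: Optional[str] = None  # "left" | "right", leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["Node"]:
        return (n for n in self.postorder() if n.is_leaf)


class SpeciesTree:
    """A rooted, strictly binary species tree with annotated leaves.

    Parameters
    ----------
    root:
        Root node of an already-linked :class:`Node` structure. The root
        must have exactly two children and every internal node exactly two.

    Raises
    ------
    ValueError
        If the tree is not binary, a leaf lacks a supergroup, species ids
        collide, or a declared ``root_side`` contradicts the topology.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index: dict[str, Node] = {}
        self._validate_and_index()

    # -- construction helpers -------------------------------------------------

    def _validate_and_index(self) -> None:
        if len(self.root.children) != 2:
            raise ValueError("root must have exactly two children")
        left, right = self.root.children
        for node in self.root.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError(f"non-binary node: {node.id!r} has {len(node.children)} children")
            if node.id in self._index:
                raise ValueError(f"duplicate node id: {node.id!r}")
            self._index[node.id] = node
        seen_species: set[str] = set()
        for side, top in (("left", left), ("right", right)):
            for leaf in top.leaves():
                if leaf.species_id is None:
                    leaf.species_id = leaf.id
                if leaf.species_id in seen_species:
                    raise ValueError(f"duplicate species_id: {leaf.species_id!r}")
                seen_species.add(leaf.species_id)
                if leaf.supergroup is None:
                    raise ValueError(f"leaf {leaf.species_id!r} missing supergroup annotation")
                if leaf.root_side is not None and leaf.root_side != side:
                    raise ValueError(
                        f"leaf {leaf.species_id!r} declared root_side={leaf.root_side!r} "
                        f"but descends from the {side} root child"
                    )
                leaf.root_side = side

    # -- queries --------------------------------------------------------------

    def node(self, node_id: str) -> Node:
        return self._index[node_id]

    @property
    def nodes(self) -> list[Node]:
        return list(self.root.postorder())

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def species_ids(self) -> list[str]:
        return [n.species_id for n in self.leaves]

    @property
    def supergroups(self) -> dict[str, str]:
        """species_id -> supergroup for every leaf."""
        return {n.species_id: n.supergroup for n in self.leaves}

    @property
    def root_sides(self) -> dict[str, str]:
        """species_id -> 'left'|'right' for every leaf."""
        return {n.species_id: n.root_side for n in self.leaves}

    def leaf_by_species(self, species_id: str) -> Node:
        for leaf in self.leaves:
            if leaf.species_id == species_id:
                return leaf
        raise KeyError(species_id)

    def mrca(self, species_ids) -> Node:
        """Most recent common ancestor of a non-empty set of leaves."""
        wanted = set(species_ids)
        if not wanted:
            raise ValueError("mrca of empty set")
        # deepest node whose leaf set covers all wanted species
        best = self.root
        node = self.root
        while node.children:
            for child in node.children:
                covered = {l.species_id for l in child.leaves()}
                if wanted <= covered:
                    node = child
                    best = child
                    break
            else:
                break
        return best

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.species_id
            return "(" + ",".join(fmt(c) for c in node.children) + ")" + (
                node.id if not node.id.startswith("_") else ""
            )

        return fmt(self.root) + ";"

    def sidecar_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_id": n.species_id,
                "supergroup": n.supergroup,
                "phylum": n.phylum if n.phylum is not None else "",
                "root_side": n.root_side,
            }
            for n in self.leaves
        ]
        return pd.DataFrame(rows)


def _parse_nhx_comment(comment: str) -> dict[str, str]:
    m = _NHX_RE.search(comment)
    if not m:
        return {}
    out = {}
    for kv in m.group(1).split(":"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    counter = [0]

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise ValueError("unlabeled leaf in Newick input")
            node = Node(id=label.replace(" ", "_"), species_id=label.replace(" ", "_"))
        else:
            counter[0] += 1
            label = dnode.label or f"_n{counter[0]}"
            node = Node(id=label)
        for comment in getattr(dnode, "comments", []) or []:
            nhx = _parse_nhx_comment(comment)
            node.supergroup = nhx.get("supergroup", node.supergroup)
            node.phylum = nhx.get("phylum", node.phylum)
            node.root_side = nhx.get("root_side", node.root_side)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    return convert(dtree.seed_node)


def _apply_sidecar(root: Node, sidecar: pd.DataFrame) -> None:
    required = {"species_id", "supergroup"}
    if not required <= set(sidecar.columns):
        raise ValueError(f"sidecar must have columns {sorted(required)}")
    meta = sidecar.set_index("species_id")
    if meta.index.has_duplicates:
        raise ValueError("duplicate species_id in sidecar")
    for leaf in (n for n in root.postorder() if not n.children):
        sid = leaf.species_id or leaf.id
        if sid not in meta.index:
            raise ValueError(f"leaf {sid!r} missing from sidecar")
        row = meta.loc[sid]
        leaf.supergroup = str(row["supergroup"])
        if "phylum" in meta.columns and str(row.get("phylum", "")) not in ("", "nan"):
            leaf.phylum = str(row["phylum"])
        if "root_side" in meta.columns and str(row.get("root_side", "")) not in ("", "nan"):
            leaf.root_side = str(row["root_side"])


def read_newick(path, sidecar=None) -> SpeciesTree:
    """Read a rooted binary species tree from a Newick file.

    Parameters
    ----------
    path:
        Newick file with named leaves.  Polytomies are rejected.
    sidecar:
        Optional path to (or DataFrame of) a TSV with columns
        ``species_id, supergroup, phylum, root_side``.  If omitted, the
        annotations must be present as inline ``[&&NHX:...]`` comments.
    """
    dtree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        extract_comment_metadata=False,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = _from_dendropy(dtree)
    if sidecar is not None:
        frame = sidecar if isinstance(sidecar, pd.DataFrame) else pd.read_csv(sidecar, sep="\t", dtype=str)
        _apply_sidecar(root, frame)
    return SpeciesTree(root)


def write_newick(tree: SpeciesTree, path, sidecar_path=None) -> None:
    """Write the tree as Newick plus (optionally) the annotation sidecar."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
    if sidecar_path is not None:
        tree.sidecar_frame().to_csv(sidecar_path, sep="\t", index=False)


def read_newick_string(newick: str, sidecar: pd.DataFrame | None = None) -> SpeciesTree:
    """Parse a Newick string (convenience wrapper for tests and fixtures)."""
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        extract_comment_metadata=False,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root = _from_dendropy(dtree)
    if sidecar is not None:
        _apply_sidecar(root, sidecar)
    return SpeciesTree(root)
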