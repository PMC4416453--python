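"""Reading ultrametric chronograms and extracting node ages.

Chronograms (newick or NEXUS, branch lengths in Myr) are parsed with
dendropy, validated (rooted, unique tip labels, branch lengths present,
ultrametric within tolerance) and wrapped in a :class:`Chronogram` from which
crown (MRCA) ages, stem ages and disjunction ages are read.  Ages are Ma
before present: tips sit at age 0 and node age = tree height minus the
node's root distance.  BEAST-style ``[&...]`` node annotations are tolerated
and ignored; trees with non-contemporaneous tips are rejected, not rescaled.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Literal

import dendropy

from .errors import (
    LabelError,
    MissingBranchLengthError,
    TreeError,
    UltrametricityError,
    UnrootedTreeError,
)

__all__ = [
    "Chronogram",
    "DisjunctionQuery",
    "read_chronogram",
    "write_chronogram",
    "mrca_age",
    "stem_age",
    "disjunction_age",
]

SplitType = Literal["W-E", "W-E&S", "E-S"]

#: relative ultrametricity tolerance (fraction of tree height)
DEFAULT_REL_TOL = 1e-4


@dataclass(frozen=True)
class DisjunctionQuery:
    """Two disjoint taxon sets whose dated split is sought."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    split_type: SplitType = "W-E"

    def __post_init__(self) -> None:
        side_a = frozenset(self.side_a)
        side_b = frozenset(self.side_b)
        if not side_a or not side_b:
            raise TreeError("disjunction query sides must be non-empty")
        if side_a & side_b:
            raise TreeError(
                f"query sides overlap: {sorted(side_a & side_b)}"
            )
        if self.split_type not in ("W-E", "W-E&S", "E-S"):
            raise TreeError(f"unknown split_type {self.split_type!r}")
        object.__setattr__(self, "side_a", side_a)
        object.__setattr__(self, "side_b", side_b)


class Chronogram:
    """A validated, rooted, ultrametric dated tree."""

    def __init__(self, tree: dendropy.Tree, height: float) -> None:
        self.tree = tree
        self.height = height
        self._taxa = {
            leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()
        }

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(self._taxa)

    def _resolve(self, labels: Iterable[str]) -> list[dendropy.Taxon]:
        labels = list(labels)
        missing = sorted(set(labels) - set(self._taxa))
        if missing:
            raise LabelError(f"labels not in chronogram: {missing}")
        return [self._taxa[label] for label in labels]

    def node_age(self, node: dendropy.Node) -> float:
        return self.height - node.distance_from_root()


def _looks_like_tree_text(source: str) -> bool:
    stripped = source.lstrip()
    return stripped.startswith(("(", "#NEXUS", "#nexus"))


def read_chronogram(source: str | os.PathLike, tol: float | None = None) -> Chronogram:
    """Parse and validate a chronogram from text or a file path.

    ``tol`` is the maximum allowed root-to-tip spread in Myr; by default it
    is ``1e-4`` times the tree height (dating-output roundoff).  The schema
    is sniffed: text starting with ``#NEXUS`` is read as NEXUS (translate
    tables honored), anything else as newick.
    """
    if isinstance(source, (str,)) and _looks_like_tree_text(source):
        text = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc

    root = tree.seed_node
    children = root.child_nodes()
    explicitly_unrooted = "[&u]" in text.lower()
    if explicitly_unrooted or len(children) > 2:
        raise UnrootedTreeError(
            "tree is unrooted (explicit [&U] or basal polytomy); a rooted "
            "chronogram is required"
        )
    if len(children) < 2 and not root.is_leaf():
        # unifurcate root: collapse the root edge
        tree.suppress_unifurcations()
        root = tree.seed_node
    # a plain newick with a basal bifurcation is read as a rooted chronogram
    tree.is_rooted = True

    leaves = tree.leaf_node_iter()
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree has unlabeled tips")
        labels.append(leaf.taxon.label)
    if len(labels) != len(set(labels)):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise MissingBranchLengthError(
                f"edge above {_describe(edge.head_node)} has no branch length"
            )
        if edge.length < 0:
            raise TreeError(
                f"negative branch length above {_describe(edge.head_node)}"
            )

    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    height = max(depths)
    spread = height - min(depths)
    allowed = DEFAULT_REL_TOL * height if tol is None else float(tol)
    if spread > allowed:
        raise UltrametricityError(
            f"root-to-tip spread {spread:.6g} Myr exceeds tolerance "
            f"{allowed:.6g}; tips are not contemporaneous"
        )
    return Chronogram(tree, height)


def _describe(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def write_chronogram(chrono: Chronogram) -> str:
    """Newick text for a chronogram (round-trips through read_chronogram)."""
    out = io.StringIO()
    chrono.tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue()


def _mrca_node(chrono: Chronogram, labels: Iterable[str]) -> dendropy.Node:
    taxa = chrono._resolve(labels)
    if len(taxa) == 1:
        return chrono.tree.find_node_with_taxon_label(taxa[0].label)
    node = chrono.tree.mrca(taxa=taxa)
    if node is None:
        raise TreeError(f"no MRCA found for {sorted(t.label for t in taxa)}")
    return node


def mrca_age(chrono: Chronogram, taxa: Iterable[str]) -> float:
    """Crown age (Ma) of the most recent common ancestor of ``taxa``.

    A single taxon returns age 0 by convention (a tip has no crown).
    """
    labels = list(taxa)
    if len(set(labels)) == 1:
        chrono._resolve(labels)
        return 0.0
    return chrono.node_age(_mrca_node(chrono, labels))


def stem_age(chrono: Chronogram, taxa: Iterable[str]) -> float:
    """Age of the branch subtending the MRCA of ``taxa`` (its parent node)."""
    node = _mrca_node(chrono, list(taxa))
    if node.parent_node is None:
        raise TreeError(
            "MRCA is the root: stem age undefined without an outgroup"
        )
    return chrono.node_age(node.parent_node)


def disjunction_age(chrono: Chronogram, query: DisjunctionQuery) -> float:
    """Age of the dated split separating the two sides of a disjunction.

    This is the MRCA age of the union of both sides; the union need not be
    monophyletic.
    """
    return mrca_age(chrono, query.side_a | query.side_b)
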