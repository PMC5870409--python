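"""Haplotype bifurcation trees and EHH decay around a core variant.

A bifurcation diagram is rooted at a core allele (here typically rs334,
with A the ancestral HbA allele and T the derived sickle allele) and
extends marker by marker away from the core, proximal or distal.  At each
step the haplotypes carrying the core allele split according to the allele
observed at the next marker; branch widths count the haplotypes sharing an
extension, portraying the breakdown of LD with distance.  The extended
haplotype homozygosity EHH(d) is the probability that two randomly drawn
core-allele carriers are identical over the first d flanking markers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .ld import MISSING_ALLELE, HaplotypePanel

__all__ = [
    "BifurcationNode",
    "BifurcationTree",
    "build_bifurcation",
    "ehh",
    "ehh_from_tree",
    "serialize_tree",
    "parse_tree",
]


@dataclass
class BifurcationNode:
    """One branch of the diagram: the allele taken at this depth and the
    number of haplotypes still sharing the extension."""

    allele: int | None  # None at the root
    depth: int
    count: int
    children: "dict[int, BifurcationNode]" = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BifurcationNode):
            return NotImplemented
        return (
            self.allele == other.allele
            and self.depth == other.depth
            and self.count == other.count
            and self.children == other.children
        )


@dataclass
class BifurcationTree:
    core_marker: str
    core_allele: int
    direction: str  # "proximal" or "distal"
    root: BifurcationNode
    #: flanking markers in traversal order (depth 1, 2, ...)
    markers: list[str] = field(default_factory=list)
    #: haplotypes dropped for missing data at each depth (index 0 = depth 1)
    dropped_per_depth: list[int] = field(default_factory=list)

    @property
    def root_count(self) -> int:
        return self.root.count

    @property
    def empty(self) -> bool:
        return self.root.count == 0

    def nodes_at_depth(self, depth: int) -> list[BifurcationNode]:
        level = [self.root]
        for _ in range(depth):
            level = [c for node in level for c in node.children.values()]
        return level

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BifurcationTree):
            return NotImplemented
        return (
            self.core_marker == other.core_marker
            and self.core_allele == other.core_allele
            and self.direction == other.direction
            and self.markers == other.markers
            and self.dropped_per_depth == other.dropped_per_depth
            and self.root == other.root
        )


def _flank_indices(panel: HaplotypePanel, core_idx: int, direction: str) -> list[int]:
    if direction == "distal":
        return list(range(core_idx + 1, panel.n_markers))
    if direction == "proximal":
        return list(range(core_idx - 1, -1, -1))
    raise ValueError("direction must be 'proximal' or 'distal'")


def build_bifurcation(
    panel: HaplotypePanel,
    core_marker: str,
    core_allele: int,
    direction: str,
    max_depth: int | None = None,
) -> BifurcationTree:
    """Group core-allele carriers by successive flanking alleles.

    Markers are taken in order of increasing distance from the core in the
    chosen direction.  A node splits when both alleles occur among its
    haplotypes; haplotypes missing the allele at the next marker leave the
    tree at that depth (counted in ``dropped_per_depth``).  If no
    chromosome carries the core allele an empty (flagged) tree is returned.
    """
    if not panel.phased:
        raise ValueError("bifurcation trees require a phased panel")
    core_idx = panel.marker_index(core_marker)
    flanks = _flank_indices(panel, core_idx, direction)
    if max_depth is not None:
        if max_depth > len(flanks):
            raise ValueError(
                f"max_depth {max_depth} exceeds {len(flanks)} markers available "
                f"{direction} of the core"
            )
        flanks = flanks[:max_depth]

    carriers = np.nonzero(panel.data[:, core_idx] == core_allele)[0]
    root = BifurcationNode(None, 0, int(carriers.size))
    tree = BifurcationTree(
        core_marker=core_marker,
        core_allele=core_allele,
        direction=direction,
        root=root,
        markers=[panel.markers[i] for i in flanks],
    )
    frontier: list[tuple[BifurcationNode, np.ndarray]] = (
        [(root, carriers)] if carriers.size else []
    )
    for depth, m in enumerate(flanks, start=1):
        nxt: list[tuple[BifurcationNode, np.ndarray]] = []
        dropped = 0
        for node, rows in frontier:
            alleles = panel.data[rows, m]
            ok = alleles != MISSING_ALLELE
            dropped += int((~ok).sum())
            for a in (0, 1):
                sub = rows[(alleles == a)]
                if sub.size:
                    child = BifurcationNode(a, depth, int(sub.size))
                    node.children[a] = child
                    nxt.append((child, sub))
        # one entry per depth even when no haplotypes remain, so the
        # depth-wise count-conservation invariant can always be checked
        tree.dropped_per_depth.append(dropped)
        frontier = nxt
    return tree


def ehh(
    panel: HaplotypePanel,
    core_marker: str,
    core_allele: int,
    depth: int,
    direction: str = "distal",
) -> float:
    """EHH(d) = sum_h C(n_h, 2) / C(n_core, 2) over distinct extensions h.

    Computed directly from haplotype strings: carriers of the core allele
    are grouped by their alleles at the first ``depth`` flanking markers
    (carriers with missing alleles within that range are dropped from the
    numerator).  EHH(0) = 1 and EHH is non-increasing in depth.
    """
    if not panel.phased:
        raise ValueError("EHH requires a phased panel")
    core_idx = panel.marker_index(core_marker)
    flanks = _flank_indices(panel, core_idx, direction)[:depth]
    if len(flanks) < depth:
        raise ValueError(f"only {len(flanks)} markers available {direction} of core")
    carriers = panel.data[panel.data[:, core_idx] == core_allele]
    n_core = carriers.shape[0]
    if n_core < 2:
        raise ValueError("EHH undefined with fewer than 2 core-allele carriers")
    if depth == 0:
        return 1.0
    ext = carriers[:, flanks]
    ok = np.all(ext != MISSING_ALLELE, axis=1)
    groups: dict[tuple, int] = {}
    for row in ext[ok]:
        key = tuple(int(x) for x in row)
        groups[key] = groups.get(key, 0) + 1
    num = sum(math.comb(c, 2) for c in groups.values())
    return num / math.comb(n_core, 2)


def ehh_from_tree(tree: BifurcationTree, depth: int) -> float:
    """EHH(d) read off the tree: branch counts at depth d are the extension
    group sizes."""
    n_core = tree.root_count
    if n_core < 2:
        raise ValueError("EHH undefined with fewer than 2 core-allele carriers")
    if depth == 0:
        return 1.0
    nodes = tree.nodes_at_depth(depth)
    return sum(math.comb(n.count, 2) for n in nodes) / math.comb(n_core, 2)


def _node_to_dict(node: BifurcationNode) -> dict:
    return {
        "allele": node.allele,
        "depth": node.depth,
        "count": node.count,
        "children": [_node_to_dict(c) for _, c in sorted(node.children.items())],
    }


def _node_from_dict(d: dict) -> BifurcationNode:
    node = BifurcationNode(
        allele=d["allele"], depth=d["depth"], count=d["count"]
    )
    for cd in d["children"]:
        node.children[cd["allele"]] = _node_from_dict(cd)
    return node


def serialize_tree(tree: BifurcationTree) -> str:
    """Lossless JSON serialization (counts included for width rendering)."""
    return json.dumps(
        {
            "core_marker": tree.core_marker,
            "core_allele": tree.core_allele,
            "direction": tree.direction,
            "markers": tree.markers,
            "dropped_per_depth": tree.dropped_per_depth,
            "root": _node_to_dict(tree.root),
        },
        indent=2,
    )


def parse_tree(text: str) -> BifurcationTree:
    d = json.loads(text)
    return BifurcationTree(
        core_marker=d["core_marker"],
        core_allele=d["core_allele"],
        direction=d["direction"],
        root=_node_from_dict(d["root"]),
        markers=list(d["markers"]),
        dropped_per_depth=list(d["dropped_per_depth"]),
    )
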