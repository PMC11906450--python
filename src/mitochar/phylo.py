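"""13-PCG supermatrix assembly and desk-scale distance/NJ trees.

The concatenation order of the 13 protein-coding genes follows the
mitogenomics convention nad5, nad4, nad4L, nad6, cox1, nad3, cox2,
cox3, atp6, atp8, nad1, nad2, cytB.  Genes are assumed pre-aligned
(equal length across taxa per gene); alignment itself is out of scope.

Distances: p (mismatch fraction), JC69 and K2P, with pairwise deletion
of sites carrying non-ACGT symbols.  Tree building is classical
neighbor joining with deterministic lexicographic tie-breaking; NJ
exactly recovers any additive (tree-like) distance matrix.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PCG_ORDER",
    "SupermatrixRow",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "concatenate_pcgs",
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "write_newick",
    "parse_newick",
]

logger = logging.getLogger(__name__)

#: Standard concatenation order of the 13 mitochondrial PCGs.
PCG_ORDER = (
    "nad5", "nad4", "nad4L", "nad6", "cox1", "nad3", "cox2",
    "cox3", "atp6", "atp8", "nad1", "nad2", "cytB",
)

_PURINES = frozenset("AG")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SupermatrixRow:
    taxon_label: str
    sequence: str
    partition_map: tuple[tuple[str, int, int], ...]  # (gene, start, end), 1-based inclusive


def concatenate_pcgs(
    per_taxon_genes: Mapping[str, Mapping[str, str]],
    order: Sequence[str] = PCG_ORDER,
) -> list[SupermatrixRow]:
    """Concatenate per-gene sequences into one supermatrix row per taxon.

    Every taxon must provide every gene in ``order`` and each gene must
    have equal length across taxa (pre-aligned input).
    """
    taxa = sorted(per_taxon_genes)
    if not taxa:
        raise ValueError("no taxa provided")
    for taxon in taxa:
        for gene in order:
            if gene not in per_taxon_genes[taxon]:
                raise ValueError(f"taxon {taxon} missing gene {gene}")
    for gene in order:
        lengths = {len(per_taxon_genes[t][gene]) for t in taxa}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene} has unequal lengths across taxa: {sorted(lengths)}")

    rows = []
    for taxon in taxa:
        parts = []
        partition = []
        offset = 0
        for gene in order:
            seq = per_taxon_genes[taxon][gene].upper()
            parts.append(seq)
            partition.append((gene, offset + 1, offset + len(seq)))
            offset += len(seq)
        rows.append(
            SupermatrixRow(
                taxon_label=taxon, sequence="".join(parts), partition_map=tuple(partition)
            )
        )
    return rows


def pairwise_distance(a: str, b: str, model: str = "p") -> float:
    """Evolutionary distance between two aligned sequences.

    Sites where either sequence carries a non-ACGT symbol are excluded
    pairwise.  Models: ``p`` (raw mismatch fraction), ``JC69``
    (-(3/4) ln(1 - 4p/3)), ``K2P`` (Kimura two-parameter from the
    transition and transversion proportions).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    a, b = a.upper(), b.upper()
    n = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if (x in _PURINES) == (y in _PURINES):
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    p = (transitions + transversions) / n
    if model == "p":
        return p
    if model == "JC69":
        if p >= 0.75:
            raise ValueError(f"JC69 saturated: p = {p:.4f} >= 3/4")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    if model == "K2P":
        P, Q = transitions / n, transversions / n
        inner1 = 1.0 - 2.0 * P - Q
        inner2 = 1.0 - 2.0 * Q
        if inner1 <= 0 or inner2 <= 0:
            raise ValueError("K2P saturated")
        return -0.5 * math.log(inner1) - 0.25 * math.log(inner2)
    raise ValueError(f"unknown model {model!r}")


@dataclass
class DistanceMatrix:
    """Symmetric distances with labelled taxa and a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def distance_matrix(rows: Sequence[SupermatrixRow], model: str = "p") -> DistanceMatrix:
    """All pairwise distances between supermatrix rows."""
    labels = [r.taxon_label for r in rows]
    k = len(rows)
    m = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        d = pairwise_distance(rows[i].sequence, rows[j].sequence, model=model)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree, stored rooted at an arbitrary internal node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (the tree's additive metric)."""
        labels = sorted(self.leaf_labels())
        idx = {lab: i for i, lab in enumerate(labels)}
        k = len(labels)
        m = np.zeros((k, k))

        def below(node: TreeNode, dist: float) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, dist)]
            out = []
            for child, brlen in node.children:
                out.extend(below(child, dist + brlen))
            return out

        def walk(node: TreeNode) -> None:
            groups = [below(child, brlen) for child, brlen in node.children]
            if node.label is not None and node.is_leaf:
                pass
            for g1, g2 in itertools.combinations(groups, 2):
                for la, da in g1:
                    for lb, db in g2:
                        m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = da + db
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return DistanceMatrix(labels=labels, values=m)


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Classical neighbor joining (Saitou-Nei, Studier-Keppler updates).

    Pair selection minimizes the Q criterion; ties are broken by the
    lexicographically smallest label pair, so the result is fully
    deterministic.  Negative branch-length estimates are clamped to
    zero with a warning.
    """
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in d.labels}
    labels = list(d.labels)
    dist = {
        (a, b): d.values[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i != j
    }

    def get(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.warning("negative branch length %.4g for %s clamped to 0", x, what)
            return 0.0
        return x

    counter = 0
    while len(labels) > 3:
        r = len(labels)
        totals = {a: sum(get(a, b) for b in labels) for a in labels}
        best = None
        for a, b in itertools.combinations(sorted(labels), 2):
            q = (r - 2) * get(a, b) - totals[a] - totals[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, f, g = best
        new_label = f"_nj{counter}"
        counter += 1
        dfg = get(f, g)
        bf = 0.5 * dfg + (totals[f] - totals[g]) / (2.0 * (r - 2))
        bg = dfg - bf
        parent = TreeNode()
        parent.children.append((nodes[f], clamp(bf, f)))
        parent.children.append((nodes[g], clamp(bg, g)))
        nodes[new_label] = parent
        for k in labels:
            if k in (f, g):
                continue
            dk = 0.5 * (get(f, k) + get(g, k) - dfg)
            dist[(new_label, k)] = dist[(k, new_label)] = dk
        labels = [k for k in labels if k not in (f, g)] + [new_label]

    a, b, c = sorted(labels)
    va = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    vb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    vc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    center = TreeNode()
    for lab, v in ((a, va), (b, vb), (c, vc)):
        center.children.append((nodes[lab], clamp(v, lab)))
    return PhyloTree(root=center)


def write_newick(tree: PhyloTree, *, precision: int = 10) -> str:
    """Serialize a tree to a Newick string with branch lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label or ""
        inner = ",".join(f"{fmt(child)}:{brlen:.{precision}g}" for child, brlen in node.children)
        return f"({inner}){node.label or ''}"

    return fmt(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (labels and branch lengths only)."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child, brlen = parse_node()
                node.children.append((child, brlen))
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError("unbalanced parentheses in Newick string")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            node.label = label
        brlen = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            brlen = float(s[start:pos])
        return node, brlen

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError(f"trailing characters in Newick string: {s[pos:]!r}")
    return PhyloTree(root=root)
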