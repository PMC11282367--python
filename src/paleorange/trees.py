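"""Dated rooted trees with node ages in Ma before present.

The package convention throughout: the present is age 0 and ages increase
into the past, so a root age of 105 means the root lineage split 105 Ma.
Branch durations are ``parent age - child age`` and must be strictly
positive.  Version 1 handles extant (contemporaneous) tips only: every tip
sits at age 0 and trees are ultrametric.
"""

from __future__ import annotations

import io
import re

import dendropy
import numpy as np

__all__ = ["TimeTree", "read_tree", "write_tree"]

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Whitespace in taxon labels is normalized to underscores on read."""
    return _WS.sub("_", label.strip())


class TimeTree:
    """A rooted, dated tree stored as flat parent/children/age arrays.

    Nodes are integer indices ``0 .. n_nodes-1``; the root has parent -1.
    Tips carry taxon labels; internal labels are optional and unused as
    join keys.  Ages are in Ma before present.
    """

    def __init__(self, parent, children, ages, labels, validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [list(c) for c in children]
        self.ages = np.asarray(ages, dtype=float)
        self.labels = list(labels)
        self._postorder = None
        self._preorder = None
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, ultrametric: bool = True,
                      tol: float = 1e-6) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        depth = np.zeros(n)
        labels: list[str | None] = [None] * n
        for nd in nodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                labels[i] = normalize_label(nd.taxon.label)
            elif nd.label:
                labels[i] = normalize_label(nd.label)
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                bl = nd.edge.length
                if bl is None:
                    raise ValueError(f"missing branch length above node {labels[i]!r}")
                if bl < 0:
                    raise ValueError(f"negative branch length {bl} above node {labels[i]!r}")
                depth[i] = depth[p] + bl
        tips = [i for i in range(n) if not children[i]]
        root_age = float(depth[tips].max()) if tips else 0.0
        ages = root_age - depth
        if ultrametric:
            scale = max(root_age, 1.0)
            bad = [labels[i] for i in tips if abs(ages[i]) > tol * scale]
            if bad:
                raise ValueError(f"non-ultrametric tips (ages != 0): {bad}")
            ages[tips] = 0.0
        return cls(parent, children, ages, labels)

    @classmethod
    def from_newick(cls, text: str, ultrametric: bool = True,
                    tol: float = 1e-6) -> "TimeTree":
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
        dtree = dendropy.Tree.get(data=text, schema=schema, preserve_underscores=True)
        return cls.from_dendropy(dtree, ultrametric=ultrametric, tol=tol)

    # -- basic structure --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips()]

    def tip_index(self) -> dict:
        return {self.labels[i]: i for i in self.tips()}

    def _invalidate(self) -> None:
        self._postorder = None
        self._preorder = None

    def postorder(self) -> list[int]:
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            order.reverse()
            self._postorder = order
        return self._postorder

    def preorder(self) -> list[int]:
        if self._preorder is None:
            self._preorder = list(reversed(self.postorder()))
        return self._preorder

    def branches(self):
        """Yield ``(node, parent_age, node_age)`` for every non-root node."""
        for v in self.postorder():
            p = self.parent[v]
            if p >= 0:
                yield v, float(self.ages[p]), float(self.ages[v])

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        if p < 0:
            return 0.0
        return float(self.ages[p] - self.ages[v])

    # -- validation and identity ------------------------------------------

    def validate(self) -> None:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.ages < 0):
            raise ValueError("negative node age")
        for v, pa, na in self.branches():
            if pa - na <= 0:
                raise ValueError(
                    f"non-positive branch duration at node {v} "
                    f"(parent age {pa}, node age {na})")
        for t in self.tips():
            if self.labels[t] is None:
                raise ValueError(f"unlabeled tip at index {t}")
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return all(abs(self.ages[t]) <= tol for t in self.tips())

    def clades(self) -> dict:
        """Map each node index to the frozenset of tip labels below it."""
        out: dict[int, frozenset] = {}
        for v in self.postorder():
            if not self.children[v]:
                out[v] = frozenset([self.labels[v]])
            else:
                s: frozenset = frozenset()
                for c in self.children[v]:
                    s = s | out[c]
                out[v] = s
        return out

    def topology_key(self) -> frozenset:
        """Label-based topology identifier (invariant to rotation)."""
        return frozenset(s for s in self.clades().values() if len(s) > 1)

    def is_monophyletic(self, labels) -> bool:
        target = frozenset(labels)
        return target in set(self.clades().values())

    def mrca(self, labels) -> int:
        target = frozenset(labels)
        best, best_size = self.root, self.n_nodes + 1
        for v, s in self.clades().items():
            if target <= s and len(s) < best_size:
                best, best_size = v, len(s)
        return best

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), [list(c) for c in self.children],
                        self.ages.copy(), list(self.labels), validate=False)

    # -- writing -----------------------------------------------------------

    def newick(self, precision: int = 15) -> str:
        fmt = f"%.{precision}g"

        def rec(v: int) -> str:
            if not self.children[v]:
                body = self.labels[v]
            else:
                body = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            p = self.parent[v]
            if p < 0:
                return body  # no root stem emitted
            return body + ":" + (fmt % (self.ages[p] - self.ages[v]))

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (f"TimeTree(n_tips={self.n_tips}, "
                f"root_age={self.root_age:.4g})")


def read_tree(text: str, ultrametric: bool = True, tol: float = 1e-6) -> TimeTree:
    """Parse a newick (or NEXUS-wrapped) tree with branch lengths in Myr.

    Node ages are computed from branch lengths with extant tips anchored
    at age 0.  ``ultrametric=True`` (the default) rejects trees whose tips
    are not contemporaneous within ``tol`` relative to the root age.
    """
    return TimeTree.from_newick(text, ultrametric=ultrametric, tol=tol)


def write_tree(tree: TimeTree, path=None, precision: int = 15) -> str:
    """Serialize a TimeTree as newick with branch lengths = age differences."""
    text = tree.newick(precision=precision)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
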