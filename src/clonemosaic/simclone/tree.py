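"""Clone phylogeny container and the default study-shaped lineage.

The default tree mirrors the anatomy of a long-term clonal collection: a
single zygote-derived founder, two independently grown field trees, four
shoot cultures introduced from the tree at different dates, and twelve
somatic embryo subpopulations derived from one embryogenic founder and
multiplied in culture. Branch durations are in years; each branch carries
its own per-bp-per-year mutation rate, so the embryo epoch can run at the
strongly elevated rate tissue culture induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GROUPS = ("embryo", "shoot", "tree")

# Default per-bp-per-year rates. The embryo:tree ratio is 35x, matching the
# scale of mutation enrichment seen in somatic embryo cultures; shoots run
# 10x the tree rate. Absolute values are inflated relative to real plant
# genomes so that desk-scale (100 kb) chromosomes accumulate counts with the
# same magnitudes the full-genome study works with.
RATE_TREE = 3.5714285714285714e-07
RATE_SHOOT = 10 * RATE_TREE
RATE_EMBRYO = 35 * RATE_TREE


@dataclass
class Branch:
    parent: str
    child: str
    years: float
    rate: float  # mutations per bp per year

    def __post_init__(self):
        if self.years < 0 or self.rate < 0:
            raise ValueError(f"branch {self.parent}->{self.child}: negative duration or rate")


@dataclass
class CloneTree:
    """Rooted clone genealogy; leaves carry a propagation-group label."""

    root: str
    branches: list[Branch]
    groups: dict[str, str] = field(default_factory=dict)  # leaf -> embryo|shoot|tree

    def __post_init__(self):
        children = [b.child for b in self.branches]
        if len(set(children)) != len(children):
            raise ValueError("a node has two parent branches")
        parents = {b.child: b.parent for b in self.branches}
        if self.root in parents:
            raise ValueError("root has a parent")
        for leaf in self.leaves():
            if leaf not in self.groups:
                raise ValueError(f"leaf {leaf} has no group label")
        for leaf, grp in self.groups.items():
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r} for {leaf}")

    def children(self, node: str) -> list[str]:
        return [b.child for b in self.branches if b.parent == node]

    def leaves(self) -> list[str]:
        kids = {b.parent for b in self.branches}
        return [b.child for b in self.branches if b.child not in kids]

    def branch_to(self, child: str) -> Branch:
        for b in self.branches:
            if b.child == child:
                return b
        raise KeyError(child)

    def path(self, leaf: str) -> list[Branch]:
        """Branches from the root down to ``leaf`` (root-most first)."""
        out = []
        node = leaf
        parents = {b.child: b for b in self.branches}
        while node in parents:
            out.append(parents[node])
            node = parents[node].parent
        if node != self.root:
            raise ValueError(f"{leaf} does not descend from the root")
        return list(reversed(out))

    def preorder_branches(self) -> list[Branch]:
        out = []

        def walk(node):
            for b in self.branches:
                if b.parent == node:
                    out.append(b)
                    walk(b.child)

        walk(self.root)
        return out

    def clade(self, node: str) -> frozenset[str]:
        """Leaf set descending from ``node`` (the node itself if a leaf)."""
        kids = self.children(node)
        if not kids:
            return frozenset([node])
        out: set[str] = set()
        for k in kids:
            out |= self.clade(k)
        return frozenset(out)

    def internal_nodes(self) -> list[str]:
        return sorted({b.parent for b in self.branches})

    def to_phylo_clade(self):
        """The truth topology as a :class:`clonemosaic.phylo.Clade`."""
        from ..phylo import Clade

        def build(node: str) -> Clade:
            kids = self.children(node)
            if not kids:
                return Clade(name=node)
            return Clade(children=[build(k) for k in kids])

        return build(self.root)


def default_tree(
    rate_embryo: float = RATE_EMBRYO,
    rate_shoot: float = RATE_SHOOT,
    rate_tree: float = RATE_TREE,
) -> CloneTree:
    """The default 12-embryo / 4-shoot / 2-tree cohort.

    Embryos: founder branch Z->Eanc (20 y, pre-culture rate), then a nested
    clade structure inside the 30-year culture epoch. Shoots and trees attach
    to the root as independent propagations (star-like), so no de novo
    mutation is shared within or across those groups in truth.
    """
    b = []
    add = lambda p, c, y, r: b.append(Branch(p, c, y, r))
    add("Z", "T1", 50, rate_tree)
    add("Z", "T2", 50, rate_tree)
    add("Z", "S1985", 40, rate_shoot)
    add("Z", "S2010", 15, rate_shoot)
    add("Z", "S2013", 12, rate_shoot)
    add("Z", "S2022", 3, rate_shoot)
    # Embryo lineage: 20 pre-culture years at the tree rate (Z -> Epre),
    # then a long shared culture epoch in the founder line (Epre -> Eanc)
    # before the subpopulations diverge. The long shared embryo branch
    # keeps within-embryo distances below embryo-to-outgroup distances, so
    # the rooted average-linkage clustering the pipeline uses can recover
    # the clades despite the strong embryo/tree rate contrast.
    add("Z", "Epre", 20, rate_tree)
    add("Epre", "Eanc", 18, rate_embryo)
    add("Eanc", "EcA", 4, rate_embryo)
    add("Eanc", "EcB", 4, rate_embryo)
    add("EcA", "EcA1", 3, rate_embryo)
    add("EcA", "EcA2", 3, rate_embryo)
    add("EcB", "EcB1", 3, rate_embryo)
    add("EcB", "EcB2", 3, rate_embryo)
    for leaf in ("E1", "E2", "E3"):
        add("EcA1", leaf, 5, rate_embryo)
    add("EcA2", "E4", 5, rate_embryo)
    add("EcA2", "EcA2b", 2, rate_embryo)
    add("EcA2b", "E5", 3, rate_embryo)
    add("EcA2b", "E6", 3, rate_embryo)
    for leaf in ("E7", "E8", "E9"):
        add("EcB1", leaf, 5, rate_embryo)
    for leaf in ("E10", "E11", "E12"):
        add("EcB2", leaf, 5, rate_embryo)
    groups = {f"E{i}": "embryo" for i in range(1, 13)}
    groups |= {s: "shoot" for s in ("S1985", "S2010", "S2013", "S2022")}
    groups |= {"T1": "tree", "T2": "tree"}
    return CloneTree(root="Z", branches=b, groups=groups)
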