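"""Somatic-mutation phylogeny: presence/absence -> JC69 -> UPGMA.

The tree is built from the binary de novo mutation matrix (samples x
filtered de novo sites). Pairwise discordance p (fraction of columns where
two samples differ, absence counted as state 0 over the union of de novo
sites) is converted to a JC69 distance d = -(3/4) ln(1 - 4p/3); clustering
is UPGMA (size-weighted average linkage), which yields a rooted ultrametric
topology. Node supports come from column bootstrap; final branch lengths
are the counts of mutations *unique* to each branch's clade (columns whose
carrier set equals the clade exactly), with non-matching columns reported
as homoplasy.

Saturation (p >= 3/4) raises rather than clamps: a clamped distance would
silently corrupt the topology. UPGMA ties merge the lexicographically
smallest cluster pair, so output is invariant to taxon input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SaturationError(ValueError):
    """Discordance at or beyond the JC69 singularity p = 3/4."""


@dataclass
class Clade:
    """A rooted (sub)tree; ``height`` is the UPGMA merge height."""

    children: list["Clade"] = field(default_factory=list)
    name: str | None = None
    height: float = 0.0
    support: float | None = None
    length: float | None = None  # unique-mutation count, once assigned

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset([self.name])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return frozenset(out)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes except trivial singletons."""
        return [n.leaves() for n in self.walk() if not n.is_leaf()]

    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Clade) -> str:
            if node.is_leaf():
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in sorted(node.children, key=lambda c: min(c.leaves())))
                sup = ""
                if supports and node.support is not None:
                    sup = f"{node.support:g}"
                label = f"({inner}){sup}"
            if lengths and node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self) + ";"


# ---------------------------------------------------------------------------


def mutation_matrix(de_novo: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Binary samples x sites matrix from classified de novo calls.

    Columns are the de novo site keys; entry 1 means the sample is a
    carrier. All-zero columns cannot occur (every site has >=1 carrier).
    """
    cols = {}
    for r in de_novo.itertuples():
        key = f"{r.chrom}:{r.pos}:{r.ref}>{r.alt}"
        cols[key] = np.array([1 if s in r.carriers else 0 for s in samples], dtype=np.int8)
    if not cols:
        return pd.DataFrame(index=pd.Index(samples, name="sample"))
    return pd.DataFrame(cols, index=pd.Index(samples, name="sample"))


def discordance(matrix: pd.DataFrame, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise fraction of discordant columns (optionally column-weighted)."""
    X = matrix.to_numpy(dtype=float)
    n, S = X.shape
    if S == 0:
        raise ValueError("mutation matrix has no columns")
    w = np.ones(S) if weights is None else np.asarray(weights, dtype=float)
    r = X @ w
    G = (X * w) @ X.T
    mism = r[:, None] + r[None, :] - 2 * G
    p = mism / w.sum()
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=matrix.index, columns=matrix.index)


def jc69_distance(matrix: pd.DataFrame, weights: np.ndarray | None = None) -> pd.DataFrame:
    """JC69 distance d = -(3/4) ln(1 - 4p/3) from pairwise discordance."""
    p = discordance(matrix, weights)
    pv = p.to_numpy()
    if (pv >= 0.75).any():
        i, j = np.argwhere(pv >= 0.75)[0]
        raise SaturationError(
            f"discordance {pv[i, j]:.4f} between {p.index[i]} and {p.index[j]} is at/beyond the JC69 limit 3/4"
        )
    d = -0.75 * np.log1p(-4.0 * pv / 3.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=p.index, columns=p.columns)


def upgma(dist: pd.DataFrame) -> Clade:
    """Size-weighted (classic) UPGMA agglomeration.

    Among equal minimal distances, the pair whose (sorted) cluster labels
    are lexicographically smallest merges first; a cluster's label is its
    smallest leaf name.
    """
    if len(dist) < 2:
        raise ValueError("need >= 2 taxa")
    D = dist.to_numpy(dtype=float).copy()
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    nodes = [Clade(name=str(s)) for s in dist.index]
    labels = [str(s) for s in dist.index]
    sizes = [1] * len(nodes)
    active = list(range(len(nodes)))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = tuple(sorted((labels[i], labels[j])))
                cand = (D[i, j], key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dmin, _, i, j = best
        new = Clade(children=[nodes[i], nodes[j]], height=dmin / 2.0)
        ni, nj = sizes[i], sizes[j]
        # size-weighted average linkage update, stored in slot i
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (ni * D[i, k] + nj * D[j, k]) / (ni + nj)
        nodes[i] = new
        labels[i] = min(labels[i], labels[j])
        sizes[i] = ni + nj
        active.remove(j)
    root = nodes[active[0]]
    # ultrametric branch "heights" are informational; mutation-count lengths
    # are assigned separately by branch_lengths_from_unique
    return root


def build_tree(matrix: pd.DataFrame) -> Clade:
    return upgma(jc69_distance(matrix))


def bootstrap_support(matrix: pd.DataFrame, B: int = 1000, seed=0, tree: Clade | None = None) -> Clade:
    """Column bootstrap: resample S columns with replacement B times, rebuild
    the tree, and score each original internal bipartition by the fraction
    of replicate trees containing it. Annotates and returns the tree."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = build_tree(matrix)
    S = matrix.shape[1]
    counts: dict[frozenset, int] = {c: 0 for c in tree.clades()}
    for _ in range(B):
        w = rng.multinomial(S, np.full(S, 1.0 / S)).astype(float)
        try:
            rep = upgma(jc69_distance(matrix, weights=w))
        except SaturationError:
            continue
        rep_clades = set(rep.clades())
        for c in counts:
            if c in rep_clades:
                counts[c] += 1
    for node in tree.walk():
        if not node.is_leaf():
            node.support = counts[node.leaves()] / B
    return tree


def branch_lengths_from_unique(matrix: pd.DataFrame, tree: Clade) -> tuple[Clade, int]:
    """Set each branch's length to the count of columns whose carrier set
    equals exactly that branch's clade; returns (tree, homoplasy count).

    Columns matching no clade (including no leaf) are homoplasy: under a
    perfect infinite-sites history every column is unique to one branch and
    the branch counts partition the columns.
    """
    leaves = set(tree.leaves())
    if not set(matrix.index) >= leaves:
        raise ValueError("tree leaves missing from matrix")
    X = matrix.loc[sorted(leaves)].to_numpy(dtype=np.int8)
    sample_order = sorted(leaves)
    carrier_sets: dict[frozenset, int] = {}
    for j in range(X.shape[1]):
        cs = frozenset(sample_order[i] for i in np.nonzero(X[:, j])[0])
        carrier_sets[cs] = carrier_sets.get(cs, 0) + 1
    matched = 0
    for node in tree.walk():
        cl = node.leaves()
        node.length = carrier_sets.get(cl, 0)
        matched += node.length
    # root clade equals the full leaf set; columns carried by everyone would
    # land there, which a filtered de novo matrix should not contain
    homoplasy = matrix.shape[1] - matched
    return tree, homoplasy


def write_distance_tsv(dist: pd.DataFrame, path: str):
    dist.to_csv(path, sep="\t", float_format="%.6f")
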