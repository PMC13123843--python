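"""Evolve a clone phylogeny over a simulated genome, retaining ground truth.

Mutations accumulate on each branch as Poisson(rate x diploid bp x years),
placed uniformly on mappable positions under an infinite-sites rule.
Chromosome-scale instability events (trisomy, loss of trisomy, segmental
deletion, copy-neutral recombination) and TE insertions are applied in
branch order and inherited by all descendants. Mutations occurring after a
trisomy on the duplicated haplotype are assigned to exactly one of its two
copies, so a later loss of that trisomy removes the mutations riding on the
lost copy -- the signal the trisomy-dating and loss-detection analyses
exploit.

Cell fractions: mutations on internal branches are fixed (fraction 1.0) in
all descendant clones. Private (terminal-branch) mutations follow the
clone's developmental layer model: somatic embryos fix most of their recent
mutations through single-cell budding (point mass at 1.0 plus a sub-fixed
tail), while shoots and trees keep layer-restricted mutations at the L1 or
L2-L3 cell fraction, producing the bimodal pattern bulk sequencing shows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .._util import idx_to_str, revcomp, rng_from
from .genome import GenomeParams, SimGenome, build_genome, trimer_context
from .tree import CloneTree

FEATURE_CATEGORIES = (
    "gene",
    "exon",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "upstream",
    "downstream",
    "intergenic",
)


class ConfigurationError(ValueError):
    """A simulation spec refers to something the genome/tree does not have."""


@dataclass
class InstabilityEventSpec:
    """One instability event, anchored to the branch ending at ``branch``.

    ``time_fraction`` places the event within the branch (0 = at the parent
    node, 1 = at the child node) relative to that branch's mutations.
    For ``copy_neutral_recombination``, ``haplotype`` names the *lost*
    haplotype distal to ``breakpoint``; for ``loss_of_trisomy``,
    ``lost_copy`` may pin which duplicated copy is removed (default random).
    """

    branch: str
    kind: str  # trisomy | loss_of_trisomy | segmental_deletion | copy_neutral_recombination
    chrom: str
    haplotype: str
    interval: tuple[int, int] | None = None
    breakpoint: int | None = None
    time_fraction: float = 0.5
    lost_copy: int | None = None


@dataclass
class TESpec:
    """Transposition process: per-branch rates, donor mix, placement bias.

    ``rates_per_year`` maps branch child names to TE insertions per year
    (absent branches are silent). ``placement_bias`` maps a donor length
    class to per-feature-category weights; a position's weight is the
    product over the categories containing it (default 1), so an empty dict
    is the uniform null. TSD lengths are drawn uniformly from
    ``tsd_range`` (inclusive), centred on the ~10 bp seen at real
    insertions.
    """

    rates_per_year: dict[str, float] = field(default_factory=dict)
    donor_weights: dict[str, float] = field(default_factory=dict)
    placement_bias: dict[str, dict[str, float]] = field(default_factory=dict)
    tsd_range: tuple[int, int] = (8, 12)


@dataclass
class LayerSpec:
    """Cell-fraction model for private (terminal-branch) mutations."""

    embryo_fixed_weight: float = 0.75
    embryo_unfixed_range: tuple[float, float] = (0.2, 0.8)
    l1_fraction: float = 0.2
    l1_weight: float = 0.35

    def layer_model(self, group: str) -> dict[str, float]:
        if group == "embryo":
            return {"fixed": 1.0}
        return {"L1": self.l1_fraction, "L2": 1.0 - self.l1_fraction}

    def draw_fraction(self, group: str, rng: np.random.Generator) -> float:
        if group == "embryo":
            if rng.random() < self.embryo_fixed_weight:
                return 1.0
            lo, hi = self.embryo_unfixed_range
            return float(rng.uniform(lo, hi))
        return self.l1_fraction if rng.random() < self.l1_weight else 1.0 - self.l1_fraction


def default_instability_spec(
    n_chromosomes: int = 4, chromosome_length: int = 100_000
) -> list[InstabilityEventSpec]:
    """Cohort-wide embryo instability, fixed at the start of the embryo
    pre-culture branch.

    All events sit at time_fraction 0 of the Z->Epre branch, so every embryo
    inherits a chr2 haplotype-B trisomy, a mid-chr3 haplotype-A segmental
    deletion and a copy-neutral recombination replacing distal chr4-B with
    chr4-A, while chr1 stays diploid; no shoot or tree is affected. Placing
    the events before any embryo-lineage mutation mirrors a duplication
    arising at (or before) culture initiation: essentially no shared
    mutation predates it.
    """
    L = chromosome_length
    events = [
        InstabilityEventSpec("Epre", "trisomy", "chr2", "B", time_fraction=0.0),
        InstabilityEventSpec(
            "Epre", "segmental_deletion", "chr3", "A",
            interval=(int(L * 0.3) + 1, int(L * 0.7)), time_fraction=0.0,
        ),
        InstabilityEventSpec(
            "Epre", "copy_neutral_recombination", "chr4", "B",
            breakpoint=int(L * 0.5) + 1, time_fraction=0.0,
        ),
    ]
    have = {f"chr{i + 1}" for i in range(n_chromosomes)}
    return [e for e in events if e.chrom in have]


def default_te_spec(tree: CloneTree | None = None) -> TESpec:
    """TE activity confined to the embryo culture epoch, with the
    qualitative placement biases real 900/5500-class elements show."""
    rates = {}
    if tree is not None:
        for b in tree.branches:
            desc = tree.clade(b.child)
            if all(tree.groups.get(leaf) == "embryo" for leaf in desc):
                rates[b.child] = 0.4
    return TESpec(
        rates_per_year=rates,
        donor_weights={"TE900": 0.25, "TE5500a": 0.375, "TE5500b": 0.375},
        placement_bias={
            "class_900": {"upstream": 3.0, "downstream": 3.0, "gene": 0.5},
            "class_5500": {"gene": 2.0, "exon": 2.0, "downstream": 2.0, "intergenic": 0.5},
        },
    )


def default_layer_spec() -> LayerSpec:
    return LayerSpec()


# ---------------------------------------------------------------------------
# resolved events and copy-number bookkeeping


@dataclass
class ResolvedEvent:
    spec: InstabilityEventSpec
    depth: int  # index of the carrying branch within its own root path
    lost_copy: int | None = None  # resolved for loss_of_trisomy

    @property
    def key(self) -> tuple[int, float]:
        return (self.depth, self.spec.time_fraction)


def _feature_membership(genome: SimGenome) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome boolean membership arrays (index 0 = position 1)."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, L in genome.chromosomes:
        m = {cat: np.zeros(L, dtype=bool) for cat in FEATURE_CATEGORIES}
        out[chrom] = m
    for g in genome.genes:
        m = out[g.chrom]
        m["gene"][g.start - 1 : g.end] = True
        for s, e in g.exons:
            m["exon"][s - 1 : e] = True
        for utr, cat in ((g.five_prime_utr, "five_prime_UTR"), (g.three_prime_utr, "three_prime_UTR")):
            if utr:
                m[cat][utr[0] - 1 : utr[1]] = True
        L = genome.length(g.chrom)
        if g.strand == "+":
            up = (max(1, g.start - 1000), g.start - 1)
            down = (g.end + 1, min(L, g.end + 1000))
        else:
            up = (g.end + 1, min(L, g.end + 1000))
            down = (max(1, g.start - 1000), g.start - 1)
        for (s, e), cat in ((up, "upstream"), (down, "downstream")):
            if s <= e:
                m[cat][s - 1 : e] = True
    for chrom in out:
        m = out[chrom]
        m["intron"] = m["gene"] & ~m["exon"]
        m["intergenic"] = ~(m["gene"] | m["upstream"] | m["downstream"])
    return out


@dataclass
class LineageTruth:
    """Ground truth of a simulated lineage.

    ``mutations`` has one row per de novo small variant with its branch of
    origin, haplotype, position, trimer context, duplicated-copy assignment
    (0 = predates any trisomy of its haplotype, else copy 1 or 2) and the
    cell fraction it reaches in carrying clones. ``te_events`` mirrors this
    for TE insertions. ``events`` are the resolved instability events in
    path order.
    """

    tree: CloneTree
    genome: SimGenome
    mutations: pd.DataFrame
    te_events: pd.DataFrame
    events: list[ResolvedEvent]
    layer_model: dict[str, dict[str, float]]

    # -- event/path helpers -------------------------------------------------

    def path_events(self, leaf_or_node: str) -> list[ResolvedEvent]:
        path_children = [b.child for b in self.tree.path(leaf_or_node)]
        evs = [e for e in self.events if e.spec.branch in path_children]
        # depth recorded is within the event's own path == index in any
        # descendant's path, so sorting by key orders them along this path
        return sorted(evs, key=lambda e: e.key)

    def copy_number(self, leaf: str, chrom: str, pos) -> tuple[np.ndarray, np.ndarray]:
        """(haplotype A copies, haplotype B copies) at ``pos`` for ``leaf``."""
        pos = np.atleast_1d(np.asarray(pos))
        n = {"A": np.ones(pos.size, dtype=np.int64), "B": np.ones(pos.size, dtype=np.int64)}
        for ev in self.path_events(leaf):
            s = ev.spec
            if s.chrom != chrom:
                continue
            if s.kind == "trisomy":
                n[s.haplotype][:] = 2
            elif s.kind == "loss_of_trisomy":
                n[s.haplotype][:] = 1
            elif s.kind == "segmental_deletion":
                lo, hi = s.interval
                sel = (pos >= lo) & (pos <= hi)
                n[s.haplotype][sel] = np.maximum(n[s.haplotype][sel] - 1, 0)
            elif s.kind == "copy_neutral_recombination":
                sel = pos >= s.breakpoint
                other = "B" if s.haplotype == "A" else "A"
                n[s.haplotype][sel] = 0
                n[other][sel] = 2 * n[other][sel]
        return n["A"], n["B"]

    def _carrying(self, mut, events_after: list[ResolvedEvent]) -> int:
        """Copies of the mutated haplotype carrying ``mut`` after ``events_after``."""
        carrying = 1
        for ev in events_after:
            s = ev.spec
            if s.chrom != mut.chrom:
                continue
            if s.kind == "trisomy" and s.haplotype == mut.haplotype and mut.dup_copy == 0:
                carrying = 2 * carrying
            elif s.kind == "loss_of_trisomy" and s.haplotype == mut.haplotype:
                if mut.dup_copy == 0:
                    carrying = max(carrying - 1, 0) if carrying > 1 else carrying
                elif mut.dup_copy == ev.lost_copy:
                    carrying = 0
            elif s.kind == "segmental_deletion" and s.haplotype == mut.haplotype:
                lo, hi = s.interval
                if lo <= mut.pos <= hi:
                    carrying = max(carrying - 1, 0)
            elif s.kind == "copy_neutral_recombination" and mut.pos >= s.breakpoint:
                if s.haplotype == mut.haplotype:
                    carrying = 0
                else:
                    carrying = 2 * carrying
        return carrying

    def leaf_mutations(self, leaf: str) -> pd.DataFrame:
        """Mutations present in ``leaf`` with carrying/total copy counts.

        Columns add ``carrying`` (copies of the site bearing the alt allele)
        and ``copies`` (total copies across both haplotypes at the site).
        """
        path = self.tree.path(leaf)
        depth_of = {b.child: i for i, b in enumerate(path)}
        evs = self.path_events(leaf)
        rows = []
        for mut in self.mutations.itertuples():
            d = depth_of.get(mut.branch)
            if d is None:
                continue
            after = [e for e in evs if e.key > (d, mut.time_u)]
            carrying = self._carrying(mut, after)
            if carrying <= 0:
                continue
            rows.append((mut.Index, carrying))
        if not rows:
            df = self.mutations.iloc[[]].copy()
            df["carrying"] = np.array([], dtype=int)
            df["copies"] = np.array([], dtype=int)
            return df
        idx, carry = zip(*rows)
        df = self.mutations.loc[list(idx)].copy()
        df["carrying"] = list(carry)
        copies = np.empty(len(df), dtype=np.int64)
        for chrom in df["chrom"].unique():
            sel = df["chrom"] == chrom
            na, nb = self.copy_number(leaf, chrom, df.loc[sel, "pos"].to_numpy())
            copies[sel.to_numpy()] = na + nb
        df["copies"] = copies
        return df

    def leaf_te_events(self, leaf: str) -> pd.DataFrame:
        path_children = {b.child for b in self.tree.path(leaf)}
        return self.te_events[self.te_events["branch"].isin(path_children)].copy()

    def branch_counts(self) -> pd.Series:
        """Truth number of small variants deposited on each branch."""
        counts = self.mutations.groupby("branch").size()
        return counts.reindex([b.child for b in self.tree.branches], fill_value=0)

    def carriers(self, mut_index) -> frozenset[str]:
        """Leaves in which a truth mutation survives (loss-aware)."""
        mut = self.mutations.loc[mut_index]
        out = []
        for leaf in self.tree.clade(mut["branch"]):
            path = self.tree.path(leaf)
            depth_of = {b.child: i for i, b in enumerate(path)}
            after = [e for e in self.path_events(leaf) if e.key > (depth_of[mut["branch"]], mut["time_u"])]
            if self._carrying(mut, after) > 0:
                out.append(leaf)
        return frozenset(out)


# ---------------------------------------------------------------------------


def _copies_before(mut_chrom, mut_hap, pos, events_before: list[ResolvedEvent]) -> int:
    """Copy number of (chrom, hap, pos) just before a prospective mutation."""
    n = 1
    for ev in events_before:
        s = ev.spec
        if s.chrom != mut_chrom:
            continue
        if s.kind == "trisomy" and s.haplotype == mut_hap:
            n = 2
        elif s.kind == "loss_of_trisomy" and s.haplotype == mut_hap:
            n = 1
        elif s.kind == "segmental_deletion" and s.haplotype == mut_hap:
            lo, hi = s.interval
            if lo <= pos <= hi:
                n = max(n - 1, 0)
        elif s.kind == "copy_neutral_recombination" and pos >= s.breakpoint:
            if s.haplotype == mut_hap:
                n = 0
            else:
                n = 2 * n
    return n


def _validate_events(genome: SimGenome, tree: CloneTree, specs: list[InstabilityEventSpec]) -> list[ResolvedEvent]:
    chrom_names = set(genome.chrom_names)
    children = {b.child for b in tree.branches}
    resolved = []
    for s in specs:
        if s.chrom not in chrom_names:
            raise ConfigurationError(f"instability event references absent chromosome {s.chrom}")
        if s.haplotype not in ("A", "B"):
            raise ConfigurationError(f"instability event references absent haplotype {s.haplotype}")
        if s.branch not in children:
            raise ConfigurationError(f"instability event references absent branch {s.branch}")
        if s.kind == "segmental_deletion" and s.interval is None:
            raise ConfigurationError("segmental_deletion needs an interval")
        if s.kind == "copy_neutral_recombination" and s.breakpoint is None:
            raise ConfigurationError("copy_neutral_recombination needs a breakpoint")
        if s.kind not in ("trisomy", "loss_of_trisomy", "segmental_deletion", "copy_neutral_recombination"):
            raise ConfigurationError(f"unknown instability kind {s.kind}")
        resolved.append(ResolvedEvent(spec=s, depth=len(tree.path(s.branch)) - 1))
    # a loss must follow a trisomy of the same chromosome/haplotype on its path
    for ev in resolved:
        if ev.spec.kind != "loss_of_trisomy":
            continue
        path_children = [b.child for b in tree.path(ev.spec.branch)]
        prior = [
            o
            for o in resolved
            if o.spec.kind == "trisomy"
            and o.spec.chrom == ev.spec.chrom
            and o.spec.haplotype == ev.spec.haplotype
            and o.spec.branch in path_children
            and o.key < ev.key
        ]
        if not prior:
            raise ConfigurationError(
                f"loss_of_trisomy on {ev.spec.chrom}{ev.spec.haplotype} has no prior trisomy on its path"
            )
    return resolved


def simulate_lineage(
    genome_params: GenomeParams | SimGenome | None,
    tree: CloneTree,
    instability_spec: list[InstabilityEventSpec] | None = None,
    te_spec: TESpec | None = None,
    layer_spec: LayerSpec | None = None,
    seed=0,
) -> tuple[SimGenome, LineageTruth]:
    """Simulate mutation accumulation over ``tree`` and return genome + truth.

    A single seeded generator drives every draw, in a fixed order: genome
    construction, then per-branch (preorder) mutation counts, placements and
    times, copy assignments, cell fractions, then TE events per branch.
    """
    rng = rng_from(seed)
    if genome_params is None or isinstance(genome_params, GenomeParams):
        genome = build_genome(genome_params, seed=rng)
    else:
        genome = genome_params
    instability_spec = instability_spec if instability_spec is not None else []
    te_spec = te_spec or TESpec()
    layer_spec = layer_spec or LayerSpec()

    events = _validate_events(genome, tree, instability_spec)
    for ev in events:
        if ev.spec.kind == "loss_of_trisomy":
            ev.lost_copy = ev.spec.lost_copy or int(rng.integers(1, 3))

    donors = {d.name: d for d in genome.te_origins}
    for name in te_spec.donor_weights:
        if name not in donors:
            raise ConfigurationError(f"te_spec names absent donor element {name}")
    membership = _feature_membership(genome)

    chrom_names = genome.chrom_names
    lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_probs = lengths / lengths.sum()
    mappable = {c: genome.mappable_positions(c) for c in chrom_names}
    used: set[tuple[str, int]] = set()
    for c in chrom_names:
        for p in genome.het_positions[c]:
            used.add((c, int(p)))

    diploid_bp = genome.diploid_bp()
    leaves = set(tree.leaves())
    path_cache = {b.child: [x.child for x in tree.path(b.child)] for b in tree.branches}

    mut_rows = []
    te_rows = []
    mut_id = 0
    te_id = 0
    for branch in tree.preorder_branches():
        depth = len(path_cache[branch.child]) - 1
        branch_events = sorted(
            (e for e in events if e.spec.branch in path_cache[branch.child]), key=lambda e: e.key
        )
        is_terminal = branch.child in leaves
        group = tree.groups.get(branch.child)

        n_mut = rng.poisson(branch.rate * diploid_bp * branch.years)
        for _ in range(n_mut):
            for _attempt in range(1000):
                chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_probs)]
                hap = "A" if rng.random() < 0.5 else "B"
                pos = int(mappable[chrom][rng.integers(mappable[chrom].size)])
                time_u = float(rng.random())
                before = [e for e in branch_events if e.key <= (depth, time_u)]
                if (chrom, pos) in used or _copies_before(chrom, hap, pos, before) == 0:
                    continue
                break
            else:  # pragma: no cover - only reachable on absurdly full genomes
                raise RuntimeError("could not place mutation (genome saturated)")
            used.add((chrom, pos))
            # copy assignment under an active trisomy of this haplotype
            gains = [
                e
                for e in before
                if e.spec.kind == "trisomy" and e.spec.chrom == chrom and e.spec.haplotype == hap
            ]
            losses = [
                e
                for e in before
                if e.spec.kind == "loss_of_trisomy" and e.spec.chrom == chrom and e.spec.haplotype == hap
            ]
            if gains and not losses:
                dup_copy = int(rng.integers(1, 3))
            elif gains and losses:
                dup_copy = 3 - losses[-1].lost_copy  # the surviving copy
            else:
                dup_copy = 0
            ref = genome.base(chrom, hap, pos)
            if rng.random() < 0.85:  # SBS : InDel mix
                var_class = "SBS"
                alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            else:
                var_class = "InDel"
                k = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    ins = idx_to_str(rng.choice(4, size=k).astype(np.uint8))
                    alt = ref + ins
                else:
                    ref = genome.seq(chrom, hap, pos, min(pos + k, genome.length(chrom)))
                    alt = ref[0]
            frac = layer_spec.draw_fraction(group, rng) if is_terminal else 1.0
            mut_rows.append(
                (
                    mut_id,
                    branch.child,
                    chrom,
                    hap,
                    pos,
                    ref,
                    alt,
                    var_class,
                    trimer_context(genome, chrom, hap, pos),
                    time_u,
                    dup_copy,
                    frac,
                )
            )
            mut_id += 1

        # --- TE events on this branch
        te_rate = te_spec.rates_per_year.get(branch.child, 0.0)
        n_te = rng.poisson(te_rate * branch.years) if te_rate > 0 else 0
        if n_te and not te_spec.donor_weights:
            raise ConfigurationError("TE events requested but donor_weights empty")
        for _ in range(n_te):
            names = sorted(te_spec.donor_weights)
            w = np.array([te_spec.donor_weights[n] for n in names], dtype=float)
            if w.sum() <= 0:
                raise ConfigurationError("TE donor weights sum to 0")
            donor = donors[names[rng.choice(len(names), p=w / w.sum())]]
            bias = te_spec.placement_bias.get(donor.length_class, {})
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_probs)]
            cand = mappable[chrom]
            weights = np.ones(cand.size, dtype=float)
            for cat, wt in bias.items():
                if cat not in FEATURE_CATEGORIES:
                    raise ConfigurationError(f"unknown feature category {cat} in placement bias")
                weights[membership[chrom][cat][cand - 1]] *= wt
            if weights.sum() <= 0:
                raise ConfigurationError("TE placement bias weights sum to 0")
            tsd_lo, tsd_hi = te_spec.tsd_range
            for _attempt in range(1000):
                pos = int(cand[rng.choice(cand.size, p=weights / weights.sum())])
                tsd_len = int(rng.integers(tsd_lo, tsd_hi + 1))
                if pos + tsd_len <= genome.length(chrom) and (chrom, pos) not in used:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not place TE insertion")
            used.add((chrom, pos))
            hap = "A" if rng.random() < 0.5 else "B"
            strand = "+" if rng.random() < 0.5 else "-"
            # the TSD is copied from the insertion site on the target haplotype
            tsd_seq = genome.seq(chrom, hap, pos, pos + tsd_len - 1)
            frac = layer_spec.draw_fraction(group, rng) if is_terminal else 1.0
            te_rows.append(
                (
                    te_id,
                    branch.child,
                    donor.name,
                    donor.length_class,
                    chrom,
                    hap,
                    pos,
                    pos + tsd_len - 1,  # right-aligned VCF anchor position
                    tsd_len,
                    tsd_seq,
                    strand,
                    donor.length,
                    frac,
                )
            )
            te_id += 1

    mutations = pd.DataFrame(
        mut_rows,
        columns=[
            "mut_id",
            "branch",
            "chrom",
            "haplotype",
            "pos",
            "ref",
            "alt",
            "var_class",
            "trimer",
            "time_u",
            "dup_copy",
            "cell_fraction",
        ],
    ).set_index("mut_id")
    te_events = pd.DataFrame(
        te_rows,
        columns=[
            "te_id",
            "branch",
            "donor",
            "length_class",
            "chrom",
            "haplotype",
            "pos",
            "vcf_pos",
            "tsd_len",
            "tsd_seq",
            "strand",
            "length",
            "cell_fraction",
        ],
    ).set_index("te_id")

    layer_model = {leaf: layer_spec.layer_model(tree.groups[leaf]) for leaf in tree.leaves()}
    truth = LineageTruth(
        tree=tree,
        genome=genome,
        mutations=mutations,
        te_events=te_events,
        events=events,
        layer_model=layer_model,
    )
    return genome, truth


def te_insertion_sequence(genome: SimGenome, row) -> str:
    """Inserted ALT sequence (donor body + trailing TSD copy) for a truth TE row."""
    donor = {d.name: d for d in genome.te_origins}[row.donor]
    body = donor.sequence if row.strand == "+" else revcomp(donor.sequence)
    return body + row.tsd_seq


_ = replace  # dataclasses.replace re-exported for config tweaking in tests
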