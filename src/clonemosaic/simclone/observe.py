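"""Render a simulated lineage through a read-depth observation model.

The simulator emits *already-called* variant records (variant calling is
upstream of the pipeline and out of scope), so this module emulates the
output of a sensitive small-variant caller over two reference modes:

``primary``
    calls against the collapsed primary assembly (haplotype A). Reads from
    both haplotypes pile onto one coordinate system, so a mutation in cell
    fraction c on a diploid site has expected allele frequency c/2, and an
    ancestral heterozygous site sits at the haplotype-B copy fraction
    (1/2 diploid, 2/3 under a haplotype-B trisomy, ...).

``concatenated``
    calls against the haplotype-phased assembly where each haplotype is its
    own contig (``chr1_A``, ``chr1_B``...). Ancestral heterozygosity
    vanishes (both alleles are in the reference) and a mutation's allele
    frequency directly estimates the fraction of cells carrying it.

Depths are Poisson with local copy-number scaling; alt-supporting reads are
binomial with per-base error rate epsilon. Both are zero-truncated for
carried mutations: the model emulates a caller's output, and caller
sensitivity is deliberately not a modelled failure mode -- false positives
are, via ``artifact_rate``, which injects low-quality spurious singleton
records that the pipeline's median-quality filters must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import rng_from, zt_binomial, zt_poisson
from .genome import SimGenome
from .lineage import LineageTruth, te_insertion_sequence

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "ref_depth",
    "alt_depth",
    "total_depth",
    "allele_frequency",
    "mappable",
    "variant_class",
    "mut_id",
    "is_artifact",
]


@dataclass
class ObservationModel:
    """Read-depth / quality model shared by both reference modes.

    ``mean_depth`` is the diploid total (reads per site when two copies are
    present); a single haplotype copy therefore draws Poisson(mean_depth/2)
    on its own contig. Quality scores separate true calls (high, Gaussian)
    from artifacts (uniform below 20) so the study's quality filters are
    exercisable. ``epsilon`` is the per-base miscall rate.
    """

    mean_depth: float = 50.0
    epsilon: float = 0.002
    quality_mean: float = 60.0
    quality_sd: float = 8.0
    quality_floor: float = 30.0
    artifact_rate: float = 0.0  # spurious calls per bp per sample
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")


@dataclass
class Observations:
    """Per-clone rendered call sets for one reference mode."""

    mode: str
    variants: dict[str, pd.DataFrame]
    depth_intervals: dict[str, pd.DataFrame]
    phased_sites: dict[str, pd.DataFrame] = field(default_factory=dict)
    sv: dict[str, pd.DataFrame] = field(default_factory=dict)


def _true_qual(rng, n, model):
    q = rng.normal(model.quality_mean, model.quality_sd, size=n)
    return np.clip(q, model.quality_floor, 99.0).round(2)


def _alt_prob(q: np.ndarray, eps: float) -> np.ndarray:
    """True alt-read fraction q adjusted for symmetric miscall rate."""
    return q * (1 - eps) + (1 - q) * eps / 3


def render_observations(
    genome: SimGenome,
    truth: LineageTruth,
    model: ObservationModel,
    reference_mode: str = "primary",
    sv_samples: tuple[str, ...] = (),
    samples: list[str] | None = None,
) -> Observations:
    """Render per-clone variant tables, depth intervals and (primary mode)
    phased ancestral-heterozygosity depths; deterministic under the model seed.

    ``sv_samples`` names the clones for which SV call sets (long-read style)
    are rendered; they receive every carried TE insertion plus the planted
    ancestral insertions shared by all samples.
    """
    if reference_mode not in ("primary", "concatenated"):
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    rng = rng_from(model.seed)
    leaves = truth.tree.leaves() if samples is None else [s for s in truth.tree.leaves() if s in set(samples)]
    occupied = {(c, int(p)) for c in genome.chrom_names for p in genome.het_positions[c]}
    occupied |= {(m.chrom, int(m.pos)) for m in truth.mutations.itertuples()}
    variants: dict[str, pd.DataFrame] = {}
    intervals: dict[str, pd.DataFrame] = {}
    phased: dict[str, pd.DataFrame] = {}
    svs: dict[str, pd.DataFrame] = {}

    for leaf in leaves:
        rows = []
        muts = truth.leaf_mutations(leaf)
        # ---- de novo mutations
        if len(muts):
            c = muts["cell_fraction"].to_numpy()
            carrying = muts["carrying"].to_numpy()
            copies = muts["copies"].to_numpy()
            if reference_mode == "primary":
                depth_mean = model.mean_depth * copies / 2.0
                q = c * carrying / copies
            else:
                hap_copies = np.empty(len(muts), dtype=np.int64)
                for chrom in muts["chrom"].unique():
                    sel = (muts["chrom"] == chrom).to_numpy()
                    na, nb = truth.copy_number(leaf, chrom, muts.loc[muts["chrom"] == chrom, "pos"].to_numpy())
                    hap_sel = muts.loc[muts["chrom"] == chrom, "haplotype"].to_numpy()
                    hap_copies[sel] = np.where(hap_sel == "A", na, nb)
                depth_mean = model.mean_depth / 2.0 * hap_copies
                q = c * carrying / hap_copies
            depth = zt_poisson(rng, depth_mean, (len(muts),))
            alt = zt_binomial(rng, depth, np.clip(_alt_prob(q, model.epsilon), 1e-9, 1.0))
            qual = _true_qual(rng, len(muts), model)
            for i, mut in enumerate(muts.itertuples()):
                chrom = mut.chrom if reference_mode == "primary" else f"{mut.chrom}_{mut.haplotype}"
                rows.append(
                    (
                        chrom,
                        mut.pos,
                        mut.ref,
                        mut.alt,
                        qual[i],
                        int(depth[i] - alt[i]),
                        int(alt[i]),
                        int(depth[i]),
                        alt[i] / depth[i],
                        bool(genome.is_mappable(mut.chrom, mut.pos)[0]),
                        mut.var_class,
                        mut.Index,
                        False,
                    )
                )

        # ---- ancestral heterozygosity (primary mode only; phased truth too)
        anc_frames = []
        if reference_mode == "primary":
            pframes = []
            for chrom in genome.chrom_names:
                het = genome.het_positions[chrom]
                if het.size == 0:
                    continue
                a_allele, b_allele = genome.het_alleles[chrom]
                na, nb = truth.copy_number(leaf, chrom, het)
                tot = na + nb
                live = tot > 0
                depth = np.zeros(het.size, dtype=np.int64)
                depth[live] = zt_poisson(rng, model.mean_depth * tot[live] / 2.0, (int(live.sum()),))
                pb = np.zeros(het.size)
                pb[live] = _alt_prob(nb[live] / tot[live], model.epsilon)
                breads = rng.binomial(depth, np.clip(pb, 0, 1))
                areads = depth - breads
                mapp = genome.is_mappable(chrom, het)
                qual = _true_qual(rng, het.size, model)
                a_str = np.frombuffer(b"ACGT", dtype="S1")[a_allele].astype("U1")
                b_str = np.frombuffer(b"ACGT", dtype="S1")[b_allele].astype("U1")
                pframes.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": het.astype(np.int64),
                            "a_allele": a_str,
                            "b_allele": b_str,
                            "depth_a": areads,
                            "depth_b": breads,
                            "mappable": mapp,
                        }
                    )
                )
                # the caller only reports the site if alt (hap-B) reads exist
                called = breads >= 1
                anc_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": het[called].astype(np.int64),
                            "ref": a_str[called],
                            "alt": b_str[called],
                            "qual": qual[called],
                            "ref_depth": areads[called],
                            "alt_depth": breads[called],
                            "total_depth": depth[called],
                            "allele_frequency": breads[called] / depth[called],
                            "mappable": mapp[called],
                            "variant_class": "SBS",
                            "mut_id": -1,
                            "is_artifact": False,
                        }
                    )
                )
            phased[leaf] = (
                pd.concat(pframes, ignore_index=True)
                if pframes
                else pd.DataFrame(columns=["chrom", "pos", "a_allele", "b_allele", "depth_a", "depth_b", "mappable"])
            )

        # ---- artifact injection (never on a real variant or het site)
        n_bp = sum(length for _, length in genome.chromosomes)
        n_art = rng.poisson(model.artifact_rate * n_bp)
        for _ in range(n_art):
            while True:
                ci = int(rng.integers(len(genome.chrom_names)))
                chrom = genome.chrom_names[ci]
                pos = int(rng.integers(1, genome.length(chrom) + 1))
                if (chrom, pos) not in occupied:
                    break
            ref = genome.base(chrom, "A", pos)
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            depth = int(zt_poisson(rng, model.mean_depth / 2.0, (1,))[0])
            altn = int(zt_binomial(rng, np.array([depth]), np.array([0.25]))[0])
            out_chrom = chrom if reference_mode == "primary" else f"{chrom}_{'A' if rng.random() < 0.5 else 'B'}"
            rows.append(
                (
                    out_chrom,
                    pos,
                    ref,
                    alt,
                    round(float(rng.uniform(2.0, 19.9)), 2),
                    depth - altn,
                    altn,
                    depth,
                    altn / depth,
                    bool(genome.is_mappable(chrom, pos)[0]),
                    "SBS",
                    -1,
                    True,
                )
            )

        frames = ([pd.DataFrame(rows, columns=VARIANT_COLUMNS)] if rows else []) + anc_frames
        if frames:
            df = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
        else:
            df = pd.DataFrame(columns=VARIANT_COLUMNS)
        df = df.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
        df = df.astype({"pos": np.int64, "ref_depth": np.int64, "alt_depth": np.int64, "total_depth": np.int64})
        variants[leaf] = df

        # ---- GVCF-style depth intervals (1 kb bins, copy-number scaled)
        irows = []
        for chrom in genome.chrom_names:
            L = genome.length(chrom)
            starts = np.arange(1, L + 1, 1000)
            ends = np.minimum(starts + 999, L)
            mids = (starts + ends) // 2
            na, nb = truth.copy_number(leaf, chrom, mids)
            if reference_mode == "primary":
                mean = model.mean_depth * (na + nb) / 2.0
                med = rng.poisson(mean)
                for s, e, d in zip(starts, ends, med):
                    irows.append((chrom, int(s), int(e), int(d)))
            else:
                for hap, n in (("A", na), ("B", nb)):
                    med = rng.poisson(model.mean_depth / 2.0 * n)
                    for s, e, d in zip(starts, ends, med):
                        irows.append((f"{chrom}_{hap}", int(s), int(e), int(d)))
        intervals[leaf] = pd.DataFrame(irows, columns=["chrom", "start", "end", "median_depth"])

        # ---- SV call sets (long-read samples only)
        if leaf in sv_samples:
            srows = []
            for sv in genome.ancestral_svs:
                srows.append((sv["chrom"] + ("_A" if reference_mode == "concatenated" else ""),
                              sv["pos"], sv["seq"], 1.0, -1))
            tes = truth.leaf_te_events(leaf)
            for te in tes.itertuples():
                seq = te_insertion_sequence(genome, te)
                if reference_mode == "primary":
                    chrom, af = te.chrom, te.cell_fraction / 2.0
                else:
                    chrom, af = f"{te.chrom}_{te.haplotype}", te.cell_fraction
                depth = int(zt_poisson(rng, model.mean_depth / (2.0 if reference_mode == "concatenated" else 1.0), (1,))[0])
                altn = int(zt_binomial(rng, np.array([depth]), np.array([max(af, 1e-9)]))[0])
                srows.append((chrom, int(te.vcf_pos), seq, altn / depth, te.Index))
            sdf = pd.DataFrame(srows, columns=["chrom", "pos", "seq", "allele_frequency", "te_id"])
            sdf["length"] = sdf["seq"].str.len()
            svs[leaf] = sdf.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    return Observations(
        mode=reference_mode, variants=variants, depth_intervals=intervals, phased_sites=phased, sv=svs
    )
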