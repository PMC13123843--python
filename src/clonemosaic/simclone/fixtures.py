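"""Emit simulated cohorts as standard-format files, plus truth tables.

Everything the downstream pipeline reads is written here: reference FASTA
in both primary and concatenated-haplotype modes, per-sample VCF and
GVCF-style depth-interval tables for both modes, SV VCFs with full inserted
sequences, GFF3 annotation, mappability BED, a TPM table, telomere-bearing
read FASTA, and TSV ground-truth tables. Output is deterministic: the same
config and seed produce byte-identical files.

Writers are plain text emission (the formats are line-oriented and
byte-stability matters); all reading elsewhere in the package goes through
cyvcf2 / gffutils / pyfaidx / Bio.SeqIO.
"""

from __future__ import annotations

import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .._util import revcomp, rng_from
from .genome import TELOMERE_UNIT, GenomeParams, SimGenome
from .lineage import (
    InstabilityEventSpec,
    LayerSpec,
    LineageTruth,
    TESpec,
    default_instability_spec,
    default_layer_spec,
    default_te_spec,
    simulate_lineage,
)
from .observe import ObservationModel, render_observations
from .tree import RATE_EMBRYO, RATE_SHOOT, RATE_TREE, default_tree


def default_config() -> dict:
    """The default study-shaped cohort configuration (YAML-serializable)."""
    return {
        "genome": {
            "n_chromosomes": 4,
            "chromosome_length": 100_000,
            "het_rate": 0.02,
            "telomere_repeat_count": 200,
            "genes_per_chromosome": 12,
            "unmappable_fraction": 0.05,
        },
        "rates": {"embryo": RATE_EMBRYO, "shoot": RATE_SHOOT, "tree": RATE_TREE},
        "observation": {"mean_depth": 50.0, "epsilon": 0.002, "artifact_rate": 5e-05},
        "instability": "default",
        "te": "default",
        "sv_samples": ["E1", "T1", "T2"],
        "reads_samples": ["E1", "E7", "S1985", "S2010", "S2022", "T1"],
        "tpm": {"n_per_chrom": 250, "noise_sd": 0.15},
    }


def config_to_objects(cfg: dict, seed: int):
    """Resolve a config dict into (tree, genome_params, specs, model)."""
    tree = default_tree(
        rate_embryo=cfg["rates"]["embryo"],
        rate_shoot=cfg["rates"]["shoot"],
        rate_tree=cfg["rates"]["tree"],
    )
    gp = GenomeParams(**cfg.get("genome", {}))
    inst = cfg.get("instability", "default")
    if inst == "default":
        inst = default_instability_spec(gp.n_chromosomes, gp.chromosome_length)
    elif inst in (None, "none"):
        inst = []
    else:
        inst = [InstabilityEventSpec(**e) for e in inst]
    te = cfg.get("te", "default")
    if te == "default":
        te = default_te_spec(tree)
    elif te in (None, "none"):
        te = TESpec()
    layer = LayerSpec(**cfg["layer"]) if "layer" in cfg else default_layer_spec()
    model = ObservationModel(seed=seed + 1, **cfg.get("observation", {}))
    return tree, gp, inst, te, layer, model


# ---------------------------------------------------------------------------
# generative side tables


def simulate_tpm(
    genome: SimGenome,
    truth: LineageTruth,
    n_per_chrom: int = 250,
    noise_sd: float = 0.15,
    clade_effects: list[tuple[list[str], int, float]] | None = None,
    seed=0,
) -> pd.DataFrame:
    """Transcript-level TPM: expression proportional to chromosome copy
    number with lognormal noise, optionally with clade-specific effects.

    ``clade_effects`` entries are (samples, n_transcripts, fold); the first
    ``n_transcripts`` transcripts get their values multiplied by ``fold`` in
    the listed samples. Columns are rescaled to sum to 1e6 per sample.
    """
    rng = rng_from(seed)
    rows = []
    for chrom, L in genome.chromosomes:
        pos = np.linspace(L * 0.05, L * 0.95, n_per_chrom).astype(int)
        for i, p in enumerate(pos):
            rows.append((f"{chrom}t{i + 1:04d}", chrom, int(p)))
    df = pd.DataFrame(rows, columns=["transcript_id", "chrom", "pos"])
    base = rng.lognormal(mean=3.0, sigma=1.0, size=len(df))
    leaves = truth.tree.leaves()
    for leaf in leaves:
        vals = base.copy()
        for chrom in genome.chrom_names:
            sel = (df["chrom"] == chrom).to_numpy()
            na, nb = truth.copy_number(leaf, chrom, df.loc[sel, "pos"].to_numpy())
            vals[sel] *= (na + nb) / 2.0
        vals *= rng.lognormal(mean=0.0, sigma=noise_sd, size=len(df))
        df[leaf] = vals
    for samples, n_tx, fold in clade_effects or []:
        for s in samples:
            df.loc[df.index[:n_tx], s] *= fold
    for leaf in leaves:
        df[leaf] = df[leaf] / df[leaf].sum() * 1e6
    return df


def simulate_reads(
    genome: SimGenome,
    telomere_repeats: int | None = None,
    read_length: int = 150,
    step: int = 100,
):
    """Deterministically tile both haplotypes into reads, with telomeric
    termini rebuilt to ``telomere_repeats`` TTTAGGG units per end.

    Yields (read_id, sequence). Uniform tiling keeps telomeric 21-mer
    density proportional to telomere length, which is what the telomere
    counter is validated against.
    """
    m = telomere_repeats if telomere_repeats is not None else genome.telomere_repeat_count
    t0 = genome.telomere_repeat_count * len(TELOMERE_UNIT)
    left = revcomp(TELOMERE_UNIT) * m
    right = TELOMERE_UNIT * m
    for chrom, L in genome.chromosomes:
        for hap in ("A", "B"):
            core = genome.seq(chrom, hap, t0 + 1, L - t0)
            seq = left + core + right
            n = 0
            for s in range(0, max(len(seq) - read_length + 1, 1), step):
                n += 1
                yield f"{chrom}_{hap}_r{n:05d}", seq[s : s + read_length]


def _telomere_repeats_for(sample: str, group: str, years_in_culture: float, base: int) -> int:
    """Default per-sample telomere sizing: embryos longest, shoots scale
    with time in culture, trees shortest."""
    if group == "embryo":
        return int(base * 1.5)
    if group == "shoot":
        return int(base * 0.75 + 2 * years_in_culture)
    return int(base * 0.75)


# ---------------------------------------------------------------------------
# writers (plain text, byte-stable)


def _write_fasta(path: str, records, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _vcf_header(contigs: list[tuple[str, int]], sample: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=clonemosaic-simclone"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    return "\n".join(lines) + "\n"


def _write_variant_vcf(path: str, df: pd.DataFrame, contigs, sample: str):
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, sample))
        for r in df.itertuples():
            gt = "1/1" if r.allele_frequency >= 0.95 else "0/1"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\tPASS\t.\t"
                f"GT:AD:DP\t{gt}:{r.ref_depth},{r.alt_depth}:{r.total_depth}\n"
            )


def _write_sv_vcf(path: str, df: pd.DataFrame, contigs, sample: str, genome: SimGenome):
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, sample))
        for r in df.itertuples():
            base_chrom = r.chrom.rsplit("_", 1)[0] if r.chrom not in genome.chrom_names else r.chrom
            ref = genome.base(base_chrom, "A", r.pos)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{ref}\t{ref}{r.seq}\t60.00\tPASS\t"
                f"SVTYPE=INS;SVLEN={len(r.seq)};AF={r.allele_frequency:.4f}\tGT\t0/1\n"
            )


def _write_gff3(path: str, genome: SimGenome):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, L in genome.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
        for g in genome.genes:
            col9 = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\tsimclone\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{col9}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsimclone\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsimclone\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            for utr, ftype in ((g.five_prime_utr, "five_prime_UTR"), (g.three_prime_utr, "three_prime_UTR")):
                if utr:
                    fh.write(
                        f"{g.chrom}\tsimclone\t{ftype}\t{utr[0]}\t{utr[1]}\t.\t{g.strand}\t.\t"
                        f"ID={mrna}.{ftype};Parent={mrna}\n"
                    )


def _write_mappability_bed(path: str, genome: SimGenome):
    """0-based half-open intervals with a {0,1} score column."""
    with open(path, "w") as fh:
        for chrom, L in genome.chromosomes:
            blocks = sorted(genome.unmappable.get(chrom, []))
            cur = 0  # 0-based
            for s, e in blocks:
                if s - 1 > cur:
                    fh.write(f"{chrom}\t{cur}\t{s - 1}\t1\n")
                fh.write(f"{chrom}\t{s - 1}\t{e}\t0\n")
                cur = e
            if cur < L:
                fh.write(f"{chrom}\t{cur}\t{L}\t1\n")


def write_fixtures(out_dir: str, cfg: dict | None = None, seed: int = 0):
    """Simulate a cohort under ``cfg`` (default config if None) and write
    every pipeline input plus truth tables under ``out_dir``.

    Returns (genome, truth) for callers that keep working in memory.
    """
    cfg = cfg or default_config()
    tree, gp, inst, te, layer, model = config_to_objects(cfg, seed)
    genome, truth = simulate_lineage(gp, tree, inst, te, layer, seed=seed)

    try:
        os.makedirs(out_dir, exist_ok=True)
        for sub in ("vcf/primary", "vcf/concatenated", "depths/primary", "depths/concatenated",
                    "phased_sites", "sv", "reads", "truth"):
            os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

        primary_contigs = genome.chromosomes
        concat_contigs = [(f"{c}_{h}", L) for c, L in genome.chromosomes for h in ("A", "B")]

        _write_fasta(
            os.path.join(out_dir, "ref_primary.fa"),
            ((c, genome.seq(c, "A")) for c, _ in genome.chromosomes),
        )
        _write_fasta(
            os.path.join(out_dir, "ref_concat.fa"),
            ((f"{c}_{h}", genome.seq(c, h)) for c, _ in genome.chromosomes for h in ("A", "B")),
        )
        _write_gff3(os.path.join(out_dir, "annotation.gff3"), genome)
        _write_mappability_bed(os.path.join(out_dir, "mappability.bed"), genome)

        groups = pd.DataFrame(sorted(truth.tree.groups.items()), columns=["sample", "group"])
        groups.to_csv(os.path.join(out_dir, "groups.tsv"), sep="\t", index=False)

        sv_samples = tuple(cfg.get("sv_samples", []))
        obs = {
            "primary": render_observations(genome, truth, model, "primary", sv_samples=sv_samples),
            "concatenated": render_observations(
                genome, truth,
                ObservationModel(**{**_model_kwargs(model), "seed": model.seed + 7919}),
                "concatenated", sv_samples=sv_samples,
            ),
        }
        for mode, ob in obs.items():
            contigs = primary_contigs if mode == "primary" else concat_contigs
            for sample, df in sorted(ob.variants.items()):
                _write_variant_vcf(os.path.join(out_dir, "vcf", mode, f"{sample}.vcf"), df, contigs, sample)
            for sample, df in sorted(ob.depth_intervals.items()):
                df.to_csv(os.path.join(out_dir, "depths", mode, f"{sample}.tsv"), sep="\t", index=False)
        for sample, df in sorted(obs["primary"].phased_sites.items()):
            df.to_csv(os.path.join(out_dir, "phased_sites", f"{sample}.tsv"), sep="\t", index=False)
        for sample, df in sorted(obs["concatenated"].sv.items()):
            _write_sv_vcf(os.path.join(out_dir, "sv", f"{sample}.vcf"), df, concat_contigs, sample, genome)

        tpm_cfg = cfg.get("tpm", {})
        tpm = simulate_tpm(
            genome, truth,
            n_per_chrom=tpm_cfg.get("n_per_chrom", 250),
            noise_sd=tpm_cfg.get("noise_sd", 0.15),
            clade_effects=tpm_cfg.get("clade_effects"),
            seed=seed + 2,
        )
        tpm.to_csv(os.path.join(out_dir, "tpm.tsv"), sep="\t", index=False, float_format="%.4f")

        years = {b.child: b.years for b in tree.branches}
        for sample in cfg.get("reads_samples", []):
            grp = tree.groups[sample]
            m = _telomere_repeats_for(sample, grp, years.get(sample, 0.0), genome.telomere_repeat_count)
            _write_fasta(
                os.path.join(out_dir, "reads", f"{sample}.fa"),
                simulate_reads(genome, telomere_repeats=m),
            )

        truth.mutations.to_csv(os.path.join(out_dir, "truth", "mutations.tsv"), sep="\t")
        truth.te_events.to_csv(os.path.join(out_dir, "truth", "te_events.tsv"), sep="\t")
        ev_rows = [
            {**asdict(e.spec), "lost_copy": e.lost_copy, "interval": str(e.spec.interval)}
            for e in truth.events
        ]
        pd.DataFrame(ev_rows).to_csv(os.path.join(out_dir, "truth", "events.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(b.parent, b.child, b.years, b.rate) for b in tree.branches],
            columns=["parent", "child", "years", "rate"],
        ).to_csv(os.path.join(out_dir, "truth", "tree.tsv"), sep="\t", index=False)
        lm = pd.DataFrame(
            [(leaf, ";".join(f"{k}={v}" for k, v in sorted(mdl.items()))) for leaf, mdl in sorted(truth.layer_model.items())],
            columns=["sample", "layer_model"],
        )
        lm.to_csv(os.path.join(out_dir, "truth", "layer_model.tsv"), sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"fixture write failed under {out_dir}: {exc}") from exc
    return genome, truth


def _model_kwargs(model: ObservationModel) -> dict:
    return {
        "mean_depth": model.mean_depth,
        "epsilon": model.epsilon,
        "quality_mean": model.quality_mean,
        "quality_sd": model.quality_sd,
        "quality_floor": model.quality_floor,
        "artifact_rate": model.artifact_rate,
        "seed": model.seed,
    }
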