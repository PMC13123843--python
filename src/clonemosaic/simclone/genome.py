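"""Phased diploid genome construction.

The simulated genome is deliberately desk-scale (default 4 chromosomes of
100 kb) but carries every structural feature the downstream analyses rely
on: two haplotypes differing only at ancestral heterozygous sites, telomeric
(TTTAGGG) termini, a gene annotation with UTR/exon/intron structure, planted
transposable-element donor loci, and a {0,1} mappability track. All internal
coordinates are 1-based inclusive; conversion to BED's 0-based half-open
convention happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import BASES, idx_to_str, revcomp, rng_from

TELOMERE_UNIT = "TTTAGGG"


@dataclass
class TEDonorSpec:
    """Where to plant a donor element and how long it is."""

    name: str
    length: int
    chrom: str
    haplotype: str
    start: int  # 1-based start of the donor locus
    length_class: str  # class_900 | class_5500 | other


@dataclass
class TEDonor:
    name: str
    chrom: str
    haplotype: str
    start: int
    length: int
    length_class: str
    sequence: str


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    # sub-features as (start, end) 1-based inclusive
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_prime_utr: tuple[int, int] | None = None
    three_prime_utr: tuple[int, int] | None = None


@dataclass
class GenomeParams:
    n_chromosomes: int = 4
    chromosome_length: int = 100_000
    het_rate: float = 0.02
    telomere_repeat_count: int = 200
    genes_per_chromosome: int = 12
    unmappable_fraction: float = 0.05
    n_ancestral_svs: int = 3
    te_donors: list[TEDonorSpec] | None = None
    base_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)

    def default_donors(self) -> list[TEDonorSpec]:
        chroms = [f"chr{i + 1}" for i in range(self.n_chromosomes)]
        return [
            TEDonorSpec("TE900", 900, chroms[0], "A", 40_001, "class_900"),
            TEDonorSpec("TE5500a", 5_500, chroms[1 % len(chroms)], "A", 60_001, "class_5500"),
            TEDonorSpec("TE5500b", 5_500, chroms[2 % len(chroms)], "B", 20_001, "class_5500"),
        ]


@dataclass
class SimGenome:
    """A phased diploid genome plus annotation tracks.

    ``haplotypes[chrom][hap]`` holds the sequence as a uint8 index array
    (0..3 = ACGT); use :meth:`seq` for strings. Haplotype A doubles as the
    primary assembly; haplotype B differs from A at exactly the ancestral
    heterozygous sites.
    """

    params: GenomeParams
    chromosomes: list[tuple[str, int]]
    haplotypes: dict[str, dict[str, np.ndarray]]
    het_positions: dict[str, np.ndarray]  # 1-based, sorted
    het_alleles: dict[str, tuple[np.ndarray, np.ndarray]]  # (A allele idx, B allele idx)
    genes: list[Gene]
    te_origins: list[TEDonor]
    unmappable: dict[str, list[tuple[int, int]]]  # 1-based inclusive intervals, score 0
    telomere_repeat_count: int
    ancestral_svs: list[dict]  # shared insertions present in every sample

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def seq(self, chrom: str, hap: str = "A", start: int | None = None, end: int | None = None) -> str:
        """Sequence of ``chrom`` haplotype ``hap`` over [start, end] (1-based inclusive)."""
        arr = self.haplotypes[chrom][hap]
        s = 0 if start is None else start - 1
        e = arr.size if end is None else end
        return idx_to_str(arr[s:e])

    def base(self, chrom: str, hap: str, pos: int) -> str:
        return idx_to_str(self.haplotypes[chrom][hap][pos - 1 : pos])

    def is_mappable(self, chrom: str, pos) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos))
        ok = np.ones(pos.shape, dtype=bool)
        for s, e in self.unmappable.get(chrom, []):
            ok &= ~((pos >= s) & (pos <= e))
        return ok

    def mappable_positions(self, chrom: str) -> np.ndarray:
        """All mappable 1-based positions outside the telomeric termini."""
        tlen = self.telomere_repeat_count * len(TELOMERE_UNIT)
        pos = np.arange(tlen + 1, self.length(chrom) - tlen + 1)
        return pos[self.is_mappable(chrom, pos)]

    def diploid_bp(self) -> int:
        return 2 * sum(length for _, length in self.chromosomes)


def _place_genes(chrom: str, length: int, tlen: int, n_genes: int) -> list[Gene]:
    """Evenly spaced genes with 5'UTR-exon-intron-exon-3'UTR structure."""
    genes = []
    usable = length - 2 * tlen - 4_000
    if n_genes <= 0 or usable <= 0:
        return genes
    spacing = usable // n_genes
    # gene body: 200 UTR + 300 exon + 400 intron + 300 exon + 200 UTR = 1400 bp
    for i in range(n_genes):
        start = tlen + 2_000 + i * spacing + 1
        end = start + 1_399
        if end > length - tlen - 2_000:
            break
        strand = "+" if i % 2 == 0 else "-"
        g = Gene(f"{chrom}g{i + 1:03d}", chrom, start, end, strand)
        if strand == "+":
            g.five_prime_utr = (start, start + 199)
            g.exons = [(start, start + 499), (end - 499, end)]
            g.three_prime_utr = (end - 199, end)
        else:
            g.three_prime_utr = (start, start + 199)
            g.exons = [(start, start + 499), (end - 499, end)]
            g.five_prime_utr = (end - 199, end)
        genes.append(g)
    return genes


def build_genome(params: GenomeParams | None = None, seed=0) -> SimGenome:
    """Draw a phased diploid genome according to ``params``.

    Haplotype B is haplotype A with a different base substituted at each
    ancestral heterozygous site. Telomeric termini are pure TTTAGGG arrays
    (G-strand on the right end, C-strand on the left end); heterozygosity,
    genes, donors and the mappability track live strictly between them.
    """
    params = params or GenomeParams()
    rng = rng_from(seed)
    tlen = params.telomere_repeat_count * len(TELOMERE_UNIT)
    if params.chromosome_length <= 2 * tlen + 8_000:
        raise ValueError("chromosome_length too small for telomeres + core")

    left = np.frombuffer((revcomp(TELOMERE_UNIT) * params.telomere_repeat_count).encode(), dtype=np.uint8)
    right = np.frombuffer((TELOMERE_UNIT * params.telomere_repeat_count).encode(), dtype=np.uint8)
    b2i = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        b2i[b] = i
    left, right = b2i[left], b2i[right]

    chroms, haplotypes, het_positions, het_alleles, unmappable = [], {}, {}, {}, {}
    genes: list[Gene] = []
    donors = params.te_donors if params.te_donors is not None else params.default_donors()

    for ci in range(params.n_chromosomes):
        name = f"chr{ci + 1}"
        L = params.chromosome_length
        chroms.append((name, L))
        core = rng.choice(4, size=L - 2 * tlen, p=params.base_probs).astype(np.uint8)
        hap_a = np.concatenate([left, core, right])
        # ancestral het sites: uniform over the core, Bernoulli het_rate
        core_pos = np.arange(tlen + 1, L - tlen + 1)
        het = core_pos[rng.random(core_pos.size) < params.het_rate]
        hap_b = hap_a.copy()
        a_allele = hap_a[het - 1]
        shift = rng.integers(1, 4, size=het.size).astype(np.uint8)
        b_allele = ((a_allele + shift) % 4).astype(np.uint8)
        hap_b[het - 1] = b_allele
        haplotypes[name] = {"A": hap_a, "B": hap_b}
        het_positions[name] = het
        het_alleles[name] = (a_allele, b_allele)
        genes.extend(_place_genes(name, L, tlen, params.genes_per_chromosome))
        # a single unmappable block per chromosome, off-centre
        if params.unmappable_fraction > 0:
            w = int((L - 2 * tlen) * params.unmappable_fraction)
            s = tlen + (L - 2 * tlen) * 3 // 4
            unmappable[name] = [(s + 1, s + w)]
        else:
            unmappable[name] = []

    te_origins = []
    for spec in donors:
        arr = haplotypes[spec.chrom][spec.haplotype]
        seqstr = idx_to_str(arr[spec.start - 1 : spec.start - 1 + spec.length])
        te_origins.append(
            TEDonor(spec.name, spec.chrom, spec.haplotype, spec.start, spec.length, spec.length_class, seqstr)
        )

    ancestral_svs = []
    for i in range(params.n_ancestral_svs):
        chrom = chroms[i % len(chroms)][0]
        pos = int(tlen + 5_000 + i * 1_111)
        seq = idx_to_str(rng.choice(4, size=300).astype(np.uint8))
        ancestral_svs.append({"chrom": chrom, "pos": pos, "seq": seq})

    return SimGenome(
        params=params,
        chromosomes=chroms,
        haplotypes=haplotypes,
        het_positions=het_positions,
        het_alleles=het_alleles,
        genes=genes,
        te_origins=te_origins,
        unmappable=unmappable,
        telomere_repeat_count=params.telomere_repeat_count,
        ancestral_svs=ancestral_svs,
    )


def trimer_context(genome: SimGenome, chrom: str, hap: str, pos: int) -> str:
    """±1 bp context around ``pos`` on the carrying haplotype (raw strand)."""
    if pos < 2 or pos > genome.length(chrom) - 1:
        return ""
    return genome.seq(chrom, hap, pos - 1, pos + 1)


_ = BASES  # re-exported alphabet (kept for callers importing from here)
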