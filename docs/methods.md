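# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `clonemosaic`. Nothing here states an
empirical result the test suite or `scripts/acceptance.py` does not itself
compute.

## The inference problem

All clones in a cohort descend from a single zygote. A variant seen against
the primary assembly is either (i) ancestral heterozygosity — an allelic
difference between the founder's two haplotypes, present in every clone
(subject to sampling), or (ii) a de novo somatic mutation confined to the
clade of clones descending from the cell in which it arose. Classification
exploits the propagation structure: somatic embryos all descend from one
founder embryo, so embryo-internal sharing is genuine shared ancestry,
whereas shoot cultures and trees were propagated independently from the
source tree, so sharing within or across those groups indicates ancestral
heterozygosity. Against the haplotype-phased assembly both founder
haplotypes are present in the reference, heterozygosity disappears from
the call set, and a variant's allele frequency directly estimates the
fraction of cells carrying it — the basis of the instability-dating,
TE cell-fraction and mosaicism analyses.

## Synthetic cohorts as the validation substrate

Real cohorts of this design involve terabases of sequencing; the package
instead validates every stage by parameter recovery on simulated cohorts.
The simulator is first-class, tested code, and its defaults define the
study conditions used throughout the tests.

**Genome.** Default 4 chromosomes × 100 kb (desk-scale stand-ins for
~30–50 Mb chromosomes; 250 windows of 400 bp stay non-degenerate).
Haplotype A doubles as the primary assembly; haplotype B differs at
ancestral het sites drawn at rate 0.02/bp — denser than a typical
outcrossing tree (~1%/bp) so that 400-bp windows hold ~8 informative sites,
preserving the per-window information content a full-size genome would
have. Termini are pure (TTTAGGG)×200 arrays; a gene annotation
(UTR–exon–intron–exon–UTR structure, 12 genes/chromosome), three planted
TE donor elements (one ~900 bp, two ~5,500 bp) and one unmappable block
(5% of the core) complete the tracks.

**Clone tree.** 12 embryos, 4 shoots (introduced 1985–2022-style ages), 2
trees, all 50 "years" from the zygote. Branch rates are per bp per year:
tree 3.57e-7, shoot 10×, embryo 35× (the rate contrasts the analyses are
designed to detect; absolute values are inflated so the 800 kb diploid
genome accumulates counts of realistic magnitude). Real per-branch
durations are unknown; the default is a plausible fixture, not a
reconstruction. Its one load-bearing property: the embryo lineage carries
a long shared culture branch (18 y at the embryo rate) before the
subpopulations split, with short terminal branches. UPGMA assumes
rate homogeneity, and with a near-zero-load outgroup it only recovers the
embryo clades when within-embryo distances stay below embryo-to-outgroup
distances — which requires the shared embryo branch to carry at least
about half of each embryo's private load. A history with long embryo
terminal branches is simply not UPGMA-recoverable, a limitation inherited
from the method, not the implementation.

**Mutation process.** Per branch, counts are Poisson(rate × diploid bp ×
years); positions are uniform on mappable non-telomeric sites under an
infinite-sites rule (one mutation per position, genome-wide); 85% SBS /
15% InDel (1–3 bp). Each mutation records its trimer context, branch,
haplotype, within-branch time, and — when it postdates a trisomy of its
haplotype — the duplicated copy it rides on, so later losses delete the
right mutations.

**Instability events** are specified per branch with a within-branch time
fraction. Defaults: chr2 haplotype-B trisomy, chr3-A mid-chromosome
deletion (30–70 kb) and chr4 copy-neutral recombination (B lost distal to
50 kb), all at time 0 of the embryo pre-culture branch — every embryo
inherits them and essentially no shared mutation predates the trisomy,
mirroring a duplication at or before culture initiation. Gain-then-loss
and independent-gain histories are exercised by dedicated configurations
rather than the defaults, keeping the default cohort's carrier sets exactly
clade-shaped (no event ever deletes an inherited mutation there).

**Cell fractions.** Internal-branch mutations are fixed (fraction 1.0) in
all descendants. Private mutations follow the clone's layer model: embryos
draw fraction 1.0 with weight 0.75 (single-cell budding repeatedly fixes
lineages) and otherwise Uniform(0.2, 0.8) (recent, not yet fixed); shoots
and trees draw the L1 fraction 0.2 with weight 0.35 and the L2–L3 fraction
0.8 otherwise (L1 is the minority of bulk leaf tissue; meristem layer cell
counts are closer to parity, hence 0.35 rather than 0.2).

**Observation model.** Depth is Poisson with local copy-number scaling
(diploid mean 50 — a typical WGS design point, and deep enough that the
median-depth filter has decisive margins even over deletions); alt reads
are binomial with per-base error 0.002. Carried mutations always yield a
record, with depth and alt count drawn zero-truncated: the model emulates
the *output* of a sensitive caller (calling is upstream of this package),
so caller false negatives are deliberately not a modelled failure mode.
False positives are: `artifact_rate` injects spurious singleton records
with quality Uniform(2, 20), below the median-quality ≥ 30 filter they are
meant to exercise; true records draw quality Normal(60, 8) clipped at 30.
Ancestral het sites are reported only when at least one haplotype-B read
exists; their phased depths are emitted separately for the instability
analysis regardless. Artifacts never collide with real variant positions.

What the simulator does **not** emulate: read-level errors and mapping
(variants are emitted as called records), indel realignment ambiguity,
caller-specific quality models, GC/coverage waves, contamination, or
organellar reads. Passing recovery tests therefore demonstrates the
correctness of the *inference* given VCF-level inputs with the stated
noise structure, not robustness to upstream calling artifacts beyond the
modelled quality/artifact channel.

## Pipeline conventions and numerics

* Coordinates are 1-based inclusive internally; BED's 0-based half-open
  convention converts at I/O. Median over an even count is the mean of the
  central pair. Sites with zero recomputed depth get a *missing* allele
  frequency, never 0. Multiallelic records decompose into per-ALT rows
  with per-allele AD.
* Site filters (median quality ≥ 30, median depth ≥ 15, mappability 1) are
  inclusive and monotone; median quality is taken over carriers (GVCF
  intervals carry no quality), median depth over the whole cohort.
* The embryo de novo rule accepts *any* embryo-only carrier set; a
  strictness switch (`embryo_requires_all`) restricts de novo status to
  singletons and all-embryo sets. SV identity uses ±10 bp position and 1%
  length tolerance (caller-style fuzziness; configurable).
* JC69 saturation (p ≥ 3/4) raises an error rather than clamping —
  clamping would silently distort the topology. UPGMA breaks distance ties
  by the lexicographically smallest cluster-label pair (a cluster's label
  is its smallest leaf name), making output invariant to taxon order.
  Bootstrap replicates that saturate are skipped (counted against
  support). Branch lengths count columns whose carrier set equals a clade
  exactly; unmatched columns are reported as homoplasy.
* The windowed test is χ² with 1 df on depth *sums* (not per-site means),
  no continuity correction. Windows with no covered site are missing and
  excluded. Calls require ≥ 20 Bonferroni-significant (within-chromosome)
  windows in a consistent direction, tolerating gaps of ≤ 2 non-significant
  windows; depth-ratio thresholds 1.25 / 0.75 separate gain, loss and
  copy-neutral; whole-chromosome means a run spanning ≥ 90% of windows.
  The χ²(1) p-values are uniform only in the well-populated-window regime;
  with few reads per window the binomial lattice shows through, so the
  null-calibration checks use windows holding ≳ 1,000 reads.
* Trisomy dating classifies duplicated-haplotype AFs with a midpoint rule:
  > 0.9 pre-duplication, < 0.6 post-duplication, the band between excluded
  as uncertain (the boundary is a stated design choice, exposed as
  configuration). Fewer than 5 informative mutations flags low confidence;
  zero pre-duplication mutations makes the ratio a lower bound. Loss
  detection accepts a loss clade when ≥ 1 post-duplication mutation is
  shared between it and trisomic relatives; with none, independent gains
  are the parsimonious reading (both event counts are reported).
* Telomere counting is exact sliding-window matching of 21-bp windows to
  any rotation phase of (TTTAGGG)×3 or a reverse complement — each window
  counts once, so a 28-bp quadruple repeat contributes 8 windows.
  Degenerate repeat variants do not match. "Nuclear reads" selection is an
  input contract.
* Origin search anchors exact 21-mers every 100 bp of the query (both
  strands) and scores candidates by banded edit-distance alignment;
  acceptance threshold 90% identity. TSD detection is ambiguous from a
  single insertion whenever the element's terminal bases coincide with the
  flank (probability ~1/4 per extra base), so the element/TSD boundary is
  fixed by a class consensus: insertions sharing an origin locus share the
  element as a common prefix while their TSDs differ, and position-wise
  agreement (≥ 90%) collapses exactly at the boundary. Loci with < 3
  insertions fall back to the aligned origin span; insertions with no
  origin fall back to longest-flank matching. Tandem duplication requires
  both halves ≥ 90% identical to the origin and total length within 15% of
  twice the origin.
* The TE bias null re-places each insertion uniformly on its own
  chromosome (feature space included; no mappability masking by default).
  Empirical p-values are add-one corrected, p = (b + 1)/(R + 1), two-sided
  by distance from the null mean; at R = 1 this yields p ∈ {0.5, 1}.
  Observed/simulated "means" are per-category membership fractions
  (scale-equivalent to counts at fixed n).
* Mosaicism: the fixed point mass is AF ≥ 0.95 (finite depth scatters true
  1.0); classification needs ≥ 30 singletons (below that, bimodality is
  undetectable). Single-lineage fixation is declared when the point mass
  holds ≥ 0.4 of the singletons; otherwise a 2-component Gaussian mixture
  on the interior AFs must show modes ≥ 0.2 apart, both weights ≥ 0.15,
  *and* a density valley (midpoint histogram density ≤ 0.6× the smaller
  mode's) — the valley check is what keeps a uniform AF cloud from being
  called bimodal. The explicit rule formalizes a pattern judged visually
  in practice; mode locations are reported as layer-fraction estimates and
  layer naming is left to the user.

## Problem sizes

The shipped tests and acceptance script run the default 18-clone,
4 × 100 kb cohort end-to-end (bootstrap B = 1000), multi-seed recovery
loops at 20–50 seeds with reduced ancillary load (e.g. het rate 0.002 for
rate recovery, zero mutation rates for instability detection, 2-chromosome
genomes for loss discrimination), a 5,000-window deep null for χ²
calibration, 200-trial × R = 1000 permutation calibration, and ~200-event
TE cohorts — the sizes at which the targeted effects are identifiable with
comfortable margins while a full run stays in the minutes range on one
CPU. All are configuration, not constants: larger genomes, deeper cohorts
and B = 10,000 bootstraps run unchanged.

## Known limitations

UPGMA's rate-homogeneity assumption (above) is the main structural one.
Classification treats "found in a sample" as ≥ 1 alt-supporting passing
record, with no genotype-likelihood modelling. The concatenated-mode
analyses assume correct assembly phasing. Trimer normalization uses
primary-assembly counts only. The loss detector assumes a single
duplicated-copy lineage per trisomy (no re-duplication). Three-layer
(L1/L2/L3) resolution, signature deconvolution, telomere length in bp and
sequential-transposition tracing are out of scope.
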