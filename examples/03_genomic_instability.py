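"""Detect chromosome-scale instability from phased allele frequencies.

At ancestral het sites the two haplotypes each contribute half the reads;
windowed chi-square tests of the haplotype depth split expose trisomy
(depth 1.5x, AF 2/3), segmental deletion (depth 0.5x) and copy-neutral
recombination (AF shift at depth 1x). A trisomy is then dated by the
allele frequencies of shared mutations on the duplicated haplotype.
"""

import numpy as np

from clonemosaic import instability as ins, simclone as sc

tree = sc.default_tree()
genome, truth = sc.simulate_lineage(
    None, tree, sc.default_instability_spec(), sc.TESpec(), None, seed=1
)
obs = sc.render_observations(genome, truth, sc.ObservationModel(seed=2), "primary",
                             samples=["E1", "T1"])

wins = {s: ins.window_statistics(obs.phased_sites[s], dict(genome.chromosomes), 250)
        for s in ("E1", "T1")}
calls = ins.call_instability(wins)
print(calls[["sample", "chrom", "haplotype", "kind", "first_window", "last_window",
             "depth_ratio", "mean_af"]].round(3).to_string(index=False))
# The embryo shows all three planted events; the tree is clean diploid.

# date the chr2 trisomy: shared mutations on the duplicated haplotype that
# predate the duplication sit on both copies (AF ~1 on the phased contig),
# later ones on a single copy (AF ~0.5)
concat = sc.render_observations(genome, truth, sc.ObservationModel(seed=3), "concatenated",
                                samples=["E1"])
muts = truth.mutations
shared_b = muts[(muts["chrom"] == "chr2") & (muts["haplotype"] == "B")
                & ~muts["branch"].isin(tree.leaves())]
v = concat.variants["E1"]
afs = v[v["mut_id"].isin(shared_b.index)]["allele_frequency"].to_numpy()
dating = ins.date_trisomy(afs)
print(f"\ntrisomy dating: {dating.n_pre} pre- vs {dating.n_post} post-duplication mutations "
      f"(ratio {np.round(dating.ratio_post_pre, 2) if dating.n_pre else 'inf'})")
print("  -> essentially no shared mutation predates the duplication: it arose "
      "at (or before) culture initiation, as configured.")
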