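"""Classify variants by clone-group sharing and build the mutation phylogeny.

Renders the cohort through the read-depth observation model (primary
assembly), recomputes per-site cohort annotation, separates ancestral
heterozygosity from de novo mutation by group sharing, and clusters the
binary de novo matrix with JC69 + UPGMA.
"""

from clonemosaic import denovo, phylo, simclone as sc, variantio as vio

tree = sc.default_tree()
genome, truth = sc.simulate_lineage(
    None, tree, sc.default_instability_spec(), sc.default_te_spec(tree), sc.default_layer_spec(), seed=1
)
obs = sc.render_observations(genome, truth, sc.ObservationModel(artifact_rate=5e-5, seed=2), "primary")

depths = {s: vio.RegionDepths(df) for s, df in obs.depth_intervals.items()}
matrix = vio.build_site_matrix(obs.variants, depths)
filtered = vio.apply_site_filters(matrix, min_median_quality=30, min_median_depth=15)
classified = denovo.classify_primary(filtered, tree.groups)
print(classified["status"].value_counts().to_string())
# "ancestral" sites are the founder's heterozygosity (shared across groups);
# low-quality artifacts fall out at the median-quality filter.

dn = denovo.de_novo_sites(classified)
M = phylo.mutation_matrix(dn, sorted(tree.leaves()))
ctree = phylo.bootstrap_support(M, B=500, seed=3)
ctree, homoplasy = phylo.branch_lengths_from_unique(M, ctree)
print(f"\n{M.shape[1]} de novo sites; homoplasy columns: {homoplasy}")
print("newick (branch lengths = unique mutations; internal labels = support):")
print(ctree.newick())
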