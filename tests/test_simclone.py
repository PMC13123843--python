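"""Simulator correctness: mutation accumulation, inheritance, instability
bookkeeping, observation-model expectations, determinism."""

import numpy as np
import pandas as pd
import pytest

from clonemosaic import simclone as sc
from clonemosaic.simclone.lineage import ConfigurationError, InstabilityEventSpec
from clonemosaic.simclone.tree import Branch, CloneTree


def two_leaf_tree(years=10.0, rate=1e-6):
    return CloneTree(
        "Z",
        [Branch("Z", "anc", years, rate), Branch("anc", "A", 1, rate), Branch("anc", "B", 1, rate)],
        {"A": "embryo", "B": "embryo"},
    )


def test_zero_rate_yields_no_mutations():
    tree = CloneTree(
        "Z",
        [Branch("Z", "A", 10, 0.0), Branch("Z", "B", 10, 0.0)],
        {"A": "tree", "B": "tree"},
    )
    genome, truth = sc.simulate_lineage(None, tree, [], sc.TESpec(), None, seed=0)
    assert len(truth.mutations) == 0
    assert len(truth.te_events) == 0


def test_poisson_rate_recovery_over_seeds():
    """Observed truth counts / (diploid bp x years) recover the branch rate
    within 3 binomial/Poisson SE pooled over 50 seeds."""
    gp = sc.GenomeParams(n_chromosomes=2, chromosome_length=30_000, het_rate=0.005, telomere_repeat_count=100)
    rate, years = 2e-6, 10.0
    tree = two_leaf_tree(years, rate)
    total = 0
    denom = 0.0
    for seed in range(50):
        genome, truth = sc.simulate_lineage(gp, tree, [], sc.TESpec(), None, seed=seed)
        total += int((truth.mutations["branch"] == "anc").sum())
        denom += genome.diploid_bp() * years
    lam = rate * denom
    assert abs(total - lam) < 3 * np.sqrt(lam)


def test_trisomy_inherited_by_all_embryos_only(default_cohort):
    truth, tree = default_cohort["truth"], default_cohort["tree"]
    for leaf in tree.leaves():
        na, nb = truth.copy_number(leaf, "chr2", [50_000])
        expected = 2 if tree.groups[leaf] == "embryo" else 1
        assert nb[0] == expected and na[0] == 1


def test_mutation_conservation_and_inheritance(default_cohort):
    """Per-clone truth mutations equal the union over root-path branches,
    and internal-branch mutations appear in all and only descendant leaves
    (the default history has no loss events)."""
    truth, tree = default_cohort["truth"], default_cohort["tree"]
    for leaf in ("E1", "E5", "S1985", "T1"):
        path_branches = {b.child for b in tree.path(leaf)}
        expected = set(truth.mutations.index[truth.mutations["branch"].isin(path_branches)])
        got = set(truth.leaf_mutations(leaf).index)
        assert got == expected
    rng = np.random.default_rng(0)
    some = rng.choice(truth.mutations.index, size=40, replace=False)
    for mid in some:
        assert truth.carriers(mid) == tree.clade(truth.mutations.loc[mid, "branch"])


def test_loss_of_trisomy_drops_lost_copy_mutations():
    tree = sc.default_tree()
    events = [
        InstabilityEventSpec("Eanc", "trisomy", "chr1", "A", time_fraction=0.0),
        InstabilityEventSpec("EcA2b", "loss_of_trisomy", "chr1", "A", time_fraction=0.0, lost_copy=1),
    ]
    genome, truth = sc.simulate_lineage(None, tree, events, sc.TESpec(), None, seed=21)
    muts = truth.mutations
    post = muts[(muts["chrom"] == "chr1") & (muts["haplotype"] == "A") & (muts["dup_copy"] > 0)]
    shared = post[post["branch"].isin(["Eanc", "EcA", "EcA2"])]
    assert len(shared) > 0
    for mid, row in shared.iterrows():
        carr = truth.carriers(mid)
        if row["dup_copy"] == 1:  # the lost copy
            assert not carr & {"E5", "E6"}
        else:
            assert {"E5", "E6"} <= carr


def test_event_validation_errors():
    tree = sc.default_tree()
    with pytest.raises(ConfigurationError):
        sc.simulate_lineage(None, tree, [InstabilityEventSpec("Epre", "trisomy", "chr99", "B")], None, None, seed=0)
    with pytest.raises(ConfigurationError):
        sc.simulate_lineage(
            None, tree, [InstabilityEventSpec("EcA1", "loss_of_trisomy", "chr2", "B")], None, None, seed=0
        )
    with pytest.raises(ConfigurationError):
        sc.simulate_lineage(
            None, tree, [], sc.TESpec(rates_per_year={"E1": 1.0}, donor_weights={"TE900": 0.0}), None, seed=0
        )


def test_simulation_determinism():
    tree = sc.default_tree()
    a = sc.simulate_lineage(None, tree, sc.default_instability_spec(), sc.default_te_spec(tree), None, seed=5)
    b = sc.simulate_lineage(None, tree, sc.default_instability_spec(), sc.default_te_spec(tree), None, seed=5)
    pd.testing.assert_frame_equal(a[1].mutations, b[1].mutations)
    pd.testing.assert_frame_equal(a[1].te_events, b[1].te_events)
    for chrom in a[0].chrom_names:
        assert np.array_equal(a[0].haplotypes[chrom]["B"], b[0].haplotypes[chrom]["B"])


@pytest.mark.parametrize("mode,expect", [("primary", 0.5), ("concatenated", 1.0)])
def test_observed_af_means_match_copy_number_arithmetic(mode, expect):
    """Fixed diploid mutations: mean AF 0.5 on the primary assembly, 1.0 on
    the carrying haplotype contig; trisomic het sites sit at 2/3."""
    gp = sc.GenomeParams(n_chromosomes=2, chromosome_length=60_000, het_rate=0.02, telomere_repeat_count=100)
    tree = two_leaf_tree(years=10, rate=2.5e-4)  # ~600 shared fixed mutations
    genome, truth = sc.simulate_lineage(
        gp, tree, [], sc.TESpec(), sc.LayerSpec(embryo_fixed_weight=1.0), seed=30
    )
    model = sc.ObservationModel(mean_depth=50, epsilon=0.0, artifact_rate=0.0, seed=31)
    obs = sc.render_observations(genome, truth, model, mode, samples=["A"])
    v = obs.variants["A"]
    v = v[v["mut_id"] >= 0]
    assert len(v) >= 500
    se = np.sqrt(expect * (1 - expect) / 50 / len(v)) if expect < 1 else 0.0
    if mode == "primary":
        assert abs(v["allele_frequency"].mean() - expect) < 3 * max(se, np.sqrt(0.25 / 50 / len(v)))
    else:
        assert v["allele_frequency"].mean() == pytest.approx(1.0, abs=1e-12)


def test_trisomic_het_af_two_thirds(default_cohort):
    ph = default_cohort["primary"].phased_sites["E1"]
    sub = ph[ph["chrom"] == "chr2"]
    af = sub["depth_b"].sum() / (sub["depth_a"].sum() + sub["depth_b"].sum())
    n = sub["depth_a"].sum() + sub["depth_b"].sum()
    assert abs(af - 2 / 3) < 3 * np.sqrt((2 / 3) * (1 / 3) / n) + 0.01


def test_fixture_determinism_and_roundtrip(small_fixture_dir, tmp_path):
    """Same config and seed give byte-identical fixture trees."""
    import filecmp
    import os

    out2 = tmp_path / "again"
    sc.write_fixtures(str(out2), small_fixture_dir["cfg"], seed=3)
    base = small_fixture_dir["path"]
    for root, _dirs, files in os.walk(base):
        rel = os.path.relpath(root, base)
        for fn in files:
            a = os.path.join(root, fn)
            b = os.path.join(out2, rel, fn)
            assert filecmp.cmp(a, b, shallow=False), f"fixture file differs: {rel}/{fn}"


def test_tpm_trisomy_effect():
    tree = sc.default_tree()
    genome, truth = sc.simulate_lineage(None, tree, sc.default_instability_spec(), sc.TESpec(), None, seed=40)
    tpm = sc.simulate_tpm(genome, truth, n_per_chrom=200, noise_sd=0.1, seed=41)
    med = tpm.groupby("chrom")["E1"].median()
    base = med[["chr1"]].mean()
    assert med["chr2"] / base == pytest.approx(1.5, rel=0.12)
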