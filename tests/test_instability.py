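"""Windowed chi-square statistics, instability calling, trisomy dating and
loss inference, and expression consequences."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonemosaic import instability as ins, simclone as sc
from clonemosaic.simclone import InstabilityEventSpec
from clonemosaic.simclone.tree import Branch, CloneTree


def phased(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "depth_a", "depth_b"])


def test_window_chi_square_closed_form():
    df = phased([("c", 10, 100, 100), ("c", 30, 150, 100)])
    w = ins.window_statistics(df, {"c": 40}, n_windows=2)
    assert w.loc[0, "chi2"] == 0.0 and w.loc[0, "p"] == 1.0
    assert w.loc[1, "chi2"] == pytest.approx(10.0, abs=1e-12)
    assert w.loc[1, "p"] == pytest.approx(stats.chi2.sf(10.0, 1), abs=1e-12)
    assert f"{w.loc[1, 'p']:.5f}" == "0.00157"


def test_empty_windows_are_missing():
    df = phased([("c", 5, 30, 30)])
    w = ins.window_statistics(df, {"c": 100}, n_windows=10)
    assert w["p"].notna().sum() == 1
    assert w.loc[w["n_sites"] == 0, "mean_af"].isna().all()


def test_null_calibration_fraction():
    """Diploid chromosome: ~5% of windows significant at p<0.05."""
    tree = CloneTree("Z", [Branch("Z", "A", 1, 0.0), Branch("Z", "B", 1, 0.0)], {"A": "tree", "B": "tree"})
    gp = sc.GenomeParams(n_chromosomes=2, chromosome_length=200_000, het_rate=0.04, telomere_repeat_count=100)
    genome, truth = sc.simulate_lineage(gp, tree, [], sc.TESpec(), None, seed=1)
    obs = sc.render_observations(genome, truth, sc.ObservationModel(mean_depth=50, seed=2), "primary", samples=["A"])
    w = ins.window_statistics(obs.phased_sites["A"], dict(genome.chromosomes), 500)
    frac = (w["p"] < 0.05).mean()
    n = w["p"].notna().sum()
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n) + 0.01


def test_instability_call_recovery(default_cohort):
    genome, truth = default_cohort["genome"], default_cohort["truth"]
    obs = default_cohort["primary"]
    wins = {s: ins.window_statistics(obs.phased_sites[s], dict(genome.chromosomes), 250) for s in ("E3", "T1", "S1985")}
    calls = ins.call_instability(wins)
    e3 = calls[calls["sample"] == "E3"].set_index("chrom")
    assert e3.loc["chr2", "kind"] == "trisomy" and e3.loc["chr2", "haplotype"] == "B"
    assert 1.3 < e3.loc["chr2", "depth_ratio"] < 1.7
    assert e3.loc["chr3", "kind"] == "segmental_deletion" and e3.loc["chr3", "haplotype"] == "A"
    assert abs(e3.loc["chr3", "first_window"] - 75) <= 2 and abs(e3.loc["chr3", "last_window"] - 174) <= 2
    assert e3.loc["chr4", "kind"] == "copy_neutral_recombination" and e3.loc["chr4", "haplotype"] == "B"
    assert abs(e3.loc["chr4", "first_window"] - 125) <= 2
    assert 0.8 < e3.loc["chr4", "depth_ratio"] < 1.2
    # balanced samples yield nothing
    assert len(calls[calls["sample"].isin(["T1", "S1985"])]) == 0
    assert "chr1" not in e3.index


def test_date_trisomy_classifier_and_boundaries():
    rng = np.random.default_rng(0)
    pre = rng.binomial(50, 0.995, 10) / 50
    post = rng.binomial(50, 0.5, 100) / 50
    d = ins.date_trisomy(np.concatenate([pre, post]))
    assert d.n_pre == 10
    se = 10 * np.sqrt(1 / d.n_pre + 1 / max(d.n_post, 1))
    assert abs(d.ratio_post_pre - 10) < se
    assert not d.low_confidence

    d = ins.date_trisomy([0.5, 0.45, 0.55])
    assert d.lower_bound_only and d.ratio_post_pre == np.inf and d.low_confidence

    d = ins.date_trisomy([1.0] * 8)
    assert d.all_pre and d.ratio_post_pre == 0.0

    d = ins.date_trisomy([0.75, 0.8])  # uncertainty band
    assert d.n_excluded == 2


def make_loss_inputs(seed, scenario):
    tree = sc.default_tree()
    if scenario == "loss":
        events = [
            InstabilityEventSpec("Eanc", "trisomy", "chr1", "A", time_fraction=0.0),
            InstabilityEventSpec("EcA2b", "loss_of_trisomy", "chr1", "A", time_fraction=0.0),
        ]
    else:
        events = [
            InstabilityEventSpec("EcA1", "trisomy", "chr1", "A", time_fraction=0.0),
            InstabilityEventSpec("EcB2", "trisomy", "chr1", "A", time_fraction=0.0),
        ]
    genome, truth = sc.simulate_lineage(None, tree, events, sc.TESpec(), None, seed=seed)
    embryos = [f"E{i}" for i in range(1, 13)]
    obs = sc.render_observations(
        genome, truth, sc.ObservationModel(artifact_rate=0.0, seed=seed + 1), "concatenated", samples=embryos
    )
    trisomic = {l for l in embryos if truth.copy_number(l, "chr1", [50_000])[0][0] == 2}
    rows = []
    for mid, mut in truth.mutations[(truth.mutations["chrom"] == "chr1") & (truth.mutations["haplotype"] == "A")].iterrows():
        carr = truth.carriers(mid)
        if len(carr) < 2:
            continue
        afs = [
            obs.variants[s].loc[obs.variants[s]["mut_id"] == mid, "allele_frequency"].iloc[0]
            for s in sorted(carr & trisomic)
        ]
        if afs:
            rows.append((mid, carr, float(np.mean(afs))))
    df = pd.DataFrame(rows, columns=["mut_id", "carriers", "af"])
    df["post_duplication"] = df["af"] < 0.6
    return tree, trisomic, df


def test_gain_then_loss_vs_independent_gains():
    tree, trisomic, df = make_loss_inputs(601, "loss")
    res = ins.detect_trisomy_loss(tree.to_phylo_clade(), trisomic, df)
    assert res.interpretation == "gain_then_loss"
    assert res.loss_clades == [frozenset({"E5", "E6"})]

    tree, trisomic, df = make_loss_inputs(701, "indep")
    res = ins.detect_trisomy_loss(tree.to_phylo_clade(), trisomic, df)
    assert res.interpretation == "independent_gains"
    assert res.n_independent_gains == 2

    res = ins.detect_trisomy_loss(tree.to_phylo_clade(), set(), df)
    assert res.interpretation == "no_trisomy"


def test_chromosome_expression_normalization():
    tpm = pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(8)],
            "chrom": ["c1"] * 4 + ["c2"] * 4,
            "pos": range(8),
            "s1": [5.0, 6, 7, 8, 5, 6, 7, 8],
            "s2": [5.0, 6, 7, 8, 10, 12, 14, 16],
        }
    )
    out = ins.chromosome_expression(tpm)
    assert np.allclose(out["s1"], 1.0)
    assert out.loc["c2", "s2"] / out.loc["c1", "s2"] == pytest.approx(2.0)

    # strict TPM > 1.0 filter: a transcript at exactly 1.0 is excluded
    tpm2 = tpm.copy()
    tpm2.loc[0, "s1"] = 1.0
    out2 = ins.chromosome_expression(tpm2)
    assert out2.loc["c1", "s1"] != out.loc["c1", "s1"]


def test_welch_and_bh_conventions():
    tpm = pd.DataFrame(
        {
            "transcript_id": ["t0"],
            "chrom": ["c1"],
            "a1": [1.0], "a2": [2.0], "a3": [3.0],
            "b1": [1.0], "b2": [2.0], "b3": [3.0],
        }
    )
    out = ins.clade_differential_expression(tpm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0
    assert out.loc[0, "p_adj"] == out.loc[0, "p"]  # BH with m=1 is identity

    flat = tpm.copy()
    for c in ("a1", "a2", "a3", "b1", "b2", "b3"):
        flat[c] = [5.0]
    out = ins.clade_differential_expression(flat, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
    assert out.loc[0, "degenerate"] and out.loc[0, "p"] == 1.0 and out.loc[0, "t"] == 0.0

    with pytest.raises(ValueError):
        ins.clade_differential_expression(tpm, ["a1"], ["b1", "b2"])


def test_differential_expression_fdr_control():
    """50 true 2x clade-effect transcripts among 1000: realized FDR stays
    near the nominal 0.05 across seeds."""
    fdrs = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n, k = 1000, 50
        base = rng.lognormal(3, 1, n)
        data = {}
        clade = [f"c{i}" for i in range(4)]
        rest = [f"r{i}" for i in range(4)]
        for s in clade + rest:
            data[s] = base * rng.lognormal(0, 0.1, n)
        for s in clade:
            data[s][:k] *= 2.0
        tpm = pd.DataFrame({"transcript_id": [f"t{i}" for i in range(n)], "chrom": "c1", **data})
        out = ins.clade_differential_expression(tpm, clade, rest)
        called = out[out["significant"]]
        if len(called):
            fdrs.append((called.index >= k).mean())
        assert (out.loc[: k - 1, "significant"]).mean() > 0.5  # reasonable power
    mean_fdr = float(np.mean(fdrs))
    se = float(np.std(fdrs, ddof=1) / np.sqrt(len(fdrs))) if len(fdrs) > 1 else 0.05
    assert mean_fdr <= 0.05 + 3 * max(se, 0.01)
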