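"""Clone-group sharing logic, SV matching, and truth recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonemosaic import denovo, variantio as vio

GROUPS = {
    **{f"E{i}": "embryo" for i in range(1, 13)},
    **{s: "shoot" for s in ("S1985", "S2010", "S2013", "S2022")},
    "T1": "tree",
    "T2": "tree",
}


def matrix_with(carrier_sets):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": range(1, len(carrier_sets) + 1),
            "ref": "A",
            "alt": "T",
            "carriers": [frozenset(c) for c in carrier_sets],
            "n_carriers": [len(c) for c in carrier_sets],
            "median_quality": 50.0,
            "median_depth": 30.0,
            "mappable": True,
            "variant_class": "SBS",
        }
    )


@pytest.mark.parametrize(
    "carriers,mode,expected",
    [
        ({"E1", "E2", "E3"}, "primary", denovo.STATUS_DE_NOVO),
        ({"S1985", "T1"}, "primary", denovo.STATUS_ANCESTRAL),
        ({"S2010", "S2013"}, "primary", denovo.STATUS_REMOVED_WITHIN),
        ({"T1", "T2"}, "primary", denovo.STATUS_REMOVED_WITHIN),
        ({"S1985"}, "primary", denovo.STATUS_DE_NOVO),
        ({"T1"}, "primary", denovo.STATUS_DE_NOVO),
        ({"E1", "T1"}, "concatenated", denovo.STATUS_REMOVED_CROSS),
        (set(f"E{i}" for i in range(1, 13)), "concatenated", denovo.STATUS_DE_NOVO),
        ({"S2010", "S2013"}, "concatenated", denovo.STATUS_REMOVED_WITHIN),
    ],
)
def test_classification_rules(carriers, mode, expected):
    out = denovo.classify_sites(matrix_with([carriers]), GROUPS, mode=mode)
    assert out.loc[0, "status"] == expected
    assert out.loc[0, "singleton"] == (len(carriers) == 1)


def test_degenerate_inputs():
    with pytest.raises(ValueError):
        denovo.classify_sites(matrix_with([set()]), GROUPS)
    with pytest.raises(KeyError, match="X9"):
        denovo.classify_sites(matrix_with([{"X9"}]), GROUPS)


def brute_force_status(carriers, groups, mode):
    """Direct enumeration of the sharing rules, independent of the
    implementation's code path."""
    gs = sorted({groups[s] for s in carriers})
    if len(gs) > 1:
        return denovo.STATUS_ANCESTRAL if mode == "primary" else denovo.STATUS_REMOVED_CROSS
    if gs[0] == "embryo":
        return denovo.STATUS_DE_NOVO
    return denovo.STATUS_DE_NOVO if len(carriers) == 1 else denovo.STATUS_REMOVED_WITHIN


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    carriers=st.sets(st.sampled_from(sorted(GROUPS)), min_size=1, max_size=18),
    mode=st.sampled_from(["primary", "concatenated"]),
    data=st.randoms(use_true_random=False),
)
def test_classification_matches_brute_force_and_is_order_invariant(carriers, mode, data):
    out = denovo.classify_sites(matrix_with([carriers]), GROUPS, mode=mode)
    assert out.loc[0, "status"] == brute_force_status(carriers, GROUPS, mode)
    # permuting the sample universe changes nothing: status is a pure
    # function of the carrier-group incidence
    shuffled = sorted(carriers, key=lambda s: data.random())
    out2 = denovo.classify_sites(matrix_with([frozenset(shuffled)]), GROUPS, mode=mode)
    assert out2.loc[0, "status"] == out.loc[0, "status"]


def test_primary_and_concatenated_agree_on_singletons():
    sets = [{"E3"}, {"S2013"}, {"T2"}]
    a = denovo.classify_sites(matrix_with(sets), GROUPS, mode="primary")
    b = denovo.classify_sites(matrix_with(sets), GROUPS, mode="concatenated")
    assert (a["status"] == b["status"]).all()


# ---------------------------------------------------------------------------


def sv_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "length", "seq"])


def test_sv_singletons_and_sharing():
    tables = {
        "E_HiFi": sv_frame([("chr1", 5000, 5500, "x")]),
        "Ref": sv_frame([("chr2", 900, 300, "y")]),
        "Tree": sv_frame([("chr2", 902, 301, "y")]),
    }
    out = denovo.classify_sv(tables)
    by_chrom = out.set_index("chrom")
    assert by_chrom.loc["chr1", "status"] == denovo.STATUS_DE_NOVO
    assert by_chrom.loc["chr2", "status"] == denovo.STATUS_ANCESTRAL  # within tolerance -> same SV

    shared = {s: sv_frame([("chr1", 5000 + i, 5500 + i, "z")]) for i, s in enumerate(["a", "b", "c"])}
    out = denovo.classify_sv(shared)
    assert len(out) == 1 and out.loc[0, "status"] == denovo.STATUS_ANCESTRAL

    with pytest.raises(ValueError):
        denovo.classify_sv({"only": sv_frame([])})


def test_sv_tolerance_boundaries():
    tables = {
        "a": sv_frame([("chr1", 5000, 5500, "x")]),
        "b": sv_frame([("chr1", 5003, 5502, "x")]),  # within +/-10 bp and 1% length
        "c": sv_frame([("chr1", 5030, 5500, "x")]),  # position outside tolerance
    }
    out = denovo.classify_sv(tables)
    assert sorted(out["n_carriers"]) == [1, 2]


# ---------------------------------------------------------------------------


def test_recovery_against_truth(default_cohort):
    """Noise-free cohort: every truth de novo mutation is recovered, no
    ancestral site leaks through, and with artifacts + study filters the
    artifact pass-through is zero."""
    tree, truth, obs = default_cohort["tree"], default_cohort["truth"], default_cohort["primary"]
    matrix = vio.build_site_matrix(obs.variants)
    cls = denovo.classify_primary(matrix, tree.groups)
    rep = denovo.recover_classification(cls, truth, obs)
    assert rep["recall"] == 1.0
    assert rep["precision"] == 1.0

    # artifact injection + study filters (median quality >= 30, depth >= 15)
    from clonemosaic import simclone as sc

    noisy = sc.render_observations(
        default_cohort["genome"], truth, sc.ObservationModel(artifact_rate=2e-4, seed=77), "primary"
    )
    depths = {s: vio.RegionDepths(df) for s, df in noisy.depth_intervals.items()}
    nm = vio.build_site_matrix(noisy.variants, depths)
    n_art = sum(int(df["is_artifact"].sum()) for df in noisy.variants.values())
    assert n_art > 50
    filt = vio.apply_site_filters(nm, 30, 15, require_mappable=True)
    rep = denovo.recover_classification(denovo.classify_primary(filt, tree.groups), truth, noisy)
    assert rep["artifact_passthrough"] == 0
    assert rep["recall"] > 0.99


def test_all_ancestral_simulation_yields_no_de_novo():
    from clonemosaic import simclone as sc
    from clonemosaic.simclone.tree import Branch, CloneTree

    tree = CloneTree(
        "Z",
        [Branch("Z", "A", 10, 0.0), Branch("Z", "B", 10, 0.0), Branch("Z", "T1", 10, 0.0)],
        {"A": "embryo", "B": "shoot", "T1": "tree"},
    )
    gp = sc.GenomeParams(n_chromosomes=2, chromosome_length=40_000, telomere_repeat_count=100)
    genome, truth = sc.simulate_lineage(gp, tree, [], sc.TESpec(), None, seed=8)
    obs = sc.render_observations(genome, truth, sc.ObservationModel(artifact_rate=0.0, seed=9), "primary")
    matrix = vio.build_site_matrix(obs.variants)
    cls = denovo.classify_primary(vio.apply_site_filters(matrix, 30, 15), tree.groups)
    assert (cls["status"] == denovo.STATUS_DE_NOVO).sum() == 0
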