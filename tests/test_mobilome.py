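"""TE insertion characterization: length classes, origin search, TSDs,
tandem duplications, feature annotation, permutation bias test, bins."""

import numpy as np
import pandas as pd
import pytest

from clonemosaic import mobilome as mb, simclone as sc
from clonemosaic._util import revcomp
from clonemosaic.simclone.lineage import _feature_membership, te_insertion_sequence


def test_length_class_windows():
    assert mb.classify_by_length([898, 902, 905]) == ["class_900"] * 3
    assert mb.classify_by_length([3000]) == ["other"]
    assert mb.classify_by_length([5500 * 1.14, 5500 * 1.16]) == ["class_5500", "other"]
    assert mb.classify_by_length([]) == []


@pytest.fixture(scope="module")
def te_cohort():
    tree = sc.default_tree()
    te = sc.default_te_spec(tree)
    te.rates_per_year = {"Eanc": 6.0}  # ~110 insertions on one shared branch
    genome, truth = sc.simulate_lineage(None, tree, [], te, None, seed=55)
    refd = {f"{c}_{h}": genome.seq(c, h) for c, _ in genome.chromosomes for h in "AB"}
    donors = {d.name: d for d in genome.te_origins}
    return dict(genome=genome, truth=truth, refd=refd, donors=donors)


def test_origin_search_exact_divergent_and_null(te_cohort):
    genome, refd, donors = te_cohort["genome"], te_cohort["refd"], te_cohort["donors"]
    don = donors["TE900"]
    hit = mb.find_origin(don.sequence, refd)
    assert hit.identity == 1.0
    assert hit.contig == f"{don.chrom}_{don.haplotype}" and abs(hit.start - don.start) <= 2

    rng = np.random.default_rng(0)
    seq = list(don.sequence)
    for i in rng.choice(len(seq), size=len(seq) // 50, replace=False):  # 2% divergence
        seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
    hit = mb.find_origin("".join(seq), refd)
    assert hit is not None and hit.contig == f"{don.chrom}_{don.haplotype}"
    assert 0.96 <= hit.identity <= 0.99

    # minus strand
    hit = mb.find_origin(revcomp(don.sequence), refd)
    assert hit is not None and hit.strand == "-" and hit.identity == 1.0

    random_seq = "".join(rng.choice(list("ACGT"), 800))
    assert mb.find_origin(random_seq, refd) is None


def test_tsd_recovery_on_simulated_insertions(te_cohort):
    genome, truth, donors = te_cohort["genome"], te_cohort["truth"], te_cohort["donors"]
    ok = n = 0
    for r in truth.te_events.itertuples():
        n += 1
        ins = te_insertion_sequence(genome, r)
        left = genome.seq(r.chrom, r.haplotype, max(1, r.vcf_pos - 30), r.vcf_pos)
        right = genome.seq(r.chrom, r.haplotype, r.vcf_pos + 1, min(r.vcf_pos + 30, genome.length(r.chrom)))
        tsd, trimmed = mb.detect_tsd(ins, left, right, origin_seq=donors[r.donor].sequence)
        ok += tsd == r.tsd_seq
    assert n >= 80
    assert ok / n >= 0.98


def test_tsd_no_duplication_and_constructed_ambiguity():
    rng = np.random.default_rng(1)
    # no TSD: pure random insert between random flanks -> length 0 nearly always
    zeros = 0
    for _ in range(200):
        ins = "".join(rng.choice(list("ACGT"), 300))
        lf = "".join(rng.choice(list("ACGT"), 30))
        rf = "".join(rng.choice(list("ACGT"), 30))
        tsd, trimmed = mb.detect_tsd(ins, lf, rf)
        zeros += tsd == ""
        assert trimmed == ins or len(trimmed) < len(ins)
    assert zeros / 200 >= 0.95

    # two candidate duplications of lengths 6 and 11 -> the longer wins
    body = "".join(rng.choice(list("ACGT"), 100))
    short, long_ = "ACGTAC", "GGATCCGGATC"
    ins = short + body + long_
    lf = "T" * 19 + long_  # suffix matches insertion suffix (11)
    rf = short + "G" * 24  # prefix matches insertion prefix (6)
    tsd, trimmed = mb.detect_tsd(ins, lf, rf)
    assert tsd == long_ and trimmed == short + body


def test_tandem_duplication_flags(te_cohort):
    donors = te_cohort["donors"]
    origin = donors["TE900"].sequence
    doubled = (origin[:896] * 2)
    assert mb.detect_tandem_duplication(doubled, origin)
    assert not mb.detect_tandem_duplication(origin, origin)  # single copy
    rng = np.random.default_rng(2)
    half_match = origin[:896] + "".join(rng.choice(list("ACGT"), 896))
    assert not mb.detect_tandem_duplication(half_match, origin)


def test_feature_masks_match_generator_annotation(small_fixture_dir):
    """GFF3 round-trip: masks parsed from the emitted annotation equal the
    simulator's own membership arrays."""
    genome = small_fixture_dir["genome"]
    gff = str(small_fixture_dir["path"] / "annotation.gff3")
    masks = mb.feature_masks(gff, dict(genome.chromosomes))
    truth_masks = _feature_membership(genome)
    for chrom in genome.chrom_names:
        for cat in mb.FEATURE_CATEGORIES:
            assert np.array_equal(masks[chrom][cat], truth_masks[chrom][cat]), (chrom, cat)


def test_annotate_features_multilabel(small_fixture_dir):
    genome = small_fixture_dir["genome"]
    masks = mb.feature_masks(str(small_fixture_dir["path"] / "annotation.gff3"), dict(genome.chromosomes))
    g = genome.genes[0]  # + strand: 5'UTR then exon1
    exonic = g.exons[0][0] + 250  # inside exon1, outside the UTR
    upstream = g.start - 500
    far = g.start - 1500 if g.start > 1500 else g.end + 1500
    df = pd.DataFrame({"chrom": [g.chrom] * 3, "pos": [exonic, upstream, far]})
    out = mb.annotate_features(df, masks)
    assert set(out.loc[0, "features"]) >= {"gene", "exon"}
    assert out.loc[1, "features"] == ("upstream",)
    assert "intergenic" in out.loc[2, "features"] or "downstream" in out.loc[2, "features"]


def test_bias_test_boundary_and_invariances(default_cohort):
    genome = default_cohort["genome"]
    masks = _feature_membership(genome)
    rng = np.random.default_rng(3)
    ins = pd.DataFrame(
        {
            "chrom": rng.choice(genome.chrom_names, 20),
            "pos": rng.integers(2000, 90_000, 20),
        }
    )
    r1 = mb.insertion_bias_test(ins, masks, R=1, seed=0, categories=("gene",))
    assert r1.loc[0, "p"] in (0.5, 1.0)

    a = mb.insertion_bias_test(ins, masks, R=500, seed=4)
    b = mb.insertion_bias_test(ins.iloc[::-1].reset_index(drop=True), masks, R=500, seed=4)
    pd.testing.assert_frame_equal(a, b)  # insertion order is irrelevant

    with pytest.raises(ValueError):
        mb.insertion_bias_test(ins.iloc[:0], masks, R=10)


def test_bias_test_detects_upstream_enrichment(default_cohort):
    genome = default_cohort["genome"]
    masks = _feature_membership(genome)
    rng = np.random.default_rng(5)
    rows = []
    for _ in range(35):
        c = str(rng.choice(genome.chrom_names))
        w = np.where(masks[c]["upstream"], 5.0, 1.0)
        rows.append((c, int(rng.choice(len(w), p=w / w.sum())) + 1))
    ins = pd.DataFrame(rows, columns=["chrom", "pos"])
    res = mb.insertion_bias_test(ins, masks, R=1000, seed=6).set_index("category")
    assert res.loc["upstream", "p"] < 0.05
    assert res.loc["upstream", "direction"] == "enriched"


def test_trimming_never_lowers_origin_identity(te_cohort):
    genome, truth, refd, donors = (
        te_cohort["genome"], te_cohort["truth"], te_cohort["refd"], te_cohort["donors"]
    )
    for r in truth.te_events.head(15).itertuples():
        ins = te_insertion_sequence(genome, r)
        before = mb.find_origin(ins, refd)
        left = genome.seq(r.chrom, r.haplotype, max(1, r.vcf_pos - 30), r.vcf_pos)
        right = genome.seq(r.chrom, r.haplotype, r.vcf_pos + 1, min(r.vcf_pos + 30, genome.length(r.chrom)))
        _, trimmed = mb.detect_tsd(ins, left, right, origin_seq=donors[r.donor].sequence)
        after = mb.find_origin(trimmed, refd)
        assert after is not None
        assert after.identity >= (before.identity if before else 0.0)


def test_cell_fraction_bins():
    ins = pd.DataFrame(
        {
            "length_class": ["class_900"] * 3 + ["class_5500"],
            "allele_frequency": [1.0, 0.5, 0.02, 1.0],
        }
    )
    out = mb.cell_fraction_bins(ins)
    c9 = out["class_900"]
    assert c9.iloc[19] == pytest.approx(1 / 3)  # AF 1.0 -> top bin
    assert c9.iloc[9] == pytest.approx(1 / 3)  # AF 0.5 -> (0.45, 0.50]
    assert c9.iloc[0] == pytest.approx(1 / 3)  # AF 0.02 -> first bin
    empty = mb.cell_fraction_bins(ins.iloc[:0])
    assert list(empty.columns) == ["bin_start", "bin_end"]
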