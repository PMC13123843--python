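"""Shared fixtures: simulated cohorts reused across test modules."""

from __future__ import annotations

import pytest

from clonemosaic import simclone as sc


SMALL_GENOME = dict(
    n_chromosomes=2,
    chromosome_length=40_000,
    het_rate=0.02,
    telomere_repeat_count=150,
    genes_per_chromosome=6,
)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-shaped cohort (noise-free observation model), rendered
    in both reference modes; shared read-only across tests."""
    tree = sc.default_tree()
    genome, truth = sc.simulate_lineage(
        None,
        tree,
        sc.default_instability_spec(),
        sc.default_te_spec(tree),
        sc.default_layer_spec(),
        seed=11,
    )
    obs_primary = sc.render_observations(
        genome, truth, sc.ObservationModel(artifact_rate=0.0, seed=12), "primary", sv_samples=("E1", "T1", "T2")
    )
    obs_concat = sc.render_observations(
        genome, truth, sc.ObservationModel(artifact_rate=0.0, seed=13), "concatenated", sv_samples=("E1", "T1", "T2")
    )
    return dict(tree=tree, genome=genome, truth=truth, primary=obs_primary, concatenated=obs_concat)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """Small written-to-disk cohort for I/O round-trip and CLI tests."""
    out = tmp_path_factory.mktemp("fixtures") / "cohort"
    cfg = sc.default_config()
    cfg["genome"] = dict(SMALL_GENOME, unmappable_fraction=0.05)
    cfg["reads_samples"] = ["E1", "S1985"]
    cfg["tpm"] = {"n_per_chrom": 100}
    genome, truth = sc.write_fixtures(str(out), cfg, seed=3)
    return dict(path=out, genome=genome, truth=truth, cfg=cfg)
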