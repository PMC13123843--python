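"""De novo vs ancestral classification by clone-group sharing.

All clones descend from one zygote, so an allelic difference present in
more than one independently propagated group (somatic embryos, shoot
cultures, field trees) is ancestral heterozygosity, not new mutation. The
classification is a pure function of the carrier-sample set and the
sample -> group map:

primary-assembly mode
    carriers spanning >1 group -> ancestral; carriers only within the
    embryo group (any number; all embryos descend from one founder embryo)
    -> de novo; sharing between >=2 shoots, or >=2 trees, -> removed as
    likely ancestral (those propagations are independent); remaining
    shoot/tree singletons -> de novo.

concatenated-haplotype mode
    both haplotypes are in the reference, so *any* cross-group sharing is
    dubious and removed; embryo-internal sharing is still de novo.

Structural variants are matched across samples with positional/length
tolerance; singleton SVs are de novo, shared SVs ancestral.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUS_ANCESTRAL = "ancestral"
STATUS_DE_NOVO = "de_novo"
STATUS_REMOVED_WITHIN = "removed_within_group_shared"
STATUS_REMOVED_CROSS = "removed_cross_group"


def _classify_carriers(carriers: frozenset, groups: dict[str, str], mode: str, embryo_requires_all: bool = False,
                       n_embryos: int | None = None) -> str:
    if not carriers:
        raise ValueError("empty carrier set")
    for s in carriers:
        if s not in groups:
            raise KeyError(f"carrier sample {s!r} missing from the group map")
    gset = {groups[s] for s in carriers}
    if len(gset) > 1:
        return STATUS_ANCESTRAL if mode == "primary" else STATUS_REMOVED_CROSS
    (g,) = gset
    if g == "embryo":
        if embryo_requires_all and n_embryos is not None and len(carriers) not in (1, n_embryos):
            return STATUS_REMOVED_WITHIN
        return STATUS_DE_NOVO
    # shoot / tree: independent propagations, so within-group sharing is
    # almost surely ancestral; singletons are de novo
    return STATUS_DE_NOVO if len(carriers) == 1 else STATUS_REMOVED_WITHIN


def classify_sites(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    mode: str = "primary",
    embryo_requires_all: bool = False,
) -> pd.DataFrame:
    """Append ``status`` and ``singleton`` columns to a site matrix.

    ``embryo_requires_all`` is a strictness switch: when set, embryo-shared
    variants are only de novo if carried by a single embryo or by all of
    them (partial sharing removed); the default accepts any embryo-only
    carrier set as de novo.
    """
    if mode not in ("primary", "concatenated"):
        raise ValueError(f"unknown mode {mode!r}")
    n_embryos = sum(1 for g in groups.values() if g == "embryo")
    out = matrix.copy()
    out["status"] = [
        _classify_carriers(c, groups, mode, embryo_requires_all, n_embryos) for c in out["carriers"]
    ]
    out["singleton"] = out["carriers"].map(len) == 1
    out["mode"] = mode
    return out


def classify_primary(matrix: pd.DataFrame, groups: dict[str, str], **kw) -> pd.DataFrame:
    return classify_sites(matrix, groups, mode="primary", **kw)


def classify_concatenated(matrix: pd.DataFrame, groups: dict[str, str], **kw) -> pd.DataFrame:
    return classify_sites(matrix, groups, mode="concatenated", **kw)


def de_novo_sites(classified: pd.DataFrame) -> pd.DataFrame:
    return classified[classified["status"] == STATUS_DE_NOVO].reset_index(drop=True)


# ---------------------------------------------------------------------------
# structural variants


def classify_sv(
    sv_tables: dict[str, pd.DataFrame],
    pos_tolerance: int = 10,
    length_tolerance_frac: float = 0.01,
) -> pd.DataFrame:
    """Single-linkage match of SV insertions across samples; singletons are
    de novo. Identity requires same contig, |delta pos| <= ``pos_tolerance``
    and length within ``length_tolerance_frac`` (relative to the larger).

    Expects per-sample frames with at least chrom, pos, length (and
    whatever payload columns, which are kept from one representative).
    """
    if len(sv_tables) < 2:
        raise ValueError("need SV calls from >=2 samples")
    frames = []
    for s, t in sorted(sv_tables.items()):
        t = t.copy()
        t["sample"] = s
        frames.append(t)
    allsv = pd.concat(frames, ignore_index=True).sort_values(["chrom", "pos"], kind="mergesort")

    cluster_id = np.full(len(allsv), -1)
    next_id = 0
    chrom = allsv["chrom"].to_numpy()
    pos = allsv["pos"].to_numpy()
    length = allsv["length"].to_numpy(dtype=float)
    order = np.arange(len(allsv))
    for i in order:
        if cluster_id[i] >= 0:
            continue
        cluster_id[i] = next_id
        for j in order[i + 1 :]:
            if chrom[j] != chrom[i] or pos[j] - pos[i] > pos_tolerance:
                break
            if cluster_id[j] >= 0:
                continue
            if abs(length[j] - length[i]) <= length_tolerance_frac * max(length[i], length[j]):
                cluster_id[j] = next_id
        next_id += 1
    allsv = allsv.assign(cluster=cluster_id)

    rows = []
    for cid, sub in allsv.groupby("cluster", sort=True):
        carriers = frozenset(sub["sample"])
        rep = sub.iloc[0]
        rows.append(
            {
                **{c: rep[c] for c in sub.columns if c not in ("sample", "cluster")},
                "carriers": carriers,
                "n_carriers": len(carriers),
                "status": STATUS_DE_NOVO if len(carriers) == 1 else STATUS_ANCESTRAL,
                "sample": rep["sample"],
            }
        )
    return pd.DataFrame(rows)


def de_novo_svs(classified_svs: pd.DataFrame) -> pd.DataFrame:
    return classified_svs[classified_svs["status"] == STATUS_DE_NOVO].reset_index(drop=True)


# ---------------------------------------------------------------------------
# validation harness against simulator truth


def recover_classification(
    classified: pd.DataFrame,
    truth,
    observations,
) -> dict:
    """Confusion summary of classified calls against simulator truth.

    Known blind spot: embryo mutations deposited before the shoot/tree
    split would be shared across groups and thus classified ancestral; the
    default simulated history has no such branch, so recall there is exact.
    Returns per-status counts split by truth origin (de novo truth /
    ancestral-het / artifact) plus precision and recall for de novo calls.
    """
    # map observed sites back to truth via the rendered mut_id annotations
    id_maps = []
    for sample, df in observations.variants.items():
        id_maps.append(df[["chrom", "pos", "ref", "alt", "mut_id", "is_artifact"]])
    ids = pd.concat(id_maps, ignore_index=True)
    # a site key may appear as both a truth record and (rarely) an artifact
    # in another sample; attribute it to the strongest origin
    prio = np.where(ids["mut_id"] >= 0, 0, np.where(~ids["is_artifact"], 1, 2))
    ids = ids.assign(_prio=prio).sort_values("_prio", kind="mergesort")
    ids = ids.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).drop(columns="_prio")
    merged = classified.merge(ids, on=["chrom", "pos", "ref", "alt"], how="left")
    merged["origin"] = np.where(
        merged["is_artifact"].fillna(False),
        "artifact",
        np.where(merged["mut_id"].fillna(-1) >= 0, "true_de_novo", "ancestral_het"),
    )
    confusion = merged.groupby(["origin", "status"]).size().unstack(fill_value=0)
    called = merged[merged["status"] == STATUS_DE_NOVO]
    n_true = int((merged["origin"] == "true_de_novo").sum())
    tp = int((called["origin"] == "true_de_novo").sum())
    return {
        "confusion": confusion,
        "precision": tp / len(called) if len(called) else np.nan,
        "recall": tp / n_true if n_true else np.nan,
        "artifact_passthrough": int((called["origin"] == "artifact").sum()),
    }
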