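"""Chromosome-scale instability from phased ancestral heterozygosity.

At a heterozygous site of a diploid the two haplotypes each contribute half
the reads, so in fixed-count windows along a chromosome the summed
haplotype-A and haplotype-B depths should split 0.5/0.5 (chi-square, 1 df,
no continuity correction). Instability leaves characteristic windowed
signatures:

    trisomy                 depth ~1.5x, allele frequency ~2/3 toward the
                            duplicated haplotype, chromosome-wide
    segmental deletion      depth ~0.5x over the interval, AF ~1 toward the
                            retained haplotype
    copy-neutral            AF shifted distal to a breakpoint with depth
    recombination           ratio ~1 (one haplotype replaced the other)

Calls are made from runs of consecutive Bonferroni-significant windows in a
consistent direction. Trisomies are dated by splitting shared de novo
mutations phased to the duplicated haplotype into pre-duplication (present
on both copies, cell-fraction AF ~1 on the duplicated contig) and
post-duplication (one copy, AF ~0.5); a lost trisomy is recognized by a
clade that lacks the trisomy yet retains post-duplication mutations shared
with trisomic relatives. Expression consequences are quantified from TPM
tables (chromosome-level medians; gene-level Welch t tests with
Benjamini-Hochberg control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phylo import Clade


def window_statistics(
    phased_sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_windows: int = 250,
) -> pd.DataFrame:
    """Fixed-count equal-width windows of phased-het allele frequency/depth.

    Per window: mean allele frequency (haplotype-B read fraction averaged
    over covered sites), summed haplotype depths, per-site mean depth, and
    a chi-square test (1 df) of the depth sums against the diploid 0.5/0.5
    expectation. Windows with no covered site are kept as missing rows and
    excluded from testing.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    out = []
    for chrom, L in chrom_lengths.items():
        edges = np.linspace(0, L, n_windows + 1)
        starts = np.floor(edges[:-1]).astype(np.int64) + 1
        ends = np.floor(edges[1:]).astype(np.int64)
        sub = phased_sites[phased_sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        da = sub["depth_a"].to_numpy(dtype=float)
        db = sub["depth_b"].to_numpy(dtype=float)
        tot = da + db
        widx = np.clip(np.searchsorted(ends, pos, side="left"), 0, n_windows - 1)
        live = tot > 0
        n_sites = np.bincount(widx, minlength=n_windows)
        sum_a = np.bincount(widx, weights=da, minlength=n_windows)
        sum_b = np.bincount(widx, weights=db, minlength=n_windows)
        af_site = np.zeros_like(tot)
        af_site[live] = db[live] / tot[live]
        n_live = np.bincount(widx[live], minlength=n_windows)
        mean_af = np.full(n_windows, np.nan)
        nz = n_live > 0
        mean_af[nz] = np.bincount(widx[live], weights=af_site[live], minlength=n_windows)[nz] / n_live[nz]
        tot_w = sum_a + sum_b
        chi2 = np.full(n_windows, np.nan)
        p = np.full(n_windows, np.nan)
        ok = tot_w > 0
        exp = tot_w[ok] / 2.0
        chi2[ok] = (sum_a[ok] - exp) ** 2 / exp + (sum_b[ok] - exp) ** 2 / exp
        p[ok] = stats.chi2.sf(chi2[ok], df=1)
        mean_site_depth = np.full(n_windows, np.nan)
        mean_site_depth[nz] = tot_w[nz] / n_live[nz]
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window": np.arange(n_windows),
                    "start": starts,
                    "end": ends,
                    "n_sites": n_sites,
                    "mean_af": mean_af,
                    "depth_a": sum_a.astype(np.int64),
                    "depth_b": sum_b.astype(np.int64),
                    "chi2": chi2,
                    "p": p,
                    "mean_site_depth": mean_site_depth,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class InstabilityCall:
    sample: str
    chrom: str
    haplotype: str
    kind: str  # trisomy | segmental_gain | segmental_deletion | copy_neutral_recombination
    start: int
    end: int
    first_window: int
    last_window: int
    depth_ratio: float
    mean_af: float


def call_instability(
    windows_by_sample: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    min_run: int = 20,
    max_gap: int = 2,
    gain_ratio: float = 1.25,
    loss_ratio: float = 0.75,
    whole_chrom_frac: float = 0.9,
) -> pd.DataFrame:
    """Classify per (sample, chromosome) against the three evidence
    signatures using run-length rules over Bonferroni-significant windows.

    A window is significant at p < alpha / (valid windows on the
    chromosome); runs of >= ``min_run`` consecutive significant windows
    with a consistent allele-frequency direction become calls. The depth
    ratio over the run (per-site mean depth vs the sample's genome-wide
    median) separates gain / loss / copy-neutral; the AF direction names
    the haplotype. Balanced chromosomes yield no call.
    """
    calls: list[InstabilityCall] = []
    for sample, win in windows_by_sample.items():
        valid_all = win[win["n_sites"] > 0]
        baseline = float(np.nanmedian(valid_all["mean_site_depth"]))
        for chrom, sub in win.groupby("chrom", sort=True):
            sub = sub.sort_values("window")
            valid = sub["p"].notna()
            n_valid = int(valid.sum())
            if n_valid == 0:
                continue
            thr = alpha / n_valid
            sig = ((sub["p"] < thr) & valid).to_numpy()
            direction = np.sign(sub["mean_af"] - 0.5).to_numpy()
            sig_dir = np.where(sig, direction, 0.0)
            n = len(sub)
            # group significant windows of one direction, tolerating short
            # gaps of non-significant windows (sparse windows fluctuate)
            runs: list[tuple[int, int, int]] = []  # (first, last, n_sig)
            cur = None
            for w in range(n):
                if sig_dir[w] == 0:
                    continue
                if cur is not None and sig_dir[w] == cur[3] and w - cur[1] <= max_gap + 1:
                    cur = (cur[0], w, cur[2] + 1, cur[3])
                else:
                    if cur is not None:
                        runs.append(cur[:3])
                    cur = (w, w, 1, sig_dir[w])
            if cur is not None:
                runs.append(cur[:3])
            for i, j, n_sig in runs:
                if n_sig >= min_run:
                    run = sub.iloc[i : j + 1]
                    ratio = float(np.nanmean(run["mean_site_depth"])) / baseline
                    af = float(np.nanmean(run["mean_af"]))
                    span_frac = (j - i + 1) / n
                    if ratio >= gain_ratio:
                        kind = "trisomy" if span_frac >= whole_chrom_frac else "segmental_gain"
                        hap = "B" if af > 0.5 else "A"
                    elif ratio <= loss_ratio:
                        kind = "segmental_deletion"
                        hap = "A" if af > 0.5 else "B"  # the depleted haplotype
                    else:
                        kind = "copy_neutral_recombination"
                        hap = "A" if af > 0.5 else "B"  # the replaced (lost) haplotype
                    calls.append(
                        InstabilityCall(
                            sample=sample,
                            chrom=chrom,
                            haplotype=hap,
                            kind=kind,
                            start=int(run["start"].iloc[0]),
                            end=int(run["end"].iloc[-1]),
                            first_window=int(run["window"].iloc[0]),
                            last_window=int(run["window"].iloc[-1]),
                            depth_ratio=ratio,
                            mean_af=af,
                        )
                    )
    cols = [
        "sample", "chrom", "haplotype", "kind", "start", "end",
        "first_window", "last_window", "depth_ratio", "mean_af",
    ]
    return pd.DataFrame([c.__dict__ for c in calls], columns=cols)


# ---------------------------------------------------------------------------
# trisomy dating and loss detection


@dataclass
class TrisomyDating:
    n_pre: int
    n_post: int
    n_excluded: int
    ratio_post_pre: float  # inf guard: np.inf when n_pre == 0
    low_confidence: bool
    all_pre: bool
    lower_bound_only: bool


def date_trisomy(
    dup_hap_afs,
    pre_threshold: float = 0.9,
    post_threshold: float = 0.6,
    min_informative: int = 5,
) -> TrisomyDating:
    """Split duplicated-haplotype shared mutations into pre-/post-duplication.

    ``dup_hap_afs`` are concatenated-mode allele frequencies on the
    duplicated haplotype's contig: a mutation on both duplicated copies
    (pre-duplication) sits near 1.0, one copy (post-duplication) near 0.5.
    A midpoint classifier with an excluded uncertainty band
    [post_threshold, pre_threshold] is used; the band is a stated stand-in
    for an unpublished procedure and is configurable.
    """
    afs = np.asarray(list(dup_hap_afs), dtype=float)
    pre = int((afs > pre_threshold).sum())
    post = int((afs < post_threshold).sum())
    excluded = int(afs.size - pre - post)
    ratio = np.inf if pre == 0 else post / pre
    return TrisomyDating(
        n_pre=pre,
        n_post=post,
        n_excluded=excluded,
        ratio_post_pre=float(ratio) if np.isfinite(ratio) else np.inf,
        low_confidence=(pre + post) < min_informative,
        all_pre=(post == 0 and pre > 0),
        lower_bound_only=(pre == 0 and post > 0),
    )


@dataclass
class TrisomyLossResult:
    interpretation: str  # gain_then_loss | independent_gains | single_gain | no_trisomy
    gain_clade: frozenset | None
    loss_clades: list[frozenset] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)  # loss clade -> retained post-dup shared mutations
    n_independent_gains: int = 0
    parsimony: dict = field(default_factory=dict)


def detect_trisomy_loss(
    tree: Clade,
    trisomic_samples: set[str],
    dup_hap_mutations: pd.DataFrame,
    min_support: int = 1,
) -> TrisomyLossResult:
    """Decide between one gain (with later losses) and independent gains.

    ``dup_hap_mutations`` needs ``carriers`` (frozenset) and
    ``post_duplication`` (bool) columns for de novo mutations phased to the
    duplicated haplotype. A maximal non-trisomic subclade inside the
    minimal clade containing all trisomic samples is a loss candidate; it
    is accepted when >= ``min_support`` post-duplication mutations are
    shared between it and trisomic samples (they rode the duplicated
    chromosome before the loss). With no such evidence the most
    parsimonious reading is independent gains.
    """
    trisomic = set(trisomic_samples)
    if not trisomic:
        return TrisomyLossResult(interpretation="no_trisomy", gain_clade=None)
    # minimal clade containing all trisomic samples
    gain_node = None
    for node in tree.walk():
        lv = node.leaves()
        if trisomic <= lv and (gain_node is None or len(lv) < len(gain_node.leaves())):
            gain_node = node
    gain_clade = gain_node.leaves()
    non_trisomic = gain_clade - trisomic
    if not non_trisomic:
        return TrisomyLossResult(interpretation="single_gain", gain_clade=gain_clade)

    # maximal non-trisomic subclades within the gain clade
    loss_candidates: list[frozenset] = []

    def collect(node: Clade):
        lv = node.leaves()
        if not (lv & trisomic):
            loss_candidates.append(lv)
            return
        for c in node.children:
            collect(c)

    collect(gain_node)

    evidence = {}
    for cand in loss_candidates:
        support = 0
        for m in dup_hap_mutations.itertuples():
            if not m.post_duplication:
                continue
            if cand <= m.carriers and (m.carriers & trisomic):
                support += 1
        evidence[cand] = support

    losses = [c for c, s in evidence.items() if s >= min_support]
    # independent-gains alternative: maximal all-trisomic clades
    gains: list[frozenset] = []

    def collect_gains(node: Clade):
        lv = node.leaves()
        if lv <= trisomic:
            gains.append(lv)
            return
        for c in node.children:
            collect_gains(c)

    collect_gains(tree)
    parsimony = {
        "gain_then_loss_events": 1 + len(loss_candidates),
        "independent_gain_events": len(gains),
    }
    if losses:
        return TrisomyLossResult(
            interpretation="gain_then_loss",
            gain_clade=gain_clade,
            loss_clades=sorted(losses, key=sorted),
            evidence=evidence,
            n_independent_gains=len(gains),
            parsimony=parsimony,
        )
    return TrisomyLossResult(
        interpretation="independent_gains",
        gain_clade=gain_clade,
        loss_clades=[],
        evidence=evidence,
        n_independent_gains=len(gains),
        parsimony=parsimony,
    )


# ---------------------------------------------------------------------------
# expression consequences


def chromosome_expression(tpm: pd.DataFrame, samples: list[str] | None = None, tpm_min: float = 1.0) -> pd.DataFrame:
    """Per-sample normalized chromosome-level expression.

    Transcripts are filtered at TPM strictly > ``tpm_min``; the median TPM
    per chromosome is normalized by the sample's mean of per-chromosome
    medians, so a balanced sample sits at 1.0 everywhere and a trisomic
    chromosome rises above 1. Chromosomes with no expressed transcript are
    missing.
    """
    if samples is None:
        samples = [c for c in tpm.columns if c not in ("transcript_id", "chrom", "pos")]
    rows = {}
    for s in samples:
        expressed = tpm[tpm[s] > tpm_min]
        med = expressed.groupby("chrom")[s].median()
        med = med.reindex(sorted(tpm["chrom"].unique()))
        rows[s] = med / med.mean()
    return pd.DataFrame(rows)


def clade_differential_expression(
    tpm: pd.DataFrame,
    clade_samples: list[str],
    other_samples: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript Welch's t test (two-sided) of a clade against the rest,
    with Benjamini-Hochberg FDR control at ``alpha``.

    Transcripts with zero variance in both groups and equal means get
    t = 0, p = 1 by convention (flagged in ``degenerate``).
    """
    if len(clade_samples) < 2 or len(other_samples) < 2:
        raise ValueError("need >= 2 samples on each side")
    a = tpm[clade_samples].to_numpy(dtype=float)
    b = tpm[other_samples].to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(np.isfinite(p), p, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    out = tpm[["transcript_id", "chrom"]].copy() if "transcript_id" in tpm.columns else pd.DataFrame(index=tpm.index)
    out["t"] = t
    out["p"] = p
    out["p_adj"] = p_adj
    out["neg_log10_p_adj"] = -np.log10(np.clip(p_adj, 1e-300, None))
    out["significant"] = p_adj < alpha
    out["degenerate"] = degenerate
    return out
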