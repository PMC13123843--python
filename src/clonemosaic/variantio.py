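"""Variant/annotation I/O and per-site cohort annotation.

Reads per-sample VCFs (via cyvcf2), GVCF-style depth-interval tables and a
{0,1} mappability BED, and reproduces the cohort-level per-site annotation
the downstream classification relies on: depths recomputed from allele
depths (total = ref AD + alt AD), allele frequency = alt AD / total,
median quality across carriers and median depth across the whole cohort
(non-carriers contribute their interval median depth at the position).

Coordinates are 1-based inclusive internally; BED's 0-based half-open
convention is converted at the boundary. Multiallelic records are
decomposed into one row per ALT allele, keeping per-allele AD, so the
carrier/group logic stays per-allele exact. Sites with zero recomputed
depth get a missing allele frequency (never 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "qual",
    "ref_depth",
    "alt_depth",
    "total_depth",
    "allele_frequency",
    "mappable",
    "variant_class",
]


class VariantParseError(ValueError):
    pass


def classify_variant(ref: str, alt: str) -> str:
    return "SBS" if len(ref) == 1 and len(alt) == 1 else "InDel"


def read_variants(vcf_path: str, sample: str | None = None) -> pd.DataFrame:
    """One row per biallelic ALT of a single-sample VCF.

    Depth fields are recomputed from the AD tag: total = ref AD + alt AD,
    allele frequency = alt AD / total (missing when total is 0). Records
    without allele depths are rejected.
    """
    vcf = VCF(vcf_path)
    if len(vcf.samples) != 1:
        raise VariantParseError(f"{vcf_path}: expected a single-sample VCF, found {vcf.samples}")
    rows = []
    for i, rec in enumerate(vcf):
        ad = rec.format("AD")
        if ad is None:
            raise VariantParseError(f"{vcf_path}: record {i + 1} at {rec.CHROM}:{rec.POS} lacks AD")
        ad = ad[0]
        if len(ad) < 1 + len(rec.ALT):
            raise VariantParseError(f"{vcf_path}: record {i + 1} AD has too few values")
        ref_depth = int(ad[0])
        for k, alt in enumerate(rec.ALT):
            alt_depth = int(ad[1 + k])
            total = ref_depth + alt_depth
            af = alt_depth / total if total > 0 else np.nan
            rows.append(
                (
                    rec.CHROM,
                    rec.POS,
                    rec.REF,
                    alt,
                    rec.QUAL if rec.QUAL is not None else np.nan,
                    ref_depth,
                    alt_depth,
                    total,
                    af,
                    True,  # until a mappability track is applied
                    classify_variant(rec.REF, alt),
                )
            )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df.attrs["sample"] = sample or vcf.samples[0]
    return df


def read_mappability(bed_path: str) -> pd.DataFrame:
    """Mappability BED (chrom, start, end, score in {0,1}) -> 1-based intervals."""
    bed = pd.read_csv(bed_path, sep="\t", header=None, names=["chrom", "start", "end", "score"])
    if not bed["score"].isin([0, 1]).all():
        raise VariantParseError(f"{bed_path}: mappability scores must be 0 or 1")
    bed["start"] = bed["start"] + 1  # to 1-based inclusive
    return bed


def apply_mappability(df: pd.DataFrame, bed: pd.DataFrame) -> pd.DataFrame:
    """Set the ``mappable`` flag from a {0,1} BED track.

    Contig names of the concatenated assembly (``chr1_A``) fall back to
    their base chromosome so one primary-coordinate track serves both modes.
    """
    out = df.copy()
    out["mappable"] = True
    zero = bed[bed["score"] == 0]
    base_chrom = out["chrom"].str.replace(r"_(A|B)$", "", regex=True)
    for r in zero.itertuples():
        sel = (base_chrom == r.chrom) & (out["pos"] >= r.start) & (out["pos"] <= r.end)
        out.loc[sel, "mappable"] = False
    return out


@dataclass
class RegionDepths:
    """Queryable position -> median-depth map from GVCF-style intervals."""

    intervals: pd.DataFrame  # chrom, start, end (1-based inclusive), median_depth

    def depth_at(self, chrom: str, pos) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos))
        out = np.full(pos.shape, np.nan)
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if len(sub):
            idx = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
            ok = idx >= 0
            ends = sub["end"].to_numpy()[np.clip(idx, 0, None)]
            ok &= pos <= ends
            out[ok] = sub["median_depth"].to_numpy()[idx[ok]]
        return out


def read_region_depths(path: str, sample: str | None = None) -> RegionDepths:
    """Read a depth-interval table (chrom, start, end, median_depth).

    Intervals within a contig must not overlap; an overlap is reported with
    the offending pair.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "median_depth"}
    if not required.issubset(df.columns):
        raise VariantParseError(f"{path}: expected columns {sorted(required)}")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        ends = sub["end"].to_numpy()
        starts = sub["start"].to_numpy()
        bad = np.nonzero(starts[1:] <= ends[:-1])[0]
        if bad.size:
            i = bad[0]
            raise VariantParseError(
                f"{path}: overlapping intervals on {chrom}: "
                f"[{starts[i]},{ends[i]}] and [{starts[i + 1]},{ends[i + 1]}]"
            )
    return RegionDepths(df)


SITE_KEY = ["chrom", "pos", "ref", "alt"]


def build_site_matrix(
    tables: dict[str, pd.DataFrame],
    depths: dict[str, RegionDepths] | None = None,
) -> pd.DataFrame:
    """Cohort site matrix: one row per (chrom, pos, ref, alt).

    Columns: ``carriers`` (frozenset of sample names), ``n_carriers``,
    ``median_quality`` (median over carrier QUALs), ``median_depth``
    (median over *all* cohort samples, carriers contributing their
    recomputed total depth and non-carriers their interval median depth),
    ``mappable`` (carriers must agree), ``variant_class``.
    """
    if not tables:
        raise ValueError("empty cohort: no sample tables given")
    samples = sorted(tables)
    frames = []
    for s in samples:
        if len(tables[s]) == 0:
            continue  # still counts toward cohort depth medians below
        t = tables[s].copy()
        t["sample"] = s
        frames.append(t)
    if not frames:
        raise ValueError("no variant records in any sample")
    allv = pd.concat(frames, ignore_index=True)

    sites = (
        allv.groupby(SITE_KEY, sort=True)
        .agg(
            median_quality=("qual", "median"),
            mappable=("mappable", "all"),
            variant_class=("variant_class", "first"),
            carriers=("sample", lambda s: frozenset(s)),
            n_carriers=("sample", "nunique"),
        )
        .reset_index()
    )

    # cohort-wide depth matrix: carriers contribute recomputed total depth,
    # non-carriers their GVCF-interval median depth at the position
    n_sites = len(sites)
    sidx = {s: j for j, s in enumerate(samples)}
    key_index = pd.MultiIndex.from_frame(sites[SITE_KEY])
    row_of = pd.Series(np.arange(n_sites), index=key_index)
    D = np.full((n_sites, len(samples)), np.nan)
    rows_all = row_of.loc[pd.MultiIndex.from_frame(allv[SITE_KEY])].to_numpy()
    cols_all = allv["sample"].map(sidx).to_numpy()
    D[rows_all, cols_all] = allv["total_depth"].to_numpy(dtype=float)
    if depths is not None:
        for s in samples:
            if s not in depths:
                continue
            j = sidx[s]
            for chrom in sites["chrom"].unique():
                sel = (sites["chrom"] == chrom).to_numpy()
                vals = depths[s].depth_at(chrom, sites.loc[sel, "pos"].to_numpy())
                fill = sel.copy()
                fill[sel] = np.isnan(D[sel, j])
                D[fill, j] = vals[np.isnan(D[sel, j])]
    with np.errstate(all="ignore"):
        sites["median_depth"] = np.nanmedian(D, axis=1)
    return sites[
        SITE_KEY + ["carriers", "n_carriers", "median_quality", "median_depth", "mappable", "variant_class"]
    ]


def write_sites_tsv(matrix: pd.DataFrame, path: str):
    """Serialize a site matrix (carriers as a ';'-joined sorted list)."""
    out = matrix.copy()
    out["carriers"] = out["carriers"].map(lambda c: ";".join(sorted(c)))
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_sites_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["carriers"] = df["carriers"].map(lambda c: frozenset(str(c).split(";")))
    return df


def apply_site_filters(
    matrix: pd.DataFrame,
    min_median_quality: float = 30.0,
    min_median_depth: float = 15.0,
    require_mappable: bool = True,
) -> pd.DataFrame:
    """Keep sites with median quality >= q, median depth >= d and (optionally)
    mappability 1. Thresholds are inclusive; the filter is monotone."""
    if min_median_quality < 0 or min_median_depth < 0:
        raise ValueError("thresholds must be nonnegative")
    keep = (matrix["median_quality"] >= min_median_quality) & (matrix["median_depth"] >= min_median_depth)
    if require_mappable:
        keep &= matrix["mappable"]
    return matrix[keep].reset_index(drop=True)
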