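"""Trinucleotide-context SBS spectra and signature matching.

Each single-base substitution is classified into one of 96 categories: 6
pyrimidine-centred substitution types (C>A, C>G, C>T, T>A, T>C, T>G) x 16
flanking contexts. Purine-centred substitutions are reverse-complemented
into the pyrimidine representation. Raw counts are normalized by how often
each trimer occurs in the reference (both strands collapsed onto the
pyrimidine-centred representation), yielding per-context rates comparable
across genomes of different composition; rates can then be matched against
known mutational-signature profiles by cosine similarity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import revcomp, str_to_idx

PYRIMIDINES = ("C", "T")
SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")

CATEGORIES_96 = tuple(
    f"{l}[{sub}]{r}" for sub in SUB_TYPES for l in _FLANKS for r in _FLANKS
)


def collapse_to_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Map an SBS with its +/-1 bp context onto the pyrimidine-centred strand.

    Idempotent: a pyrimidine-centred input comes back unchanged.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not centre on ref {ref!r}")
    if ref in PYRIMIDINES:
        return ref, alt, context
    return revcomp(ref), revcomp(alt), revcomp(context)


def category_of(ref: str, alt: str, context: str) -> str:
    ref, alt, context = collapse_to_pyrimidine(ref, alt, context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def count_reference_trimers(sequences) -> pd.Series:
    """Pyrimidine-centred trimer counts over both strands of a reference.

    ``sequences`` is an iterable of sequence strings (e.g. primary-assembly
    chromosomes). A purine-centred trimer occurrence counts toward its
    reverse complement, so the result has 32 keys.
    """
    counts = np.zeros(64, dtype=np.int64)
    for seq in sequences:
        idx = str_to_idx(seq)
        if idx.size < 3:
            continue
        code = 16 * idx[:-2].astype(np.int64) + 4 * idx[1:-1] + idx[2:]
        counts += np.bincount(code, minlength=64)
    out = {}
    bases = "ACGT"
    for code in range(64):
        l, c, r = bases[code // 16], bases[(code // 4) % 4], bases[code % 4]
        tri = l + c + r
        canonical = tri if c in PYRIMIDINES else revcomp(tri)
        out[canonical] = out.get(canonical, 0) + int(counts[code])
    return pd.Series(out).sort_index()


def tricontext_spectrum(
    sbs_calls: pd.DataFrame,
    reference,
    sample: str | None = None,
) -> pd.DataFrame:
    """96-category spectrum of SBS calls with reference-trimer normalization.

    ``reference`` is a pyfaidx.Fasta (or any mapping chrom -> sliceable
    sequence) in the coordinate system of the calls. Calls at a chromosome
    end without +/-1 bp context are excluded; their count is stored in
    ``df.attrs['excluded_no_context']``. Categories whose reference trimer
    count is zero keep a missing rate (flagged, never divided).
    """
    counts = dict.fromkeys(CATEGORIES_96, 0)
    excluded = 0
    for r in sbs_calls.itertuples():
        if len(r.ref) != 1 or len(r.alt) != 1:
            continue
        seq = reference[r.chrom]
        if r.pos < 2 or r.pos + 1 > len(seq):
            excluded += 1
            continue
        context = str(seq[r.pos - 2 : r.pos + 1]).upper()
        counts[category_of(r.ref, r.alt, context)] += 1

    trimers = count_reference_trimers(str(reference[c][:]).upper() for c in _contig_names(reference))
    df = pd.DataFrame({"category": CATEGORIES_96})
    df["sub_type"] = df["category"].str[2:5]
    df["trimer"] = df["category"].str[0] + df["category"].str[2] + df["category"].str[6]
    df["count"] = df["category"].map(counts)
    df["trimer_count"] = df["trimer"].map(trimers).fillna(0).astype(np.int64)
    df["zero_reference_trimer"] = df["trimer_count"] == 0
    with np.errstate(all="ignore"):
        df["rate"] = np.where(df["trimer_count"] > 0, df["count"] / df["trimer_count"], np.nan)
    df.attrs["excluded_no_context"] = excluded
    df.attrs["sample"] = sample
    return df


def _contig_names(reference):
    keys = getattr(reference, "keys", None)
    return list(keys()) if callable(keys) else list(reference)


def spectrum_similarity(spectrum: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of a normalized spectrum against profile columns.

    ``catalog`` rows are the 96 categories (index or a ``category``
    column); each profile column sums to 1. The spectrum's rate vector is
    rescaled to sum 1 before comparison. Returns profiles ranked by
    descending similarity.
    """
    if "category" in catalog.columns:
        catalog = catalog.set_index("category")
    v = spectrum.set_index("category")["rate"].reindex(catalog.index).fillna(0.0).to_numpy()
    if not np.isfinite(v).all() or v.sum() <= 0:
        raise ValueError("spectrum rate vector is zero/undefined; cannot compute similarity")
    v = v / v.sum()
    rows = []
    for name in catalog.columns:
        u = catalog[name].to_numpy(dtype=float)
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            raise ValueError(f"profile {name} is a zero vector")
        rows.append((name, float(np.dot(u, v) / denom)))
    out = pd.DataFrame(rows, columns=["profile", "cosine_similarity"])
    return out.sort_values("cosine_similarity", ascending=False, kind="mergesort").reset_index(drop=True)
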