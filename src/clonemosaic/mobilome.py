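"""De novo TE insertion characterization and insertion-site bias testing.

Given de novo SV insertions (full inserted sequences), this module:
clusters them into length classes (the recurrent ~900 bp and ~5,500 bp
elements); locates each insertion's origin in the haplotype-phased
reference by seeded exact-k-mer anchoring plus banded alignment (edlib);
detects and trims the target-site duplication (TSD) the integration
machinery copies from the insertion site; flags insertions whose two
halves both match the origin (transposition followed by tandem
duplication); annotates insertion sites against a GFF3 annotation
(multi-label: an exonic hit also counts as genic); tests feature bias
against a permutation null in which every insertion is re-placed uniformly
at random on its own chromosome; and bins insertions by the fraction of
cells carrying them (allele frequency on the phased assembly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import gffutils
import numpy as np
import pandas as pd

from ._util import revcomp

FEATURE_CATEGORIES = (
    "gene",
    "exon",
    "intron",
    "five_prime_UTR",
    "three_prime_UTR",
    "upstream",
    "downstream",
    "intergenic",
)

LENGTH_CLASS_CENTERS = {"class_900": 900, "class_5500": 5500}


def classify_by_length(lengths, centers: dict[str, int] | None = None, window_frac: float = 0.15) -> list[str]:
    """Assign each insertion length to a histogram-peak window (center
    +/- ``window_frac``); lengths outside every window are ``other``."""
    centers = centers or LENGTH_CLASS_CENTERS
    out = []
    for L in lengths:
        label = "other"
        for name, c in centers.items():
            if abs(L - c) <= window_frac * c:
                label = name
                break
        out.append(label)
    return out


# ---------------------------------------------------------------------------
# origin search


@dataclass
class OriginHit:
    contig: str
    start: int  # 1-based
    end: int
    strand: str
    identity: float


def _identity(query: str, target: str) -> tuple[float, tuple[int, int] | None]:
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, None
    return 1.0 - res["editDistance"] / len(query), res["locations"][0]


def find_origin(
    insertion_seq: str,
    reference: dict[str, str],
    k: int = 21,
    anchor_step: int = 100,
    min_identity: float = 0.9,
) -> OriginHit | None:
    """Best full-length match of an insertion in a (phased) reference.

    Seeded search: exact ``k``-mers sampled every ``anchor_step`` bp from
    the query (forward and reverse complement) anchor candidate loci, which
    are then scored by banded alignment over a padded window; the best hit
    is returned if its identity reaches ``min_identity``, else None
    (origin unknown, insertion retained).
    """
    q = insertion_seq.upper()
    if len(q) < k:
        return None
    best: OriginHit | None = None
    for strand, qs in (("+", q), ("-", revcomp(q))):
        offsets = list(range(0, len(qs) - k + 1, anchor_step)) + [len(qs) - k]
        candidates: dict[tuple[str, int], None] = {}
        for o in offsets:
            anchor = qs[o : o + k]
            for contig, seq in reference.items():
                start = 0
                while True:
                    h = seq.find(anchor, start)
                    if h < 0:
                        break
                    candidates[(contig, max(0, (h - o) // 50 * 50))] = None
                    start = h + 1
        pad = max(50, len(qs) // 10)
        for contig, approx in candidates:
            seq = reference[contig]
            lo = max(0, approx - pad)
            hi = min(len(seq), approx + len(qs) + pad)
            ident, loc = _identity(qs, seq[lo:hi])
            if loc is None:
                continue
            if best is None or ident > best.identity:
                best = OriginHit(
                    contig=contig,
                    start=lo + loc[0] + 1,
                    end=lo + loc[1] + 1,
                    strand=strand,
                    identity=ident,
                )
    if best is not None and best.identity >= min_identity:
        return best
    return None


# ---------------------------------------------------------------------------
# target-site duplications and tandem duplications


def detect_tsd(
    insertion_seq: str,
    left_flank: str,
    right_flank: str,
    min_len: int = 4,
    max_len: int = 20,
    origin_seq: str | None = None,
) -> tuple[str, str]:
    """Duplicated motif consistent with TSD geometry; returns
    (tsd_sequence, trimmed_insertion), ("" , unchanged) when none found.

    An integration with an L-bp TSD leaves the motif both in the reference
    flank and at one end of the called inserted sequence: a right-aligned
    call carries it as the insertion's suffix (equal to the left flank's
    suffix), a left-aligned call as its prefix (equal to the right flank's
    prefix).

    Flank matching alone is ambiguous when the element's end happens to
    match the flank one base further, so when the origin sequence is known
    (from the origin search) the donor/TSD boundary is fixed by aligning
    the origin into the insertion and the residue is verified against the
    flank; without an origin the longest exact flank match wins.
    """
    ins = insertion_seq.upper()
    lf = left_flank.upper()
    rf = right_flank.upper()
    if origin_seq:
        best = None
        for o in (origin_seq.upper(), revcomp(origin_seq.upper())):
            res = edlib.align(o, ins, mode="HW", task="locations")
            if res["editDistance"] >= 0 and res["locations"]:
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], res["locations"][0])
        if best is not None:
            s, e = best[1]
            tail = ins[e + 1 :]
            head = ins[:s]
            if min_len <= len(tail) <= max_len and len(tail) <= len(lf) and tail == lf[-len(tail) :]:
                return tail, ins[: e + 1]
            if min_len <= len(head) <= max_len and len(head) <= len(rf) and head == rf[: len(head)]:
                return head, ins[s:]
    for L in range(min(max_len, len(ins) - 1, max(len(lf), len(rf))), min_len - 1, -1):
        if L <= len(lf) and ins[-L:] == lf[-L:]:
            return ins[-L:], ins[:-L]
        if L <= len(rf) and ins[:L] == rf[:L]:
            return ins[:L], ins[L:]
    return "", ins


def detect_tandem_duplication(
    insertion_seq: str,
    origin_seq: str,
    min_identity: float = 0.9,
    length_tol: float = 0.15,
) -> bool:
    """True iff both halves of the insertion independently match the origin
    and the insertion is about twice the origin length."""
    n = len(insertion_seq)
    if abs(n - 2 * len(origin_seq)) > length_tol * 2 * len(origin_seq):
        return False
    first, second = insertion_seq[: n // 2], insertion_seq[n // 2 :]
    id1, _ = _identity(first, origin_seq)
    id2, _ = _identity(second, origin_seq)
    return id1 >= min_identity and id2 >= min_identity


def donor_consensus(insertion_seqs: list[str], min_agreement: float = 0.9) -> str | None:
    """Element boundary from multiple insertions of the same origin.

    Insertions of one element at different sites share the element itself
    as a common prefix (in insert orientation) while their target-site
    duplications differ, so position-wise agreement collapses exactly at
    the element/TSD boundary. Returns the consensus element sequence, or
    None with fewer than 3 members (no consensus power).
    """
    if len(insertion_seqs) < 3:
        return None
    min_len = min(len(s) for s in insertion_seqs)
    out = []
    n = len(insertion_seqs)
    for i in range(min_len):
        freq: dict[str, int] = {}
        for s in insertion_seqs:
            freq[s[i]] = freq.get(s[i], 0) + 1
        base, count = max(freq.items(), key=lambda kv: kv[1])
        if count / n < min_agreement:
            break
        out.append(base)
    return "".join(out) if out else None


def characterize_insertions(
    events: pd.DataFrame,
    reference: dict[str, str],
    flank: int = 30,
    min_identity: float = 0.9,
) -> pd.DataFrame:
    """Full per-insertion characterization: origin, TSD, tandem duplication.

    Expects columns chrom, pos, seq. Origins are found per insertion; the
    element/TSD boundary is then refined by a class consensus over
    insertions sharing an origin locus and strand (falling back to the
    aligned origin span for loci with < 3 insertions), the TSD is trimmed,
    and doubled-element insertions are flagged.
    """
    ev = events.reset_index(drop=True).copy()
    hits = [find_origin(s, reference, min_identity=min_identity) for s in ev["seq"]]
    group_key = [
        (h.contig, h.strand, round(h.start / 200)) if h else None for h in hits
    ]
    consensus: dict[tuple, str | None] = {}
    for key in set(k for k in group_key if k):
        members = [ev.loc[i, "seq"] for i, k in enumerate(group_key) if k == key]
        consensus[key] = donor_consensus(members)

    origins, tsds, trimmed_seqs, tandems = [], [], [], []
    for i, r in enumerate(ev.itertuples()):
        h = hits[i]
        contig_seq = reference.get(r.chrom, "")
        left = contig_seq[max(0, r.pos - flank): r.pos]
        right = contig_seq[r.pos: r.pos + flank]
        origin_seq = None
        if h is not None:
            origin_seq = consensus.get(group_key[i]) or reference[h.contig][h.start - 1: h.end]
        tsd, trimmed = detect_tsd(r.seq, left, right, origin_seq=origin_seq)
        tandem = h is not None and detect_tandem_duplication(trimmed, origin_seq)
        origins.append(h)
        tsds.append(tsd)
        trimmed_seqs.append(trimmed)
        tandems.append(tandem)
    ev["origin_contig"] = [h.contig if h else None for h in origins]
    ev["origin_start"] = [h.start if h else -1 for h in origins]
    ev["origin_end"] = [h.end if h else -1 for h in origins]
    ev["origin_strand"] = [h.strand if h else "." for h in origins]
    ev["origin_identity"] = [h.identity if h else np.nan for h in origins]
    ev["tsd"] = tsds
    ev["tsd_len"] = [len(t) for t in tsds]
    ev["trimmed_seq"] = trimmed_seqs
    ev["tandem_duplication"] = tandems
    return ev


# ---------------------------------------------------------------------------
# feature annotation


def feature_masks(gff3_path: str, chrom_lengths: dict[str, int], flank: int = 1000) -> dict[str, dict[str, np.ndarray]]:
    """Per-chromosome boolean membership arrays for each feature category.

    Introns are gene minus exon; upstream/downstream are strand-aware
    ``flank``-bp windows beyond the gene; intergenic is everything not in a
    gene or its flanks. A malformed feature hierarchy (sub-feature outside
    any gene) is reported with the feature id.
    """
    db = gffutils.create_db(gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True)
    masks = {
        chrom: {cat: np.zeros(L, dtype=bool) for cat in FEATURE_CATEGORIES}
        for chrom, L in chrom_lengths.items()
    }
    genes = list(db.features_of_type("gene"))
    gene_spans = {g.id: (g.seqid, g.start, g.end) for g in genes}
    for g in genes:
        if g.seqid not in masks:
            continue
        m = masks[g.seqid]
        L = chrom_lengths[g.seqid]
        m["gene"][g.start - 1 : g.end] = True
        if g.strand == "+":
            up = (max(1, g.start - flank), g.start - 1)
            down = (g.end + 1, min(L, g.end + flank))
        else:
            up = (g.end + 1, min(L, g.end + flank))
            down = (max(1, g.start - flank), g.start - 1)
        for (s, e), cat in ((up, "upstream"), (down, "downstream")):
            if s <= e:
                m[cat][s - 1 : e] = True
    for ftype, cat in (("exon", "exon"), ("five_prime_UTR", "five_prime_UTR"), ("three_prime_UTR", "three_prime_UTR")):
        for f in db.features_of_type(ftype):
            if f.seqid not in masks:
                continue
            inside = any(
                s == f.seqid and gs <= f.start and f.end <= ge for s, gs, ge in gene_spans.values()
            )
            if not inside:
                raise ValueError(f"malformed feature hierarchy: {ftype} {f.id} lies outside every gene")
            masks[f.seqid][cat][f.start - 1 : f.end] = True
    for chrom in masks:
        m = masks[chrom]
        m["intron"] = m["gene"] & ~m["exon"]
        m["intergenic"] = ~(m["gene"] | m["upstream"] | m["downstream"])
    return masks


def _base_chrom(contig: str) -> str:
    return contig[:-2] if contig.endswith(("_A", "_B")) else contig


def annotate_features(insertions: pd.DataFrame, masks: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Multi-label feature membership for each insertion position.

    Haplotype contig names (``chr1_B``) fall back to their base chromosome,
    since the annotation lives in primary coordinates.
    """
    out = insertions.copy()
    for cat in FEATURE_CATEGORIES:
        vals = []
        for r in insertions.itertuples():
            chrom = _base_chrom(r.chrom)
            if chrom not in masks:
                vals.append(False)
                continue
            vals.append(bool(masks[chrom][cat][int(r.pos) - 1]))
        out[cat] = vals
    out["features"] = [
        tuple(cat for cat in FEATURE_CATEGORIES if row[cat]) for _, row in out.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# permutation null


def insertion_bias_test(
    insertions: pd.DataFrame,
    masks: dict[str, dict[str, np.ndarray]],
    R: int = 10_000,
    seed=0,
    categories: tuple[str, ...] = FEATURE_CATEGORIES,
) -> pd.DataFrame:
    """Permutation test of insertion-site feature bias.

    Each replicate re-places every insertion uniformly at random on its own
    chromosome and records the per-category mean membership fraction. The
    two-sided empirical p-value is add-one corrected,
    p = (b + 1) / (R + 1) with b the number of replicate means at least as
    far from the null mean as the observed mean. Categories absent from
    the annotation are excluded with a warning.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = [_base_chrom(c) for c in insertions["chrom"]]
    pos = insertions["pos"].to_numpy(dtype=np.int64)
    n = len(insertions)
    if n == 0:
        raise ValueError("no insertions to test")

    usable = []
    for cat in categories:
        if any(masks[c][cat].any() for c in masks):
            usable.append(cat)
        else:
            warnings.warn(f"feature category {cat!r} absent from annotation; excluded", stacklevel=2)

    obs = {
        cat: float(np.mean([masks[c][cat][p - 1] for c, p in zip(chroms, pos)])) for cat in usable
    }

    null_sums = {cat: np.zeros(R) for cat in usable}
    for chrom in sorted(set(chroms)):
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        L = masks[chrom][usable[0]].size
        draws = rng.integers(0, L, size=(R, len(idx)))
        for cat in usable:
            null_sums[cat] += masks[chrom][cat][draws].sum(axis=1)
    rows = []
    for cat in usable:
        null_means = null_sums[cat] / n
        mu = float(null_means.mean())
        b = int((np.abs(null_means - mu) >= abs(obs[cat] - mu) - 1e-12).sum())
        p = min(1.0, (b + 1) / (R + 1))
        rows.append(
            {
                "category": cat,
                "observed_mean": obs[cat],
                "null_mean": mu,
                "null_sd": float(null_means.std(ddof=0)),
                "p": p,
                "direction": "enriched" if obs[cat] > mu else ("depleted" if obs[cat] < mu else "none"),
                "R": R,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell-fraction bins


def cell_fraction_bins(insertions: pd.DataFrame, class_column: str = "length_class") -> pd.DataFrame:
    """Right-closed 0.05-wide allele-frequency bins, proportions per class.

    Bin k covers (0.05 k, 0.05 (k+1)]; an allele frequency of exactly 0
    lands in the first bin, 1.0 in the top bin (fixed in all cells).
    """
    edges = np.round(np.linspace(0.0, 1.0, 21), 2)
    classes = sorted(insertions[class_column].unique()) if len(insertions) else []
    out = pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:]})
    for cls in classes:
        af = insertions.loc[insertions[class_column] == cls, "allele_frequency"].to_numpy(dtype=float)
        idx = np.clip(np.ceil(af / 0.05).astype(int) - 1, 0, 19)
        counts = np.bincount(idx, minlength=20)
        out[cls] = counts / counts.sum() if counts.sum() else 0.0
    return out
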