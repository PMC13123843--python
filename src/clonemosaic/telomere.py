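"""Telomeric repeat content from reads by exact 21-mer counting.

The plant telomeric repeat is TTTAGGG; the counter slides a 21-bp window
over every read and counts windows consisting of three tandem units,
(TTTAGGG)x3 in any rotation phase, under canonical k-mer equivalence (a
window matching a reverse complement counts identically, and each window
is counted once). A 28-bp quadruple repeat therefore contributes all 8 of
its windows, one per offset.
Counts are normalized by the total read bases, giving a depth-corrected
telomere content comparable across samples. Reads shorter than 21 bp
contribute bases but no windows. Degenerate repeat variants are *not*
matched; only the exact motif counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from scipy import stats

from ._util import revcomp

TELOMERE_UNIT = "TTTAGGG"
KMER = TELOMERE_UNIT * 3  # 21 bp
K = len(KMER)
# a window sliding over a telomeric array matches one of the 7 rotation
# phases of the triple repeat (or a reverse complement); each 21-bp window
# of a read can match at most one of these 14 distinct motifs
_ROTATIONS = tuple((KMER * 2)[i : i + K] for i in range(len(TELOMERE_UNIT)))
MOTIFS = _ROTATIONS + tuple(revcomp(m) for m in _ROTATIONS)


def _count_overlapping(seq: str, motif: str) -> int:
    n, start = 0, 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


@dataclass
class TelomereCount:
    sample: str
    telomeric_kmer_count: int
    total_bases: int

    @property
    def normalized_count(self) -> float:
        return self.telomeric_kmer_count / self.total_bases if self.total_bases else 0.0


def count_in_sequences(seqs, sample: str = "") -> TelomereCount:
    """Count telomeric 21-mer windows over an iterable of sequence strings."""
    kmers = 0
    bases = 0
    for seq in seqs:
        s = str(seq).upper()
        bases += len(s)
        if len(s) >= K:
            kmers += sum(_count_overlapping(s, m) for m in MOTIFS)
    return TelomereCount(sample=sample, telomeric_kmer_count=kmers, total_bases=bases)


def count_telomeric_kmers(reads_path: str, sample: str | None = None, fmt: str | None = None) -> TelomereCount:
    """Count telomeric 21-mers in a FASTA/FASTQ read file.

    The caller supplies nuclear reads (organellar filtering is an input
    contract). Counts are additive over files; see
    :func:`count_in_sequences` for the counting rule.
    """
    if fmt is None:
        fmt = "fastq" if reads_path.endswith((".fq", ".fastq")) else "fasta"
    if sample is None:
        sample = reads_path.rsplit("/", 1)[-1].split(".")[0]
    seqs = (str(rec.seq) for rec in SeqIO.parse(reads_path, fmt))
    tc = count_in_sequences(seqs, sample=sample)
    if tc.total_bases == 0:
        raise ValueError(f"{reads_path}: no read bases")
    return tc


def compare_telomere_content(
    counts: list[TelomereCount],
    grouping: dict[str, str] | None = None,
    order_key: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate normalized counts per sample/group, ordered descending.

    When ``order_key`` maps samples to a covariate (e.g. years in
    culture), the Spearman rank correlation between the covariate and the
    normalized counts is stored in ``df.attrs['spearman_rho']`` /
    ``['spearman_p']``.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 samples to compare")
    df = pd.DataFrame(
        {
            "sample": [c.sample for c in counts],
            "telomeric_kmer_count": [c.telomeric_kmer_count for c in counts],
            "total_bases": [c.total_bases for c in counts],
            "normalized_count": [c.normalized_count for c in counts],
        }
    )
    if grouping:
        df["group"] = df["sample"].map(grouping)
    df = df.sort_values("normalized_count", ascending=False, kind="mergesort").reset_index(drop=True)
    if order_key:
        sub = df[df["sample"].isin(order_key)]
        rho, p = stats.spearmanr(sub["sample"].map(order_key), sub["normalized_count"])
        df.attrs["spearman_rho"] = float(rho)
        df.attrs["spearman_p"] = float(p)
    return df
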