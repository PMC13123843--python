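"""Small shared helpers: sequence alphabet, reverse complement, RNG plumbing."""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# complement lookup for uint8-encoded sequences (indices into BASES)
_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.uint8)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def idx_to_str(idx: np.ndarray) -> str:
    """Decode a uint8 base-index array (0..3 = ACGT) to a string."""
    return BASES[idx].tobytes().decode("ascii")


def str_to_idx(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(raw.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[raw == b] = i
    return out


def revcomp_idx(idx: np.ndarray) -> np.ndarray:
    return _COMP_IDX[idx[::-1]]


def rng_from(seed) -> np.random.Generator:
    """Normalize a seed (int or Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def zt_poisson(rng: np.random.Generator, lam, size) -> np.ndarray:
    """Poisson conditioned on >= 1 (simple redraw; lam is large in practice)."""
    lam = np.broadcast_to(np.asarray(lam, dtype=float), size).copy()
    out = rng.poisson(lam)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam[bad])
        bad = out == 0
    return out


def zt_binomial(rng: np.random.Generator, n, p) -> np.ndarray:
    """Binomial(n, p) conditioned on >= 1 for each element."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape).copy()
    out = rng.binomial(n, p)
    bad = out == 0
    while bad.any():
        out[bad] = rng.binomial(n[bad], p[bad])
        bad = out == 0
    return out
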