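"""Developmental mosaicism from singleton-mutation allele frequencies.

Against the haplotype-phased (concatenated) assembly, a variant's allele
frequency directly estimates the fraction of cells carrying it. Singleton
de novo mutations therefore read out a clone's developmental history:

* somatic embryos repeatedly bud from single cells, fixing mutations -- a
  large point mass at cell fraction 1.0 plus a low-fraction tail of
  not-yet-fixed recent mutations (single-lineage fixation);
* shoot cultures and trees keep mutations confined to meristem layers --
  essentially nothing fixed, with a bimodal cell-fraction distribution at
  the L1 and L2-L3 layer fractions (~0.2 / ~0.8 of bulk leaf tissue).

The explicit decision rule here (point-mass weight, two-component mixture
with a valley check) is this package's own formalization of a pattern the
source analyses judged visually; it is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture


def cell_fraction(af, mode: str):
    """Fraction of cells carrying a variant given its allele frequency.

    concatenated mode: fraction = AF (the haplotype is its own contig);
    primary mode (diploid locus): fraction = min(2 AF, 1).
    """
    if mode not in ("primary", "concatenated"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(af, dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise ValueError("allele frequency outside [0, 1]")
    out = a if mode == "concatenated" else np.minimum(2.0 * a, 1.0)
    return float(out) if np.isscalar(af) else out


@dataclass
class FixationProfile:
    sample: str
    q_range: tuple[int, int]
    depth_min: float
    bins: np.ndarray  # histogram bin edges (21 edges, 0..1 by 0.05)
    histograms: dict[int, np.ndarray]  # q -> counts per bin
    afs: dict[int, np.ndarray]  # q -> singleton AFs passing the threshold
    fixed_threshold: float = 0.95

    def fixed_fraction(self, q: int) -> float:
        a = self.afs[q]
        return float((a >= self.fixed_threshold).mean()) if a.size else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in sorted(self.histograms):
            for b, c in enumerate(self.histograms[q]):
                rows.append((self.sample, q, self.bins[b], self.bins[b + 1], int(c)))
        return pd.DataFrame(rows, columns=["sample", "min_quality", "bin_start", "bin_end", "count"])


def fixation_profile(
    singletons: pd.DataFrame,
    sample: str,
    q_range: tuple[int, int] = (5, 40),
    depth_min: float = 10.0,
    fixed_threshold: float = 0.95,
) -> FixationProfile:
    """Allele-frequency histograms of one clone's singletons across a
    quality-threshold sweep (the overlay-plot convention).

    ``singletons`` are sample-unique de novo calls in concatenated mode
    with ``qual``, ``total_depth`` and ``allele_frequency`` columns. The
    depth filter (>= ``depth_min``) applies throughout; histogram mass is
    non-increasing in the quality threshold by construction. An empty
    input yields an empty (flagged) profile.
    """
    sub = singletons[singletons["total_depth"] >= depth_min]
    bins = np.linspace(0.0, 1.0, 21)
    histograms, afs = {}, {}
    for q in range(q_range[0], q_range[1] + 1):
        a = sub.loc[sub["qual"] >= q, "allele_frequency"].to_numpy(dtype=float)
        afs[q] = a
        histograms[q] = np.histogram(a, bins=bins)[0]
    prof = FixationProfile(
        sample=sample,
        q_range=q_range,
        depth_min=depth_min,
        bins=bins,
        histograms=histograms,
        afs=afs,
        fixed_threshold=fixed_threshold,
    )
    prof.empty = len(sub) == 0
    return prof


@dataclass
class LayerModelFit:
    interpretation: str  # single_lineage_fixation | two_layer_bimodal | indeterminate
    fixed_weight: float
    mode_locations: list[float] = field(default_factory=list)
    mode_weights: list[float] = field(default_factory=list)
    n_singletons: int = 0


def classify_mosaicism(
    profile: FixationProfile,
    q: int | None = None,
    min_singletons: int = 30,
    fixed_weight_threshold: float = 0.4,
    mode_separation: float = 0.2,
    valley_ratio: float = 0.6,
    seed: int = 0,
) -> LayerModelFit:
    """Decide single-lineage fixation vs two-layer bimodal mosaicism.

    The point mass at AF >= the fixed threshold is weighed first: when it
    dominates (>= ``fixed_weight_threshold``) the clone shows
    single-lineage fixation. Otherwise a two-component Gaussian mixture is
    fit to the interior AFs; bimodality requires modes separated by
    >= ``mode_separation`` *and* a genuine density valley between them
    (midpoint histogram density below ``valley_ratio`` x the smaller mode
    density) -- a uniform AF cloud fails the valley check and comes back
    indeterminate. Mode locations estimate the layer cell fractions.
    """
    q = q if q is not None else profile.q_range[0]
    a = profile.afs[q]
    if a.size < min_singletons:
        return LayerModelFit(interpretation="indeterminate", fixed_weight=np.nan, n_singletons=int(a.size))
    fixed = a >= profile.fixed_threshold
    w_fix = float(fixed.mean())
    interior = a[~fixed]
    if w_fix >= fixed_weight_threshold or interior.size < min_singletons:
        return LayerModelFit(
            interpretation="single_lineage_fixation",
            fixed_weight=w_fix,
            mode_locations=[1.0],
            mode_weights=[w_fix],
            n_singletons=int(a.size),
        )
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3).fit(interior.reshape(-1, 1))
    mus = gm.means_.ravel()
    ws = gm.weights_.ravel()
    order = np.argsort(mus)
    mus, ws = mus[order], ws[order]
    separated = (mus[1] - mus[0]) >= mode_separation and min(ws) >= 0.15
    bimodal = False
    if separated:
        hist, edges = np.histogram(interior, bins=20, range=(0.0, 1.0), density=True)
        centers = (edges[:-1] + edges[1:]) / 2

        def density_at(x):
            return hist[np.clip(np.searchsorted(edges, x) - 1, 0, 19)]

        mid = (mus[0] + mus[1]) / 2
        peak = min(density_at(mus[0]), density_at(mus[1]))
        bimodal = peak > 0 and density_at(mid) <= valley_ratio * peak
        _ = centers
    if bimodal:
        return LayerModelFit(
            interpretation="two_layer_bimodal",
            fixed_weight=w_fix,
            mode_locations=[float(m) for m in mus],
            mode_weights=[float(w) for w in ws],
            n_singletons=int(a.size),
        )
    return LayerModelFit(
        interpretation="indeterminate",
        fixed_weight=w_fix,
        mode_locations=[float(m) for m in mus],
        mode_weights=[float(w) for w in ws],
        n_singletons=int(a.size),
    )
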