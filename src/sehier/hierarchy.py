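"""H-score computation and hierarchical SE / hub enhancer classification.

Each super-enhancer is divided into resolution-grid bins (5 kb by default,
matching the Hi-C matrix). Per-bin significant-interaction frequencies are
standardized to z-scores within the SE; the H-score is the maximum z. An SE
whose H-score exceeds the threshold (default 1.5) is hierarchical, and its
constituent enhancers overlapping a bin with z above the threshold are hub
enhancers; the remaining constituents of the same SE are non-hub.

With population-SD standardization the maximum attainable z for an n-bin SE
is sqrt(n - 1), so SEs spanning three or fewer bins can never be called
hierarchical at the default threshold.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic import DEFAULT_RESOLUTION, BinFrequencyTrack
from .intervals import GenomicInterval, IntervalIndex
from .se_calling import SuperEnhancer

DEFAULT_H_THRESHOLD = 1.5

INTERACTION_TYPES = ("enhancer-CTCF", "enhancer-enhancer", "enhancer-promoter", "none")

__all__ = [
    "HierarchyCall",
    "se_bins",
    "h_score",
    "classify_se",
    "label_enhancers",
    "score_super_enhancers",
    "filter_interactions_by_type",
]


@dataclass
class HierarchyCall:
    """Per-SE bin frequencies, z-scores, H-score and hub labels."""

    se: SuperEnhancer
    bins: list[GenomicInterval]
    frequencies: np.ndarray
    z: np.ndarray
    h_score: float
    threshold: float = DEFAULT_H_THRESHOLD
    is_hierarchical: bool = False
    hub_bins: list[GenomicInterval] = field(default_factory=list)
    enhancer_labels: dict[GenomicInterval, str] = field(default_factory=dict)


def se_bins(
    se: SuperEnhancer | GenomicInterval, resolution: int = DEFAULT_RESOLUTION
) -> list[GenomicInterval]:
    """Genome-grid bins intersecting the SE span, in coordinate order.

    Bins are grid-aligned (bin k covers [k*res, (k+1)*res)), not SE-start
    aligned: the Hi-C matrix defines the grid.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    region = se.region if isinstance(se, SuperEnhancer) else se
    first = region.start // resolution
    last = (region.end - 1) // resolution
    return [
        GenomicInterval(region.chrom, k * resolution, (k + 1) * resolution)
        for k in range(first, last + 1)
    ]


def h_score(frequencies: Sequence[int]) -> tuple[np.ndarray, float]:
    """Standardize bin frequencies to z-scores and return (z, max z).

    Uses the population SD (divide by n). A constant vector (including
    all-zero) has no dispersion: all z = 0 and H = 0.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("at least one bin frequency is required")
    sd = f.std()  # population SD
    if sd == 0:
        return np.zeros_like(f), 0.0
    z = (f - f.mean()) / sd
    return z, float(z.max())


def classify_se(call: HierarchyCall, threshold: float = DEFAULT_H_THRESHOLD) -> HierarchyCall:
    """Set the hierarchical flag (H > threshold, strict) and the hub bins (z > threshold)."""
    call.threshold = threshold
    call.is_hierarchical = call.h_score > threshold
    call.hub_bins = (
        [b for b, z in zip(call.bins, call.z) if z > threshold]
        if call.is_hierarchical
        else []
    )
    return call


def label_enhancers(call: HierarchyCall) -> HierarchyCall:
    """Label constituents of a hierarchical SE as hub / non-hub.

    A constituent is a hub enhancer iff it overlaps at least one bin whose
    z-score exceeds the threshold. Constituents of non-hierarchical SEs carry
    no label (they form the separate "enhancers in non-hierarchical SEs"
    comparison group).
    """
    if not call.is_hierarchical:
        call.enhancer_labels = {}
        return call
    idx = IntervalIndex(call.hub_bins)
    call.enhancer_labels = {
        c: ("hub" if idx.overlaps(c.chrom, c.start, c.end) else "non-hub")
        for c in call.se.constituents
    }
    return call


def score_super_enhancers(
    ses: Sequence[SuperEnhancer],
    track: BinFrequencyTrack,
    resolution: int = DEFAULT_RESOLUTION,
    threshold: float = DEFAULT_H_THRESHOLD,
) -> list[HierarchyCall]:
    """Full per-SE pipeline: bins -> frequencies -> z/H -> classify -> label."""
    calls = []
    for se in ses:
        bins = se_bins(se, resolution)
        freqs = track.frequencies(
            se.region.chrom, [b.start // resolution for b in bins]
        )
        z, h = h_score(freqs)
        call = HierarchyCall(se=se, bins=bins, frequencies=freqs, z=z, h_score=h)
        classify_se(call, threshold)
        label_enhancers(call)
        calls.append(call)
    return calls


def _anchor_labels(
    chroms: np.ndarray,
    mids: np.ndarray,
    resolution: int,
    anchor_flank: int,
    annotations: dict[str, IntervalIndex],
) -> dict[str, np.ndarray]:
    half = resolution // 2
    labels = {}
    for kind, idx in annotations.items():
        labels[kind] = np.array(
            [
                idx.overlaps(c, int(m) - half - anchor_flank, int(m) + half + anchor_flank)
                for c, m in zip(chroms, mids)
            ],
            dtype=bool,
        )
    return labels


def filter_interactions_by_type(
    significant: pd.DataFrame,
    exclude: str,
    enhancers: Sequence[GenomicInterval],
    ctcf_peaks: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    resolution: int = DEFAULT_RESOLUTION,
    anchor_flank: int = 0,
) -> pd.DataFrame:
    """Drop significant pairs of an excluded subtype for leave-out reanalysis.

    Each anchor bin (the resolution-grid bin around a midpoint, optionally
    extended by ``anchor_flank``) is labelled by what it overlaps: enhancer,
    CTCF peak and/or promoter (a bin may carry several labels). A pair is
    dropped when its unordered label pair matches the excluded subtype, e.g.
    ``enhancer-CTCF`` drops pairs with one enhancer-labelled anchor and one
    CTCF-labelled anchor.
    """
    if exclude not in INTERACTION_TYPES:
        raise ValueError(f"exclude must be one of {INTERACTION_TYPES}")
    if exclude == "none" or len(significant) == 0:
        return significant.copy()
    kinds = {"enhancer": enhancers, "CTCF": ctcf_peaks, "promoter": promoters}
    indices = {k: IntervalIndex(v) for k, v in kinds.items()}
    chroms = significant["chrom"].to_numpy()
    lab1 = _anchor_labels(chroms, significant["mid1"].to_numpy(), resolution, anchor_flank, indices)
    lab2 = _anchor_labels(chroms, significant["mid2"].to_numpy(), resolution, anchor_flank, indices)
    a, b = exclude.split("-")  # e.g. ("enhancer", "CTCF")
    drop = (lab1[a] & lab2[b]) | (lab1[b] & lab2[a])
    return significant[~drop].copy()
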