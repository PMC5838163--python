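"""Downstream annotation statistics for enhancer groups.

Covers variant fold-enrichment against a shuffled-enhancer background with
Fisher exact tests, CTCF binding-context classification with cell-type
consensus and PWM motif scores, TAD-boundary overlap, signal profiles around
anchor sets (sitepro-style), enhancer-promoter mapping constrained to TADs,
and expression cell-type specificity.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hic import DEFAULT_RESOLUTION
from .intervals import (
    GenomeTable,
    GenomicInterval,
    IntervalIndex,
    shuffle_intervals,
)

logger = logging.getLogger(__name__)

# trait keywords selecting blood-associated GWAS records (case-insensitive
# substring match on the trait field)
BLOOD_TRAIT_KEYWORDS = (
    "Erythrocyte", "F-cell", "HbA2", "Hematocrit", "Hematological",
    "Hematology", "Hemoglobin", "Platelet", "Blood", "Anemia",
    "Sickle cell disease", "Thalassemia", "Leukemia", "Lymphoma",
    "Lymphocyte", "B cell ", "B-cell", "White blood cell",
)

__all__ = [
    "EnrichmentResult",
    "CTCFContext",
    "SiteproProfile",
    "EPMap",
    "BLOOD_TRAIT_KEYWORDS",
    "enrichment",
    "shuffled_background",
    "filter_variants_by_trait",
    "ctcf_context",
    "consensus_score",
    "read_jaspar_pwm",
    "motif_scan",
    "sitepro",
    "map_enhancers_to_promoters",
    "expression_specificity",
    "boundary_overlap_fraction",
    "boundaries_from_tads",
]


@dataclass
class EnrichmentResult:
    """Fold enrichment (m/n)/(M/N) of variants in one enhancer group.

    m, M: within-group and background loci overlapping >= 1 variant (or raw
    variant counts in per-variant mode); n, N: group and background sizes.
    """

    group_name: str
    m: int
    n: int
    M: int
    N: int
    score: float
    fisher_p: float


def enrichment(
    group_loci: Sequence[GenomicInterval],
    variants: Sequence[GenomicInterval],
    background_loci: Sequence[GenomicInterval],
    group_name: str = "group",
    unit: str = "locus",
) -> EnrichmentResult:
    """Fold enrichment of a variant set in a group of loci vs a background.

    With ``unit='locus'`` (default) m counts group loci overlapping >= 1
    variant, matching bar labels of the form "number of enhancers overlapping
    eQTLs"; with ``unit='variant'`` m counts variants overlapping >= 1 group
    locus. The Fisher exact p (two-sided) comes from the 2x2 table
    [[m, n-m], [M, N-M]].
    """
    n, N = len(group_loci), len(background_loci)
    if n == 0 or N == 0:
        raise ValueError("group and background must be non-empty")
    if unit == "locus":
        vidx = IntervalIndex(variants)
        m = int(sum(vidx.overlaps(g.chrom, g.start, g.end) for g in group_loci))
        M = int(sum(vidx.overlaps(g.chrom, g.start, g.end) for g in background_loci))
    elif unit == "variant":
        gidx = IntervalIndex(group_loci)
        bidx = IntervalIndex(background_loci)
        m = int(sum(gidx.overlaps(v.chrom, v.start, v.end) for v in variants))
        M = int(sum(bidx.overlaps(v.chrom, v.start, v.end) for v in variants))
    else:
        raise ValueError("unit must be 'locus' or 'variant'")
    if M == 0:
        raise ValueError("background overlap count M is 0: score undefined")
    score = (m / n) / (M / N)
    table = [[m, n - m], [M, N - M]]
    if unit == "variant":
        # columns must be non-negative; per-variant counts are not bounded by n
        table = [[m, max(n - m, 0)], [M, max(N - M, 0)]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(group_name, m, n, M, N, score, float(fisher_p))


def shuffled_background(
    regular_enhancers: Sequence[GenomicInterval],
    genome: GenomeTable,
    seed: int,
    multiplier: int = 10,
    excluded: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Genome-wide background: regular enhancers shuffled ``multiplier`` times."""
    out: list[GenomicInterval] = []
    for k in range(multiplier):
        out.extend(shuffle_intervals(regular_enhancers, genome, seed + k, excluded))
    return out


def filter_variants_by_trait(
    variants: pd.DataFrame,
    keywords: Iterable[str] = BLOOD_TRAIT_KEYWORDS,
    trait_column: str = "trait",
) -> pd.DataFrame:
    """Keep variant rows whose trait contains any keyword (case-insensitive)."""
    traits = variants[trait_column].astype(str).str.lower()
    mask = np.zeros(len(variants), dtype=bool)
    for kw in keywords:
        mask |= traits.str.contains(kw.lower(), regex=False).to_numpy()
    return variants[mask]


@dataclass
class CTCFContext:
    """One CTCF peak with its regulatory context and optional motif evidence."""

    peak: GenomicInterval
    context: str  # hub | non-hub | TAD-boundary | excluded | other
    consensus: float | None = None
    motif_score: float | None = None
    motif_site: GenomicInterval | None = None


def ctcf_context(
    ctcf_peaks: Sequence[GenomicInterval],
    hub_enhancers: Sequence[GenomicInterval],
    nonhub_enhancers: Sequence[GenomicInterval],
    boundaries: Sequence[GenomicInterval],
) -> list[CTCFContext]:
    """Assign each CTCF peak exactly one context class.

    Peaks overlapping both a hub enhancer and a TAD boundary are 'excluded'
    (removed from downstream comparisons); otherwise hub > TAD-boundary >
    non-hub > other.
    """
    hub = IntervalIndex(hub_enhancers)
    nonhub = IntervalIndex(nonhub_enhancers)
    bound = IntervalIndex(boundaries)
    out = []
    for p in ctcf_peaks:
        on_hub = hub.overlaps(p.chrom, p.start, p.end)
        on_bound = bound.overlaps(p.chrom, p.start, p.end)
        if on_hub and on_bound:
            ctx = "excluded"
        elif on_hub:
            ctx = "hub"
        elif on_bound:
            ctx = "TAD-boundary"
        elif nonhub.overlaps(p.chrom, p.start, p.end):
            ctx = "non-hub"
        else:
            ctx = "other"
        out.append(CTCFContext(peak=p, context=ctx))
    return out


def consensus_score(
    peak: GenomicInterval, peaksets_by_celltype: dict[str, Sequence[GenomicInterval]]
) -> float:
    """Percentage of cell types in which the peak is detected (any overlap)."""
    if not peaksets_by_celltype:
        raise ValueError("at least one cell-type peak set is required")
    hits = sum(
        IntervalIndex(peaks).overlaps(peak.chrom, peak.start, peak.end)
        for peaks in peaksets_by_celltype.values()
    )
    return 100.0 * hits / len(peaksets_by_celltype)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def read_jaspar_pwm(path) -> np.ndarray:
    """Read a JASPAR-format count matrix into a 4 x width array (rows A,C,G,T)."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    return np.array([motif.counts[b] for b in "ACGT"], dtype=float)


def motif_scan(
    sequence: str,
    pwm: np.ndarray,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1e-3,
) -> tuple[float, tuple[int, int, str]]:
    """Maximum log2-odds PWM match over both strands of a sequence.

    The PWM (4 x width, rows A,C,G,T; counts or probabilities) gets a
    pseudocount per cell and is column-normalized; the score at an offset is
    sum of log2(P(base|PWM) / P(base|background)). Ambiguous bases score 0
    (background probability on both sides). Returns the maximum score and
    (start, end, strand) of the best window on the forward coordinates.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("PWM must have 4 rows (A, C, G, T)")
    width = pwm.shape[1]
    if len(sequence) < width:
        raise ValueError("sequence shorter than motif width")
    probs = pwm + pseudocount
    probs /= probs.sum(axis=0, keepdims=True)
    bg = np.asarray(background, dtype=float)
    logodds = np.log2(probs / bg[:, None])

    def scan(seq: str) -> tuple[float, int]:
        codes = np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)
        best, best_off = -np.inf, 0
        scores_by_base = np.vstack([logodds, np.zeros((1, width))])  # row 4 = ambiguous
        for off in range(len(seq) - width + 1):
            window = codes[off : off + width]
            s = scores_by_base[window, np.arange(width)].sum()
            if s > best:
                best, best_off = s, off
        return best, best_off

    fwd, fwd_off = scan(sequence)
    rev, rev_off = scan(sequence.translate(_COMPLEMENT)[::-1])
    if fwd >= rev:
        return float(fwd), (fwd_off, fwd_off + width, "+")
    start = len(sequence) - rev_off - width
    return float(rev), (start, start + width, "-")


@dataclass
class SiteproProfile:
    """Mean signal in offset bins around a set of anchor centers."""

    flank: int
    bin: int
    smoothing: int
    offsets: np.ndarray  # left edge of each offset bin relative to center
    values: np.ndarray
    n_centers: int = 0


def sitepro(
    signal: Sequence[GenomicInterval],
    centers: Sequence[GenomicInterval],
    flank: int = 5_000,
    bin: int = 50,
    smoothing: int = 0,
    point_features: bool = False,
) -> SiteproProfile:
    """Aggregate a signal track around anchor midpoints (strand-ignored).

    ``signal`` is a bedGraph-like list of scored intervals; uncovered bases
    count as 0. With ``point_features=True`` the track is a set of point
    events (e.g. mutations) counted per offset bin before averaging, yielding
    a frequency profile. ``smoothing`` applies a centered moving average of
    the stated bp window (rounded to whole bins).
    """
    if not centers:
        raise ValueError("centers must be non-empty")
    if 2 * flank % bin:
        raise ValueError("2*flank must be a multiple of bin")
    n_bins = 2 * flank // bin
    offsets = np.arange(-flank, flank, bin)
    acc = np.zeros(n_bins)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in signal:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    used = 0
    skipped = 0
    for center in centers:
        track = by_chrom.get(center.chrom)
        if track is None and signal:
            skipped += 1
            continue
        used += 1
        c = center.midpoint
        lo, hi = c - flank, c + flank
        for iv in track or ():
            if iv.end <= lo or iv.start >= hi:
                continue
            value = iv.score if iv.score is not None else 1.0
            if point_features:
                pos = iv.midpoint
                if lo <= pos < hi:
                    acc[(pos - lo) // bin] += 1
            else:
                first = max(iv.start, lo)
                last = min(iv.end, hi)
                b0, b1 = (first - lo) // bin, (last - 1 - lo) // bin
                for b in range(b0, b1 + 1):
                    blo, bhi = lo + b * bin, lo + (b + 1) * bin
                    ov = min(last, bhi) - max(first, blo)
                    acc[b] += value * ov / bin
    if skipped:
        logger.info("sitepro: skipped %d centers on chromosomes without signal", skipped)
    if used == 0:
        raise ValueError("no usable centers")
    values = acc / used
    if smoothing:
        w = max(1, int(round(smoothing / bin)))
        kernel = np.ones(w) / w
        values = np.convolve(values, kernel, mode="same")
    return SiteproProfile(flank, bin, smoothing, offsets, values, n_centers=used)


@dataclass
class EPMap:
    """Enhancer-promoter edges supported by significant interactions within TADs."""

    edges: list[tuple[GenomicInterval, GenomicInterval]] = field(default_factory=list)

    def target_counts(self) -> dict[GenomicInterval, int]:
        out: dict[GenomicInterval, int] = {}
        for e, _ in self.edges:
            out[e] = out.get(e, 0) + 1
        return out


def _contained(iv: GenomicInterval, tad: GenomicInterval) -> bool:
    return iv.chrom == tad.chrom and tad.start <= iv.start and iv.end <= tad.end


def map_enhancers_to_promoters(
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    significant: pd.DataFrame,
    tads: Sequence[GenomicInterval],
    resolution: int = DEFAULT_RESOLUTION,
) -> EPMap:
    """Connect enhancers to promoters via significant interactions within TADs.

    An edge (e, p) exists iff some significant pair has one anchor bin
    overlapping e and the other overlapping p, with e, p and both anchor bins
    all contained in a single TAD.
    """
    edges: set[tuple[GenomicInterval, GenomicInterval]] = set()
    if len(significant) == 0:
        return EPMap([])
    if "significant" in significant:
        significant = significant[significant["significant"]]
    half = resolution // 2
    for row in significant.itertuples(index=False):
        a1 = GenomicInterval(row.chrom, int(row.mid1) - half, int(row.mid1) + half)
        a2 = GenomicInterval(row.chrom, int(row.mid2) - half, int(row.mid2) + half)
        for first, second in ((a1, a2), (a2, a1)):
            es = [e for e in enhancers if e.overlaps(first)]
            if not es:
                continue
            ps = [p for p in promoters if p.overlaps(second)]
            if not ps:
                continue
            for tad in tads:
                if _contained(a1, tad) and _contained(a2, tad):
                    for e in es:
                        if not _contained(e, tad):
                            continue
                        for p in ps:
                            if _contained(p, tad):
                                edges.add((e, p))
    return EPMap(sorted(edges, key=lambda ep: (
        ep[0].chrom, ep[0].start, ep[0].end, ep[1].chrom, ep[1].start, ep[1].end)))


def expression_specificity(expr: pd.DataFrame, cell: str) -> pd.Series:
    """Fold-change of each gene's expression in ``cell`` vs its mean across
    cell types; genes with zero mean are reported as missing (NaN)."""
    if cell not in expr.columns:
        raise ValueError(f"cell type {cell!r} not in expression matrix")
    mean = expr.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = expr[cell] / mean
    out[mean == 0] = np.nan
    return out


def boundary_overlap_fraction(
    hub_enhancers: Sequence[GenomicInterval], boundaries: Sequence[GenomicInterval]
) -> float:
    """Percentage of hub enhancers overlapping >= 1 TAD boundary."""
    if not hub_enhancers:
        raise ValueError("hub enhancer list is empty")
    idx = IntervalIndex(boundaries)
    hits = sum(idx.overlaps(h.chrom, h.start, h.end) for h in hub_enhancers)
    return 100.0 * hits / len(hub_enhancers)


def boundaries_from_tads(
    tads: Sequence[GenomicInterval], flank: int = DEFAULT_RESOLUTION // 2
) -> list[GenomicInterval]:
    """Derive boundary windows (+-flank) around TAD edges when only TAD
    intervals are available."""
    out = []
    for tad in tads:
        for edge in (tad.start, tad.end):
            out.append(GenomicInterval(tad.chrom, max(0, edge - flank), edge + flank))
    return out
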