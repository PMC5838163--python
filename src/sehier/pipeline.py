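"""End-to-end pipeline: peaks + contacts -> SE calls -> H-scores -> hub labels
-> downstream statistics, with deterministic text outputs and a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    boundaries_from_tads,
    boundary_overlap_fraction,
    enrichment,
    shuffled_background,
)
from .hic import (
    DEFAULT_RESOLUTION,
    BinFrequencyTrack,
    SignificanceConfig,
    bin_frequency,
    call_significant,
    fit_expected,
    ice_normalize_contacts,
    read_contacts,
)
from .hierarchy import DEFAULT_H_THRESHOLD, HierarchyCall, score_super_enhancers
from .intervals import (
    GenomeTable,
    GenomicInterval,
    filter_enhancer_candidates,
    promoters_from_tss,
    read_genome_table,
    read_intervals,
    write_bed,
)
from .se_calling import DEFAULT_STITCH_GAP, SuperEnhancer, call_super_enhancers

__all__ = ["PipelineConfig", "PipelineResult", "analyze", "run_all"]

PROMOTER_FLANK = 2_000


@dataclass
class PipelineConfig:
    """File paths and parameters for a full run (flags mirror these fields)."""

    peaks: str
    contacts: str
    chrom_sizes: str
    outdir: str
    blacklist: str | None = None
    tss: str | None = None
    tads: str | None = None
    variants: str | None = None
    peak_format: str = "narrowPeak"
    resolution: int = DEFAULT_RESOLUTION
    stitch_gap: int = DEFAULT_STITCH_GAP
    min_distance: int = 10_000
    max_distance: int = 2_000_000
    fdr: float = 0.01
    h_threshold: float = DEFAULT_H_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h_threshold <= 0:
            raise ValueError("h_threshold must be > 0")
        if not (1_000 <= self.resolution <= 25_000):
            raise ValueError("resolution must be within 1000..25000")


@dataclass
class PipelineResult:
    regions: list[SuperEnhancer]
    calls: list[HierarchyCall]
    track: BinFrequencyTrack
    tested: pd.DataFrame
    enrichments: list = field(default_factory=list)
    boundary_overlap_pct: float | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def super_enhancers(self) -> list[SuperEnhancer]:
        return [r for r in self.regions if r.is_super]

    @property
    def regular_regions(self) -> list[SuperEnhancer]:
        return [r for r in self.regions if not r.is_super]

    def hub_enhancers(self) -> list[GenomicInterval]:
        return [
            e for c in self.calls for e, lab in c.enhancer_labels.items() if lab == "hub"
        ]

    def nonhub_enhancers(self) -> list[GenomicInterval]:
        return [
            e for c in self.calls for e, lab in c.enhancer_labels.items() if lab == "non-hub"
        ]


def analyze(
    peaks: list[GenomicInterval],
    contacts: pd.DataFrame,
    genome: GenomeTable,
    blacklist: list[GenomicInterval] | None = None,
    tss: list[GenomicInterval] | None = None,
    tads: list[GenomicInterval] | None = None,
    variants: list[GenomicInterval] | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    stitch_gap: int = DEFAULT_STITCH_GAP,
    sig_config: SignificanceConfig | None = None,
    h_threshold: float = DEFAULT_H_THRESHOLD,
    seed: int = 0,
) -> PipelineResult:
    """In-memory pipeline: filter -> stitch/rank/cutoff -> normalize/test/bin
    -> H-score/classify/label -> enrichment and boundary statistics."""
    sig_config = sig_config or SignificanceConfig()
    promoters = promoters_from_tss(tss, PROMOTER_FLANK, genome) if tss else []
    candidates = filter_enhancer_candidates(peaks, blacklist or [], promoters)
    regions = call_super_enhancers(candidates, gap=stitch_gap)
    supers = [r for r in regions if r.is_super]

    normalized = ice_normalize_contacts(contacts, resolution)
    expected = fit_expected(normalized, sig_config)
    tested = call_significant(normalized, expected, sig_config)
    significant = tested[tested["significant"]]
    track = bin_frequency(significant, resolution)
    calls = score_super_enhancers(supers, track, resolution, h_threshold)

    result = PipelineResult(regions=regions, calls=calls, track=track, tested=tested)

    regular = [r.region for r in regions if not r.is_super]
    if variants and regular:
        background = shuffled_background(regular, genome, seed)
        groups = {
            "hub": result.hub_enhancers(),
            "non-hub": result.nonhub_enhancers(),
            "regular": regular,
        }
        for name, loci in groups.items():
            if loci:
                result.enrichments.append(
                    enrichment(loci, variants, background, group_name=name)
                )
    if tads:
        hubs = result.hub_enhancers()
        if hubs:
            result.boundary_overlap_pct = boundary_overlap_fraction(
                hubs, boundaries_from_tads(tads, resolution // 2)
            )
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ses = sorted(result.regions, key=lambda r: r.rank)
    write_bed(
        [
            GenomicInterval(
                r.region.chrom, r.region.start, r.region.end,
                name=f"SE_{r.rank}" if r.is_super else f"RE_{r.rank}",
                score=round(r.total_signal, 4),
            )
            for r in ses
        ],
        outdir / "superenhancers.bed",
    )
    write_bed(
        [
            GenomicInterval(c.chrom, c.start, c.end,
                            name=f"SE_{r.rank}" if r.is_super else f"RE_{r.rank}",
                            score=c.score)
            for r in ses
            for c in r.constituents
        ],
        outdir / "constituents.bed",
    )
    with open(outdir / "hierarchy_calls.tsv", "w") as fh:
        fh.write("# se_id\tchrom\tstart\tend\tn_bins\th_score\tclass\tn_hub_bins\n")
        for call in result.calls:
            r = call.se
            cls = "hierarchical" if call.is_hierarchical else "non-hierarchical"
            fh.write(
                f"SE_{r.rank}\t{r.region.chrom}\t{r.region.start}\t{r.region.end}\t"
                f"{len(call.bins)}\t{call.h_score:.6f}\t{cls}\t{len(call.hub_bins)}\n"
            )
    write_bed(result.hub_enhancers(), outdir / "hub_enhancers.bed")
    write_bed(result.nonhub_enhancers(), outdir / "nonhub_enhancers.bed")
    result.track.to_bedgraph(outdir / "bin_frequency.bedgraph")
    sig = result.tested[result.tested["significant"]]
    with open(outdir / "significant.bedpe", "w") as fh:
        import numpy as np

        res = result.track.resolution
        half = res // 2
        for row in sig.itertuples(index=False):
            mlq = -np.log10(max(row.q, 1e-300))
            fh.write(
                f"{row.chrom}\t{row.mid1 - half}\t{row.mid1 + half}\t"
                f"{row.chrom}\t{row.mid2 - half}\t{row.mid2 + half}\t"
                f".\t{mlq:.4f}\n"
            )
    if result.enrichments:
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("# group\tm\tn\tM\tN\tscore\tfisher_p\n")
            for e in result.enrichments:
                fh.write(
                    f"{e.group_name}\t{e.m}\t{e.n}\t{e.M}\t{e.N}\t"
                    f"{e.score:.6f}\t{e.fisher_p:.6e}\n"
                )


def run_all(config: PipelineConfig) -> Path:
    """File-based pipeline run; writes all artifacts plus ``manifest.json``."""
    genome = read_genome_table(config.chrom_sizes)
    peaks = read_intervals(config.peaks, format=config.peak_format)
    blacklist = read_intervals(config.blacklist) if config.blacklist else []
    tss = read_intervals(config.tss) if config.tss else []
    tads = read_intervals(config.tads) if config.tads else []
    variants = read_intervals(config.variants) if config.variants else []
    contacts = read_contacts(config.contacts)

    sig_config = SignificanceConfig(
        min_distance=config.min_distance,
        max_distance=config.max_distance,
        fdr=config.fdr,
    )
    result = analyze(
        peaks, contacts, genome,
        blacklist=blacklist, tss=tss, tads=tads, variants=variants,
        resolution=config.resolution, stitch_gap=config.stitch_gap,
        sig_config=sig_config, h_threshold=config.h_threshold, seed=config.seed,
    )
    outdir = Path(config.outdir)
    _write_outputs(result, outdir)
    manifest = {
        "version": __version__,
        "parameters": {
            "resolution": config.resolution,
            "stitch_gap": config.stitch_gap,
            "min_distance": config.min_distance,
            "max_distance": config.max_distance,
            "fdr": config.fdr,
            "h_threshold": config.h_threshold,
            "seed": config.seed,
        },
        "inputs": {
            "peaks": str(config.peaks),
            "contacts": str(config.contacts),
            "chrom_sizes": str(config.chrom_sizes),
            "blacklist": str(config.blacklist) if config.blacklist else None,
            "tss": str(config.tss) if config.tss else None,
            "tads": str(config.tads) if config.tads else None,
            "variants": str(config.variants) if config.variants else None,
        },
        "counts": {
            "stitched_regions": len(result.regions),
            "super_enhancers": len(result.super_enhancers),
            "hierarchical_ses": sum(c.is_hierarchical for c in result.calls),
            "significant_interactions": int(result.tested["significant"].sum()),
            "hub_enhancers": len(result.hub_enhancers()),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
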