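"""Seedable synthetic fixtures: genome, peaks with planted SE structure,
distance-decay Hi-C contacts with planted hub loops, TADs, CTCF peaks and
variants enriched at planted hubs — with ground-truth labels throughout.

The contact model is Poisson with power-law distance decay: the count for a
pair of bins at distance d (in bins) has mean ``mu * d**-alpha``, doubled
(by default) for pairs inside one TAD to emulate domain insulation. Each
planted hierarchical SE designates its last 5 kb bin as the hub; the hub bin
is connected to a few nearby partner bins (10-15 kb away, within the same
TAD) by loops whose contact mean is multiplied by the hub fold-change.
Sparse partner loops — rather than inflating every contact touching the hub
bin — are essential: a uniform row multiplier is exactly a multiplicative
bias and would be removed in full by matrix balancing.

Peak scores are log-normal with SE constituents shifted well above regular
enhancers so the rank-cutoff has a planted answer. Decoy peaks overlapping
the blacklist or a promoter window are planted to exercise the candidate
filter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeTable, GenomicInterval

__all__ = ["SimulationConfig", "TruthTable", "FixtureBundle", "simulate",
           "golden_config", "golden_fixture", "GOLDEN_SEED"]

GOLDEN_SEED = 20_240_917

_SE_UNIT_MARGIN = 2          # empty bins before the SE span inside its unit
_SE_UNIT_TAIL = 6            # empty bins after the SE span (hosts partner bins)
_RE_UNIT_BINS = 4
_FILLER_UNIT_BINS = 4
_PEAK_PAD = 300              # bp inset of the SE span inside its first/last bin
_DIAG_MEAN_FACTOR = 4.0      # self-pair (d=0) count mean, in units of mu*boost


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``background_contact_mean`` is the Poisson mean for adjacent bins
    (distance 1 bin); ``decay_exponent`` the power-law decay; ``hub_fold``
    the loop-strength multiplier at planted hub bins; ``tad_boost`` the
    within-TAD contact enrichment.
    """

    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 1_500_000
    resolution: int = 5_000
    n_se: int = 56
    n_re: int = 40
    frac_hierarchical: float = 0.5
    hub_fold: float = 5.0
    background_contact_mean: float = 10.0
    decay_exponent: float = 1.0
    tad_boost: float = 2.0
    tad_size: int = 750_000
    se_n_bins: int = 8
    min_constituents: int = 4
    max_constituents: int = 7
    partner_offsets: tuple[int, ...] = (2, 3)
    n_variants: int = 400
    hub_variant_fold: float = 5.0

    def __post_init__(self) -> None:
        if self.hub_fold < 1 or self.hub_variant_fold < 1 or self.tad_boost < 1:
            raise ValueError("fold parameters must be >= 1")
        if not (0 <= self.frac_hierarchical <= 1):
            raise ValueError("frac_hierarchical must be in [0, 1]")
        if min(self.n_chrom, self.n_se, self.n_re, self.n_variants) < 0:
            raise ValueError("counts must be non-negative")
        if self.chrom_length % self.resolution:
            raise ValueError("chrom_length must be a multiple of resolution")

    @property
    def se_unit_bins(self) -> int:
        return _SE_UNIT_MARGIN + self.se_n_bins + _SE_UNIT_TAIL


@dataclass
class TruthTable:
    """Ground-truth labels consistent with the emitted fixtures."""

    ses: list[dict] = field(default_factory=list)
    enhancers: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)

    def hub_bins(self) -> set[tuple[str, int]]:
        out = set()
        for se in self.ses:
            for b in se["hub_bins"]:
                out.add((se["chrom"], b))
        return out

    def se_bins(self) -> set[tuple[str, int]]:
        out = set()
        for se in self.ses:
            for b in range(se["first_bin"], se["last_bin"] + 1):
                out.add((se["chrom"], b))
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(ses=d["ses"], enhancers=d["enhancers"], variants=d["variants"])


@dataclass
class FixtureBundle:
    """All fixtures for one simulated dataset, in memory."""

    config: SimulationConfig
    genome: GenomeTable
    peaks: list[GenomicInterval]
    decoy_peaks: list[GenomicInterval]
    tss: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    tads: list[GenomicInterval]
    ctcf: list[GenomicInterval]
    variants: list[GenomicInterval]
    contacts: pd.DataFrame
    truth: TruthTable

    @property
    def all_peaks(self) -> list[GenomicInterval]:
        return sorted(self.peaks + self.decoy_peaks, key=lambda p: (p.chrom, p.start))

    def write(self, outdir) -> None:
        from .intervals import write_bed

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "chrom.sizes", "w") as fh:
            for chrom, length in self.genome.entries.items():
                fh.write(f"{chrom}\t{length}\n")
        with open(out / "peaks.narrowPeak", "w") as fh:
            for p in self.all_peaks:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t"
                    f"{min(1000, int(round(p.score)))}\t.\t{p.score:.4f}\t-1\t-1\t-1\n"
                )
        write_bed(self.tss, out / "tss.bed")
        write_bed(self.blacklist, out / "blacklist.bed")
        write_bed(self.tads, out / "tads.bed")
        write_bed(self.ctcf, out / "ctcf.bed")
        write_bed(self.variants, out / "variants.bed")
        self.contacts.to_csv(
            out / "contacts.tsv", sep="\t", header=False, index=False,
            columns=["chrom", "mid1", "chrom2", "mid2", "count"],
        )
        self.truth.to_json(out / "truth.json")

    def contacts_5col(self) -> pd.DataFrame:
        df = self.contacts.copy()
        return df[["chrom", "mid1", "mid2", "count"]]


def _layout_chromosome(cfg: SimulationConfig, rng, n_se: int, n_re: int):
    """Assign SE/RE/filler units across one chromosome; returns unit list
    [(kind, start_bin, width_bins), ...] in coordinate order."""
    chrom_bins = cfg.chrom_length // cfg.resolution
    used = n_se * cfg.se_unit_bins + n_re * _RE_UNIT_BINS
    free = chrom_bins - used
    if free < 0:
        raise ValueError(
            f"genome too small: need {used} bins per chromosome, have {chrom_bins}"
        )
    n_filler = free // _FILLER_UNIT_BINS
    kinds = ["SE"] * n_se + ["RE"] * n_re + ["filler"] * n_filler
    rng.shuffle(kinds)
    units = []
    cursor = 0
    for kind in kinds:
        width = {"SE": cfg.se_unit_bins, "RE": _RE_UNIT_BINS, "filler": _FILLER_UNIT_BINS}[kind]
        units.append((kind, cursor, width))
        cursor += width
    return units


def _tads_from_units(cfg: SimulationConfig, chrom: str, units) -> list[GenomicInterval]:
    """TADs tile the chromosome with edges on unit boundaries (~tad_size each)."""
    target = cfg.tad_size // cfg.resolution
    tads = []
    tad_start = 0
    for kind, start, width in units:
        if start + width - tad_start >= target:
            tads.append(GenomicInterval(
                chrom, tad_start * cfg.resolution, (start + width) * cfg.resolution))
            tad_start = start + width
    chrom_bins = cfg.chrom_length // cfg.resolution
    if tad_start < chrom_bins:
        tads.append(GenomicInterval(
            chrom, tad_start * cfg.resolution, chrom_bins * cfg.resolution))
    return tads


def _se_peaks(cfg: SimulationConfig, rng, chrom: str, first_bin: int, se_id: int):
    """Constituent peaks evenly spread over the SE span so that neighbouring
    peaks stay within stitching distance and the last peak sits in the last
    (hub-candidate) bin."""
    res = cfg.resolution
    span_start = first_bin * res + _PEAK_PAD
    span_end = (first_bin + cfg.se_n_bins) * res - _PEAK_PAD
    n_c = int(rng.integers(cfg.min_constituents, cfg.max_constituents + 1))
    width = int(rng.integers(1500, 2500))
    starts = np.linspace(span_start, span_end - width, n_c).astype(int)
    scores = np.exp(rng.normal(3.5, 0.3, size=n_c))
    return [
        GenomicInterval(chrom, int(s), int(s) + width,
                        name=f"SE{se_id}_c{k}", score=float(round(sc, 4)))
        for k, (s, sc) in enumerate(zip(starts, scores))
    ]


def simulate(config: SimulationConfig) -> FixtureBundle:
    """Generate a complete fixture bundle; fully reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    res = cfg.resolution
    chrom_bins = cfg.chrom_length // res
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genome = GenomeTable({c: cfg.chrom_length for c in chroms})

    # round-robin SE/RE counts per chromosome
    se_per = [cfg.n_se // cfg.n_chrom + (i < cfg.n_se % cfg.n_chrom) for i in range(cfg.n_chrom)]
    re_per = [cfg.n_re // cfg.n_chrom + (i < cfg.n_re % cfg.n_chrom) for i in range(cfg.n_chrom)]
    n_hier = int(round(cfg.n_se * cfg.frac_hierarchical))

    peaks: list[GenomicInterval] = []
    decoys: list[GenomicInterval] = []
    tss: list[GenomicInterval] = []
    blacklist: list[GenomicInterval] = []
    tads: list[GenomicInterval] = []
    ctcf: list[GenomicInterval] = []
    truth = TruthTable()
    hub_bins_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    tad_id_by_chrom: dict[str, np.ndarray] = {}

    se_id = 0
    for ci, chrom in enumerate(chroms):
        units = _layout_chromosome(cfg, rng, se_per[ci], re_per[ci])
        chrom_tads = _tads_from_units(cfg, chrom, units)
        tads.extend(chrom_tads)
        tid = np.zeros(chrom_bins, dtype=int)
        for t_i, t in enumerate(chrom_tads):
            tid[t.start // res : t.end // res] = t_i
        tad_id_by_chrom[chrom] = tid
        for t in chrom_tads[:-1]:  # CTCF at internal TAD boundaries
            ctcf.append(GenomicInterval(chrom, t.end - 200, t.end + 200, name="ctcf_boundary"))

        filler_units = [u for u in units if u[0] == "filler"]
        re_i = 0
        for kind, start, width in units:
            if kind == "SE":
                first_bin = start + _SE_UNIT_MARGIN
                members = _se_peaks(cfg, rng, chrom, first_bin, se_id)
                peaks.extend(members)
                hier = se_id < 0  # assigned below after shuffling order
                truth.ses.append({
                    "chrom": chrom,
                    "start": members[0].start,
                    "end": members[-1].end,
                    "first_bin": first_bin,
                    "last_bin": first_bin + cfg.se_n_bins - 1,
                    "is_hierarchical": hier,
                    "hub_bins": [],
                    "constituents": [[m.start, m.end] for m in members],
                })
                se_id += 1
            elif kind == "RE":
                width_bp = int(rng.integers(1500, 2500))
                center = (start + 2) * res
                score = float(round(np.exp(rng.normal(1.0, 0.25)), 4))
                p = GenomicInterval(chrom, center - width_bp // 2,
                                    center - width_bp // 2 + width_bp,
                                    name=f"RE_{chrom}_{re_i}", score=score)
                peaks.append(p)
                truth.enhancers.append(
                    {"chrom": p.chrom, "start": p.start, "end": p.end, "label": "re"})
                re_i += 1

        # blacklist region + decoy peak inside it; promoter TSS + decoy nearby
        if len(filler_units) >= 2:
            _, fstart, fwidth = filler_units[0]
            b0 = fstart * res + 500
            blacklist.append(GenomicInterval(chrom, b0, b0 + 8_000, name="blacklist"))
            decoys.append(GenomicInterval(chrom, b0 + 1_000, b0 + 3_000,
                                          name="decoy_blacklisted", score=50.0))
            _, fstart, fwidth = filler_units[1]
            t0 = fstart * res + fwidth * res // 2
            tss.append(GenomicInterval(chrom, t0, t0 + 1, name=f"gene_{chrom}_p"))
            decoys.append(GenomicInterval(chrom, t0 + 500, t0 + 2_000,
                                          name="decoy_promoter", score=50.0))
            for _, fstart, fwidth in filler_units[2:: max(1, len(filler_units) // 4)]:
                t0 = fstart * res + fwidth * res // 2
                tss.append(GenomicInterval(chrom, t0, t0 + 1, name=f"gene_{chrom}_{fstart}"))

    # choose which SEs are hierarchical and plant their hubs
    hier_idx = rng.choice(len(truth.ses), size=n_hier, replace=False)
    for i in sorted(hier_idx):
        se = truth.ses[i]
        se["is_hierarchical"] = True
        hub = se["last_bin"]
        se["hub_bins"] = [hub]
        hub_bins_by_chrom[se["chrom"]].append(hub)
        # CTCF peak inside the hub bin; promoter TSS in the first partner bin
        hub_mid = hub * res + res // 2
        ctcf.append(GenomicInterval(se["chrom"], hub_mid - 200, hub_mid + 200,
                                    name="ctcf_hub"))
        partner_mid = (hub + cfg.partner_offsets[0]) * res + res // 2
        tss.append(GenomicInterval(se["chrom"], partner_mid, partner_mid + 1,
                                   name=f"gene_{se['chrom']}_hub{i}"))

    # constituent truth labels (hub iff overlapping the hub bin)
    for se in truth.ses:
        hub_set = set(se["hub_bins"])
        for start, end in se["constituents"]:
            bins = set(range(start // res, (end - 1) // res + 1))
            if not se["is_hierarchical"]:
                label = "constituent"
            elif bins & hub_set:
                label = "hub"
            else:
                label = "non-hub"
            truth.enhancers.append(
                {"chrom": se["chrom"], "start": start, "end": end, "label": label})

    # contacts: Poisson(mu * d^-alpha), within-TAD boost, planted hub loops
    mu, alpha = cfg.background_contact_mean, cfg.decay_exponent
    frames = []
    for chrom in chroms:
        tid = tad_id_by_chrom[chrom]
        hubs = np.array(sorted(hub_bins_by_chrom[chrom]), dtype=int)
        rows_i, rows_j, rows_c = [], [], []
        for d in range(0, chrom_bins):
            i = np.arange(chrom_bins - d)
            j = i + d
            base = mu * d ** -alpha if d > 0 else _DIAG_MEAN_FACTOR * mu
            mean = np.full(len(i), base)
            mean[tid[i] == tid[j]] *= cfg.tad_boost
            if d in cfg.partner_offsets and hubs.size:
                mean[np.isin(i, hubs)] *= cfg.hub_fold
            counts = rng.poisson(mean)
            rows_i.append(i)
            rows_j.append(j)
            rows_c.append(counts)
        i = np.concatenate(rows_i)
        j = np.concatenate(rows_j)
        c = np.concatenate(rows_c)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "mid1": i * res + res // 2,
            "chrom2": chrom,
            "mid2": j * res + res // 2,
            "count": c,
        }))
    contacts = pd.concat(frames, ignore_index=True)
    contacts = contacts.sort_values(["chrom", "mid1", "mid2"], kind="stable").reset_index(drop=True)

    # variants: uniform over bins, hub bins oversampled
    hub_set = truth.hub_bins()
    weights = []
    bin_keys = []
    for chrom in chroms:
        for b in range(chrom_bins):
            bin_keys.append((chrom, b))
            weights.append(cfg.hub_variant_fold if (chrom, b) in hub_set else 1.0)
    weights = np.array(weights)
    weights /= weights.sum()
    variants = []
    picks = rng.choice(len(bin_keys), size=cfg.n_variants, p=weights)
    offsets = rng.integers(0, res, size=cfg.n_variants)
    for k, (pick, off) in enumerate(zip(picks, offsets)):
        chrom, b = bin_keys[pick]
        pos = b * res + int(off)
        cls = "hub" if (chrom, b) in hub_set else "background"
        variants.append(GenomicInterval(chrom, pos, pos + 1, name=f"v{k}_{cls}"))
        truth.variants.append({"chrom": chrom, "pos": pos, "class": cls})
    variants.sort(key=lambda v: (v.chrom, v.start))

    return FixtureBundle(
        config=cfg,
        genome=genome,
        peaks=sorted(peaks, key=lambda p: (p.chrom, p.start)),
        decoy_peaks=decoys,
        tss=sorted(tss, key=lambda t: (t.chrom, t.start)),
        blacklist=blacklist,
        tads=tads,
        ctcf=sorted(ctcf, key=lambda c: (c.chrom, c.start)),
        variants=variants,
        contacts=contacts,
        truth=truth,
    )


def golden_config() -> SimulationConfig:
    """The checked-in regression fixture: 2 chromosomes x 2 Mb, 12 SEs, 60 REs."""
    return SimulationConfig(
        seed=GOLDEN_SEED,
        n_chrom=2,
        chrom_length=2_000_000,
        n_se=12,
        n_re=60,
        n_variants=200,
    )


def golden_fixture() -> FixtureBundle:
    """Regenerate the golden fixture from its stored seed (deterministic)."""
    return simulate(golden_config())


def golden_expected_dir() -> Path:
    """Directory of frozen expected pipeline outputs for the golden fixture."""
    return Path(__file__).parent / "data" / "golden"
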