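import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sehier.annotation import (
    BLOOD_TRAIT_KEYWORDS,
    boundaries_from_tads,
    boundary_overlap_fraction,
    consensus_score,
    ctcf_context,
    enrichment,
    expression_specificity,
    filter_variants_by_trait,
    map_enhancers_to_promoters,
    motif_scan,
    read_jaspar_pwm,
    shuffled_background,
    sitepro,
)
from sehier.intervals import GenomeTable, GenomicInterval


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def hypergeom_two_sided(m, n, M, N):
    """Independent oracle: sum of hypergeometric pmf over tables as extreme."""
    total, succ, draws = n + N, m + M, n
    k = np.arange(max(0, draws - (total - succ)), min(draws, succ) + 1)
    pmf = stats.hypergeom.pmf(k, total, succ, draws)
    p_obs = stats.hypergeom.pmf(m, total, succ, draws)
    return pmf[pmf <= p_obs * (1 + 1e-7)].sum()


class TestEnrichment:
    def test_direct_formula(self):
        # 10 of 100 group loci hit vs 1000 of 100000 background -> 10-fold
        group = [iv("chr1", i * 1000, i * 1000 + 100) for i in range(100)]
        variants = [iv("chr1", i * 1000 + 50, i * 1000 + 51) for i in range(10)]
        bg = [iv("chr2", i * 1000, i * 1000 + 100) for i in range(1000)]
        bg_variants = variants + [iv("chr2", i * 1000 + 50, i * 1000 + 51)
                                  for i in range(10)]
        res = enrichment(group, bg_variants, bg)
        assert res.m == 10 and res.n == 100 and res.M == 10 and res.N == 1000
        assert res.score == pytest.approx((10 / 100) / (10 / 1000))

    def test_group_against_itself_scores_exactly_one(self, rng):
        loci = [iv("chr1", int(s), int(s) + 200) for s in rng.integers(0, 100_000, 50)]
        variants = [iv("chr1", int(s), int(s) + 1) for s in rng.integers(0, 100_000, 30)]
        res = enrichment(loci, variants, loci)
        assert res.score == 1.0

    def test_fisher_matches_hypergeometric_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            N = int(rng.integers(2, 140))
            m = int(rng.integers(0, n + 1))
            M = int(rng.integers(1, N + 1))
            _, p = stats.fisher_exact([[m, n - m], [M, N - M]])
            assert p == pytest.approx(hypergeom_two_sided(m, n, M, N), abs=1e-10)

    def test_enrichment_fisher_p_on_fixture(self, rng):
        group = [iv("chr1", i * 500, i * 500 + 100) for i in range(40)]
        bg = [iv("chr2", i * 500, i * 500 + 100) for i in range(80)]
        variants = [iv("chr1", i * 500 + 10, i * 500 + 11) for i in range(12)] + \
                   [iv("chr2", i * 500 + 10, i * 500 + 11) for i in range(6)]
        res = enrichment(group, variants, bg)
        assert res.fisher_p == pytest.approx(
            hypergeom_two_sided(res.m, res.n, res.M, res.N), abs=1e-10)

    def test_per_variant_counting_mode(self):
        group = [iv("chr1", 0, 1000)]
        variants = [iv("chr1", 10, 11), iv("chr1", 20, 21), iv("chr2", 0, 1)]
        bg = [iv("chr1", 0, 1000), iv("chr2", 0, 1000)]
        res = enrichment(group, variants, bg, unit="variant")
        assert res.m == 2 and res.M == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enrichment([], [iv("chr1", 0, 1)], [iv("chr1", 0, 10)])

    def test_shuffled_background_size(self):
        genome = GenomeTable({"chr1": 1_000_000})
        res = shuffled_background([iv("chr1", 0, 500)] * 3, genome, seed=0, multiplier=10)
        assert len(res) == 30 and all(len(r) == 500 for r in res)


class TestCtcfContext:
    hub = [iv("chr1", 1_000, 2_000)]
    nonhub = [iv("chr1", 10_000, 11_000)]
    bound = [iv("chr1", 1_500, 2_500), iv("chr1", 50_000, 51_000)]

    def classify(self, peak):
        return ctcf_context([peak], self.hub, self.nonhub, self.bound)[0].context

    def test_hub_and_boundary_is_excluded(self):
        assert self.classify(iv("chr1", 1_600, 1_900)) == "excluded"

    def test_hub_only(self):
        assert self.classify(iv("chr1", 1_000, 1_200)) == "hub"

    def test_boundary_only(self):
        assert self.classify(iv("chr1", 50_100, 50_200)) == "TAD-boundary"

    def test_nonhub(self):
        assert self.classify(iv("chr1", 10_100, 10_300)) == "non-hub"

    def test_other(self):
        assert self.classify(iv("chr1", 90_000, 90_200)) == "other"

    def test_partition_matches_brute_force(self, rng):
        peaks = [iv("chr1", int(s), int(s) + 300) for s in rng.integers(0, 60_000, 200)]
        out = ctcf_context(peaks, self.hub, self.nonhub, self.bound)
        assert len(out) == len(peaks)
        for ctx in out:
            p = ctx.peak
            on_hub = any(p.overlaps(x) for x in self.hub)
            on_b = any(p.overlaps(x) for x in self.bound)
            on_nh = any(p.overlaps(x) for x in self.nonhub)
            expected = ("excluded" if on_hub and on_b else
                        "hub" if on_hub else
                        "TAD-boundary" if on_b else
                        "non-hub" if on_nh else "other")
            assert ctx.context == expected


class TestConsensus:
    def test_fraction_of_cell_types(self):
        peak = iv("chr1", 100, 200)
        sets = {f"ct{i}": [iv("chr1", 150, 160)] if i < 11 else [iv("chr2", 0, 10)]
                for i in range(55)}
        assert consensus_score(peak, sets) == pytest.approx(20.0)

    def test_present_everywhere(self):
        peak = iv("chr1", 100, 200)
        sets = {"a": [iv("chr1", 0, 500)], "b": [iv("chr1", 199, 300)]}
        assert consensus_score(peak, sets) == 100.0

    def test_no_cell_types_rejected(self):
        with pytest.raises(ValueError):
            consensus_score(iv("chr1", 0, 10), {})


def naive_scan(seq, logodds):
    comp = str.maketrans("ACGT", "TGCA")
    width = logodds.shape[1]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    best = -np.inf
    for strand, s in (("+", seq), ("-", seq.translate(comp)[::-1])):
        for off in range(len(s) - width + 1):
            score = sum(
                logodds[idx[b], k] if b in idx else 0.0
                for k, b in enumerate(s[off:off + width])
            )
            best = max(best, score)
    return best


class TestMotifScan:
    pwm = np.array([  # consensus TACGT
        [0, 9, 0, 0, 0],
        [0, 0, 9, 0, 0],
        [0, 0, 0, 9, 0],
        [9, 0, 0, 0, 9],
    ], dtype=float)

    def test_consensus_attains_pwm_maximum(self):
        score, (start, end, strand) = motif_scan("TACGT", self.pwm)
        probs = self.pwm + 1e-3
        probs /= probs.sum(axis=0)
        expected_max = np.log2(probs.max(axis=0) / 0.25).sum()
        assert score == pytest.approx(expected_max)
        assert (start, end, strand) == (0, 5, "+")

    def test_reverse_complement_found_on_minus_strand(self):
        score_f, _ = motif_scan("TACGT", self.pwm)
        score_r, (_, _, strand) = motif_scan("ACGTA", self.pwm)  # revcomp of TACGT
        assert strand == "-" and score_r == pytest.approx(score_f)

    def test_uniform_pwm_scores_zero(self):
        uni = np.full((4, 4), 2.5)
        score, _ = motif_scan("ACGTACGT", uni)
        assert score == pytest.approx(0.0)

    def test_ambiguous_bases_score_background(self):
        score, _ = motif_scan("NNNNN", self.pwm)
        assert score == pytest.approx(0.0)

    def test_matches_exhaustive_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        pwm = rng.random((4, 6)) * 10
        probs = pwm + 1e-3
        probs = probs / probs.sum(axis=0)
        logodds = np.log2(probs / 0.25)
        score, _ = motif_scan(seq, pwm)
        assert score == pytest.approx(naive_scan(seq, logodds), abs=1e-9)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            motif_scan("ACG", self.pwm)

    def test_jaspar_reader(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0000.1 TOY\nA [ 1 0 9 ]\nC [ 2 1 0 ]\nG [ 3 8 0 ]\nT [ 4 1 1 ]\n")
        pwm = read_jaspar_pwm(p)
        assert pwm.shape == (4, 3) and pwm[0, 2] == 9


class TestSitepro:
    def test_constant_track_gives_flat_profile(self):
        signal = [iv("chr1", 0, 100_000, score=3.0)]
        centers = [iv("chr1", 50_000, 50_001)]
        prof = sitepro(signal, centers, flank=1_000, bin=100)
        assert np.allclose(prof.values, 3.0)

    def test_spike_at_center_peaks_at_offset_zero(self):
        signal = [iv("chr1", 49_975, 50_025, score=10.0)]
        centers = [iv("chr1", 50_000, 50_001)]
        prof = sitepro(signal, centers, flank=1_000, bin=50)
        center_bin = len(prof.values) // 2
        assert prof.values[center_bin] == prof.values.max() > 0

    def test_point_features_recover_offset_histogram(self):
        centers = [iv("chr1", 10_000, 10_001), iv("chr1", 50_000, 50_001)]
        muts = [iv("chr1", 10_000 + 120, 10_000 + 121),
                iv("chr1", 50_000 + 120, 50_000 + 121),
                iv("chr1", 50_000 - 200, 50_000 - 199)]
        prof = sitepro(muts, centers, flank=500, bin=10, point_features=True)
        hist = dict(zip(prof.offsets, prof.values))
        assert hist[120] == pytest.approx(1.0)  # both centers hit at +120
        assert hist[-200] == pytest.approx(0.5)
        assert sum(prof.values) == pytest.approx(1.5)

    def test_matches_naive_extraction(self, rng):
        signal = [iv("chr1", i * 200, (i + 1) * 200, score=float(rng.random()))
                  for i in range(500)]
        centers = [iv("chr1", int(c), int(c) + 1)
                   for c in rng.integers(5_000, 95_000, 100)]
        prof = sitepro(signal, centers, flank=1_000, bin=100)
        vals = {(s.start, s.end): s.score for s in signal}
        expected = np.zeros(20)
        for c in centers:
            mid = c.midpoint
            for b in range(20):
                lo = mid - 1_000 + b * 100
                acc = 0.0
                for (s, e), v in vals.items():
                    ov = min(e, lo + 100) - max(s, lo)
                    if ov > 0:
                        acc += v * ov / 100
                expected[b] += acc
        expected /= len(centers)
        assert np.allclose(prof.values, expected)

    def test_smoothing_is_moving_average(self):
        signal = [iv("chr1", 50_000, 50_010, score=10.0)]
        centers = [iv("chr1", 50_005, 50_006)]
        raw = sitepro(signal, centers, flank=100, bin=10)
        sm = sitepro(signal, centers, flank=100, bin=10, smoothing=30)
        kernel = np.ones(3) / 3
        assert np.allclose(sm.values, np.convolve(raw.values, kernel, mode="same"))

    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError):
            sitepro([], [], flank=100, bin=10)


class TestEpMap:
    res = 5000

    def test_cross_tad_connection_is_rejected(self):
        enh = [iv("chr1", 11_000, 12_000)]
        prom = [iv("chr1", 100_000, 104_000)]
        sig = pd.DataFrame({"chrom": ["chr1"], "mid1": [12_500], "mid2": [102_500]})
        tads_split = [iv("chr1", 0, 50_000), iv("chr1", 50_000, 200_000)]
        tads_joint = [iv("chr1", 0, 200_000)]
        assert map_enhancers_to_promoters(enh, prom, sig, tads_split, self.res).edges == []
        out = map_enhancers_to_promoters(enh, prom, sig, tads_joint, self.res)
        assert out.edges == [(enh[0], prom[0])]

    def test_no_pairs_gives_empty_map(self):
        out = map_enhancers_to_promoters(
            [iv("chr1", 0, 100)], [iv("chr1", 500, 600)],
            pd.DataFrame(columns=["chrom", "mid1", "mid2"]),
            [iv("chr1", 0, 10_000)], self.res)
        assert out.edges == []

    def test_matches_brute_force_triple_overlap(self, rng):
        enh = [iv("chr1", int(s), int(s) + 2_000) for s in rng.integers(0, 490_000, 10)]
        prom = [iv("chr1", int(s), int(s) + 4_000) for s in rng.integers(0, 490_000, 10)]
        tads = [iv("chr1", i * 100_000, (i + 1) * 100_000) for i in range(5)]
        m1 = rng.integers(0, 99, 30) * self.res + self.res // 2
        m2 = m1 + rng.integers(1, 12, 30) * self.res
        sig = pd.DataFrame({"chrom": "chr1", "mid1": m1, "mid2": m2})
        out = map_enhancers_to_promoters(enh, prom, sig, tads, self.res)

        def contained(x, t):
            return t.start <= x.start and x.end <= t.end

        expected = set()
        half = self.res // 2
        for a, b in zip(m1, m2):
            a1 = iv("chr1", int(a) - half, int(a) + half)
            a2 = iv("chr1", int(b) - half, int(b) + half)
            for t in tads:
                if not (contained(a1, t) and contained(a2, t)):
                    continue
                for x, y in ((a1, a2), (a2, a1)):
                    for e in enh:
                        if e.overlaps(x) and contained(e, t):
                            for p in prom:
                                if p.overlaps(y) and contained(p, t):
                                    expected.add((e, p))
        assert set(out.edges) == expected

    def test_target_counts_are_out_degrees(self):
        e1, e2 = iv("chr1", 0, 100), iv("chr1", 200, 300)
        p1, p2 = iv("chr1", 400, 500), iv("chr1", 600, 700)
        from sehier.annotation import EPMap

        m = EPMap([(e1, p1), (e1, p2), (e2, p1)])
        assert m.target_counts() == {e1: 2, e2: 1}


class TestExpression:
    def test_uniform_gene_has_unit_specificity(self):
        expr = pd.DataFrame({"K562": [4.0], "GM": [4.0], "H1": [4.0]}, index=["g"])
        assert expression_specificity(expr, "K562")["g"] == pytest.approx(1.0)

    def test_exclusive_gene_scales_with_cell_count(self):
        expr = pd.DataFrame({"K562": [6.0], "GM": [0.0], "H1": [0.0]}, index=["g"])
        assert expression_specificity(expr, "K562")["g"] == pytest.approx(3.0)

    def test_zero_mean_is_missing(self):
        expr = pd.DataFrame({"K562": [0.0], "GM": [0.0]}, index=["g"])
        assert np.isnan(expression_specificity(expr, "K562")["g"])

    def test_matches_direct_recomputation(self, rng):
        expr = pd.DataFrame(rng.random((20, 5)) * 10,
                            columns=[f"c{i}" for i in range(5)])
        out = expression_specificity(expr, "c2")
        assert np.allclose(out, expr["c2"] / expr.mean(axis=1))

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError):
            expression_specificity(pd.DataFrame({"a": [1.0]}), "b")


class TestBoundaries:
    def test_no_boundaries_gives_zero(self):
        assert boundary_overlap_fraction([iv("chr1", 0, 100)], []) == 0.0

    def test_all_on_boundaries_gives_hundred(self):
        hubs = [iv("chr1", 0, 100), iv("chr1", 500, 600)]
        assert boundary_overlap_fraction(hubs, [iv("chr1", 0, 1_000)]) == 100.0

    def test_matches_brute_force(self, rng):
        hubs = [iv("chr1", int(s), int(s) + 500) for s in rng.integers(0, 50_000, 40)]
        bounds = [iv("chr1", int(s), int(s) + 2_000) for s in rng.integers(0, 50_000, 5)]
        expected = 100 * sum(
            any(h.overlaps(b) for b in bounds) for h in hubs) / len(hubs)
        assert boundary_overlap_fraction(hubs, bounds) == pytest.approx(expected)

    def test_empty_hub_list_rejected(self):
        with pytest.raises(ValueError):
            boundary_overlap_fraction([], [iv("chr1", 0, 10)])

    def test_boundaries_from_tads_window_edges(self):
        tads = [iv("chr1", 10_000, 50_000)]
        out = boundaries_from_tads(tads, flank=2_500)
        assert [(b.start, b.end) for b in out] == [(7_500, 12_500), (47_500, 52_500)]


class TestTraitFilter:
    def test_case_insensitive_substring(self):
        df = pd.DataFrame({
            "trait": ["Mean platelet volume", "Height", "chronic lymphocytic leukemia"],
        })
        out = filter_variants_by_trait(df)
        assert out["trait"].tolist() == [
            "Mean platelet volume", "chronic lymphocytic leukemia"]

    def test_keyword_list_contains_core_blood_terms(self):
        assert "Hemoglobin" in BLOOD_TRAIT_KEYWORDS
        assert "Thalassemia" in BLOOD_TRAIT_KEYWORDS
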