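"""IUPAC scanning, background Z-scores and motif modules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tflink.core import GenomicInterval, Peak
from tflink.motifs import (
    IUPAC_SETS,
    MotifConsensus,
    MotifHit,
    RUNX_VARIANTS,
    count_hits,
    find_modules,
    module_enrichment,
    motif_zscore,
    region_motif_summary,
    reverse_complement,
    sample_background,
    scan,
)

RUNX = MotifConsensus("RUNX", "TGYGGY")


def naive_scan(seq, iupac):
    """Position-by-position oracle over explicit IUPAC sets."""
    def matches(window, pattern):
        return len(window) == len(pattern) and all(
            base in IUPAC_SETS[code] for base, code in zip(window, pattern))

    hits = []
    m = len(iupac)
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - m + 1):
        if matches(seq[i:i + m], iupac):
            hits.append((i, "+"))
    for j in range(n - m + 1):
        if matches(rc[j:j + m], iupac):
            hits.append((n - j - m, "-"))
    return sorted(hits)


class TestScan:
    def test_forward_hit(self):
        (hit,) = scan("TGTGGT", RUNX, both_strands=False)
        assert (hit.offset, hit.strand, hit.matched) == (0, "+", "TGTGGT")

    def test_reverse_complement_hit(self):
        (hit,) = scan("ACCACA", RUNX)
        assert (hit.offset, hit.strand) == (0, "-")
        assert hit.matched == "TGTGGT"

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            MotifConsensus("bad", "TGXGGT")
        with pytest.raises(ValueError):
            scan("TGQGGT", RUNX)

    def test_sequence_n_only_matches_pattern_n(self):
        assert scan("TGNGGT", RUNX) == []
        assert len(scan("TGNGGT", MotifConsensus("x", "TGNGGT"),
                        both_strands=False)) == 1

    def test_planted_motifs_equal_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        for pos in (100, 2500, 5000, 7000, 9990):
            seq = seq[:pos] + "TGCGGC" + seq[pos + 6:]
        got = sorted((h.offset, h.strand) for h in scan(seq, RUNX))
        assert got == naive_scan(seq, "TGYGGY")
        assert {100, 2500, 5000, 7000, 9990} <= {o for o, _ in got}

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50)
    def test_random_sequences_equal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), 300,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        motif = ["TGYGGY", "MGGAA", "TGASTCA", "NRNCGN"][seed % 4]
        got = sorted((h.offset, h.strand)
                     for h in scan(seq, MotifConsensus("m", motif)))
        assert got == naive_scan(seq, motif)

    def test_reverse_complement_of_genome_swaps_strands(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        fwd = scan(seq, RUNX)
        rev = scan(reverse_complement(seq), RUNX)
        n = len(seq)
        flipped = sorted((n - h.offset - len(h.matched),
                          "+" if h.strand == "-" else "-") for h in rev)
        assert sorted((h.offset, h.strand) for h in fwd) == flipped


class TestRegionSummary:
    def test_peak_beyond_chromosome_end_errors(self, small_genome):
        peak = Peak(GenomicInterval("chr1", 199_990, 200_100), name="pX")
        with pytest.raises(ValueError, match="pX"):
            region_motif_summary([peak], small_genome, [RUNX])

    def test_motif_free_sequence_has_no_hits(self):
        genome = {"chr1": "AC" * 500}
        peaks = [Peak(GenomicInterval("chr1", 0, 1000))]
        counts, fraction, _ = region_motif_summary(peaks, genome, [RUNX])
        assert fraction == 0.0

    def test_counting_additive_over_disjoint_subregions(self, small_genome):
        whole = Peak(GenomicInterval("chr1", 1000, 3000), name="w")
        left = Peak(GenomicInterval("chr1", 1000, 2000), name="l")
        right = Peak(GenomicInterval("chr1", 2000, 3000), name="r")
        n_whole = count_hits([whole], small_genome, RUNX)
        n_parts = count_hits([left], small_genome, RUNX) + count_hits(
            [right], small_genome, RUNX)
        # parts may miss only occurrences straddling the split point
        straddle = len(scan(small_genome["chr1"][1995:2005], RUNX))
        assert n_parts <= n_whole <= n_parts + straddle


class TestBackground:
    def test_deterministic_per_seed(self, small_genome):
        a = sample_background(small_genome, 20, [200, 300], seed=5)
        b = sample_background(small_genome, 20, [200, 300], seed=5)
        assert [(p.start, p.end) for p in a] == [(p.start, p.end) for p in b]

    def test_full_exclusion_errors(self, small_genome):
        exclusion = [GenomicInterval("chr1", 0, 200_000)]
        with pytest.raises(RuntimeError):
            sample_background(small_genome, 5, [300], seed=1,
                              exclusion=exclusion, max_tries_per_region=50)

    def test_lengths_match_source_distribution(self, small_genome, rng):
        source = rng.integers(150, 600, 500)
        regions = sample_background(small_genome, 1000, source, seed=2)
        from scipy.stats import ks_2samp

        drawn = [p.interval.length for p in regions]
        assert ks_2samp(drawn, source).pvalue > 0.01

    def test_exclusion_respected(self, small_genome):
        exclusion = [GenomicInterval("chr1", 0, 150_000)]
        regions = sample_background(small_genome, 50, [100], seed=3,
                                    exclusion=exclusion)
        assert all(p.start >= 150_000 for p in regions)


class TestZScore:
    def test_definition_on_constructed_counts(self):
        # observed region with 30 planted hits; background sets built to
        # hold exactly 8 or 12 hits each -> mean 10, z = 20 / sd
        seq = ["A"] * 100_000
        def plant(start, n):
            for i in range(n):
                pos = start + 10 * i
                seq[pos:pos + 6] = "TGTGGT"
        plant(0, 30)
        backgrounds = []
        counts = []
        for i in range(30):
            start = 1000 * (i + 1)
            n = 8 if i % 2 == 0 else 12
            plant(start, n)
            counts.append(n)
            backgrounds.append(
                [Peak(GenomicInterval("chr1", start, start + 400))])
        genome = {"chr1": "".join(seq)}
        obs = [Peak(GenomicInterval("chr1", 0, 400))]
        result = motif_zscore(obs, genome, RUNX, backgrounds)
        assert result.observed == 30
        assert result.background_mean == pytest.approx(10.0)
        assert result.z == pytest.approx(
            20.0 / np.std(counts, ddof=1))

    def test_zero_sd_flagged_absent(self):
        seq = ["A"] * 20_000
        seq[0:6] = "TGTGGT"
        genome = {"chr1": "".join(seq)}
        obs = [Peak(GenomicInterval("chr1", 0, 100))]
        backgrounds = [[Peak(GenomicInterval("chr1", 10_000 + 10 * i,
                                             10_050 + 10 * i))]
                       for i in range(30)]
        result = motif_zscore(obs, genome, RUNX, backgrounds)
        assert result.background_sd == 0.0 and result.z is None

    def test_null_regions_give_moderate_z(self, small_genome):
        rng = np.random.default_rng(7)
        obs = sample_background(small_genome, 50, [300], seed=99)
        backgrounds = [
            sample_background(small_genome, 50, [300], seed=int(s))
            for s in rng.integers(0, 2**31, 60)
        ]
        result = motif_zscore(obs, small_genome, RUNX, backgrounds)
        assert result.z is not None and abs(result.z) <= 3.5

    def test_planting_motifs_increases_z(self, small_genome):
        rng = np.random.default_rng(8)
        backgrounds = [
            sample_background(small_genome, 40, [300], seed=int(s))
            for s in rng.integers(0, 2**31, 40)
        ]
        obs = sample_background(small_genome, 40, [300], seed=1234)
        base = motif_zscore(obs, small_genome, RUNX, backgrounds)
        genome2 = dict(small_genome)
        seq = list(genome2["chr1"])
        for p in obs:
            mid = (p.start + p.end) // 2
            seq[mid:mid + 6] = "TGTGGT"
        genome2["chr1"] = "".join(seq)
        planted = motif_zscore(obs, genome2, RUNX, backgrounds)
        assert planted.z > base.z

    def test_requires_30_background_sets(self, small_genome):
        with pytest.raises(ValueError):
            motif_zscore([], small_genome, RUNX, [[]] * 10)


def hit(region, offset, length=6, motif="RUNX", strand="+"):
    return MotifHit(region, motif, offset, strand, "X" * length)


class TestModules:
    def test_gap_rule_example(self):
        runx = hit("r1", 100)           # ends at 106
        ets = MotifHit("r1", "ETS", 140, "+", "MGGAA")
        (module,) = find_modules([runx], [ets], max_gap=50)
        assert module.gap == 34

    def test_gap_boundary(self):
        a, b = hit("r1", 0), hit("r1", 57)   # gap 51
        assert find_modules([a], [b], max_gap=50) == []
        a, b = hit("r1", 0), hit("r1", 56)   # gap 50
        assert len(find_modules([a], [b], max_gap=50)) == 1

    def test_overlapping_motifs_gap_zero(self):
        a, b = hit("r1", 0), hit("r1", 3)
        (module,) = find_modules([a], [b])
        assert module.gap == 0

    def test_same_motif_needs_distinct_hits(self):
        a = hit("r1", 10)
        assert find_modules([a], [a]) == []
        b = hit("r1", 30)
        assert len(find_modules([a, b], [a, b])) == 1  # unordered pair once

    def test_random_hits_equal_all_pairs_oracle(self, rng):
        hits_a = [hit("r1", int(o)) for o in rng.integers(0, 500, 30)]
        hits_b = [MotifHit("r1", "ETS", int(o), "+", "MGGAA")
                  for o in rng.integers(0, 500, 30)]
        got = {(m.hit_a.offset, m.hit_b.offset)
               for m in find_modules(hits_a, hits_b, max_gap=50)}
        expected = set()
        for a in hits_a:
            for b in hits_b:
                gap = max(0, max(a.offset, b.offset)
                          - min(a.offset + 6, b.offset + 5))
                if gap <= 50:
                    expected.add((a.offset, b.offset))
        assert got == expected

    def test_enrichment_null_near_one_and_planted_elevated(self, rng):
        def make_regions(n, plant_modules):
            genome_seq = list("".join(rng.choice(list("ACGT"), 200_000)))
            regions = []
            for i in range(n):
                start = i * 1000
                if plant_modules:
                    genome_seq[start + 50:start + 56] = "TGTGGT"
                    genome_seq[start + 70:start + 75] = "AGGAA"
                regions.append(Peak(
                    GenomicInterval("chr1", start, start + 300),
                    name=f"r{i}"))
            return {"chr1": "".join(genome_seq)}, regions

        genome_bg, bg = make_regions(60, plant_modules=False)
        ets = MotifConsensus("ETS", "MGGAA")
        folds = module_enrichment(
            {"null": bg}, genome_bg, RUNX, ets, background=bg)
        assert folds["null"] == 1.0  # partition equals its own background
        genome_pl, planted = make_regions(60, plant_modules=True)
        genome_pl["chr1"] = genome_pl["chr1"][:60_000] + genome_bg["chr1"][60_000:]
        planted = planted[:50]
        folds2 = module_enrichment(
            {"de_novo": planted}, genome_pl, RUNX, ets,
            background=[Peak(GenomicInterval("chr1", 100_000 + i * 1000,
                                             100_300 + i * 1000))
                        for i in range(50)])
        assert folds2["de_novo"] > 2.0

    def test_empty_partition_reports_absent(self, small_genome):
        ets = MotifConsensus("ETS", "MGGAA")
        bg = [Peak(GenomicInterval("chr1", 0, 1000))]
        folds = module_enrichment({"empty": []}, small_genome, RUNX, ets,
                                  background=bg)
        assert folds["empty"] is None
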