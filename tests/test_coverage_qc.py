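"""Coverage QC: k-mer-unique regions, chromosome coverage, outliers, verdicts."""

import math
from collections import Counter

import numpy as np
import pytest

from cnvburden import (
    CnvError,
    DepthTrack,
    GenomicInterval,
    QcParameters,
    SimulationConfig,
    chromosome_coverage,
    coverage_profile,
    detect_outlier_chromosomes,
    find_repetitive_free_regions,
    sample_qc,
    simulate_depth_profile,
    simulate_reference,
)

_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_region_oracle(reference, params):
    """Independent repetitive-free-region finder.

    Counts every k-mer (canonicalized with its reverse complement) in a
    hash table, scans all windows for full k-mer uniqueness, then applies
    the documented placement rule (leftmost qualifying window per equal
    bin, greedy left-to-right fill).
    """
    k, L = params.k, params.region_length
    counts = Counter()
    for seq in reference.values():
        for p in range(len(seq) - k + 1):
            km = seq[p : p + k]
            if any(b not in "ACGT" for b in km):
                continue
            rc = km.translate(_COMP)[::-1]
            counts[min(km, rc)] += 1
    out = {}
    for chrom, seq in reference.items():
        n = len(seq)
        unique = []
        for p in range(n - k + 1):
            km = seq[p : p + k]
            if any(b not in "ACGT" for b in km):
                unique.append(False)
            else:
                rc = km.translate(_COMP)[::-1]
                unique.append(counts[min(km, rc)] == 1)
        ok = []
        span = L - k + 1
        bad_prefix = [0]
        for u in unique:
            bad_prefix.append(bad_prefix[-1] + (0 if u else 1))
        for s in range(n - L + 1):
            ok.append(bad_prefix[s + span] - bad_prefix[s] == 0)
        chosen = []
        nb = params.regions_per_chromosome
        edges = [round(i * n / nb) for i in range(nb + 1)]
        cursor = 0
        for i in range(nb):
            for s in range(max(edges[i], cursor), min(edges[i + 1], len(ok))):
                if ok[s]:
                    chosen.append((s, s + L))
                    cursor = s + L
                    break
        if len(chosen) < nb:
            s = 0
            while s < len(ok) and len(chosen) < nb:
                if ok[s] and all(s + L <= cs or s >= ce for cs, ce in chosen):
                    chosen.append((s, s + L))
                    s += L
                else:
                    s += 1
        out[chrom] = [GenomicInterval(chrom, s, e) for s, e in sorted(chosen)]
    return out


@pytest.fixture(scope="module")
def qc_params():
    return QcParameters(k=25, region_length=5_000, regions_per_chromosome=10)


class TestRepetitiveFreeRegions:
    def test_matches_bruteforce_oracle_on_random_reference(self, qc_params):
        cfg = SimulationConfig(seed=21, chromosome_lengths={"chr1": 80_000, "chr2": 40_000})
        ref = simulate_reference(cfg)
        got = find_repetitive_free_regions(ref, qc_params)
        expected = brute_force_region_oracle(ref, qc_params)
        assert got == expected
        for ivs in got.values():
            assert all(iv.length == qc_params.region_length for iv in ivs)

    def test_regions_avoid_implanted_duplication(self, qc_params):
        cfg = SimulationConfig(
            seed=22,
            chromosome_lengths={"chr1": 120_000},
            n_implanted_duplications=1,
            implant_length=5_000,
        )
        ref = simulate_reference(cfg)
        got = find_repetitive_free_regions(ref, qc_params)
        assert got == brute_force_region_oracle(ref, qc_params)
        # locate both copies of the duplicated block by brute force and
        # verify no region window overlaps a non-unique k-mer
        k = qc_params.k
        counts = Counter()
        seq = ref["chr1"]
        for p in range(len(seq) - k + 1):
            km = seq[p : p + k]
            rc = km.translate(_COMP)[::-1]
            counts[min(km, rc)] += 1
        for iv in got["chr1"]:
            for p in range(iv.start, iv.end - k + 1):
                km = seq[p : p + k]
                rc = km.translate(_COMP)[::-1]
                assert counts[min(km, rc)] == 1

    def test_short_chromosome_yields_no_regions(self, qc_params):
        cfg = SimulationConfig(seed=23, chromosome_lengths={"tiny": 3_000, "chr1": 40_000})
        ref = simulate_reference(cfg)
        got = find_repetitive_free_regions(ref, qc_params)
        assert got["tiny"] == []
        assert len(got["chr1"]) > 0

    def test_deterministic(self, qc_params):
        cfg = SimulationConfig(seed=24, chromosome_lengths={"chr1": 50_000})
        ref = simulate_reference(cfg)
        assert find_repetitive_free_regions(ref, qc_params) == find_repetitive_free_regions(
            ref, qc_params
        )

    def test_ambiguous_bases_disqualify_windows(self, qc_params):
        cfg = SimulationConfig(seed=25, chromosome_lengths={"chr1": 30_000})
        ref = simulate_reference(cfg)
        seq = ref["chr1"]
        ref_n = {"chr1": seq[:10_000] + "N" + seq[10_001:]}
        got = find_repetitive_free_regions(ref_n, qc_params)
        for iv in got["chr1"]:
            assert "N" not in ref_n["chr1"][iv.start : iv.end]
        assert got == brute_force_region_oracle(ref_n, qc_params)


class TestChromosomeCoverage:
    def test_constant_depth(self):
        track = DepthTrack.from_array({"chr1": np.full(1_000, 30)})
        regions = {"chr1": [GenomicInterval("chr1", 0, 500)]}
        assert chromosome_coverage(track, regions) == {"chr1": 30.0}

    def test_split_depth_averages(self):
        arr = np.concatenate([np.full(500, 20), np.full(500, 40)])
        track = DepthTrack.from_array({"chr1": arr})
        regions = {"chr1": [GenomicInterval("chr1", 0, 1_000)]}
        assert chromosome_coverage(track, regions)["chr1"] == pytest.approx(30.0)

    def test_poisson_depth_recovers_mean(self):
        rng = np.random.default_rng(3)
        n = 40_000
        arr = rng.poisson(35, size=n)
        track = DepthTrack.from_array({"chr1": arr})
        regions = {"chr1": [GenomicInterval("chr1", 0, n)]}
        cov = chromosome_coverage(track, regions)["chr1"]
        se = math.sqrt(35 / n)
        assert abs(cov - 35) < 3 * se

    def test_chromosome_without_regions_is_undefined(self):
        track = DepthTrack.from_array({"chr1": np.full(100, 30)})
        cov = chromosome_coverage(track, {"chr1": [], "chr2": []})
        assert all(math.isnan(v) for v in cov.values())


class TestOutliers:
    def test_no_outliers_when_equal(self):
        res = detect_outlier_chromosomes({f"chr{i}": 30.0 for i in range(1, 23)})
        assert res.outliers == frozenset()
        assert res.overall_mean == 30.0 and res.sd == 0.0

    def test_trisomy_like_flagged(self):
        cov = {f"chr{i}": 30.0 for i in range(1, 22)}
        cov["chr21"] = 45.0
        res = detect_outlier_chromosomes(cov)
        assert res.outliers == frozenset({"chr21"})
        assert res.overall_mean == pytest.approx(30.0)

    def test_monosomy_like_flagged(self):
        cov = {f"chr{i}": 30.0 for i in range(1, 22)}
        cov["chrX"] = 15.0
        res = detect_outlier_chromosomes(cov)
        assert res.outliers == frozenset({"chrX"})

    def test_all_flagged_is_error(self):
        with pytest.raises(CnvError):
            detect_outlier_chromosomes({"a": 1.0, "b": 100.0},
                                       QcParameters(outlier_fraction=1e-6))


class TestSampleQc:
    def test_zero_sd_passes(self):
        res = detect_outlier_chromosomes({"a": 30.0, "b": 30.0})
        assert sample_qc(res).passed

    def test_uneven_sample_fails_without_outlier_exclusion(self):
        cov = {f"chr{i}": 30.0 for i in range(1, 22)}
        cov["chr22"] = 60.0
        res = detect_outlier_chromosomes(cov, QcParameters(outlier_fraction=math.inf))
        assert res.overall_mean == pytest.approx(31.36, abs=0.01)
        assert res.sd == pytest.approx(6.25, abs=0.01)
        verdict = sample_qc(res)
        assert not verdict.passed
        assert verdict.threshold == pytest.approx(0.15 * 31.36, abs=0.01)

    def test_boundary_sd_passes(self):
        # strict inequality: sd exactly 15% of mean still passes
        class P:
            overall_mean = 100.0
            sd = 15.0

        assert sample_qc(P()).passed

    def test_scale_invariance(self):
        cov = {f"chr{i}": v for i, v in enumerate([28, 30, 31, 29, 33, 30.5], 1)}
        v1 = sample_qc(detect_outlier_chromosomes(cov))
        v2 = sample_qc(detect_outlier_chromosomes({c: 7.3 * x for c, x in cov.items()}))
        assert v1.passed == v2.passed


class TestEndToEnd:
    def test_even_sample_passes_and_trisomy_flagged(self):
        params = QcParameters(k=25, region_length=5_000, regions_per_chromosome=5)
        cfg = SimulationConfig(
            seed=31,
            chromosome_lengths={"chr1": 40_000, "chr2": 40_000, "chr3": 40_000,
                                "chr4": 40_000},
            depth_mean=40.0,
        )
        ref = simulate_reference(cfg)
        regions = find_repetitive_free_regions(ref, params)
        assert all(len(v) > 0 for v in regions.values())

        even = simulate_depth_profile(ref, cfg, stream=0)
        profile = coverage_profile("even", even, regions, params)
        assert profile.passed and profile.outliers == frozenset()

        trisomy = simulate_depth_profile(ref, cfg, {"chr3": 1.5}, stream=1)
        profile = coverage_profile("trisomy", trisomy, regions, params)
        assert profile.outliers == frozenset({"chr3"})
        # aneuploidy reported as an outlier chromosome, not coverage noise
        assert profile.passed
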