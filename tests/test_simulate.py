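"""Synthetic-data generator: determinism, statistical recovery, round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from cnvburden import (
    MergeParameters,
    SampleCallset,
    SimulationConfig,
    build_cohort_table,
    consolidate_sample_cnvs,
    mask_composition,
    merge_caller_callsets,
    read_bed,
    read_cnv_vcf,
    read_fasta,
    read_mask,
    read_phenotypes,
    simulate_caller_observations,
    simulate_cohort,
    simulate_mask,
    simulate_reference,
    vcf_to_sample_calls,
)
from cnvburden.coverage import DepthTrack


class TestReference:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=3, chromosome_lengths={"chr1": 30_000})
        assert simulate_reference(cfg) == simulate_reference(cfg)

    def test_different_seed_differs(self):
        a = simulate_reference(SimulationConfig(seed=3, chromosome_lengths={"chr1": 10_000}))
        b = simulate_reference(SimulationConfig(seed=4, chromosome_lengths={"chr1": 10_000}))
        assert a != b

    def test_implanted_duplication_kmers_repeat(self):
        cfg = SimulationConfig(
            seed=6, chromosome_lengths={"chr1": 60_000},
            n_implanted_duplications=1, implant_length=4_000,
        )
        ref = simulate_reference(cfg)
        base = simulate_reference(
            SimulationConfig(seed=6, chromosome_lengths={"chr1": 60_000})
        )
        # the duplicated block exists twice: total 25-mer multiset shrinks
        from cnvburden.coverage import genome_kmer_uniqueness

        uniq_dup = genome_kmer_uniqueness(ref, 25)["chr1"]
        uniq_base = genome_kmer_uniqueness(base, 25)["chr1"]
        assert uniq_dup.sum() < uniq_base.sum()
        # at least one window's worth of repeated k-mers on both copies
        assert (~uniq_dup).sum() >= 2 * (4_000 - 25)


class TestCohort:
    def test_null_cohort_has_no_systematic_case_excess(self, small_config):
        truth, ph = simulate_cohort(small_config)
        counts = truth.groupby("sample_id").size().reindex(ph.sample_ids).fillna(0)
        is_case = ph.is_case().to_numpy()
        diff = counts[is_case].mean() - counts[~is_case].mean()
        sd = counts.std()
        assert abs(diff) < 3 * sd  # loose null sanity bound

    def test_allele_frequency_recovered(self):
        cfg = SimulationConfig(seed=41, n_samples=1_000, n_cases=500,
                               n_pool_cnvs=1,
                               chromosome_lengths={"chr1": 100_000})
        truth, ph = simulate_cohort(cfg)
        pool = truth.attrs["pool"]
        af = float(pool["allele_frequency"].iloc[0])
        carriers = truth["sample_id"].nunique()
        p_carrier = 1 - (1 - af) ** 2
        se = math.sqrt(p_carrier * (1 - p_carrier) / 1_000)
        assert abs(carriers / 1_000 - p_carrier) < 3 * se

    def test_injected_effect_mean_recovered(self):
        cfg = SimulationConfig(seed=42, n_samples=400, n_cases=200,
                               burden_effect=16.0)
        truth, ph = simulate_cohort(cfg)
        dup = truth[truth["svtype"] == "DUP"]
        counts = dup.groupby("sample_id").size().reindex(ph.sample_ids).fillna(0)
        is_case = ph.is_case().to_numpy()
        diff = counts[is_case].mean() - counts[~is_case].mean()
        se = math.sqrt(16 / 200) * 2  # Poisson-dominated
        assert diff == pytest.approx(16, abs=3 * se + 0.5)

    def test_truth_is_conflict_free_per_sample(self, small_config):
        from cnvburden.model import frame_to_calls

        truth, ph = simulate_cohort(small_config)
        for sample, grp in truth.groupby("sample_id"):
            calls = frame_to_calls(grp)
            dels = [c for c in calls if c.svtype == "DEL"]
            dups = [c for c in calls if c.svtype == "DUP"]
            assert not any(
                d.interval.overlaps(p.interval) for d in dels for p in dups
            )


class TestCallerNoise:
    def test_zero_noise_equals_truth(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, jitter_sd=0.0, fn_rate=0.0,
                                  split_rate=0.0)
        truth, _ = simulate_cohort(cfg)
        obs = simulate_caller_observations(truth, cfg)
        for per_sample in obs.values():
            rows = [
                (c.chrom, c.start, c.end, c.svtype, c.copy_number, c.sample_id)
                for cs in per_sample.values() for c in cs
            ]
            got = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                              "copy_number", "sample_id"])
            got = got.sort_values(list(got.columns)).reset_index(drop=True)
            want = truth[got.columns].sort_values(list(got.columns)).reset_index(drop=True)
            pd.testing.assert_frame_equal(got, want)

    def test_full_split_rate_conserves_unions(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, jitter_sd=0.0, fn_rate=0.0,
                                  split_rate=1.0)
        truth, _ = simulate_cohort(cfg)
        obs = simulate_caller_observations(truth, cfg)
        caller = cfg.callers[0]
        n_truth = len(truth)
        n_obs = sum(len(cs) for cs in obs[caller].values())
        # every event of length >= 2 becomes exactly two book-ended pieces
        n_splittable = int((truth["end"] - truth["start"] >= 2).sum())
        assert n_obs == n_truth + n_splittable
        for cs in obs[caller].values():
            merged = consolidate_sample_cnvs(cs)
            key = ["chrom", "start", "end", "svtype", "sample_id"]
            got = pd.DataFrame(
                [(c.chrom, c.start, c.end, c.svtype, c.sample_id) for c in merged],
                columns=key).sort_values(key).reset_index(drop=True)
            sample = got["sample_id"].iloc[0]
            want = truth.loc[truth["sample_id"] == sample, key]
            want = want.sort_values(key).reset_index(drop=True)
            pd.testing.assert_frame_equal(got[key], want)

    def test_harmonization_recovers_truth_with_default_noise(self):
        """End-to-end truth recovery through merge + consolidation.

        Merged calls span the earliest start to the latest end of their
        members, so a merged breakpoint is the extreme of ~3 independent
        jitters: P(|min of 3 N(0, sd)| > 2 sd) ~ 6.5% per side, capping
        recovery at a 2-sd tolerance near 87%. At 3 sd the extreme-value
        tail is covered and recovery should exceed ~98% minus merge
        losses. Bounds below are 3-sigma relaxations of those
        expectations at this cohort size (~3,000 events).
        """
        cfg = SimulationConfig(seed=0)
        truth, ph = simulate_cohort(cfg)
        obs = simulate_caller_observations(truth, cfg)
        params = MergeParameters(max_breakpoint_distance=2 * int(cfg.jitter_sd))
        recovered = {2: 0, 3: 0}
        total = 0
        for sample, grp in truth.groupby("sample_id"):
            callsets = [obs[c][sample] for c in obs if sample in obs[c]]
            if not callsets:
                continue
            merged = merge_caller_callsets(callsets, params)
            cons = consolidate_sample_cnvs(merged)
            assert not cons.has_overlaps()
            for row in grp.itertuples(index=False):
                total += 1
                for mult in (2, 3):
                    tol = mult * cfg.jitter_sd
                    if any(
                        c.chrom == row.chrom
                        and c.svtype == row.svtype
                        and abs(c.start - row.start) <= tol
                        and abs(c.end - row.end) <= tol
                        for c in cons
                    ):
                        recovered[mult] += 1
        assert total > 1_000
        assert recovered[2] / total >= 0.80
        assert recovered[3] / total >= 0.93


class TestDepthAndMask:
    def test_mask_proportions_recovered(self, small_config):
        comp = mask_composition(simulate_mask(small_config))
        for label, want in small_config.mask_proportions.items():
            assert comp[label] == pytest.approx(want, abs=0.006)

    def test_depth_mean_recovered_within_one_percent(self):
        cfg = SimulationConfig(seed=51, chromosome_lengths={"chr1": 50_000},
                               depth_mean=37.0)
        from cnvburden import simulate_depth_profile, chromosome_coverage
        from cnvburden.model import GenomicInterval

        ref = simulate_reference(cfg)
        track = simulate_depth_profile(ref, cfg)
        regions = {"chr1": [GenomicInterval("chr1", 0, 50_000)]}
        cov = chromosome_coverage(track, regions)["chr1"]
        assert abs(cov - 37.0) / 37.0 < 0.01


class TestFixtures:
    def test_fixture_files_round_trip(self, fixture_dir, small_config):
        ref = read_fasta(fixture_dir["reference"])
        assert {c: len(s) for c, s in ref.items()} == dict(
            small_config.chromosome_lengths
        )
        truth = pd.read_csv(fixture_dir["truth"], sep="\t")
        res = read_cnv_vcf(fixture_dir["vcf"])
        ph = read_phenotypes(fixture_dir["phenotypes"])
        assert len(ph) == small_config.n_samples
        # VCF genotypes reproduce the truth table exactly
        rows = []
        for s in res.samples:
            for c in vcf_to_sample_calls(res, s):
                rows.append((c.chrom, c.start, c.end, c.svtype, c.copy_number, s))
        got = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                          "copy_number", "sample_id"])
        key = list(got.columns)
        got = got.sort_values(key).reset_index(drop=True)
        want = truth[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)
        mask = read_mask(fixture_dir["mask"])
        assert set(mask.frame["label"]) <= set("PNLHZ")
        for p in fixture_dir["depth"].values():
            DepthTrack.from_bedgraph(p)

    def test_fixture_directory_byte_reproducible(self, tmp_path, small_config):
        from cnvburden import write_fixtures

        a = tmp_path / "a"
        b = tmp_path / "b"
        write_fixtures(small_config, a)
        write_fixtures(small_config, b)
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel

    def test_per_caller_vcfs_parse(self, fixture_dir):
        caller = next(iter(fixture_dir["callers"]))
        sample, path = next(iter(fixture_dir["callers"][caller].items()))
        res = read_cnv_vcf(path)
        cs = vcf_to_sample_calls(res, sample, source=caller)
        assert len(cs) == len(res.records)
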