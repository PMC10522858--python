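import math

import numpy as np
import pytest

from vnarpan.errors import UndefinedStatisticError
from vnarpan.seqio import RoundTable
from vnarpan.simulate import (
    DEFAULT_LENGTH_MIXTURE,
    SimConfig,
    capture_probability,
    estimate_enrichment,
    generate_library,
    sample_reads,
    sanity_check_cassette,
    simulate_campaign,
    simulate_paired,
    simulate_round,
    simulate_single,
)


def test_cassette_constants_are_anchor_clean():
    sanity_check_cassette()


class TestGenerateLibrary:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_clones=30, seed=5)
        lib1 = generate_library(cfg, np.random.default_rng(5))
        lib2 = generate_library(cfg, np.random.default_rng(5))
        assert [c.cdr3_nt for c in lib1.clones] == [c.cdr3_nt for c in lib2.clones]
        assert (lib1.counts0 == lib2.counts0).all()

    def test_single_clone_gets_whole_pool(self):
        cfg = SimConfig(n_clones=1, pool_size=777)
        lib = generate_library(cfg, np.random.default_rng(0))
        assert lib.counts0.tolist() == [777]

    def test_counts_sum_to_pool(self):
        cfg = SimConfig(n_clones=50, pool_size=12345)
        lib = generate_library(cfg, np.random.default_rng(1))
        assert lib.counts0.sum() == 12345

    def test_length_histogram_within_3sd(self):
        cfg = SimConfig(n_clones=10_000, pool_size=10_000)
        lib = generate_library(cfg, np.random.default_rng(2))
        lengths = [len(c.cdr3_aa) for c in lib.clones]
        n = len(lengths)
        total_w = sum(w for _, w in DEFAULT_LENGTH_MIXTURE)
        for length, w in DEFAULT_LENGTH_MIXTURE:
            p = w / total_w
            observed = sum(1 for x in lengths if x == length)
            sd = math.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sd, (length, observed, n * p)

    def test_translation_consistency(self):
        from vnarpan.annotate import translate_frame

        cfg = SimConfig(n_clones=100)
        lib = generate_library(cfg, np.random.default_rng(3))
        for clone in lib.clones:
            assert translate_frame(clone.cdr3_nt, 0) == clone.cdr3_aa
            assert clone.kd > 0

    def test_mixture_length_above_cap_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(length_mixture=((40, 1.0),))


class TestCaptureProbability:
    def test_no_antigen_no_capture(self):
        assert capture_probability(1e-8, 0.0, 0.0, 0.0, 5) == 0.0

    def test_monovalent_no_penalty_reduces_to_occupancy(self):
        kd, conc = 2e-8, 1e-8
        b = conc / (conc + kd)
        assert capture_probability(kd, conc, 50.0, 0.0, 1) == pytest.approx(b)

    def test_avidity_algebra(self):
        # b = 0.5, d = 1, valence 5 -> 1 - 0.5^5
        kd = 1e-8
        assert capture_probability(kd, kd, 0.0, 0.0, 5) == pytest.approx(0.96875)

    def test_monotonicities(self):
        base = capture_probability(1e-8, 1e-8, 20.0, 2.0, 2)
        assert capture_probability(1e-7, 1e-8, 20.0, 2.0, 2) < base  # worse kd
        assert capture_probability(1e-8, 1e-7, 20.0, 2.0, 2) > base  # more antigen
        assert capture_probability(1e-8, 1e-8, 40.0, 2.0, 2) < base  # more rare codons
        assert capture_probability(1e-8, 1e-8, 20.0, 2.0, 5) > base  # more valence

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            capture_probability(-1e-8, 1e-8, 0.0, 0.0, 1)
        with pytest.raises(ValueError):
            capture_probability(1e-8, 1e-8, 0.0, 0.0, 0)


class TestSimulateRound:
    def test_extinction_is_absorbing_and_total_conserved(self, rng):
        counts = np.array([0, 100, 900])
        q = np.array([0.9, 0.5, 0.5])
        out = simulate_round(counts, q, 1000, rng)
        assert out[0] == 0
        assert out.sum() == 1000

    def test_two_clone_capture_ratio(self):
        # q1 = 2*q2: mean round-1 count ratio ~ 2x input ratio
        q = np.array([0.4, 0.2])
        counts = np.array([1000, 1000])
        totals = np.zeros(2)
        for seed in range(500):
            out = simulate_round(counts, q, 2000, np.random.default_rng(seed))
            totals += out
        ratio = totals[0] / totals[1]
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_round(np.array([0, 0]), np.array([0.5, 0.5]), 100, rng)


class TestCampaigns:
    def test_counts_conserved_per_round(self, small_campaign):
        for counts in small_campaign.counts:
            assert counts.sum() == small_campaign.cfg.pool_size

    def test_read_depth_conserved(self, small_campaign, small_reads):
        assert len(small_reads) == small_campaign.cfg.read_depth

    def test_error_free_reads_recover_ground_truth(self, small_campaign, small_reads):
        from vnarpan import annotate_all

        records, stats = annotate_all(small_reads)
        assert stats.total == 0
        truth = {c.cdr3_aa for c in small_campaign.clones}
        assert {r.aa for r in records} <= truth

    def test_campaign_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_clones=20, pool_size=2000, read_depth=500, rounds=2,
                        error_rate=0.01, seed=99)
        m1 = simulate_campaign(cfg, "phage", str(tmp_path / "a"))
        m2 = simulate_campaign(cfg, "phage", str(tmp_path / "b"))
        for p1, p2 in zip(m1["outputs"]["phage"]["fastq"], m2["outputs"]["phage"]["fastq"]):
            assert open(p1, "rb").read() == open(p2, "rb").read()
        t1 = open(m1["outputs"]["phage"]["ground_truth"]).read()
        t2 = open(m2["outputs"]["phage"]["ground_truth"]).read()
        assert t1 == t2

    def test_paired_mode_shares_library(self):
        cfg = SimConfig(n_clones=25, pool_size=2000, read_depth=500, rounds=1, seed=4)
        phage, yeast = simulate_paired(cfg)
        assert [c.cdr3_nt for c in phage.clones] == [c.cdr3_nt for c in yeast.clones]
        assert (phage.counts[0] == yeast.counts[0]).all()
        # but mode defaults differ
        assert phage.cfg.valence == 5 and yeast.cfg.valence == 1
        assert phage.cfg.lambda_codon > 0 and yeast.cfg.lambda_codon == 0

    def test_neutrality_limit_flat_in_expectation(self):
        # saturating antigen, no codon penalty: all q = 1, drift only
        cfg = SimConfig(n_clones=50, pool_size=100_000, rounds=4, seed=1,
                        antigen_conc=1e6, lambda_codon=0.0, valence=1,
                        kd_min=1e-9, kd_max=1e-8)
        res = simulate_single(cfg, "phage")
        assert np.allclose(res.q, 1.0, atol=1e-12)
        tables = [
            RoundTable(label=f"r{r}", counts={
                c.cdr3_aa: int(n) for c, n in zip(res.clones, res.counts[r]) if n > 0
            })
            for r in range(5)
        ]
        slopes = []
        for clone in res.clones:
            try:
                slope, _ = estimate_enrichment(tables, clone.cdr3_aa)
                slopes.append(slope)
            except UndefinedStatisticError:
                pass
        assert abs(np.mean(slopes)) < 0.05

    def test_selection_limit_dominant_clone_sweeps(self):
        cfg = SimConfig(n_clones=40, pool_size=50_000, rounds=4, seed=2,
                        antigen_conc=1e-7, kd_min=1e-4, kd_max=1e-3,
                        valence=1, lambda_codon=0.0)
        res = simulate_single(cfg, "phage")
        # make one clone vastly tighter and re-run the rounds
        res.clones[0].kd = 1e-12
        from vnarpan.simulate import capture_probability, run_campaign, Library

        lib = Library(clones=res.clones, counts0=res.counts[0])
        res2 = run_campaign(cfg, "phage", lib, np.random.default_rng(7))
        final_share = res2.counts[-1][0] / cfg.pool_size
        assert final_share > 0.99


class TestEstimateEnrichment:
    def _tables(self, series):
        # series: list of dicts cdr3 -> count
        return [RoundTable(label=f"r{i}", counts=c) for i, c in enumerate(series)]

    def test_flat_slope_zero(self):
        tables = self._tables([{"A": 5, "B": 5}] * 4)
        slope, rounds = estimate_enrichment(tables, "A")
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert rounds == [0, 1, 2, 3]

    def test_doubling_slope_ln2(self):
        # abundance doubles each round: 10% -> 20% -> 40% -> 80%
        tables = self._tables([
            {"A": 10, "B": 90}, {"A": 20, "B": 80}, {"A": 40, "B": 60}, {"A": 80, "B": 20},
        ])
        slope, _ = estimate_enrichment(tables, "A")
        assert slope == pytest.approx(math.log(2))

    def test_single_round_is_error(self):
        tables = self._tables([{"A": 1, "B": 1}, {"B": 2}, {"B": 2}])
        with pytest.raises(UndefinedStatisticError):
            estimate_enrichment(tables, "A")

    def test_top_q_clone_trajectory_nondecreasing_in_mean(self):
        # Monte-Carlo over 100 seeds: the clone with the largest capture
        # probability has non-decreasing expected abundance across rounds
        cfg = SimConfig(n_clones=8, pool_size=4000, rounds=3, read_depth=500,
                        seed=0, valence=1, lambda_codon=0.0)
        lib = None
        from vnarpan.simulate import generate_library, run_campaign

        lib = generate_library(cfg, np.random.default_rng(123))
        mean_ab = np.zeros(cfg.rounds + 1)
        best = None
        for seed in range(100):
            res = run_campaign(cfg, "phage", lib, np.random.default_rng(seed))
            if best is None:
                best = int(np.argmax(res.q))
            for r in range(cfg.rounds + 1):
                mean_ab[r] += res.counts[r][best] / cfg.pool_size
        mean_ab /= 100
        assert all(mean_ab[i + 1] >= mean_ab[i] - 1e-9 for i in range(cfg.rounds))
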