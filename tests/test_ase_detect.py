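"""ASE detection: count filters, folding, statistic, resampling null, BH."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divase import ase_detect as ad
from divase import synthetic_data as sd
from divase.errors import ConfigError, DataError
from divase.variant_io import GeneMap


class TestSnpFilter:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (29, 2, False),   # minor 2 < 3
            (27, 3, True),    # minor 3, total 30, ratio 10%
            (400, 3, False),  # ratio 0.74% < 1%
            (15, 14, False),  # total 29 < 30
            (15, 15, True),
            (0, 0, False),
        ],
    )
    def test_rule_clauses(self, ref, alt, expected):
        assert ad.filter_ase_snp(np.array([ref]), np.array([alt]))[0] == expected

    def test_symmetric_in_labels(self, rng):
        ref = rng.integers(0, 100, 200)
        alt = rng.integers(0, 100, 200)
        np.testing.assert_array_equal(
            ad.filter_ase_snp(ref, alt), ad.filter_ase_snp(alt, ref)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            ad.filter_ase_snp(np.array([-1]), np.array([3]))


class TestFolding:
    def test_tie_folds_to_half(self):
        m, d = ad.fold_counts(np.array([10]), np.array([10]))
        assert (m[0], d[0]) == (10, 20)

    @given(ref=st.integers(0, 500), alt=st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_label_symmetry_and_majority(self, ref, alt):
        m1, d1 = ad.fold_counts(np.array([ref]), np.array([alt]))
        m2, d2 = ad.fold_counts(np.array([alt]), np.array([ref]))
        assert m1[0] == m2[0] and d1[0] == d2[0]
        assert 2 * m1[0] >= d1[0]


class TestStatistic:
    def test_balanced_counts_give_zero(self):
        m = np.array([10.0, 25.0, 7.0])
        d = 2 * m
        assert ad.ase_statistic(m, d, np.array([0, 0, 1])) == 0.0

    def test_complete_imbalance_closed_form(self):
        d = 37
        t = ad.ase_statistic(np.array([d]), np.array([d]), np.array([0]))
        assert t == pytest.approx(2 * d * math.log(2), rel=1e-12)

    def test_matches_straight_line_reimplementation(self):
        genes = GeneMap(
            pd.DataFrame(
                {"gene_id": ["g"], "contig": ["1"], "start": [1], "end": [1000]}
            )
        )
        cfg = sd.AseSimConfig(
            groups=(("LB", 24),), n_individuals=10, snps_per_gene=3,
            depth_mean=50, pi_truth=0.7, seed=17,
        )
        counts, _ = sd.simulate_ase_counts(genes, cfg)
        m, d = ad.fold_counts(
            counts["ref_reads"].to_numpy(), counts["alt_reads"].to_numpy()
        )
        codes, _ = pd.factorize(counts["individual"], sort=True)
        got = ad.ase_statistic(m, d, codes)

        expected = 0.0
        for j in np.unique(codes):
            mj, dj = m[codes == j], d[codes == j]
            p_hat = mj.sum() / dj.sum()
            for ms, ds in zip(mj, dj):
                term = 0.0
                if ms:
                    term += ms * math.log(p_hat)
                if ds - ms:
                    term += (ds - ms) * math.log(1 - p_hat)
                term -= ds * math.log(0.5)
                expected += 2 * term
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(50):
            d = rng.integers(30, 80, size=12)
            x = rng.binomial(d, 0.5)
            m = np.maximum(x, d - x)
            assert ad.ase_statistic(m, d, np.repeat(np.arange(4), 3)) >= 0

    def test_empty_gene_raises(self):
        with pytest.raises(DataError):
            ad.ase_statistic(np.array([]), np.array([]), np.array([], dtype=int))


class TestResamplingTest:
    def test_null_statistic_saturates_and_stops_early(self):
        m = np.array([20.0, 15.0])
        d = np.array([40.0, 30.0])  # exactly balanced: T_obs = 0
        t, used, p = ad.ase_test(
            m, d, np.array([0, 1]), np.random.default_rng(0),
            r_max=10_000, batch=1_000, stop_hits=50,
        )
        assert t == 0.0
        assert used == 1_000  # stop after the first batch
        assert p > 0.05

    def test_strong_signal_floors_at_smallest_p(self):
        genes = GeneMap(
            pd.DataFrame({"gene_id": ["g"], "contig": ["1"], "start": [1], "end": [500]})
        )
        cfg = sd.AseSimConfig(
            groups=(("LB", 10),), n_individuals=10, snps_per_gene=5,
            depth_mean=100, pi_truth=0.9, seed=23,
        )
        counts, _ = sd.simulate_ase_counts(genes, cfg)
        m, d = ad.fold_counts(
            counts["ref_reads"].to_numpy(), counts["alt_reads"].to_numpy()
        )
        codes, _ = pd.factorize(counts["individual"], sort=True)
        _, used, p = ad.ase_test(
            m, d, codes, np.random.default_rng(1), r_max=10_000
        )
        assert used == 10_000
        assert p == pytest.approx(1 / 10_001)

    def test_p_value_validity_bound(self, rng):
        d = rng.integers(30, 60, size=6).astype(float)
        x = rng.binomial(d.astype(int), 0.6)
        m = np.maximum(x, d - x).astype(float)
        _, used, p = ad.ase_test(
            m, d, np.repeat(np.arange(3), 2), np.random.default_rng(2), r_max=2_000
        )
        assert p >= 1 / (used + 1) - 1e-15

    def test_r_max_below_batch_rejected(self):
        with pytest.raises(ConfigError):
            ad.ase_test(
                np.array([5.0]), np.array([10.0]), np.array([0]),
                np.random.default_rng(0), r_max=10, batch=100,
            )


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            ad.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(ad.bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_textbook_step_up(self, rng):
        def textbook_bh(p):
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, p[idx] * m / rank)
                q[idx] = prev
            return q

        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(ad.bh_adjust(p), textbook_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            ad.bh_adjust(np.array([0.0, 0.5]))


@pytest.fixture(scope="module")
def genes():
    n = 12
    return GeneMap(
        pd.DataFrame(
            {
                "gene_id": [f"g{i:02d}" for i in range(n)],
                "contig": "1",
                "start": np.arange(n) * 1000 + 1,
                "end": np.arange(n) * 1000 + 900,
            }
        )
    )


class TestDetectAse:
    def test_results_independent_of_row_order(self, genes):
        cfg = sd.AseSimConfig(groups=(("LB", 10), ("LSL", 10)), pi_truth=0.6, seed=31)
        counts, _ = sd.simulate_ase_counts(genes, cfg)
        r1 = ad.detect_ase(counts, r_max=1_000, seed=5)
        r2 = ad.detect_ase(counts.sample(frac=1, random_state=3), r_max=1_000, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_gene_with_no_accepted_snps_skipped(self, genes):
        counts = pd.DataFrame(
            [["i1", "LB", 10, "g00", "1", 5, 2, 1]],  # fails every clause
            columns=["individual", "strain", "week", "gene_id", "contig", "pos",
                     "ref_reads", "alt_reads"],
        )
        out = ad.detect_ase(counts, r_max=1_000, seed=1)
        assert out.empty

    def test_q_values_within_group(self, genes):
        cfg = sd.AseSimConfig(groups=(("LB", 10), ("LSL", 10)), pi_truth=0.55, seed=37)
        counts, _ = sd.simulate_ase_counts(genes, cfg)
        out = ad.detect_ase(counts, r_max=1_000, seed=7)
        for _, grp in out.groupby(["strain", "week"]):
            np.testing.assert_allclose(
                grp["q_bh"].to_numpy(),
                ad.bh_adjust(grp["p_empirical"].to_numpy()),
                atol=1e-12,
            )

    def test_mean_statistic_monotone_in_imbalance(self, genes):
        """Stronger true imbalance yields a larger mean statistic."""
        means = []
        for pi in (0.5, 0.6, 0.7, 0.8):
            cfg = sd.AseSimConfig(groups=(("LB", 10),), pi_truth=pi, seed=41)
            counts, _ = sd.simulate_ase_counts(genes, cfg)
            out = ad.detect_ase(counts, r_max=1_000, seed=2)
            means.append(out["statistic_T"].mean())
        assert means == sorted(means)
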