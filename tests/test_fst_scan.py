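"""Weir–Cockerham estimator and the gene-level Z screen.

The oracle here is a deliberately plain, scalar transliteration of the
two-population method-of-moments formulas, kept independent of the
vectorized implementation it checks.
"""

import math

import numpy as np
import pandas as pd
import pytest

from divase import fst_scan as fs
from divase import snp_filter as sf
from divase.errors import ConfigError, DataError
from divase.variant_io import GeneMap


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Straight-line evaluation of the r=2 variance-component formulas."""
    r = 2.0
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - s2 * (r - 1.0) / r
        - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    return a, b, c, (a / denom if denom != 0 else math.nan)


class TestWcTheta:
    def test_complete_fixation_gives_theta_one(self):
        comp = fs.wc_theta_snp(np.full(10, 2.0), np.zeros(10))
        assert comp.theta == pytest.approx(1.0, abs=1e-15)
        assert comp.a == pytest.approx(0.5, abs=1e-15)
        assert comp.b == pytest.approx(0.0, abs=1e-15)
        assert comp.c == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_pair_theta_undefined(self):
        comp = fs.wc_theta_snp(np.zeros(10), np.zeros(10))
        assert not comp.defined

    @pytest.mark.parametrize(
        "summ",
        [
            (10, 0.6, 0.48, 10, 0.4, 0.48),
            (90, 0.75, 0.30, 21, 0.10, 0.15),
            (50, 0.5, 0.5, 50, 0.5, 0.5),
        ],
    )
    def test_matches_independent_formula_oracle(self, summ):
        n1, p1, h1, n2, p2, h2 = summ
        a, b, c, theta = wc_oracle(*map(float, summ))
        row = fs.wc_from_summaries(n1, p1, h1, n2, p2, h2).iloc[0]
        assert row["a"] == pytest.approx(a, abs=1e-12)
        assert row["b"] == pytest.approx(b, abs=1e-12)
        assert row["c"] == pytest.approx(c, abs=1e-12)
        if math.isnan(theta):
            assert math.isnan(row["theta"])
        else:
            assert row["theta"] == pytest.approx(theta, abs=1e-12)

    def test_dosage_path_matches_oracle_via_summaries(self, rng):
        d1 = rng.integers(0, 3, size=25).astype(float)
        d2 = rng.integers(0, 3, size=30).astype(float)
        d1[rng.random(25) < 0.2] = np.nan
        n1 = np.sum(~np.isnan(d1))
        n2 = np.sum(~np.isnan(d2))
        p1 = np.nansum(d1) / (2 * n1)
        p2 = np.nansum(d2) / (2 * n2)
        h1 = np.nansum(d1 == 1) / n1
        h2 = np.nansum(d2 == 1) / n2
        _, _, _, theta = wc_oracle(n1, p1, h1, n2, p2, h2)
        comp = fs.wc_theta_snp(d1, d2)
        assert comp.theta == pytest.approx(theta, abs=1e-12)

    def test_negative_theta_retained(self):
        # identical frequencies, many heterozygotes -> small negative a
        d = np.array([1.0] * 8 + [0.0, 2.0])
        comp = fs.wc_theta_snp(d, d)
        assert comp.defined and comp.theta < 0

    def test_all_missing_population_raises(self):
        with pytest.raises(DataError):
            fs.wc_theta_snp(np.full(5, np.nan), np.zeros(5))

    def test_tiny_sample_raises(self):
        with pytest.raises(DataError):
            fs.wc_theta_snp(np.array([1.0]), np.array([np.nan, 1.0]))

    def test_theta_never_exceeds_one(self, rng):
        d1 = rng.integers(0, 3, size=(500, 12)).astype(float)
        d2 = rng.integers(0, 3, size=(500, 12)).astype(float)
        comp = fs.wc_components_matrix(d1, d2)
        assert np.nanmax(comp["theta"]) <= 1.0 + 1e-12


def test_permutation_null_centers_theta_at_zero(small_cohort, rng):
    """Shuffling population labels should erase differentiation."""
    gm, _, _ = small_cohort
    filtered, _ = sf.apply_filters(gm, ("A", "B"))
    perm = rng.permutation(filtered.n_individuals)
    half = filtered.n_individuals // 2
    comp = fs.wc_components_matrix(
        filtered.dosage[:, perm[:half]], filtered.dosage[:, perm[half:]]
    )
    assert abs(np.nanmean(comp["theta"])) < 0.01


class TestAggregation:
    @pytest.fixture()
    def per_snp(self):
        return pd.DataFrame(
            {
                "contig": ["1"] * 6,
                "pos": [100, 150, 200, 250, 900, 950],
                "id": [f"s{i}" for i in range(6)],
                "a": [0.1] * 6,
                "b": [0.1] * 6,
                "c": [0.1] * 6,
                "theta": [0.1, 0.2, 0.3, np.nan, 0.5, 0.6],
            }
        )

    @pytest.fixture()
    def genes(self):
        return GeneMap(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "contig": ["1", "1"],
                    "start": [100, 900],
                    "end": [300, 1000],
                }
            )
        )

    def test_mean_and_min_snps(self, per_snp, genes):
        out = fs.aggregate_gene_fst(per_snp, genes, min_snps=3)
        # g1 has thetas {0.1, 0.2, 0.3} (NaN dropped); g2 only 2 -> dropped
        assert out["gene_id"].tolist() == ["g1"]
        assert out.loc[0, "mean_fst"] == pytest.approx(0.2)
        assert out.loc[0, "n_snps"] == 3

    def test_undefined_theta_not_counted(self, per_snp, genes):
        out = fs.aggregate_gene_fst(per_snp, genes, min_snps=4)
        assert out.empty  # the NaN SNP must not rescue g1

    def test_overlapping_genes_count_snp_in_each(self, per_snp):
        genes = GeneMap(
            pd.DataFrame(
                {
                    "gene_id": ["g1", "g2"],
                    "contig": ["1", "1"],
                    "start": [100, 100],
                    "end": [300, 300],
                }
            )
        )
        out = fs.aggregate_gene_fst(per_snp, genes, min_snps=3)
        assert out["gene_id"].tolist() == ["g1", "g2"]
        np.testing.assert_allclose(out["mean_fst"], 0.2)

    def test_assignment_matches_all_pairs_brute_force(self, rng):
        n_snps, n_genes = 500, 40
        snps = pd.DataFrame(
            {
                "contig": rng.choice(["1", "2"], n_snps),
                "pos": rng.integers(1, 10_000, n_snps),
                "id": [f"s{i}" for i in range(n_snps)],
            }
        )
        starts = rng.integers(1, 9_000, n_genes)
        genes = GeneMap(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n_genes)],
                    "contig": rng.choice(["1", "2"], n_genes),
                    "start": starts,
                    "end": starts + rng.integers(50, 2_000, n_genes),
                }
            )
        )
        got = fs.assign_snps_to_genes(snps, genes)
        got_set = set(map(tuple, got.to_numpy()))
        brute = {
            (i, g.gene_id)
            for i, s in snps.iterrows()
            for g in genes.table.itertuples(index=False)
            if s["contig"] == g.contig and g.start <= s["pos"] <= g.end
        }
        assert got_set == brute

    def test_empty_gene_map_raises(self, per_snp):
        with pytest.raises(DataError):
            fs.aggregate_gene_fst(per_snp, GeneMap(), min_snps=3)


class TestZTransform:
    def test_unit_example(self):
        z, mu, sigma = fs.z_transform([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0], atol=1e-15)
        assert mu == 2.0 and sigma == 1.0

    def test_all_equal_degenerate(self):
        with pytest.raises(DataError):
            fs.z_transform([0.3, 0.3, 0.3])

    def test_normalization_identity(self, rng):
        vals = rng.random(500)
        z, _, _ = fs.z_transform(vals)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1.0) < 1e-12


class TestSelection:
    @pytest.fixture()
    def results(self, rng):
        n = 200
        return pd.DataFrame(
            {"gene_id": [f"g{i:04d}" for i in range(n)], "z_fst": rng.normal(size=n)}
        )

    def test_boundary_z_exactly_threshold_is_candidate(self, results):
        results.loc[0, "z_fst"] = 4.0
        out = fs.select_candidates(results, 4.0)
        assert bool(out.loc[0, "is_candidate"])

    def test_top_fraction_is_ceil(self, results):
        out = fs.select_top_fraction(results, 0.01)
        assert out["in_top_fraction"].sum() == math.ceil(0.01 * len(results))

    def test_top_fraction_count_matches_reported_universe(self):
        """ceil(0.01 * 8929) = 90 genes in a screen of that size."""
        n = 8929
        res = pd.DataFrame(
            {"gene_id": [f"g{i:05d}" for i in range(n)],
             "z_fst": np.linspace(-3, 5, n)}
        )
        out = fs.select_top_fraction(res, 0.01)
        assert out["in_top_fraction"].sum() == 90

    def test_threshold_monotonicity(self, results):
        counts = [
            fs.select_candidates(results, t)["is_candidate"].sum()
            for t in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_tie_break_deterministic(self):
        res = pd.DataFrame({"gene_id": ["b", "a", "c"], "z_fst": [1.0, 1.0, 0.0]})
        out = fs.select_top_fraction(res, 1 / 3)
        assert out.loc[out["in_top_fraction"], "gene_id"].tolist() == ["a"]

    def test_bad_fraction_rejected(self, results):
        with pytest.raises(ConfigError):
            fs.select_top_fraction(results, 0.0)
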