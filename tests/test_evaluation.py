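import numpy as np
import pytest

from restore import (
    BackgroundEstimate,
    CompositionVector,
    FeatureTable,
    InputError,
    ReplicateGroup,
    SimConfig,
    UndefinedStatisticError,
    coefficient_of_variation,
    composition_correlation,
    kmeans_concordance,
    local_vs_global_report,
    normalize,
    quantile_normalize,
    simulate_sections,
)
from restore.simulation import sections_pair_config


def comp(sample, fractions, total=100):
    fractions = np.asarray(fractions, dtype=float)
    return CompositionVector(
        sample_id=sample,
        categories=[f"k{i}" for i in range(len(fractions))],
        counts=fractions * total,
        total_cells=total,
    )


class TestCompositionCorrelation:
    def test_identical_vectors_give_one(self):
        a = comp("a", [0.1, 0.2, 0.7])
        assert composition_correlation(a, comp("b", [0.1, 0.2, 0.7])) == pytest.approx(1.0)

    def test_reversed_vector_gives_minus_one(self):
        # reversal flips the correlation to exactly -1 when the vector is
        # anti-symmetric about its mean (x + reverse(x) constant)
        a = comp("a", [0.1, 0.2, 0.3, 0.4])
        b = comp("b", [0.4, 0.3, 0.2, 0.1])
        assert composition_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_hand_rolled_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.dirichlet(np.ones(6))
            y = rng.dirichlet(np.ones(6))
            got = composition_correlation(comp("a", x), comp("b", y))
            xc, yc = x - x.mean(), y - y.mean()
            expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
            assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            composition_correlation(comp("a", [0.5, 0.5]), comp("b", [0.3, 0.7]))

    def test_category_mismatch_rejected(self):
        a = comp("a", [0.5, 0.5])
        b = CompositionVector("b", ["x", "y"], np.array([1.0, 2.0]), 3)
        with pytest.raises(InputError):
            composition_correlation(a, b)


class TestCoefficientOfVariation:
    def test_no_dispersion_gives_zero(self):
        assert coefficient_of_variation([10, 10, 10]) == 0.0

    def test_sample_sd_convention(self):
        # (8,10,12): sample sd 2, mean 10
        assert coefficient_of_variation([8, 10, 12]) == pytest.approx(0.2)

    def test_scale_invariance(self):
        v = np.array([3.0, 5.0, 9.0])
        assert coefficient_of_variation(7 * v) == pytest.approx(
            coefficient_of_variation(v)
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([0, 0, 0])


class TestKmeansConcordance:
    @staticmethod
    def _replicated_table(seed=0, n=120):
        rng = np.random.default_rng(seed)
        block = rng.gamma(2.0, 1.0, size=(n, 3))
        return FeatureTable(
            cell_id=np.array([f"c{i}" for i in range(n)] * 3, dtype=object),
            sample_id=np.array(
                ["s1"] * n + ["s2"] * n + ["s3"] * n, dtype=object
            ),
            markers=["a", "b", "c"],
            intensities=np.vstack([block, block, block]),
        )

    def test_identical_replicates_give_unit_correlation(self):
        table = self._replicated_table()
        groups = [ReplicateGroup("g", ["s1", "s2", "s3"])]
        rep = kmeans_concordance(table, groups, k_values=(5, 10), seed=0)
        np.testing.assert_allclose(rep.r, 1.0, rtol=1e-12)

    def test_fixed_seed_is_bit_reproducible(self):
        table = self._replicated_table(seed=3)
        groups = [ReplicateGroup("g", ["s1", "s2", "s3"])]
        a = kmeans_concordance(table, groups, k_values=(5,), seed=7)
        b = kmeans_concordance(table, groups, k_values=(5,), seed=7)
        assert a.equals(b)

    def test_k_exceeding_cells_rejected(self):
        table = self._replicated_table(n=4)
        groups = [ReplicateGroup("g", ["s1", "s2", "s3"])]
        with pytest.raises(InputError):
            kmeans_concordance(table, groups, k_values=(50,), seed=0)


class TestQuantileNormalize:
    def test_single_sample_is_identity(self, random_table):
        single = random_table.subset(random_table.sample_id == "a")
        out = quantile_normalize(single)
        np.testing.assert_allclose(out.intensities, single.intensities)

    def test_pure_gain_difference_aligns_windows(self):
        rng = np.random.default_rng(5)
        base = rng.gamma(2.0, 1.0, size=(300, 2))
        table = FeatureTable(
            cell_id=np.array([f"c{i}" for i in range(600)], dtype=object),
            sample_id=np.array(["s1"] * 300 + ["s2"] * 300, dtype=object),
            markers=["a", "b"],
            intensities=np.vstack([base, 3.0 * base]),
        )
        out = quantile_normalize(table)
        for j in range(2):
            p1 = [
                np.percentile(out.intensities[out.sample_id == s, j], [1, 99])
                for s in ("s1", "s2")
            ]
            np.testing.assert_allclose(p1[0], p1[1], rtol=1e-9)

    def test_inflates_sample_without_positives_where_restore_does_not(self):
        """The known QN failure mode: a sample with no positive cells for
        a marker has its negatives stretched into the pooled positive
        range, while background normalization leaves them at background."""
        rng = np.random.default_rng(8)
        n = 200
        pos = np.arange(n) < 100
        ref_a = np.where(pos, rng.uniform(9, 11, n), rng.lognormal(0, 0.2, n))
        other_a = np.where(~pos, rng.uniform(9, 11, n), rng.lognormal(0, 0.2, n))
        ref_b = rng.lognormal(0, 0.2, n)           # no positives in sample B
        other_b = rng.uniform(9, 11, n)
        table = FeatureTable(
            cell_id=np.array([f"c{i}" for i in range(2 * n)], dtype=object),
            sample_id=np.array(["A"] * n + ["B"] * n, dtype=object),
            markers=["REF", "OTHER"],
            intensities=np.vstack(
                [np.column_stack([ref_a, other_a]), np.column_stack([ref_b, other_b])]
            ),
        )
        qn = quantile_normalize(table)
        assert qn.column("REF")[table.sample_id == "B"].max() > 5.0
        ests = []
        for s, neg_mask in [("A", ~pos), ("B", np.ones(n, bool))]:
            col = table.column("REF")[table.sample_id == s][neg_mask]
            ests.append(
                BackgroundEstimate(
                    sample_id=s, reference="REF", targets_used=["OTHER"],
                    B_bar=float(np.percentile(col, 99)),
                    method="percentile", percentile=99.0, n_negative=int(neg_mask.sum()),
                )
            )
        restored = normalize(table, ests)
        assert restored.column("REF")[table.sample_id == "B"].max() < 1.5


class TestLocalVsGlobalReport:
    def test_equal_gains_make_modes_agree(self):
        cfg = SimConfig(
            sbr=10.0, n_cells_per_section=600, section_gains=(1.0, 1.0, 1.0), seed=9
        )
        table, _ = simulate_sections(cfg)
        groups = [ReplicateGroup("core", table.samples)]
        rep = local_vs_global_report(
            table, groups, sections_pair_config(), seed=0, max_cells=200
        )
        r = rep[rep.statistic == "pairwise_r"].groupby("mode").value.mean()
        assert r["local"] > 0.9
        assert r["global"] > 0.9
        assert abs(r["local"] - r["global"]) < 0.1

    def test_statistics_invariant_under_consistent_category_permutation(self):
        rng = np.random.default_rng(11)
        x = rng.dirichlet(np.ones(8))
        y = rng.dirichlet(np.ones(8))
        perm = rng.permutation(8)
        r = composition_correlation(comp("a", x), comp("b", y))
        r_perm = composition_correlation(comp("a", x[perm]), comp("b", y[perm]))
        assert r_perm == pytest.approx(r, rel=1e-12)
        counts = rng.integers(5, 50, size=4)
        assert coefficient_of_variation(counts[::-1]) == pytest.approx(
            coefficient_of_variation(counts)
        )
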