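"""Identity clustering, divergence correction, rarefaction."""

import dataclasses

import numpy as np
import pytest

from ribotraits import synthetic
from ribotraits.errors import InsufficientDataError, InvalidInputError
from ribotraits.variants import (
    DEFAULT_THRESHOLDS,
    Variant,
    VariantPool,
    corrected_divergence,
    dominant_proportion,
    expected_rarefied_richness,
    greedy_cluster,
    leveling_threshold,
    pairwise_identity,
    rarefied_richness,
    richness_vs_cn_regression,
    threshold_scan,
)


def _mutate_at(seq: str, positions, rng=None) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def _pool(seq_counts, **kw):
    variants = tuple(
        Variant(s, c, f"v{i}") for i, (s, c) in enumerate(seq_counts)
    )
    return VariantPool(
        cell_id=kw.pop("cell_id", "c1"),
        pool_type=kw.pop("pool_type", "rDNA"),
        variants=variants,
        **kw,
    )


BASE = synthetic.random_template(100, seed=99)


class TestPairwiseIdentity:
    def test_self_identity(self):
        assert pairwise_identity(BASE, BASE) == 1.0

    def test_hamming_case(self):
        assert pairwise_identity(BASE, _mutate_at(BASE, [5, 40, 77])) == pytest.approx(
            0.97
        )

    def test_internal_deletion_counts_gap_columns(self):
        # 2-nt internal deletion: 100 alignment columns, 98 matches
        deleted = BASE[:50] + BASE[52:]
        assert pairwise_identity(BASE, deleted) == pytest.approx(0.980)

    def test_terminal_gaps_excluded(self):
        assert pairwise_identity(BASE, BASE + "ACGTACGT") == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            pairwise_identity("", BASE)


class TestGreedyCluster:
    def test_identical_sequences_single_cluster(self):
        pool = _pool([(BASE, 10), (BASE, 5)])
        for t in (0.89, 0.97, 1.0):
            assert greedy_cluster(pool, t).otu_count == 1

    def test_three_percent_divergence_splits_at_098(self):
        minor = _mutate_at(BASE, [3, 33, 63])
        pool = _pool([(BASE, 100), (minor, 10)])
        assert greedy_cluster(pool, 0.97).otu_count == 1
        assert greedy_cluster(pool, 0.98).otu_count == 2

    def test_exact_grouping_at_unity(self):
        pool = _pool([(BASE, 5), (_mutate_at(BASE, [1]), 4), (BASE[::-1], 3)])
        assert greedy_cluster(pool, 1.0).otu_count == 3

    def test_order_invariance(self):
        seqs = [(BASE, 50), (_mutate_at(BASE, [2, 30]), 20), (_mutate_at(BASE, range(12)), 7)]
        a = greedy_cluster(_pool(seqs), 0.97)
        b = greedy_cluster(_pool(seqs[::-1]), 0.97)
        assert [c.centroid.sequence for c in a.clusters] == [
            c.centroid.sequence for c in b.clusters
        ]

    def test_threshold_bounds(self):
        with pytest.raises(InvalidInputError):
            greedy_cluster(_pool([(BASE, 1)]), 0.5)


class TestThresholdScan:
    def test_single_variant_flat_scan(self):
        scan = threshold_scan(_pool([(BASE, 7)]))
        assert all(c == 1 for _, c in scan)
        assert len(scan) == len(DEFAULT_THRESHOLDS)

    def test_counts_non_increasing_as_threshold_drops(self, steinii):
        pool = synthetic.gen_variant_pool(
            steinii, substitution_error_rate=0.01, seed=5
        )
        counts = [c for _, c in threshold_scan(pool)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_steps_at_constructed_divergences(self):
        # variants at 2% and 8% divergence: counts drop at 0.98 and 0.92
        pool = _pool(
            [(BASE, 100), (_mutate_at(BASE, [1, 51]), 20), (_mutate_at(BASE, range(0, 80, 10)), 10)]
        )
        scan = dict(threshold_scan(pool))
        assert scan[0.99] == 3
        assert scan[0.98] == 2  # 2%-divergent variant merges
        assert scan[0.93] == 2
        assert scan[0.92] == 1  # 8%-divergent variant merges


class TestLevelingAndCorrection:
    def test_single_variant_levels_at_unity(self):
        level, leveled = leveling_threshold(threshold_scan(_pool([(BASE, 3)])))
        assert (level, leveled) == (1.0, True)

    def test_marine_rdna_configuration(self):
        # one variant 1% divergent from the dominant: single OTU from the
        # 99% cutoff downward, zero residual error → divergence 1%
        template = synthetic.random_template(445, seed=3)
        minor = _mutate_at(template, [10, 120, 230, 340])
        pool = _pool([(template, 1500), (minor, 100)])
        level, leveled = leveling_threshold(threshold_scan(pool))
        assert leveled and level == pytest.approx(0.99)
        assert corrected_divergence(level, 0.0) == pytest.approx(0.01)

    def test_never_leveling_is_flagged(self):
        far = _mutate_at(BASE, range(0, 60, 2))  # 30% divergent
        level, leveled = leveling_threshold(threshold_scan(_pool([(BASE, 9), (far, 5)])))
        assert not leveled and level == pytest.approx(0.89)

    @pytest.mark.parametrize(
        "leveling,error,expected",
        [(0.89, 0.01, 0.10), (0.95, 0.01, 0.04), (1.00, 0.00, 0.0), (0.99, 0.0, 0.01)],
    )
    def test_corrected_divergence_examples(self, leveling, error, expected):
        assert corrected_divergence(leveling, error) == pytest.approx(expected)

    @pytest.mark.parametrize("true_div", [0.04, 0.06, 0.10])
    def test_divergence_round_trip_without_error(self, true_div):
        # a pool built at known max divergence (isolated interior
        # substitutions) and zero error recovers the divergence to within
        # one grid step
        n = round(true_div * len(BASE))
        pool = _pool([(BASE, 100), (_mutate_at(BASE, range(5, 5 + 5 * n, 5)), 10)])
        level, leveled = leveling_threshold(threshold_scan(pool))
        assert leveled
        assert abs(corrected_divergence(level, 0.0) - true_div) <= 0.01 + 1e-12


class TestDominantProportion:
    def test_single_variant(self):
        assert dominant_proportion(_pool([(BASE, 42)])) == 1.0

    def test_equal_split(self):
        far = _mutate_at(BASE, range(0, 60, 2))
        assert dominant_proportion(_pool([(BASE, 50), (far, 50)]), 0.97) == 0.5

    def test_generated_pools_cover_observed_band(self, steinii, inflata):
        # observed dominant-OTU proportions span 87%–100%
        for profile, seed in ((steinii, 1), (inflata, 2)):
            pool = synthetic.gen_variant_pool(profile, seed=seed)
            assert 0.87 <= dominant_proportion(pool, 0.99) <= 1.0


class TestRarefaction:
    def test_single_variant_any_depth(self):
        assert rarefied_richness(_pool([(BASE, 2000)]), depth=1600) == 1.0

    def test_full_depth_equals_pool_count(self):
        pool = _pool([(BASE, 900), (_mutate_at(BASE, range(20)), 700)])
        assert rarefied_richness(pool, depth=1600, threshold=0.97) == 2.0

    def test_matches_hypergeometric_expectation(self):
        rng = np.random.default_rng(99)
        counts = [1024, 512, 256, 128, 64, 32, 16, 8, 4, 2]
        seqs = [synthetic.random_template(120, seed=200 + i) for i in range(10)]
        pool = _pool(list(zip(seqs, counts)))
        mean = rarefied_richness(pool, depth=1600, threshold=1.0, reps=100, seed=7)
        expect = expected_rarefied_richness(pool, depth=1600, threshold=1.0)
        assert abs(mean - expect) <= 0.2

    def test_depth_exceeding_reads_errors(self):
        with pytest.raises(InsufficientDataError):
            rarefied_richness(_pool([(BASE, 100)]), depth=1600)

    def test_seed_determinism(self):
        pool = _pool([(BASE, 1800), (_mutate_at(BASE, range(10)), 300)])
        a = rarefied_richness(pool, depth=1600, reps=20, seed=5)
        b = rarefied_richness(pool, depth=1600, reps=20, seed=5)
        assert a == b


class TestRichnessRegression:
    def test_monotone_decreasing_data_gives_negative_slope(self):
        cn = np.logspace(3, 6, 12)
        otus = 6.0 - 1.2 * np.log10(cn) / 2 + 0.01
        fit = richness_vs_cn_regression(otus, cn)
        assert fit.slope < 0
        assert fit.r_squared > 0.9

    def test_flat_richness_gives_zero_slope(self):
        cn = np.logspace(3, 6, 10)
        fit = richness_vs_cn_regression(np.full(10, 3.0), cn)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_generator_reproduces_reported_effect_size_band(self):
        # weak negative coupling: R² should land in a plausible 0.1–0.5 band
        rng = np.random.default_rng(11)
        cn = 10 ** rng.uniform(3, 6, 60)
        otus = np.clip(6.5 - 0.9 * np.log10(cn) + rng.normal(0, 1.4, 60), 1, None)
        fit = richness_vs_cn_regression(otus, cn)
        assert fit.slope < 0
        assert 0.1 <= fit.r_squared <= 0.5
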