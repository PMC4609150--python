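import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from g2o import (
    ExpressionMatrix,
    RocThresholds,
    auc_null_se,
    auc_p_value,
    compute_auc,
    derive_fingerprint,
    generate_paired_cohorts,
    SyntheticConfig,
)
from g2o.genotype import MutationPattern


def pairwise_auc(expr, labels):
    """Independent oracle: explicit concordant-pair enumeration."""
    pos = [e for e, l in zip(expr, labels) if l == 1]
    neg = [e for e, l in zip(expr, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def permutation_aucs(n1, n0):
    """All AUC values over label permutations of distinct expression values."""
    n = n1 + n0
    expr = np.arange(1.0, n + 1)
    values = []
    for pos_idx in itertools.combinations(range(n), n1):
        labels = np.zeros(n, dtype=int)
        labels[list(pos_idx)] = 1
        values.append(pairwise_auc(expr, labels))
    return np.array(values)


class TestComputeAuc:
    def test_perfect_separation_is_one(self):
        assert compute_auc([1, 2, 9, 8], [0, 0, 1, 1]) == 1.0

    def test_constant_expression_all_ties_is_half(self):
        assert compute_auc([3.0] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_hand_enumerated_example(self):
        # pairs (2,1),(2,3),(4,1),(4,3): three concordant of four
        assert compute_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_matches_pair_enumeration_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(4, 15))
            expr = rng.choice([0.0, 1.0, 2.5, 7.0, 7.0, 9.0], size=n)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert compute_auc(expr, labels) == pytest.approx(
                pairwise_auc(expr, labels), abs=1e-12
            )

    def test_flip_symmetry(self):
        rng = np.random.default_rng(1)
        expr = rng.normal(size=10)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        assert compute_auc(expr, labels) == pytest.approx(
            1.0 - compute_auc(expr, 1 - labels), abs=1e-12
        )

    @given(
        st.lists(st.integers(-5000, 5000), min_size=4, max_size=12, unique=True),
        st.data(),
    )
    def test_invariant_under_strictly_increasing_transform(self, expr, data):
        n = len(expr)
        n1 = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, dtype=int)
        labels[:n1] = 1
        expr = np.array(expr, dtype=float) / 100.0
        raw = compute_auc(expr, labels)
        assert compute_auc(np.exp(expr / 25.0), labels) == pytest.approx(raw, abs=1e-12)
        assert compute_auc(3.0 * expr + 7.0, labels) == pytest.approx(raw, abs=1e-12)

    def test_single_class_pattern_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc([1.0, 2.0], [1, 1])


class TestAucNullSe:
    def test_two_point_null(self):
        # n1 = n0 = 1: AUC is 0 or 1 with equal probability, SD 1/2
        assert auc_null_se(1, 1) == pytest.approx(0.5)

    def test_enumerated_2v2(self):
        assert auc_null_se(2, 2) == pytest.approx(math.sqrt(5 / 48))

    def test_symmetry(self):
        assert auc_null_se(3, 7) == auc_null_se(7, 3)

    @pytest.mark.parametrize("n1", [1, 2, 3, 4])
    @pytest.mark.parametrize("n0", [1, 2, 3, 4])
    def test_exact_permutation_sd(self, n1, n0):
        aucs = permutation_aucs(n1, n0)
        assert auc_null_se(n1, n0) == pytest.approx(aucs.std(ddof=0), abs=1e-12)

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            auc_null_se(0, 5)


class TestAucPValue:
    def test_null_auc_gives_p_one(self):
        assert auc_p_value(0.5, 10, 20) == 1.0

    def test_symmetric_in_direction(self):
        assert auc_p_value(0.8, 9, 14) == pytest.approx(auc_p_value(0.2, 9, 14))

    def test_frozen_perfect_separation_example(self):
        # z = 0.5 / sqrt(11/300), checked against an independent erf form
        z = 0.5 / math.sqrt(11 / 300)
        assert z == pytest.approx(2.6112, abs=5e-5)
        p_erf = math.erfc(z / math.sqrt(2))
        assert auc_p_value(1.0, 5, 5) == pytest.approx(p_erf, rel=1e-12)
        assert auc_p_value(1.0, 5, 5) == pytest.approx(9.0e-3, abs=5e-4)

    def test_normal_approximation_tracks_exact_permutation_p(self):
        # At n1 = n0 = 20 the analytic p stays within 15% of the exact
        # Mann-Whitney permutation p for moderate effect sizes (|z| < 3).
        n1 = n0 = 20
        rng = np.random.default_rng(9)
        for shift in (0.3, 0.6, 0.9):
            x1 = rng.normal(shift, 1, n1)
            x0 = rng.normal(0, 1, n0)
            auc = compute_auc(
                np.concatenate([x1, x0]), np.r_[np.ones(n1, int), np.zeros(n0, int)]
            )
            z = abs(auc - 0.5) / auc_null_se(n1, n0)
            if z >= 3:
                continue
            exact = stats.mannwhitneyu(
                x1, x0, alternative="two-sided", method="exact"
            ).pvalue
            approx = auc_p_value(auc, n1, n0)
            assert abs(approx - exact) / exact < 0.15


def _matrix_and_pattern(values, labels, genes=None):
    genes = genes or [f"G{i}" for i in range(len(values))]
    samples = [f"S{i}" for i in range(len(labels))]
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    pattern = MutationPattern(samples, np.array(labels, int), ("DRV",))
    return expr, pattern


class TestDeriveFingerprint:
    def test_threshold_membership(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        strong_up = np.r_[rng.normal(5, 0.5, 10), rng.normal(0, 0.5, 10)]
        weak = rng.normal(0, 1, 20)
        strong_down = -strong_up
        expr, pattern = _matrix_and_pattern(
            [strong_up, weak, strong_down], labels, ["UPG", "WEAK", "DNG"]
        )
        sets = derive_fingerprint(expr, pattern)
        assert sets.up_genes == ["UPG"]
        assert sets.down_genes == ["DNG"]
        assert sets.table.loc[sets.table["gene"] == "WEAK", "set"].item() == "none"

    def test_auc_below_floor_excluded_despite_tiny_p(self):
        # With huge groups even AUC 0.60 is highly significant, but the
        # effect-size floor at 0.65 still excludes the gene.
        rng = np.random.default_rng(8)
        n = 2000
        labels = np.r_[np.ones(n, int), np.zeros(n, int)]
        shift = 0.36  # AUC ~ Phi(0.36/sqrt(2)) ~ 0.60
        gene = np.r_[rng.normal(shift, 1, n), rng.normal(0, 1, n)]
        expr, pattern = _matrix_and_pattern([gene], labels, ["GMID"])
        sets = derive_fingerprint(expr, pattern)
        row = sets.table.iloc[0]
        assert row["p"] < 1e-6 and 0.55 < row["auc"] < 0.65
        assert sets.up_genes == [] and sets.down_genes == []

    def test_fewer_than_seven_mutated_gives_na(self):
        rng = np.random.default_rng(0)
        labels = np.r_[np.ones(6, int), np.zeros(30, int)]
        expr, pattern = _matrix_and_pattern([rng.normal(size=36)], labels)
        sets = derive_fingerprint(expr, pattern)
        assert sets.na and sets.up == [] and sets.down == []
        assert sets.n_mutated == 6

    def test_up_down_disjoint_and_swap_under_flip(self, small_synthetic):
        data = small_synthetic
        from g2o import build_mutation_pattern, filter_somatic_calls

        calls = filter_somatic_calls(data.calls)
        pattern = build_mutation_pattern(
            calls, data.ngs_expr.sample_ids, [data.truth.driver_gene]
        )
        sets = derive_fingerprint(data.ngs_expr, pattern)
        assert not set(sets.up_genes) & set(sets.down_genes)
        flipped = derive_fingerprint(data.ngs_expr, pattern.flipped())
        assert flipped.up_genes == sets.down_genes
        assert flipped.down_genes == sets.up_genes

    def test_planted_genes_recovered_in_correct_direction(self, small_synthetic):
        data = small_synthetic
        from g2o import build_mutation_pattern, filter_somatic_calls

        calls = filter_somatic_calls(data.calls)
        pattern = build_mutation_pattern(
            calls, data.ngs_expr.sample_ids, [data.truth.driver_gene]
        )
        sets = derive_fingerprint(data.ngs_expr, pattern)
        up_recovered = set(sets.up_genes) & set(data.truth.up_genes)
        down_recovered = set(sets.down_genes) & set(data.truth.down_genes)
        assert len(up_recovered) >= 0.8 * len(data.truth.up_genes)
        assert len(down_recovered) >= 0.8 * len(data.truth.down_genes)
        # no planted gene lands in the wrong list
        assert not set(sets.up_genes) & set(data.truth.down_genes)
        assert not set(sets.down_genes) & set(data.truth.up_genes)

    def test_null_fraction_matches_threshold_induced_rate(self):
        # Expression independent of the pattern: the up+down fraction is
        # governed by the two-sided tail mass beyond both gates.
        rng = np.random.default_rng(12)
        n1, n0, n_genes = 40, 160, 4000
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        values = rng.normal(size=(n_genes, n1 + n0))
        expr, pattern = _matrix_and_pattern(values, labels)
        sets = derive_fingerprint(expr, pattern)
        thr = RocThresholds()
        se0 = auc_null_se(n1, n0)
        z_auc = (thr.auc_min - 0.5) / se0
        z_p = stats.norm.isf(thr.p_max / 2)
        expected = 2 * stats.norm.sf(max(z_auc, z_p))
        observed = (len(sets.up) + len(sets.down)) / n_genes
        assert observed <= thr.p_max
        # within binomial noise of the analytic tail mass
        sd = math.sqrt(expected * (1 - expected) / n_genes)
        assert abs(observed - expected) < 4 * sd + 1e-4

    def test_misaligned_samples_rejected(self):
        expr, pattern = _matrix_and_pattern([[1.0, 2.0, 3.0]], [1, 0, 1])
        bad = MutationPattern(["X1", "X2", "X3"], pattern.labels, ("DRV",))
        with pytest.raises(ValueError, match="sample ids differ"):
            derive_fingerprint(expr, bad)


class TestRocThresholds:
    @pytest.mark.parametrize("kwargs", [dict(auc_min=0.5), dict(auc_min=1.0),
                                        dict(p_max=0.0), dict(p_max=1.0)])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RocThresholds(**kwargs)
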