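import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from snpcombine import (
    CASE_ENRICHED,
    CONTROL_ENRICHED,
    BinaryItemMatrix,
    ContingencyTable2x2,
    Pattern,
    PhenotypeVector,
    chi2_df1,
    contingency,
    fisher_exact,
    jump,
    odds_ratio,
    supmaxpair,
    support,
)
from snpcombine.pattern_stats import (
    chi2_df1_counts,
    fisher_two_sided_counts,
    odds_ratio_counts,
)

from conftest import random_dataset, single_column_table
from snpcombine import encode_binary


# --- independent oracles ----------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    n, r, k = a + b + c + d, a + b, a + c

    def pmf(x):
        return (
            math.comb(k, x) * math.comb(n - k, r - x) / math.comb(n, r)
        )

    obs = pmf(a)
    lo, hi = max(0, r - (n - k)), min(r, k)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= obs * (1 + 1e-7))


def chi2_cellwise_oracle(a, b, c, d):
    """Sum over cells of (O-E)^2/E."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def jump_oracle(P, B, labels):
    """Jump via independent re-enumeration of all proper subsets."""
    def chi2_of(items):
        pres = B.bits[:, [B.item_index(s, c) for s, c in items]].all(axis=1)
        a = int((pres & labels.is_case).sum())
        b = int((pres & ~labels.is_case).sum())
        return chi2_df1(
            ContingencyTable2x2(a, b, labels.n_case - a, labels.n_ctrl - b)
        )[0]

    best = max(
        chi2_of(sub)
        for k in range(1, P.size)
        for sub in itertools.combinations(P.items, k)
    )
    return chi2_of(P.items) - best


# --- support and supmaxpair -------------------------------------------------

class TestSupport:
    def test_fraction_of_group(self):
        B, labels = single_column_table(35, 5, 35, 65)
        P = Pattern((("snpA", "mm"),))
        assert support(P, B, labels.is_case) == 35 / 70

    def test_single_item_equals_column_mean(self, small_data):
        B, labels = small_data
        P = Pattern((B.item_label(4),))
        assert support(P, B, np.ones(B.n_samples, bool)) == pytest.approx(
            B.bits[:, 4].mean()
        )

    def test_empty_group_error(self, small_data):
        B, _ = small_data
        with pytest.raises(ValueError):
            support(Pattern((B.item_label(0),)), B, np.zeros(B.n_samples, bool))


def _matrix_from_bits(bit_rows, labels_mask):
    """Build a BinaryItemMatrix directly from per-item sample bit columns."""
    bits = np.array(bit_rows, dtype=bool).T  # rows: items -> columns
    n, n_items = bits.shape
    assert n_items % 3 == 0
    B = BinaryItemMatrix(
        [f"s{i}" for i in range(n)],
        [f"snp{j}" for j in range(n_items // 3)],
        bits,
    )
    labels = PhenotypeVector(B.sample_ids, np.asarray(labels_mask, bool))
    return B, labels


class TestSupMaxPair:
    def test_size2_is_plain_support_difference(self, rng):
        # size-2 pattern: its only size-2 subset is itself
        G, labels = random_dataset(rng, n_samples=40, n_snps=4)
        B = encode_binary(G)
        P = Pattern((B.item_label(0), B.item_label(5))).sorted_by(B)
        smp = supmaxpair(P, B, labels, CASE_ENRICHED)
        assert smp == pytest.approx(
            support(P, B, labels.is_case) - support(P, B, ~labels.is_case)
        )

    def test_size3_uses_max_pair_support(self, rng):
        # on random data, check the definition by explicit pair enumeration
        G, labels = random_dataset(rng, n_samples=50, n_snps=5)
        B = encode_binary(G)
        P = Pattern(
            (B.item_label(2), B.item_label(4), B.item_label(8))
        ).sorted_by(B)
        expected = support(P, B, labels.is_case) - max(
            support(Pattern(q), B, ~labels.is_case)
            for q in itertools.combinations(P.items, 2)
        )
        assert supmaxpair(P, B, labels, CASE_ENRICHED) == pytest.approx(expected)

    def test_direction_mirrors_under_label_swap(self, rng):
        G, labels = random_dataset(rng, n_samples=50, n_snps=5)
        B = encode_binary(G)
        flipped = PhenotypeVector(labels.sample_ids, ~labels.is_case)
        P = Pattern((B.item_label(0), B.item_label(4))).sorted_by(B)
        assert supmaxpair(P, B, labels, CONTROL_ENRICHED) == pytest.approx(
            supmaxpair(P, B, flipped, CASE_ENRICHED)
        )

    def test_size1_rejected(self, small_data):
        B, labels = small_data
        with pytest.raises(ValueError):
            supmaxpair(Pattern((B.item_label(0),)), B, labels)


# --- contingency and 2x2 statistics -----------------------------------------

class TestContingency:
    def test_counts(self):
        B, labels = single_column_table(35, 5, 35, 65)
        T = contingency(Pattern((("snpA", "mm"),)), B, labels)
        assert T == (35, 5, 35, 65)

    def test_margins_conserved(self, small_data, rng):
        B, labels = small_data
        for _ in range(10):
            cols = rng.choice(B.n_items, 2, replace=False)
            try:
                P = Pattern(tuple(B.item_label(c) for c in cols))
            except ValueError:
                continue
            T = contingency(P, B, labels)
            assert T.a + T.c == labels.n_case
            assert T.b + T.d == labels.n_ctrl


class TestChi2:
    def test_known_value(self):
        stat, p = chi2_df1(ContingencyTable2x2(35, 5, 5, 35))
        assert stat == pytest.approx(45.0)
        assert p == pytest.approx(sps.chi2.sf(45.0, 1))

    def test_closed_form_matches_cellwise_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 50, size=4)
            stat, _ = chi2_df1(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert stat == pytest.approx(chi2_cellwise_oracle(a, b, c, d))

    def test_independence_and_degenerate(self):
        assert chi2_df1(ContingencyTable2x2(20, 20, 20, 20)) == (0.0, 1.0)
        assert chi2_df1(ContingencyTable2x2(0, 0, 30, 40)) == (0.0, 1.0)

    def test_swap_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            s1, _ = chi2_df1(ContingencyTable2x2(a, b, c, d))
            s2, _ = chi2_df1(ContingencyTable2x2(d, c, b, a))
            assert s1 == pytest.approx(s2)

    def test_agrees_with_scipy_contingency(self, rng):
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, size=4))
            stat, p = chi2_df1(ContingencyTable2x2(a, b, c, d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestOddsRatio:
    def test_cross_product(self):
        assert odds_ratio(ContingencyTable2x2(35, 5, 5, 35)).value == 49.0
        assert odds_ratio(ContingencyTable2x2(20, 20, 20, 20)).value == 1.0

    def test_haldane_correction_flagged(self):
        res = odds_ratio(ContingencyTable2x2(10, 0, 60, 70))
        assert res.haldane
        assert res.value == pytest.approx((10.5 * 70.5) / (0.5 * 60.5))


class TestFisher:
    def test_independence(self):
        assert fisher_exact(ContingencyTable2x2(20, 20, 20, 20)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact(ContingencyTable2x2(a, b, c, d)) == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), rel=1e-8
            )

    def test_monotone_in_extremity(self):
        ps = [
            fisher_exact(ContingencyTable2x2(35 + k, 5 - k, 5 - k, 35 + k))
            for k in range(6)
        ]
        assert all(x > y for x, y in zip(ps, ps[1:]))


class TestJump:
    def test_simple_difference(self, rng):
        G, labels = random_dataset(rng, n_samples=60, n_snps=5)
        B = encode_binary(G)
        P = Pattern((B.item_label(0), B.item_label(3))).sorted_by(B)
        own = chi2_df1(contingency(P, B, labels))[0]
        best = max(
            chi2_df1(contingency(Pattern((it,)), B, labels))[0]
            for it in P.items
        )
        assert jump(P, B, labels) == pytest.approx(own - best)

    def test_matches_subset_enumeration_oracle(self, rng):
        G, labels = random_dataset(rng, n_samples=60, n_snps=8)
        B = encode_binary(G)
        for _ in range(25):
            k = int(rng.integers(2, 6))
            snps = rng.choice(8, k, replace=False)
            items = tuple(
                B.item_label(3 * s + rng.integers(3)) for s in snps
            )
            P = Pattern(items).sorted_by(B)
            assert jump(P, B, labels) == pytest.approx(jump_oracle(P, B, labels))

    def test_negative_when_subset_stronger(self):
        # a pattern diluting a perfectly discriminative single item
        case = np.arange(40) < 20
        item_strong = case.copy()               # perfect separator
        item_noise = np.arange(40) % 2 == 0     # uninformative
        B, labels = _matrix_from_bits(
            [item_strong, np.zeros(40, bool), np.zeros(40, bool),
             item_noise, np.zeros(40, bool), np.zeros(40, bool)],
            case,
        )
        P = Pattern((("snp0", "mm"), ("snp1", "mm"))).sorted_by(B)
        assert jump(P, B, labels) < 0

    def test_size1_rejected(self, small_data):
        B, labels = small_data
        with pytest.raises(ValueError):
            jump(Pattern((B.item_label(0),)), B, labels)


# --- anti-monotonicity properties -------------------------------------------

class TestAntiMonotonicity:
    def test_support_and_supmaxpair_anti_monotone(self, rng):
        G, labels = random_dataset(rng, n_samples=80, n_snps=12)
        B = encode_binary(G)
        n_checked = 0
        while n_checked < 2000:
            k = int(rng.integers(2, 5))
            snps = rng.choice(12, k + 1, replace=False)
            items = tuple(
                B.item_label(3 * s + rng.integers(3)) for s in snps
            )
            sup_pat = Pattern(items).sorted_by(B)
            sub_pat = Pattern(sup_pat.items[:k])
            grp = labels.is_case
            assert support(sup_pat, B, grp) <= support(sub_pat, B, grp)
            assert supmaxpair(sup_pat, B, labels) <= supmaxpair(
                sub_pat, B, labels
            ) + 1e-12
            n_checked += 1

    def test_jump_bounded_by_chi2(self, rng):
        G, labels = random_dataset(rng, n_samples=60, n_snps=6)
        B = encode_binary(G)
        for _ in range(50):
            snps = rng.choice(6, 3, replace=False)
            P = Pattern(
                tuple(B.item_label(3 * s + rng.integers(3)) for s in snps)
            ).sorted_by(B)
            assert jump(P, B, labels) <= chi2_df1(contingency(P, B, labels))[0]


# --- batched statistics vs single-table routines ----------------------------

class TestBatchedStats:
    def test_batch_matches_reference(self, rng):
        n_case, n_ctrl = 37, 43
        a = rng.integers(0, n_case + 1, size=300)
        b = rng.integers(0, n_ctrl + 1, size=300)
        chi2_batch = chi2_df1_counts(a, b, n_case, n_ctrl)
        fish_batch = fisher_two_sided_counts(a, b, n_case, n_ctrl)
        or_batch, hald = odds_ratio_counts(a, b, n_case, n_ctrl)
        for i in range(300):
            T = ContingencyTable2x2(
                int(a[i]), int(b[i]), n_case - int(a[i]), n_ctrl - int(b[i])
            )
            assert chi2_batch[i] == pytest.approx(chi2_df1(T)[0], abs=1e-9)
            assert fish_batch[i] == pytest.approx(fisher_exact(T), rel=1e-6)
            orr = odds_ratio(T)
            assert or_batch[i] == pytest.approx(orr.value)
            assert hald[i] == orr.haldane
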