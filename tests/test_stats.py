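"""Contingency-table statistics: G2, the interaction statistic C,
Haldane odds ratios, Pearson chi-square and Fisher exact tests."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpmkit import (
    MISSING,
    GenotypeDataset,
    TwoByTwo,
    crosstab_pair,
    fisher_exact,
    g2_independence,
    haldane_or,
    interaction_C,
    pearson_chi2,
)

from conftest import AMD_CASE_3X3, AMD_CTRL_3X3, AMD_M_T, AMD_PATTERN_2X2


# ---------------------------------------------------------------- crosstab

def test_crosstab_routes_missing_to_fourth_genotype():
    ds = GenotypeDataset(
        genotypes=np.array([[0, 0], [MISSING, 1], [2, 2]], dtype=np.int8),
        phenotype=np.array([True, True, False]),
        variant_ids=["a", "b"],
        chromosome=["1", "2"],
    )
    tab = crosstab_pair(ds, 0, 1)
    assert tab.case4x4[0, 0] == 1
    assert tab.case4x4[3, 1] == 1
    assert tab.case3x3.sum() == 1  # the half-missing case is excluded
    assert tab.ctrl3x3.sum() == 1
    assert tab.case4x4.sum() == 2 and tab.ctrl4x4.sum() == 1


def test_crosstab_reproduces_published_pair_tables(amd_dataset):
    tab = crosstab_pair(amd_dataset, 0, 1)
    np.testing.assert_array_equal(tab.case3x3, AMD_CASE_3X3)
    np.testing.assert_array_equal(tab.ctrl3x3, AMD_CTRL_3X3)
    # no missing genotypes: the 4x4 margins are empty
    assert tab.case4x4[3].sum() == 0 and tab.case4x4[:, 3].sum() == 0
    assert tab.case4x4.sum() == 96 and tab.ctrl4x4.sum() == 50


def test_crosstab_rejects_identical_indices(amd_dataset):
    with pytest.raises(ValueError):
        crosstab_pair(amd_dataset, 1, 1)


# ---------------------------------------------------------------- G2

def test_g2_zero_for_exact_independence():
    g2, min_e = g2_independence(np.full((3, 3), 4))
    assert g2 == pytest.approx(0.0, abs=1e-12)
    assert min_e == pytest.approx(4.0)


@pytest.mark.parametrize(
    "table, expected",
    [(AMD_CASE_3X3, 21.9317), (AMD_CTRL_3X3, 30.3285)],
    ids=["case", "control"],
)
def test_g2_matches_direct_evaluation(table, expected):
    """Frozen values from an independent term-by-term evaluation of
    2*sum(n*log(n/e)) on the published tables."""
    g2, _ = g2_independence(table)
    assert g2 == pytest.approx(expected, abs=5e-4)


def test_g2_invariant_under_permutation_and_transpose():
    rng = np.random.default_rng(7)
    t = rng.integers(0, 20, size=(3, 3))
    ref, _ = g2_independence(t)
    for perm in itertools.permutations(range(3)):
        assert g2_independence(t[list(perm), :])[0] == pytest.approx(ref)
        assert g2_independence(t[:, list(perm)])[0] == pytest.approx(ref)
    assert g2_independence(t.T)[0] == pytest.approx(ref)


def test_g2_rejects_all_zero_table():
    with pytest.raises(ValueError):
        g2_independence(np.zeros((3, 3)))


# ---------------------------------------------------------------- C

def test_interaction_c_exactly_zero_for_identical_tables():
    t = np.array([[3, 1, 4], [1, 5, 9], [2, 6, 5]])
    res = interaction_C(t, t)
    assert res.C == 0.0
    assert res.p == 1.0


def test_interaction_c_reproduces_published_pair():
    res = interaction_C(AMD_CASE_3X3, AMD_CTRL_3X3, min_expected_limit=1.0)
    assert res.analyzable
    assert res.df == 4
    assert res.C == pytest.approx(52.1415, abs=5e-3)
    assert res.p == pytest.approx(1.2886e-10, rel=1e-3)
    assert res.C == pytest.approx(
        res.g2_case + res.g2_ctrl - res.g2_combined, abs=1e-10
    )
    # Bonferroni over the genome-wide number of analyzed pairs
    assert res.p * AMD_M_T == pytest.approx(0.0380, abs=5e-4)


def test_interaction_c_screens_low_expected_counts():
    case = np.array([[0, 0, 0], [1, 2, 1], [1, 1, 2]])
    res = interaction_C(case, case + 1, min_expected_limit=1.0)
    assert not res.analyzable
    assert res.min_expected < 1.0


def test_interaction_c_doubles_with_counts():
    r1 = interaction_C(AMD_CASE_3X3, AMD_CTRL_3X3)
    r2 = interaction_C(2 * AMD_CASE_3X3, 2 * AMD_CTRL_3X3)
    for field in ("g2_case", "g2_ctrl", "g2_combined", "C"):
        assert getattr(r2, field) == pytest.approx(2 * getattr(r1, field))


def test_interaction_c_symmetric_in_variant_order():
    r1 = interaction_C(AMD_CASE_3X3, AMD_CTRL_3X3)
    r2 = interaction_C(AMD_CASE_3X3.T, AMD_CTRL_3X3.T)
    assert r2.C == pytest.approx(r1.C)
    assert r2.p == pytest.approx(r1.p)


def test_interaction_c_rejects_negative_counts():
    bad = AMD_CASE_3X3.copy()
    bad[0, 0] = -1
    with pytest.raises(ValueError):
        interaction_C(bad, AMD_CTRL_3X3)


# ---------------------------------------------------------------- odds ratio

def test_haldane_or_published_pattern():
    or_, or_prime = haldane_or(AMD_PATTERN_2X2)
    assert or_ == pytest.approx(0.0178, abs=5e-5)
    assert or_prime == pytest.approx(56.19, abs=5e-3)


@pytest.mark.parametrize(
    "t, expected_or",
    [(TwoByTwo(5, 5, 5, 5), 1.0), (TwoByTwo(0, 0, 0, 0), 1.0)],
)
def test_haldane_or_symmetric_and_degenerate(t, expected_or):
    or_, or_prime = haldane_or(t)
    assert or_ == pytest.approx(expected_or)
    assert or_prime == pytest.approx(1.0)


@given(st.tuples(*[st.integers(0, 40)] * 4))
@settings(max_examples=100, deadline=None)
def test_haldane_or_phenotype_swap_inverts(counts):
    t = TwoByTwo(*counts)
    swapped = TwoByTwo(a=t.c, b=t.d, c=t.a, d=t.b)
    or1, orp1 = haldane_or(t)
    or2, orp2 = haldane_or(swapped)
    assert or2 == pytest.approx(1.0 / or1)
    assert orp2 == pytest.approx(orp1)


# ---------------------------------------------------------------- chi-square

def test_pearson_chi2_independence_and_perfect_association():
    stat, p, _ = pearson_chi2(TwoByTwo(10, 10, 10, 10))
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
    stat, p, _ = pearson_chi2(TwoByTwo(20, 0, 0, 20))
    assert stat == pytest.approx(40.0)  # equals N for perfect association


def test_pearson_chi2_published_pattern():
    stat, _, analyzable = pearson_chi2(AMD_PATTERN_2X2)
    assert stat == pytest.approx(22.8409, abs=5e-4)
    assert analyzable  # smallest expected count is 11*96/146 > 1


def test_pearson_chi2_rejects_empty_table():
    with pytest.raises(ValueError):
        pearson_chi2(TwoByTwo(0, 0, 0, 0))


# ---------------------------------------------------------------- Fisher

def _fisher_oracle(t: TwoByTwo, side: str) -> float:
    """Brute-force hypergeometric enumeration over all feasible tables."""
    n, n_case, k = t.total, t.a + t.b, t.a + t.c
    denom = comb(n, k)
    lo, hi = max(0, k - (t.c + t.d)), min(k, n_case)
    pmf = {x: comb(n_case, x) * comb(n - n_case, k - x) / denom
           for x in range(lo, hi + 1)}
    if side == "F2":
        return sum(p for x, p in pmf.items() if x >= t.a)
    if side == "F1":
        return sum(p for x, p in pmf.items() if x <= t.a)
    p_obs = pmf[t.a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))


def test_fisher_f1_published_pattern_is_exact_hypergeometric():
    p = fisher_exact(AMD_PATTERN_2X2, "F1")
    assert p == pytest.approx(comb(50, 11) / comb(146, 11), rel=1e-9)
    assert p == pytest.approx(3.414e-6, rel=1e-3)


def test_fisher_f2_at_minimum_possible_a_is_one():
    assert fisher_exact(AMD_PATTERN_2X2, "F2") == pytest.approx(1.0)


def test_fisher_degenerate_margin_gives_one_for_all_sides():
    t = TwoByTwo(0, 7, 0, 5)  # no pattern carriers at all
    for side in ("F1", "F2", "F3"):
        assert fisher_exact(t, side) == pytest.approx(1.0)


def test_fisher_rejects_unknown_side():
    with pytest.raises(ValueError):
        fisher_exact(AMD_PATTERN_2X2, "F4")


@given(
    st.tuples(*[st.integers(0, 15)] * 4).filter(lambda c: sum(c) > 0)
)
@settings(max_examples=300, deadline=None)
def test_fisher_matches_enumeration_oracle(counts):
    t = TwoByTwo(*counts)
    for side in ("F1", "F2", "F3"):
        assert fisher_exact(t, side) == pytest.approx(
            min(1.0, _fisher_oracle(t, side)), rel=1e-9, abs=1e-12
        )
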