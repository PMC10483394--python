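"""Table-level statistics for variant-pair and genotype-pair tests.

This module implements the statistical core of the toolkit:

* cross-tabulation of a variant pair with "missing" treated as a fourth
  genotype (4x4 tables), and the known-genotype 3x3 subtables;
* the likelihood-ratio (G-test) independence statistic G2;
* the interaction statistic ``C = G2_case + G2_ctrl - G2_combined``,
  referred to a chi-square distribution with 4 df, which tests whether
  the interaction structure of a variant pair differs between cases and
  controls irrespective of single-variant main effects;
* Haldane-corrected odds ratios for 2x2 pattern tables;
* Pearson chi-square and one/two-sided Fisher exact tests (F1/F2/F3) on
  2x2 phenotype-by-pattern-presence tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import hypergeom

from .dataset import MISSING, GenotypeDataset

#: Relative tolerance when comparing point probabilities in the two-sided
#: Fisher test; absorbs floating-point ties between equally likely tables.
_F3_RELTOL = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of individuals by phenotype and pattern presence.

    ``a``/``b`` are cases with/without the pattern, ``c``/``d`` controls
    with/without.  The "without" cells count only individuals with known
    genotypes at both variants, so ``a + b`` and ``c + d`` are the
    known-genotype group totals, never the raw group sizes.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def support(self) -> int:
        """Number of individuals carrying the pattern (a + c)."""
        return self.a + self.c

    @property
    def confidence(self) -> float:
        """Fraction of pattern carriers who are cases, a / (a + c)."""
        s = self.support
        return self.a / s if s else 0.0


@dataclass(frozen=True)
class GroupedPairTable:
    """Per-phenotype genotype cross-tabulations for one variant pair.

    ``case4x4``/``ctrl4x4`` index genotypes ``{0, 1, 2, missing}`` of the
    first variant (rows) against the second (columns); the 3x3 subtables
    restrict to known genotypes.
    """

    case4x4: np.ndarray
    ctrl4x4: np.ndarray

    @property
    def case3x3(self) -> np.ndarray:
        return self.case4x4[:3, :3]

    @property
    def ctrl3x3(self) -> np.ndarray:
        return self.ctrl4x4[:3, :3]

    def pattern_table(self, gi: int, gj: int) -> TwoByTwo:
        """2x2 phenotype-by-presence table for genotype pair ``(gi, gj)``.

        The "absent" cells are known-genotype totals minus the pattern
        count, so missing individuals contribute to neither column.
        """
        if not (0 <= gi <= 2 and 0 <= gj <= 2):
            raise ValueError("genotype codes must be 0, 1 or 2")
        a = int(self.case4x4[gi, gj])
        c = int(self.ctrl4x4[gi, gj])
        known_cases = int(self.case3x3.sum())
        known_ctrls = int(self.ctrl3x3.sum())
        return TwoByTwo(a=a, b=known_cases - a, c=c, d=known_ctrls - c)


@dataclass(frozen=True)
class InteractionResult:
    """Outcome of the 4-df interaction test on one variant pair."""

    g2_case: float
    g2_ctrl: float
    g2_combined: float
    C: float
    df: int
    p: float
    min_expected: float
    analyzable: bool


def crosstab_pair(dataset: GenotypeDataset, i: int, j: int) -> GroupedPairTable:
    """Cross-tabulate genotypes of variants ``i`` and ``j`` by phenotype.

    Missing genotypes are routed to a fourth row/column; every individual
    is counted exactly once per table.
    """
    if i == j:
        raise ValueError("variant indices must differ")
    n_var = dataset.n_variants
    if not (0 <= i < n_var and 0 <= j < n_var):
        raise IndexError(f"variant index out of range for {n_var} variants")
    gi = dataset.genotypes[:, i].astype(np.intp)
    gj = dataset.genotypes[:, j].astype(np.intp)
    # missing (-1) becomes index 3
    gi = np.where(gi == MISSING, 3, gi)
    gj = np.where(gj == MISSING, 3, gj)
    code = gi * 4 + gj
    case = np.bincount(code[dataset.phenotype], minlength=16).reshape(4, 4)
    ctrl = np.bincount(code[~dataset.phenotype], minlength=16).reshape(4, 4)
    return GroupedPairTable(case4x4=case, ctrl4x4=ctrl)


def g2_independence(table: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio independence statistic for a contingency table.

    Returns ``(G2, min_expected)`` where ``G2 = 2 * sum n * log(n / e)``
    with natural logarithms and the convention ``0 * log 0 = 0``, and
    ``min_expected`` is the smallest expected count over cells whose row
    and column margins are both nonzero (cells in all-zero margins are
    structurally empty and excluded from the screen).
    """
    t = np.asarray(table, dtype=float)
    total = t.sum()
    if total <= 0:
        raise ValueError("G2 is undefined for an all-zero table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    expected = np.outer(rows, cols) / total
    nz = t > 0
    g2 = 2.0 * float(np.sum(t[nz] * np.log(t[nz] / expected[nz])))
    realizable = (rows > 0)[:, None] & (cols > 0)[None, :]
    min_expected = float(expected[realizable].min())
    return g2, min_expected


def interaction_C(
    case3x3: np.ndarray,
    ctrl3x3: np.ndarray,
    min_expected_limit: float = 1.0,
) -> InteractionResult:
    """Test whether variant-pair interaction differs between phenotypes.

    Computes G2 for the case table, the control table and their cellwise
    sum; ``C`` is the case + control sum minus the combined statistic and
    follows chi-square with 4 df under the null of equal interaction.
    The pair is flagged not analyzable when any expected count in any of
    the three G2 computations falls below ``min_expected_limit``.
    Stratified/pooled (Simpson-type) configurations can make ``C``
    non-positive; the statistic is reported as computed and ``p`` is
    clamped to 1.
    """
    case = np.asarray(case3x3, dtype=float)
    ctrl = np.asarray(ctrl3x3, dtype=float)
    if (case < 0).any() or (ctrl < 0).any():
        raise ValueError("counts must be non-negative")
    g2_case, me_case = g2_independence(case)
    g2_ctrl, me_ctrl = g2_independence(ctrl)
    g2_comb, me_comb = g2_independence(case + ctrl)
    c_stat = g2_case + g2_ctrl - g2_comb
    min_expected = min(me_case, me_ctrl, me_comb)
    p = float(_chi2.sf(c_stat, 4)) if c_stat > 0 else 1.0
    return InteractionResult(
        g2_case=g2_case,
        g2_ctrl=g2_ctrl,
        g2_combined=g2_comb,
        C=c_stat,
        df=4,
        p=p,
        min_expected=min_expected,
        analyzable=min_expected >= min_expected_limit,
    )


def haldane_or(t: TwoByTwo) -> tuple[float, float]:
    """Haldane-corrected odds ratio and its direction-free form.

    Adds 1/2 to every cell before forming ``OR = (a+.5)(d+.5) /
    [(b+.5)(c+.5)]`` so zero cells yield finite ratios, and returns
    ``(OR, OR' = max(OR, 1/OR))``.
    """
    or_ = (t.a + 0.5) * (t.d + 0.5) / ((t.b + 0.5) * (t.c + 0.5))
    return or_, max(or_, 1.0 / or_)


def pearson_chi2(
    t: TwoByTwo, min_expected_limit: float = 1.0
) -> tuple[float, float, bool]:
    """1-df Pearson chi-square on a 2x2 table, without continuity correction.

    Returns ``(statistic, p, analyzable)``; ``analyzable`` is False when
    any expected count falls below ``min_expected_limit``.  Degenerate
    margins (an empty row or column) give statistic 0 and p = 1.
    """
    n = t.total
    if n == 0:
        raise ValueError("chi-square is undefined for an empty table")
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if 0 in (r1, r2, c1, c2):
        return 0.0, 1.0, False
    stat = n * (t.a * t.d - t.b * t.c) ** 2 / (r1 * r2 * c1 * c2)
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    return float(stat), float(_chi2.sf(stat, 1)), expected_min >= min_expected_limit


def fisher_exact(t: TwoByTwo, side: str) -> float:
    """Fisher's exact test on a 2x2 pattern table.

    ``side`` selects the alternative: ``"F2"`` — pattern more frequent in
    cases (sums tables with ``a`` at or above the observed value);
    ``"F1"`` — pattern more frequent in controls (``a`` at or below);
    ``"F3"`` — two-sided by the point-probability rule (sums all tables
    whose probability does not exceed the observed one, with a small
    relative tolerance for floating-point ties).
    """
    n = t.total
    if n == 0:
        raise ValueError("Fisher test is undefined for an empty table")
    n_case = t.a + t.b
    k = t.a + t.c  # pattern carriers, the conditioned margin
    if side == "F2":
        return float(min(1.0, hypergeom.sf(t.a - 1, n, n_case, k)))
    if side == "F1":
        return float(min(1.0, hypergeom.cdf(t.a, n, n_case, k)))
    if side == "F3":
        lo = max(0, k - (t.c + t.d))
        hi = min(k, n_case)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, n, n_case, k)
        p_obs = pmf[t.a - lo]
        return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _F3_RELTOL)].sum()))
    raise ValueError(f"unknown Fisher test side {side!r}; expected F1, F2 or F3")
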