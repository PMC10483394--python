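"""Exhaustive variant-pair interaction scan (the *Vpairs* engine).

Every admissible variant pair is cross-tabulated by phenotype and tested
with the 4-df interaction statistic ``C``; pairs in which any expected
count falls below a user-set limit are screened out, and the number of
pairs actually analyzed, ``M_t``, is the Bonferroni multiplier
``p_B = min(1, p * M_t)``.  A per-pair drill-down (:func:`pairsnps_report`)
lists all nine genotype pairs of a chosen variant pair with their odds
ratios, support and confidence, to show which genotype pattern drives a
large ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from joblib import Parallel, delayed

from .dataset import GenotypeDataset
from .pairs import chromosome_mask, n_pairs, pair_from_index, partition
from .stats import TwoByTwo, crosstab_pair, haldane_or, interaction_C


@dataclass(frozen=True)
class PairResult:
    """Interaction-test record for one variant pair."""

    pair_id: int
    var_i: str
    var_j: str
    C: float
    p: float
    p_B: float
    analyzable: bool = True


@dataclass(frozen=True)
class PatternEntry:
    """One genotype pair of a variant pair, with effect-size summaries."""

    gi: int
    gj: int
    table: TwoByTwo
    odds_ratio: float
    or_prime: float
    support: int
    confidence: float


def _scan_chunk(dataset, ids, min_expected, admit):
    out = []
    n_analyzable = 0
    nv = dataset.n_variants
    for k in ids:
        i1, j1 = pair_from_index(k, nv)
        i, j = i1 - 1, j1 - 1
        if not admit(i, j):
            continue
        tab = crosstab_pair(dataset, i, j)
        res = interaction_C(tab.case3x3, tab.ctrl3x3, min_expected)
        if not res.analyzable:
            continue
        n_analyzable += 1
        out.append(
            PairResult(
                pair_id=k,
                var_i=dataset.variant_ids[i],
                var_j=dataset.variant_ids[j],
                C=res.C,
                p=res.p,
                p_B=res.p,  # corrected in a second pass once M_t is known
            )
        )
    return out, n_analyzable


def scan_variant_pairs(
    dataset: GenotypeDataset,
    min_expected: float = 1.0,
    cross_chrom_only: bool = False,
    workers: int = 1,
    top_r: int = 100_000,
) -> tuple[list[PairResult], int]:
    """Test all admissible variant pairs for interaction differences.

    Returns ``(results, M_t)``: the analyzable pairs ranked by ascending
    p (ties broken by pair id), truncated to the best ``top_r``, and the
    count ``M_t`` of pairs that passed the expected-count screen.
    Bonferroni correction uses ``M_t``, computed after the full scan.
    The output is identical for any ``workers`` value: work is split
    into contiguous id ranges whose results are concatenated in id
    order before ranking.
    """
    if dataset.n_variants < 2:
        raise ValueError("need at least two variants to form pairs")
    if workers < 1:
        raise ValueError("need at least one worker")
    admit = chromosome_mask(dataset, cross_chrom_only)
    ranges = partition(n_pairs(dataset.n_variants), workers)
    if workers == 1:
        chunks = [_scan_chunk(dataset, ranges[0], min_expected, admit)]
    else:
        chunks = Parallel(n_jobs=workers)(
            delayed(_scan_chunk)(dataset, r, min_expected, admit)
            for r in ranges
            if len(r)
        )
    results: list[PairResult] = []
    m_t = 0
    for chunk, n_ana in chunks:
        results.extend(chunk)
        m_t += n_ana
    results = [
        replace(r, p_B=min(1.0, r.p * m_t)) for r in results
    ]
    results.sort(key=lambda r: (r.p, r.pair_id))
    return results[:top_r], m_t


def pairsnps_report(
    dataset: GenotypeDataset, i: int, j: int
) -> list[PatternEntry]:
    """Drill into one variant pair: all nine genotype pairs with OR'.

    For each genotype pair ``(gi, gj)`` (codes 0/1/2 at variants ``i``
    and ``j``, 0-based column indices) the 2x2 phenotype-by-presence
    table is built from known-genotype totals, with Haldane odds ratio,
    OR' = max(OR, 1/OR), support ``a + c`` and confidence ``a/(a+c)``.
    Entries are sorted by OR' descending (ties by genotype pair).
    """
    if i == j:
        raise ValueError("variant indices must differ")
    tab = crosstab_pair(dataset, i, j)
    entries = []
    for gi in range(3):
        for gj in range(3):
            t = tab.pattern_table(gi, gj)
            or_, or_prime = haldane_or(t)
            entries.append(
                PatternEntry(
                    gi=gi,
                    gj=gj,
                    table=t,
                    odds_ratio=or_,
                    or_prime=or_prime,
                    support=t.support,
                    confidence=t.confidence,
                )
            )
    entries.sort(key=lambda e: (-e.or_prime, e.gi, e.gj))
    return entries
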