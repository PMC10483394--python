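"""Exhaustive genotype-pair association scan (the *Gpairs* engine).

Where the variant-pair scan summarizes a whole 3x3 x phenotype structure
in one statistic, this scan tests each of the nine genotype pairs of
every admissible variant pair on its own 2x2 phenotype-by-presence
table, in the style of frequent-pattern mining: patterns below a minimum
*support* (carriers, ``a + c``) or *confidence* (``a/(a+c)``, the
positive predictive value) are not tested.  Presence/absence counts come
from known-genotype totals — an individual missing at either variant is
in neither column — so Bonferroni correction can use an exact count of
tests actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from joblib import Parallel, delayed

from .dataset import GenotypeDataset
from .pairs import chromosome_mask, n_pairs, pair_from_index, partition
from .stats import TwoByTwo, crosstab_pair, fisher_exact, haldane_or, pearson_chi2

TESTS = ("chi2", "F1", "F2", "F3")


@dataclass(frozen=True)
class PatternResult:
    """Association-test record for one genotype pair (pattern)."""

    pair_id: int
    var_i: str
    var_j: str
    gi: int
    gj: int
    table: TwoByTwo
    support: int
    confidence: float
    test: str
    p: float
    p_B: float
    odds_ratio: float
    or_prime: float


def _scan_chunk(dataset, ids, test, min_support, min_confidence, min_expected, admit):
    out = []
    n_tested = 0
    nv = dataset.n_variants
    for k in ids:
        i1, j1 = pair_from_index(k, nv)
        i, j = i1 - 1, j1 - 1
        if not admit(i, j):
            continue
        tab = crosstab_pair(dataset, i, j)
        for gi in range(3):
            for gj in range(3):
                t = tab.pattern_table(gi, gj)
                if t.support < min_support or t.support == 0:
                    continue
                if t.confidence < min_confidence:
                    continue
                if test == "chi2":
                    stat, p, analyzable = pearson_chi2(t, min_expected)
                    if not analyzable:
                        continue
                else:
                    p = fisher_exact(t, test)
                n_tested += 1
                or_, or_prime = haldane_or(t)
                out.append(
                    PatternResult(
                        pair_id=k,
                        var_i=dataset.variant_ids[i],
                        var_j=dataset.variant_ids[j],
                        gi=gi,
                        gj=gj,
                        table=t,
                        support=t.support,
                        confidence=t.confidence,
                        test=test,
                        p=p,
                        p_B=p,  # corrected once the test count is known
                        odds_ratio=or_,
                        or_prime=or_prime,
                    )
                )
    return out, n_tested


def scan_genotype_pairs(
    dataset: GenotypeDataset,
    test: str = "F3",
    min_support: int = 10,
    min_confidence: float = 0.0,
    min_expected: float = 1.0,
    cross_chrom_only: bool = False,
    workers: int = 1,
    top_r: int = 100_000,
) -> tuple[list[PatternResult], int]:
    """Test every suitable genotype pair for case-control association.

    ``test`` is ``"chi2"`` (Pearson, with an expected-count screen at
    ``min_expected``) or a Fisher exact variant ``"F1"`` (enriched in
    controls), ``"F2"`` (enriched in cases), ``"F3"`` (two-sided); exact
    tests need no expected-count screen.  Returns ``(results,
    tested_count)`` with results ranked by ascending p (ties by pair id,
    then genotype pair) and truncated to ``top_r``; ``tested_count`` is
    the exact number of patterns tested under this configuration and is
    the Bonferroni multiplier for ``p_B``.  Output is invariant to
    ``workers``.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must be in [0, 1]")
    if min_support < 0:
        raise ValueError("min_support must be non-negative")
    if dataset.n_variants < 2:
        raise ValueError("need at least two variants to form pairs")
    if workers < 1:
        raise ValueError("need at least one worker")
    admit = chromosome_mask(dataset, cross_chrom_only)
    ranges = partition(n_pairs(dataset.n_variants), workers)
    args = (test, min_support, min_confidence, min_expected, admit)
    if workers == 1:
        chunks = [_scan_chunk(dataset, ranges[0], *args)]
    else:
        chunks = Parallel(n_jobs=workers)(
            delayed(_scan_chunk)(dataset, r, *args) for r in ranges if len(r)
        )
    results: list[PatternResult] = []
    tested_count = 0
    for chunk, n_tested in chunks:
        results.extend(chunk)
        tested_count += n_tested
    results = [
        replace(r, p_B=min(1.0, r.p * tested_count)) for r in results
    ]
    results.sort(key=lambda r: (r.p, r.pair_id, r.gi, r.gj))
    return results[:top_r], tested_count


def rank_patterns(
    results: list[PatternResult], key: str = "p"
) -> list[PatternResult]:
    """Order patterns by ascending p or descending OR'.

    Ties break by pair id, then genotype pair, for reproducibility.
    """
    if key == "p":
        return sorted(results, key=lambda r: (r.p, r.pair_id, r.gi, r.gj))
    if key == "or_prime":
        return sorted(results, key=lambda r: (-r.or_prime, r.pair_id, r.gi, r.gj))
    raise ValueError(f"unknown ranking key {key!r}; expected 'p' or 'or_prime'")


def pattern_rank(
    results: list[PatternResult], target: PatternResult, key: str = "p"
) -> int:
    """Competition rank of ``target``: 1 + number of strictly better patterns.

    "Better" is a smaller p or a larger OR' depending on ``key``; tied
    patterns share the same rank.
    """
    if key == "p":
        better = sum(1 for r in results if r.p < target.p)
    elif key == "or_prime":
        better = sum(1 for r in results if r.or_prime > target.or_prime)
    else:
        raise ValueError(f"unknown ranking key {key!r}; expected 'p' or 'or_prime'")
    return 1 + better
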