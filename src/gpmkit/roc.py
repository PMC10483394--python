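"""Empirical ROC evaluation of top-ranked genotype patterns.

Pattern presence in an individual is read as a phenotype predictor: with
the one-sided Fisher directions, a pattern predicts "case" (F2) or
"control" (F1).  Each pattern's 2x2 table then yields one (FPR, TPR)
point; many patterns yield a cloud that is condensed into a binned
empirical ROC curve: the FPR axis is cut into equal-width classes, the
mean TPR is plotted at each class midpoint, empty interior classes are
linearly interpolated, and the area under the anchored polyline is the
AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gpairs import PatternResult
from .stats import TwoByTwo, fisher_exact


@dataclass(frozen=True)
class RocCurve:
    """Binned empirical ROC curve."""

    points: list[tuple[float, float]]  # (FPR, TPR), sorted by FPR
    auc: float
    n_classes: int
    direction: str


def decision_rates(t: TwoByTwo, direction: str) -> tuple[float, float]:
    """(FPR, TPR) of a pattern used as a phenotype indicator.

    Direction ``"F2"``: the pattern predicts "case", so TPR = a/(a+b)
    (sensitivity among cases) and FPR = c/(c+d).  Direction ``"F1"``:
    the pattern predicts "control", and the roles of the two phenotype
    groups swap.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("rates are undefined with an empty phenotype group")
    case_rate = t.a / (t.a + t.b)
    ctrl_rate = t.c / (t.c + t.d)
    if direction == "F2":
        return ctrl_rate, case_rate
    if direction == "F1":
        return case_rate, ctrl_rate
    raise ValueError(f"unknown direction {direction!r}; expected 'F1' or 'F2'")


def binned_roc(
    tables: Sequence[TwoByTwo],
    direction: str = "F1",
    n_classes: int = 20,
    top_k: int = 100,
) -> RocCurve:
    """Binned empirical ROC over the best ``top_k`` pattern tables.

    Tables are ranked by the matching one-sided Fisher test's p-value
    (F1 or F2 per ``direction``); the ``top_k`` best contribute (FPR,
    TPR) points.  The FPR axis is split into ``n_classes`` equal-width
    bins on [0, 1]; each nonempty bin yields one point (mean FPR, mean
    TPR) over its members, empty bins are filled by linear interpolation
    at their midpoints between nearest nonempty neighbours (these points
    lie on the polyline and do not change its area), the anchors (0,0)
    and (1,1) are always present, and the AUC is the trapezoid-rule area
    under the resulting polyline.  A pattern cloud lying exactly on the
    diagonal therefore gives AUC 0.5, and a single (FPR 0, TPR 1) table
    gives AUC 1.
    """
    if not tables:
        raise ValueError("need at least one pattern table")
    if n_classes < 2:
        raise ValueError("need at least two FPR classes")
    if top_k < 1:
        raise ValueError("top_k must be positive")
    ranked = sorted(tables, key=lambda t: fisher_exact(t, direction))
    rates = [decision_rates(t, direction) for t in ranked[:top_k]]

    fpr_sums = np.zeros(n_classes)
    tpr_sums = np.zeros(n_classes)
    counts = np.zeros(n_classes, dtype=int)
    for fpr, tpr in rates:
        b = min(int(fpr * n_classes), n_classes - 1)
        fpr_sums[b] += fpr
        tpr_sums[b] += tpr
        counts[b] += 1

    filled = np.nonzero(counts)[0]
    known_x = np.concatenate(([0.0], fpr_sums[filled] / counts[filled], [1.0]))
    known_y = np.concatenate(([0.0], tpr_sums[filled] / counts[filled], [1.0]))

    # empty bins get interpolated points at their midpoints; these lie on
    # the anchored polyline so the AUC is unaffected by the fill
    midpoints = (np.arange(n_classes) + 0.5) / n_classes
    empty_x = midpoints[counts == 0]
    empty_y = np.interp(empty_x, known_x, known_y)

    xs = np.concatenate((known_x, empty_x))
    ys = np.concatenate((known_y, empty_y))
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]

    auc = float(np.trapezoid(ys, xs))
    points = [(float(x), float(y)) for x, y in zip(xs, ys)]
    return RocCurve(points=points, auc=auc, n_classes=n_classes, direction=direction)


def roc_from_patterns(
    results: Iterable[PatternResult],
    direction: str = "F1",
    n_classes: int = 20,
    top_k: int = 100,
    dedupe_variants: bool = False,
) -> RocCurve:
    """Build a binned ROC curve from genotype-pair scan results.

    With ``dedupe_variants`` set, a pattern is skipped when either of
    its variants already occurs in a better-ranked selected pattern, so
    each variant contributes at most one pattern to the curve; the
    default keeps every pattern.
    """
    ordered = sorted(results, key=lambda r: (r.p, r.pair_id, r.gi, r.gj))
    tables: list[TwoByTwo] = []
    seen: set[str] = set()
    for r in ordered:
        if dedupe_variants:
            if r.var_i in seen or r.var_j in seen:
                continue
            seen.update((r.var_i, r.var_j))
        tables.append(r.table)
        if len(tables) == top_k:
            break
    return binned_roc(tables, direction=direction, n_classes=n_classes, top_k=top_k)
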