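"""Synthetic case-control genotype data with a known planted structure.

Background variants are drawn independently under Hardy-Weinberg
proportions (genotype ~ Binomial(2, MAF) copies of the minor allele).
Optionally, one variant pair carries a planted digenic effect: a 3x3
table of odds multipliers over its genotype pairs feeds a logistic
disease model, and case/control status is assigned by rejection
sampling until the requested group sizes are reached exactly.  The
:func:`pure_interaction_table` helper builds multiplier tables with no
marginal (single-variant) effect, so the planted signal is visible only
to interaction-aware tests.

Missingness is applied after phenotype assignment, uniformly at random
and independently of genotype and phenotype (MCAR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated case-control dataset.

    ``planted_pair`` is ``((i, j), table)`` with 0-based variant indices
    and a 3x3 positive array of odds multipliers indexed by the genotype
    pair; ``None`` plants nothing (a pure null dataset).
    """

    n_case: int = 500
    n_ctrl: int = 500
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_chromosomes: int = 22
    planted_pair: tuple[tuple[int, int], np.ndarray] | None = None
    missing_rate: float = 0.02
    seed: int = 0
    _batch: int = field(default=0, repr=False)  # 0 = auto

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValueError("need at least one case and one control")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.planted_pair is not None:
            (i, j), table = self.planted_pair
            if not (0 <= i < self.n_variants and 0 <= j < self.n_variants) or i == j:
                raise ValueError("planted variant indices out of range or equal")
            table = np.asarray(table, dtype=float)
            if table.shape != (3, 3) or (table <= 0).any():
                raise ValueError("planted table must be 3x3 with positive entries")


def hwe_weights(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2)."""
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def pure_interaction_table(
    strength: float, maf1: float, maf2: float
) -> np.ndarray:
    """3x3 odds-multiplier table with interaction but no marginal effect.

    Models dominant-coded epistasis, the usual planted digenic effect in
    simulation studies: the disease odds depend on whether an individual
    *carries* the minor allele at each variant, but only through the
    joint carrier state.  The table is ``1 + eps * u1 u2^T`` where ``u``
    is the carrier indicator (0, 1, 1) centered at its Hardy-Weinberg
    mean ``1 - (1-MAF)^2``, so the HWE-weighted row and column averages
    are all exactly 1 — a single variant's genotype distribution is the
    same in cases and controls — while genotype *pairs* shift by up to
    the factor ``strength`` (the max/min cell ratio equals
    ``strength``).
    """
    if strength <= 0:
        raise ValueError("strength must be positive")
    carrier = np.array([0.0, 1.0, 1.0])
    u1 = carrier - (1.0 - (1.0 - maf1) ** 2)
    u2 = carrier - (1.0 - (1.0 - maf2) ** 2)
    outer = np.outer(u1, u2)
    if strength == 1.0 or np.allclose(outer, 0.0):
        return np.ones((3, 3))
    hi, lo = outer.max(), outer.min()
    eps = (strength - 1.0) / (hi - strength * lo)
    return 1.0 + eps * outer


def _solve_base_odds(table: np.ndarray, w1: np.ndarray, w2: np.ndarray,
                     target: float) -> float:
    """Bisect the intercept so the marginal case probability hits target."""
    weights = np.outer(w1, w2)

    def frac(theta: float) -> float:
        pr = theta * table / (1.0 + theta * table)
        return float((weights * pr).sum())

    lo, hi = 1e-12, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_dataset(config: SimulationConfig) -> GenotypeDataset:
    """Draw one case-control dataset under ``config``.

    Individuals are sampled in batches; each draw's case probability
    comes from the logistic disease model (odds = intercept x planted
    multiplier for its genotype at the planted pair, or a constant when
    nothing is planted) and draws are kept in order until both groups
    are full, so group sizes are exact.  Cases precede controls in the
    returned dataset.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nv = config.n_variants
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, nv) if hi > lo else np.full(nv, lo)
    target = config.n_case / (config.n_case + config.n_ctrl)

    if config.planted_pair is not None:
        (pi, pj), raw = config.planted_pair
        table = np.asarray(raw, dtype=float)
        theta = _solve_base_odds(
            table, hwe_weights(mafs[pi]), hwe_weights(mafs[pj]), target
        )
    else:
        pi = pj = -1
        table = None
        theta = None

    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    need = config.n_case + config.n_ctrl
    batch = config._batch or max(2 * need, 512)
    while len(case_rows) < config.n_case or len(ctrl_rows) < config.n_ctrl:
        geno = rng.binomial(2, mafs, size=(batch, nv)).astype(np.int8)
        if table is not None:
            odds = theta * table[geno[:, pi], geno[:, pj]]
            pr = odds / (1.0 + odds)
        else:
            pr = np.full(batch, target)
        is_case = rng.random(batch) < pr
        for row, case in zip(geno, is_case):
            if case and len(case_rows) < config.n_case:
                case_rows.append(row)
            elif not case and len(ctrl_rows) < config.n_ctrl:
                ctrl_rows.append(row)

    genotypes = np.vstack(case_rows + ctrl_rows)
    phenotype = np.zeros(need, dtype=bool)
    phenotype[: config.n_case] = True

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        variant_ids=[f"v{k + 1:05d}" for k in range(nv)],
        chromosome=[str(k % config.n_chromosomes + 1) for k in range(nv)],
        alleles=[("A", "B")] * nv,
    )
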