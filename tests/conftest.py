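"""Shared fixtures: the published AMD variant-pair tables and helpers.

The canonical worked example throughout the suite is the most
significant variant pair of the AMD (age-related macular degeneration)
case-control dataset, rs994542 (chr 6) x rs9298846 (chr 9): 96 cases
and 50 controls whose 3x3 genotype cross-tabulations are known, along
with the 2x2 presence/absence table of the (A/A, A/B) genotype pattern
(a=0, b=96, c=11, d=39).
"""

from __future__ import annotations

import numpy as np
import pytest

from gpmkit import GenotypeDataset, TwoByTwo

AMD_CASE_3X3 = np.array([[1, 0, 10], [5, 26, 28], [5, 16, 5]])
AMD_CTRL_3X3 = np.array([[2, 11, 0], [4, 10, 4], [0, 4, 15]])
AMD_PATTERN_2X2 = TwoByTwo(a=0, b=96, c=11, d=39)

#: Number of analyzed variant pairs in the published genome-wide AMD scan,
#: used as the Bonferroni multiplier for the worked example.
AMD_M_T = 294_643_816


def dataset_from_pair_tables(
    case3x3: np.ndarray,
    ctrl3x3: np.ndarray,
    variant_ids: tuple[str, str] = ("rs994542", "rs9298846"),
    chromosomes: tuple[str, str] = ("6", "9"),
) -> GenotypeDataset:
    """Two-variant dataset whose pair cross-tabulation equals the tables."""
    rows, pheno = [], []
    for table, is_case in ((case3x3, True), (ctrl3x3, False)):
        for g1 in range(3):
            for g2 in range(3):
                for _ in range(int(table[g1][g2])):
                    rows.append((g1, g2))
                    pheno.append(is_case)
    return GenotypeDataset(
        genotypes=np.array(rows, dtype=np.int8),
        phenotype=np.array(pheno),
        variant_ids=list(variant_ids),
        chromosome=list(chromosomes),
    )


@pytest.fixture(scope="session")
def amd_dataset() -> GenotypeDataset:
    return dataset_from_pair_tables(AMD_CASE_3X3, AMD_CTRL_3X3)


def random_dataset(seed: int, n_ind: int = 30, n_var: int = 8,
                   missing_rate: float = 0.1) -> GenotypeDataset:
    """Small random dataset (not HWE; for I/O and invariance tests)."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(n_ind, n_var)).astype(np.int8)
    geno[rng.random(geno.shape) < missing_rate] = -1
    pheno = rng.random(n_ind) < 0.5
    pheno[0], pheno[1] = True, False  # ensure both groups
    return GenotypeDataset(
        genotypes=geno,
        phenotype=pheno,
        variant_ids=[f"chr{v % 3 + 1}:snp{v}" for v in range(n_var)],
        chromosome=[str(v % 3 + 1) for v in range(n_var)],
        alleles=[("A", "C") if v % 2 else ("G", "T") for v in range(n_var)],
    )
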