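"""Core in-memory container for case-control genotype data.

Genotypes are stored as a dense ``int8`` matrix of shape
``(n_individuals, n_variants)`` with codes::

    0 = homozygous A1/A1
    1 = heterozygous A1/A2
    2 = homozygous A2/A2
   -1 = missing (the :data:`MISSING` sentinel)

Phenotypes are boolean: ``True`` = case, ``False`` = control.  In the
field's customary genotype-label notation, codes 0/1/2 correspond to the
genotype labels 1 (A/A), 2 (A/B) and 3 (B/B).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel genotype code for a missing call.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeDataset:
    """Individuals x variants genotype matrix with phenotypes and metadata.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_variants)`` integer matrix with codes in
        ``{0, 1, 2, MISSING}``.
    phenotype
        Boolean vector, one entry per individual; ``True`` marks a case.
    variant_ids
        Unique identifier per variant (e.g. an rs number).
    chromosome
        Chromosome label per variant.  Compared by string equality when
        filtering same-chromosome pairs, so ``"1"`` and ``"chr1"`` differ.
    alleles
        ``(A1, A2)`` allele pair per variant.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    variant_ids: list[str]
    chromosome: list[str]
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n_ind, n_var = self.genotypes.shape
        if self.phenotype.shape != (n_ind,):
            raise ValueError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n_ind} individuals"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} at "
                f"individual {i}, variant {j}"
            )
        if not self.alleles:
            self.alleles = [("A", "B")] * n_var
        for name, seq in (
            ("variant_ids", self.variant_ids),
            ("chromosome", self.chromosome),
            ("alleles", self.alleles),
        ):
            if len(seq) != n_var:
                raise ValueError(
                    f"{name} has {len(seq)} entries for {n_var} variants"
                )
        if len(set(self.variant_ids)) != n_var:
            raise ValueError("variant_ids are not unique")
        if not self.phenotype.any() or self.phenotype.all():
            raise ValueError("need at least one case and one control")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.phenotype).sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenotypeDataset({self.n_individuals} individuals "
            f"[{self.n_cases} cases / {self.n_controls} controls], "
            f"{self.n_variants} variants)"
        )
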