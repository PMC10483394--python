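"""Reading and writing genotype data and result tables.

Two input formats are supported: PLINK 1 binary filesets
(``.bed``/``.bim``/``.fam``, SNP-major) — the de-facto interchange
format for case-control genotype data — and a plain-text TSV dialect
(one row per individual: id, phenotype, then one genotype code per
variant; ``NA`` or ``-1`` marks a missing call) with an optional
``<path>.chrom`` sidecar carrying per-variant chromosome labels and
alleles.  Without a sidecar, a variant id of the form ``chr:rest`` has
its chromosome taken from the prefix.

Result tables (variant-pair and genotype-pair scans, per-pair pattern
reports) are written as TSV with fixed headers; p-values are printed in
scientific notation with 6 significant digits and rows are sorted by
ascending p, ties broken by pair id.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .gpairs import PatternResult
from .stats import TwoByTwo
from .vpairs import PairResult, PatternEntry

logger = logging.getLogger("gpmkit")

_BED_MAGIC = bytes((0x6C, 0x1B))
# 2-bit bed codes, LSB-first within each byte: 00 hom A1, 01 missing,
# 10 het, 11 hom A2
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a PLINK binary fileset ``prefix.bed/.bim/.fam``.

    The bed file must be SNP-major (magic ``6C 1B 01``).  fam phenotype
    code 2 maps to case and 1 to control; individuals with any other
    phenotype code are dropped (their count is logged).
    """
    paths = {ext: Path(str(prefix) + ext) for ext in (".bed", ".bim", ".fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"PLINK file not found: {p}")

    fam = pd.read_csv(
        paths[".fam"], sep=r"\s+", header=None, keep_default_na=False,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    bim = pd.read_csv(
        paths[".bim"], sep=r"\s+", header=None, keep_default_na=False,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str,
    )
    n_ind, n_var = len(fam), len(bim)

    raw = paths[".bed"].read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise ValueError(f"{paths['.bed']}: not a PLINK bed file (bad magic bytes)")
    if raw[2] == 0x00:
        raise ValueError(
            f"{paths['.bed']}: individual-major bed layout is not supported"
        )
    if raw[2] != 0x01:
        raise ValueError(f"{paths['.bed']}: unknown bed mode byte {raw[2]:#x}")
    bytes_per_variant = (n_ind + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_var * bytes_per_variant:
        raise ValueError(
            f"{paths['.bed']}: expected {n_var * bytes_per_variant} data bytes "
            f"for {n_ind} individuals x {n_var} variants, found {body.size}"
        )
    packed = body.reshape(n_var, bytes_per_variant)
    twobit = (packed[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = _BED_DECODE[twobit.reshape(n_var, -1)[:, :n_ind]].T  # (ind, var)

    pheno = fam["pheno"].to_numpy()
    keep = np.isin(pheno, ("1", "2"))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d individuals with non-case/control phenotype", dropped)

    return GenotypeDataset(
        genotypes=codes[keep],
        phenotype=pheno[keep] == "2",
        variant_ids=bim["id"].tolist(),
        chromosome=bim["chrom"].tolist(),
        alleles=list(zip(bim["a1"], bim["a2"])),
    )


def write_plink(dataset: GenotypeDataset, prefix: str | os.PathLike) -> None:
    """Write ``dataset`` as a SNP-major PLINK binary fileset."""
    n_ind, n_var = dataset.genotypes.shape
    with open(f"{prefix}.fam", "w") as fh:
        for k in range(n_ind):
            code = 2 if dataset.phenotype[k] else 1
            fh.write(f"F{k + 1} I{k + 1} 0 0 0 {code}\n")
    with open(f"{prefix}.bim", "w") as fh:
        for v in range(n_var):
            a1, a2 = dataset.alleles[v]
            fh.write(
                f"{dataset.chromosome[v]}\t{dataset.variant_ids[v]}\t0\t{v + 1}"
                f"\t{a1}\t{a2}\n"
            )
    bytes_per_variant = (n_ind + 3) // 4
    out = bytearray(_BED_MAGIC + b"\x01")
    for v in range(n_var):
        col = dataset.genotypes[:, v]
        buf = bytearray(bytes_per_variant)
        for k in range(n_ind):
            buf[k >> 2] |= _BED_ENCODE[int(col[k])] << ((k & 3) * 2)
        out += buf
    Path(f"{prefix}.bed").write_bytes(bytes(out))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".chrom")


def read_tsv(path: str | os.PathLike) -> GenotypeDataset:
    """Read the genotype TSV dialect.

    Header: individual id, phenotype, then one column per variant.
    Genotype cells are ``0``/``1``/``2`` or ``NA``/``-1`` for missing;
    phenotypes are ``case``/``control`` (case-insensitive).  Chromosome
    labels come from a ``<path>.chrom`` sidecar (columns: variant id,
    chromosome, optionally A1 and A2) or from a ``chr:rest`` variant-id
    prefix; otherwise all variants get the label ``"0"``.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValueError(f"{path}: empty genotype file")
    columns = header.split("\t")
    if len(columns) < 3:
        raise ValueError(f"{path}: need id, phenotype and at least one variant column")
    variant_ids = columns[2:]
    if len(set(variant_ids)) != len(variant_ids):
        raise ValueError(f"{path}: duplicate variant ids in header")
    # header parsed above (pandas would mangle duplicate column names);
    # keep_default_na off so the literal token "NA" survives
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, skiprows=1,
                     keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: no individuals")
    if df.shape[1] != len(columns):
        raise ValueError(f"{path}: rows do not match the header width")

    pheno_raw = df.iloc[:, 1].str.lower()
    bad = ~pheno_raw.isin(("case", "control"))
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"{path}: row {row + 1}: unknown phenotype {df.iloc[row, 1]!r}"
        )

    cells = df.iloc[:, 2:].to_numpy(dtype=str)
    codes = np.full(cells.shape, np.int8(99), dtype=np.int8)
    for token, value in (("0", 0), ("1", 1), ("2", 2), ("NA", MISSING),
                         ("na", MISSING), ("-1", MISSING)):
        codes[cells == token] = value
    if (codes == 99).any():
        r, c = np.argwhere(codes == 99)[0]
        raise ValueError(
            f"{path}: row {r + 1}, variant {variant_ids[c]}: "
            f"unknown genotype token {cells[r, c]!r}"
        )

    sidecar = _sidecar_path(path)
    alleles = [("A", "B")] * len(variant_ids)
    if sidecar.exists():
        side = pd.read_csv(sidecar, sep="\t", header=None, dtype=str,
                           keep_default_na=False)
        mapping = dict(zip(side.iloc[:, 0], side.iloc[:, 1]))
        missing_ids = [v for v in variant_ids if v not in mapping]
        if missing_ids:
            raise ValueError(f"{sidecar}: no chromosome for variant {missing_ids[0]}")
        chromosome = [mapping[v] for v in variant_ids]
        if side.shape[1] >= 4:
            amap = dict(zip(side.iloc[:, 0], zip(side.iloc[:, 2], side.iloc[:, 3])))
            alleles = [amap.get(v, ("A", "B")) for v in variant_ids]
    elif all(":" in v for v in variant_ids):
        chromosome = [v.split(":", 1)[0] for v in variant_ids]
    else:
        chromosome = ["0"] * len(variant_ids)

    return GenotypeDataset(
        genotypes=codes,
        phenotype=(pheno_raw == "case").to_numpy(),
        variant_ids=variant_ids,
        chromosome=chromosome,
        alleles=alleles,
    )


def write_tsv(dataset: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write ``dataset`` in the TSV dialect, plus its ``.chrom`` sidecar."""
    path = Path(path)
    cols = {"iid": [f"I{k + 1}" for k in range(dataset.n_individuals)],
            "phenotype": ["case" if c else "control" for c in dataset.phenotype]}
    df = pd.DataFrame(cols)
    geno = dataset.genotypes.astype(object)
    for v, vid in enumerate(dataset.variant_ids):
        col = geno[:, v]
        df[vid] = ["NA" if g == MISSING else str(g) for g in col]
    df.to_csv(path, sep="\t", index=False)
    with open(_sidecar_path(path), "w") as fh:
        for vid, chrom, (a1, a2) in zip(
            dataset.variant_ids, dataset.chromosome, dataset.alleles
        ):
            fh.write(f"{vid}\t{chrom}\t{a1}\t{a2}\n")


_PAIR_HEADER = ["pair_id", "var_i", "var_j", "C", "p", "p_B"]
_PATTERN_HEADER = [
    "pair_id", "var_i", "var_j", "g_i", "g_j", "a", "b", "c", "d",
    "support", "confidence", "test", "p", "p_B", "OR", "OR_prime",
]


def _sci(x: float) -> str:
    return f"{x:.5e}"


def write_results(
    records: Sequence[PairResult | PatternResult],
    path: str | os.PathLike,
    kind: str | None = None,
) -> None:
    """Write scan results as TSV, sorted by ascending p then pair id.

    ``kind`` ("pair" or "pattern") selects the header when ``records``
    is empty; otherwise it is inferred from the first record.
    """
    if records:
        kind = "pair" if isinstance(records[0], PairResult) else "pattern"
    elif kind is None:
        kind = "pair"
    rows = sorted(records, key=lambda r: (r.p, r.pair_id))
    with open(path, "w") as fh:
        if kind == "pair":
            fh.write("\t".join(_PAIR_HEADER) + "\n")
            for r in rows:
                fh.write(
                    f"{r.pair_id}\t{r.var_i}\t{r.var_j}\t{r.C:.6g}\t"
                    f"{_sci(r.p)}\t{_sci(r.p_B)}\n"
                )
        else:
            fh.write("\t".join(_PATTERN_HEADER) + "\n")
            for r in rows:
                t = r.table
                fh.write(
                    f"{r.pair_id}\t{r.var_i}\t{r.var_j}\t{r.gi}\t{r.gj}\t"
                    f"{t.a}\t{t.b}\t{t.c}\t{t.d}\t{r.support}\t"
                    f"{r.confidence:.6g}\t{r.test}\t{_sci(r.p)}\t{_sci(r.p_B)}\t"
                    f"{r.odds_ratio:.6g}\t{r.or_prime:.6g}\n"
                )


def write_pairsnps(
    entries: Sequence[PatternEntry], var_i: str, var_j: str,
    path: str | os.PathLike,
) -> None:
    """Write a per-pair drill-down report (entries in given OR' order)."""
    with open(path, "w") as fh:
        fh.write("var_i\tvar_j\tg_i\tg_j\ta\tb\tc\td\tsupport\tconfidence"
                 "\tOR\tOR_prime\n")
        for e in entries:
            t = e.table
            fh.write(
                f"{var_i}\t{var_j}\t{e.gi}\t{e.gj}\t{t.a}\t{t.b}\t{t.c}\t{t.d}"
                f"\t{e.support}\t{e.confidence:.6g}\t{e.odds_ratio:.6g}"
                f"\t{e.or_prime:.6g}\n"
            )


def read_pattern_results(path: str | os.PathLike) -> list[PatternResult]:
    """Read back a genotype-pair results TSV (for ROC evaluation)."""
    df = pd.read_csv(path, sep="\t", dtype={"var_i": str, "var_j": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PatternResult(
                pair_id=int(row.pair_id), var_i=row.var_i, var_j=row.var_j,
                gi=int(row.g_i), gj=int(row.g_j),
                table=TwoByTwo(int(row.a), int(row.b), int(row.c), int(row.d)),
                support=int(row.support), confidence=float(row.confidence),
                test=row.test, p=float(row.p), p_B=float(row.p_B),
                odds_ratio=float(row.OR), or_prime=float(row.OR_prime),
            )
        )
    return out


def write_roc(curve, path: str | os.PathLike) -> None:
    """Write ROC curve points as a (FPR, TPR) TSV with the AUC in a comment."""
    with open(path, "w") as fh:
        fh.write(f"# direction={curve.direction} n_classes={curve.n_classes} "
                 f"auc={curve.auc:.6g}\n")
        fh.write("FPR\tTPR\n")
        for x, y in curve.points:
            fh.write(f"{x:.6g}\t{y:.6g}\n")
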