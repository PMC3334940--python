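"""Genotype/phenotype I/O, quality-control filtering and the 3-column binary encoding.

Genotypes are dosage-coded: 0 = homozygous major (MM), 1 = heterozygous (Mm),
2 = homozygous minor (mm); ``NA`` marks a missing call.  Each SNP expands
losslessly into three boolean item columns (mm, Mm, MM), so a combination of
SNP genotypes becomes a conjunction of boolean items and its presence in a
sample is a plain bitwise AND.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: genotype codes in item order; for one SNP the item columns are (mm, Mm, MM)
GENOTYPE_CODES: tuple[str, str, str] = ("mm", "Mm", "MM")

#: dosage value encoded by each item offset: offset 0 (mm) <-> dosage 2, etc.
_OFFSET_TO_DOSAGE = np.array([2, 1, 0], dtype=np.int8)
_DOSAGE_TO_OFFSET = {2: 0, 1: 1, 0: 2}

_NON_AUTOSOMES = {"X", "Y", "MT", "M", "XY"}


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with row/column identifiers.

    ``values[i, j]`` is the minor-allele dosage of sample ``i`` at SNP ``j``
    (0/1/2) or :data:`MISSING`.  ``chrom`` optionally labels each SNP's
    chromosome for autosome filtering.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    chrom: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise DataError("genotype values must be a 2-D samples x SNPs array")
        n, s = self.values.shape
        if n == 0:
            raise DataError("no samples")
        if len(self.sample_ids) != n or len(self.snp_ids) != s:
            raise DataError("ID lists do not match the value matrix shape")
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample IDs")
        if len(set(self.snp_ids)) != s:
            raise DataError("duplicate SNP IDs")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"invalid genotype value {self.values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if self.chrom is not None and len(self.chrom) != s:
            raise DataError("chrom list does not match the number of SNPs")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.values == MISSING).mean(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and self.chrom == other.chrom
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a sample-ID list."""

    sample_ids: list[str]
    is_case: np.ndarray  # boolean, True = case

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.is_case.shape != (len(self.sample_ids),):
            raise DataError("label vector does not match the sample-ID list")
        if not self.is_case.any() or self.is_case.all():
            raise DataError("need at least one case and one control")

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_ctrl(self) -> int:
        return int((~self.is_case).sum())

    @property
    def labels(self) -> list[str]:
        return ["case" if c else "control" for c in self.is_case]


@dataclass
class BinaryItemMatrix:
    """Lossless 3-columns-per-SNP boolean expansion of a genotype matrix.

    Item ``3*j + o`` is (snp ``j``, genotype ``GENOTYPE_CODES[o]``); items are
    totally ordered by this index (SNP file order, then mm < Mm < MM), and all
    candidate generation in the miner relies on that order for determinism.
    A missing genotype leaves all three columns 0, so any pattern touching
    that SNP counts as absent in the sample.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    bits: np.ndarray  # samples x (3 * n_snps), bool

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.sample_ids), 3 * len(self.snp_ids)):
            raise DataError("bit matrix shape does not match IDs")

    @property
    def n_samples(self) -> int:
        return self.bits.shape[0]

    @property
    def n_items(self) -> int:
        return self.bits.shape[1]

    @property
    def items(self) -> list[tuple[str, str]]:
        return [
            (snp, code) for snp in self.snp_ids for code in GENOTYPE_CODES
        ]

    def item_index(self, snp_id: str, code: str) -> int:
        j = self.snp_ids.index(snp_id)
        return 3 * j + GENOTYPE_CODES.index(code)

    def item_label(self, idx: int) -> tuple[str, str]:
        return self.snp_ids[idx // 3], GENOTYPE_CODES[idx % 3]


def encode_binary(G: GenotypeMatrix) -> BinaryItemMatrix:
    """Expand a genotype matrix into its 3-column boolean item matrix.

    With no missing values exactly one third of the bits are 1 (each sample
    contributes one 1 per SNP), which is the density the miner's bitwise
    support counting is designed around.
    """
    n, s = G.values.shape
    bits = np.zeros((n, 3 * s), dtype=bool)
    for offset in range(3):
        dosage = _OFFSET_TO_DOSAGE[offset]
        bits[:, offset::3] = G.values == dosage
    return BinaryItemMatrix(list(G.sample_ids), list(G.snp_ids), bits)


def decode_binary(B: BinaryItemMatrix) -> GenotypeMatrix:
    """Invert :func:`encode_binary`; all-zero triples decode to MISSING."""
    n = B.n_samples
    s = len(B.snp_ids)
    values = np.full((n, s), MISSING, dtype=np.int8)
    for offset in range(3):
        sel = B.bits[:, offset::3]
        values[sel] = _OFFSET_TO_DOSAGE[offset]
    return GenotypeMatrix(list(B.sample_ids), list(B.snp_ids), values)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a samples-as-rows dosage TSV (header = SNP IDs, col 0 = sample IDs).

    Cells must be 0, 1, 2 or NA.  An optional comment line starting with
    ``#chrom`` directly above the header provides per-SNP chromosome labels.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    chrom = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#chrom"):
            chrom = first.rstrip("\n").split("\t")[1:]
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str, comment="#")
    if df.shape[0] == 0:
        raise DataError(f"{path}: no samples")
    sample_ids = [str(s) for s in df.index]
    snp_ids = [str(s) for s in df.columns]
    values = np.full(df.shape, MISSING, dtype=np.int8)
    raw = df.to_numpy(dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("NA", "", "NaN", "nan"):
                continue
            if cell not in ("0", "1", "2"):
                raise DataError(
                    f"{path}: invalid genotype {cell!r} at sample "
                    f"{sample_ids[i]!r}, SNP {snp_ids[j]!r}"
                )
            values[i, j] = int(cell)
    return GenotypeMatrix(sample_ids, snp_ids, values, chrom=chrom)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        if G.chrom is not None:
            fh.write("#chrom\t" + "\t".join(G.chrom) + "\n")
        fh.write("sample_id\t" + "\t".join(G.snp_ids) + "\n")
        for i, sid in enumerate(G.sample_ids):
            row = [
                "NA" if v == MISSING else str(int(v)) for v in G.values[i]
            ]
            fh.write(sid + "\t" + "\t".join(row) + "\n")


def read_phenotypes(path, sample_ids: list[str] | None = None) -> PhenotypeVector:
    """Read a two-column TSV ``sample_id<TAB>label`` with label in {case, control}.

    If ``sample_ids`` is given, labels are re-ordered to match it and every
    listed sample must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns sample_id, label")
    df.columns = ["sample_id", "label"] + list(df.columns[2:])
    lab = dict(zip(df["sample_id"], df["label"]))
    if len(lab) != len(df):
        raise DataError(f"{path}: duplicate sample IDs")
    bad = set(df["label"]) - {"case", "control"}
    if bad:
        raise DataError(f"{path}: invalid labels {sorted(bad)}")
    if sample_ids is None:
        sample_ids = list(df["sample_id"])
    try:
        is_case = np.array([lab[s] == "case" for s in sample_ids])
    except KeyError as e:
        raise DataError(f"{path}: missing phenotype for sample {e.args[0]!r}")
    return PhenotypeVector(list(sample_ids), is_case)


def write_phenotypes(ph: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(ph.sample_ids, ph.labels):
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    G: GenotypeMatrix,
    max_missing_frac: float = 0.05,
    autosomes_only: bool = False,
) -> GenotypeMatrix:
    """Drop SNPs with *more than* ``max_missing_frac`` missing calls.

    The inequality is strict: a SNP missing exactly 5/100 calls survives a
    0.05 threshold.  With ``autosomes_only``, SNPs on X/Y/MT (any ``chr``
    prefix, case-insensitive) are dropped too.  Survivor order is preserved
    and the operation is idempotent.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    keep = G.missing_fraction() <= max_missing_frac
    if autosomes_only:
        if G.chrom is None:
            raise DataError("autosomes_only requires chromosome labels")
        auto = np.array(
            [c.upper().removeprefix("CHR") not in _NON_AUTOSOMES
             for c in (ch.upper() for ch in G.chrom)]
        )
        keep &= auto
    if not keep.any():
        raise DataError("QC filter removed all SNPs")
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        list(G.sample_ids),
        [G.snp_ids[j] for j in idx],
        G.values[:, idx],
        chrom=None if G.chrom is None else [G.chrom[j] for j in idx],
    )


# ---------------------------------------------------------------------------
# gene maps, gene sets, networks
# ---------------------------------------------------------------------------

@dataclass
class GeneMap:
    """SNP -> gene symbol assignment (each SNP maps to at most one gene)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def gene(self, snp_id: str) -> str | None:
        return self.mapping.get(snp_id)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


def read_gene_map(path) -> GeneMap:
    """Read a two-column TSV ``snp_id<TAB>gene``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns snp_id, gene")
    if df.iloc[0, 0] in ("snp_id", "snp"):
        df = df.iloc[1:]
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return GeneMap(mapping)


def write_gene_map(gm: GeneMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tgene\n")
        for snp, gene in gm.mapping.items():
            fh.write(f"{snp}\t{gene}\n")


@dataclass
class GeneSetCollection:
    """Named gene sets retained after a maximum-set-size filter."""

    sets: dict[str, frozenset[str]]
    max_set_size: int | None = None

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


def read_gene_sets(path, max_set_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated genes per line).

    Sets with more than ``max_set_size`` genes are excluded (a set of exactly
    ``max_set_size`` genes is retained).
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene"
                )
            name = parts[0]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise DataError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene set {name!r}")
            if max_set_size is not None and len(genes) > max_set_size:
                continue
            sets[name] = genes
    if not sets:
        warnings.warn("no gene sets retained after size filtering")
    return GeneSetCollection(sets, max_set_size=max_set_size)
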