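"""Per-pattern association statistics.

A *pattern* is a conjunction of genotype items at distinct SNPs; it is
present in a sample iff every item bit is set.  Presence vs phenotype is a
2x2 table, so every pattern — whatever its size — is tested with one degree
of freedom, which keeps chi-square statistics of different sizes directly
comparable and is what makes the jump statistic meaningful.

Two search-related statistics live here as well:

* ``supmaxpair`` — support of the pattern in its enriched class minus the
  maximum support of any of its size-2 subsets in the other class.  It is
  anti-monotone (adding items can only shrink the first term and grow the
  second), which is what lets the Apriori miner prune safely.
* ``jump`` — the pattern's chi-square minus the best chi-square among all of
  its proper subsets.  A positive jump means the combination carries
  association beyond every part of it; jump is *not* anti-monotone and is
  only ever applied as a post-hoc filter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .genotype_io import GENOTYPE_CODES, BinaryItemMatrix, PhenotypeVector

CASE_ENRICHED = "case-enriched"
CONTROL_ENRICHED = "control-enriched"
DIRECTIONS = (CASE_ENRICHED, CONTROL_ENRICHED)


@dataclass(frozen=True)
class Pattern:
    """An ordered set of (snp_id, genotype_code) items at distinct SNPs."""

    items: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.items) < 1:
            raise ValueError("a pattern needs at least one item")
        snps = [s for s, _ in self.items]
        if len(set(snps)) != len(snps):
            raise ValueError("pattern items must come from distinct SNPs")
        for _, code in self.items:
            if code not in GENOTYPE_CODES:
                raise ValueError(f"unknown genotype code {code!r}")

    @property
    def size(self) -> int:
        return len(self.items)

    def sorted_by(self, B: BinaryItemMatrix) -> "Pattern":
        """Return the pattern with items in the global item order of ``B``."""
        idx = sorted(B.item_index(s, c) for s, c in self.items)
        return Pattern(tuple(B.item_label(i) for i in idx))

    def column_indices(self, B: BinaryItemMatrix) -> list[int]:
        return [B.item_index(s, c) for s, c in self.items]

    def presence(self, B: BinaryItemMatrix) -> np.ndarray:
        """Boolean per-sample presence vector (AND over item columns)."""
        cols = self.column_indices(B)
        return B.bits[:, cols].all(axis=1)

    def subsets(self, sizes: Iterable[int]) -> Iterable["Pattern"]:
        for k in sizes:
            for combo in itertools.combinations(self.items, k):
                yield Pattern(combo)

    def __str__(self) -> str:
        return ";".join(f"{s}:{c}" for s, c in self.items)

    @classmethod
    def parse(cls, text: str) -> "Pattern":
        items = []
        for tok in text.split(";"):
            snp, _, code = tok.rpartition(":")
            items.append((snp, code))
        return cls(tuple(items))


class ContingencyTable2x2(NamedTuple):
    """Pattern-presence x phenotype counts.

    a/b = pattern-present cases/controls, c/d = pattern-absent cases/controls.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class OddsRatioResult(NamedTuple):
    value: float
    haldane: bool  # True when the +0.5 zero-cell correction was applied


@dataclass
class PatternStats:
    supp_case: float
    supp_ctrl: float
    supmaxpair: float
    chi2: float
    p_chi2: float
    odds_ratio: float
    odds_ratio_haldane: bool
    fisher_p: float
    jump: float
    direction: str


def support(P: Pattern, B: BinaryItemMatrix, group: np.ndarray) -> float:
    """Fraction of the samples selected by boolean mask ``group`` in which
    ``P`` is present."""
    group = np.asarray(group, dtype=bool)
    n = int(group.sum())
    if n == 0:
        raise ValueError("empty sample group")
    return float(P.presence(B)[group].sum()) / n


def supmaxpair(
    P: Pattern,
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    direction: str = CASE_ENRICHED,
) -> float:
    """Support of ``P`` in the enriched class minus the maximal support of
    its size-2 subsets in the other class (for size 2, the pattern is its own
    only size-2 subset)."""
    if P.size < 2:
        raise ValueError("supmaxpair is defined for patterns of size >= 2")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    case = labels.is_case
    enriched, other = (case, ~case) if direction == CASE_ENRICHED else (~case, case)
    s_enr = support(P, B, enriched)
    max_pair = max(
        support(Q, B, other) for Q in P.subsets([2])
    )
    return s_enr - max_pair


def contingency(
    P: Pattern, B: BinaryItemMatrix, labels: PhenotypeVector
) -> ContingencyTable2x2:
    pres = P.presence(B)
    case = labels.is_case
    a = int((pres & case).sum())
    b = int((pres & ~case).sum())
    return ContingencyTable2x2(a, b, labels.n_case - a, labels.n_ctrl - b)


def chi2_df1(T: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) with 1 df.

    Degenerate tables (a zero row or column margin) return (0, 1): such a
    pattern carries no case/control contrast.
    """
    a, b, c, d = T
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def odds_ratio(T: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product odds ratio; any zero cell triggers the Haldane–Anscombe
    +0.5 correction on all cells and is flagged."""
    a, b, c, d = T
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return OddsRatioResult(float(a * d / (b * c)), True)
    return OddsRatioResult(float(a * d / (b * c)), False)


def fisher_exact(T: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value."""
    return float(
        sps.fisher_exact([[T.a, T.b], [T.c, T.d]], alternative="two-sided")[1]
    )


def jump(P: Pattern, B: BinaryItemMatrix, labels: PhenotypeVector) -> float:
    """chi2(P) minus the best chi2 among all 2^k - 2 proper non-empty subsets.

    Exhaustive by construction; the miner computes the same quantity from its
    survivor tables, and the two are asserted equal in tests.
    """
    if P.size < 2:
        raise ValueError("jump needs a pattern of size >= 2 (proper subsets)")
    own, _ = chi2_df1(contingency(P, B, labels))
    best = max(
        chi2_df1(contingency(Q, B, labels))[0]
        for Q in P.subsets(range(1, P.size))
    )
    return own - best


def compute_stats(
    P: Pattern,
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    direction: str = CASE_ENRICHED,
) -> PatternStats:
    """Full per-pattern statistics bundle (reference single-pattern path)."""
    T = contingency(P, B, labels)
    chi2, p = chi2_df1(T)
    orr = odds_ratio(T)
    return PatternStats(
        supp_case=T.a / labels.n_case,
        supp_ctrl=T.b / labels.n_ctrl,
        supmaxpair=supmaxpair(P, B, labels, direction) if P.size >= 2 else math.nan,
        chi2=chi2,
        p_chi2=p,
        odds_ratio=orr.value,
        odds_ratio_haldane=orr.haldane,
        fisher_p=fisher_exact(T),
        jump=jump(P, B, labels) if P.size >= 2 else math.nan,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# vectorised batch statistics (used by the miner for large result sets)
# ---------------------------------------------------------------------------

def chi2_df1_counts(
    a: np.ndarray, b: np.ndarray, n_case: int, n_ctrl: int
) -> np.ndarray:
    """Vectorised Pearson chi-square for tables (a, b, n_case-a, n_ctrl-b)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = n_case - a
    d = n_ctrl - b
    n = float(n_case + n_ctrl)
    r1 = a + b
    r2 = c + d
    denom = r1 * r2 * float(n_case) * float(n_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom == 0, 0.0, stat)


def fisher_two_sided_counts(
    a: np.ndarray, b: np.ndarray, n_case: int, n_ctrl: int
) -> np.ndarray:
    """Vectorised two-sided Fisher p for tables sharing the case/control margin.

    Tables are grouped by the number of pattern-present samples r = a + b;
    within a group the p-value is the sum of hypergeometric probabilities no
    larger than the observed one (with the usual (1 + 1e-7) slack against
    floating-point ties).
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    r = a + b
    N = n_case + n_ctrl
    out = np.empty(a.shape, dtype=np.float64)
    for rv in np.unique(r):
        sel = r == rv
        lo = max(0, rv - n_ctrl)
        hi = min(rv, n_case)
        ks = np.arange(lo, hi + 1)
        pmf = sps.hypergeom.pmf(ks, N, n_case, rv)
        order = np.argsort(pmf)
        csum = np.cumsum(pmf[order])
        obs = sps.hypergeom.pmf(a[sel], N, n_case, rv)
        # number of mass points with pmf <= observed * (1 + eps)
        pos = np.searchsorted(pmf[order], obs * (1 + 1e-7), side="right")
        p = np.where(pos > 0, csum[np.maximum(pos, 1) - 1], 0.0)
        out[sel] = np.minimum(p, 1.0)
    return out


def odds_ratio_counts(
    a: np.ndarray, b: np.ndarray, n_case: int, n_ctrl: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised odds ratios with the Haldane–Anscombe zero-cell correction."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = n_case - a
    d = n_ctrl - b
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a2 = np.where(zero, a + 0.5, a)
    b2 = np.where(zero, b + 0.5, b)
    c2 = np.where(zero, c + 0.5, c)
    d2 = np.where(zero, d + 0.5, d)
    return a2 * d2 / (b2 * c2), zero
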