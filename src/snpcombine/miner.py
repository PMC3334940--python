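"""Apriori mining of discriminative SNP-genotype combinations.

The search is level-wise and bottom-up: level-k candidates are formed only
by prefix-joining surviving level-(k-1) patterns, and a candidate is kept
iff its SupMaxPair value meets the threshold.  Because SupMaxPair is
anti-monotone, pruning a failing pattern can never lose a qualifying
superset, so the output is exactly the set of qualifying patterns — the
same set a brute-force enumeration produces (``brute_force_mine``, kept as
an independent oracle for testing).

Support counting uses packed 64-bit sample bitsets: each surviving pattern
carries its per-class presence bitset, a child's bitset is the AND of its
two parents', and counts come from hardware popcount.  The maximum size-2
subset support in the contrast class is maintained incrementally: for a
child P = prefix + {x, y} joined from parents P1 (…x) and P2 (…y), every
size-2 subset of P is a subset of P1, a subset of P2, or the new pair
{x, y}.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import (
    GENOTYPE_CODES,
    BinaryItemMatrix,
    GeneMap,
    GeneSetCollection,
    PhenotypeVector,
)
from .pattern_stats import (
    CASE_ENRICHED,
    CONTROL_ENRICHED,
    DIRECTIONS,
    Pattern,
    PatternStats,
    chi2_df1_counts,
    fisher_two_sided_counts,
    odds_ratio_counts,
)
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: slack used in every SupMaxPair >= threshold comparison, so that float
#: rounding can never break the subset-superset ordering the pruning relies on
_EPS = 1e-9


class MiningBudgetError(RuntimeError):
    """The surviving candidate frontier exceeded the configured budget."""


@dataclass
class MiningConfig:
    """Parameters of one mining run.

    threshold        SupMaxPair cutoff in (0, 1]; every reported pattern has
                     support >= threshold in its enriched class.
    max_size         largest pattern size searched (default 10).
    directions       which enrichment directions to mine (default both).
    min_size_report  smallest size included in the result (default 2).
    gene_map/gene_sets  optional gene-set constraint: a pattern is eligible
                     only if the genes of all its SNPs lie jointly in at
                     least one retained gene set (anti-monotone, applied at
                     every level).
    jump_min         optional post-hoc jump filter threshold (applied by
                     :func:`jump_filter`, echoed here so permutation runs
                     reproduce the full pipeline).
    candidate_budget maximum surviving frontier size per level; exceeding it
                     raises :class:`MiningBudgetError` advising a higher
                     threshold.
    """

    threshold: float
    max_size: int = 10
    directions: tuple[str, ...] = DIRECTIONS
    min_size_report: int = 2
    gene_map: GeneMap | None = None
    gene_sets: GeneSetCollection | None = None
    jump_min: float | None = None
    candidate_budget: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.max_size < 2:
            raise ValueError("max_size must be >= 2")
        if self.min_size_report < 1:
            raise ValueError("min_size_report must be >= 1")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        if (self.gene_sets is None) != (self.gene_map is None):
            raise ValueError("gene_map and gene_sets must be given together")

    def digest(self) -> str:
        """Stable digest of every search-relevant setting (used to assert
        that permutation runs replicate the real run's setup)."""
        h = hashlib.sha256()
        parts = [
            f"threshold={self.threshold!r}",
            f"max_size={self.max_size}",
            f"directions={','.join(self.directions)}",
            f"min_size_report={self.min_size_report}",
            f"jump_min={self.jump_min!r}",
        ]
        if self.gene_map is not None:
            parts.append("gene_map=" + ";".join(
                f"{k}:{v}" for k, v in sorted(self.gene_map.mapping.items())))
        if self.gene_sets is not None:
            parts.append("gene_sets=" + ";".join(
                f"{name}:{','.join(sorted(genes))}"
                for name, genes in sorted(self.gene_sets.sets.items())))
        h.update("\n".join(parts).encode())
        return h.hexdigest()


@dataclass
class MiningResult:
    """Qualifying patterns with statistics plus run provenance."""

    patterns: list[tuple[Pattern, PatternStats]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patterns)

    def counts_per_size(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for p, _ in self.patterns:
            out[p.size] = out.get(p.size, 0) + 1
        return out


# ---------------------------------------------------------------------------
# bitset helpers
# ---------------------------------------------------------------------------

def _pack_columns(bits: np.ndarray) -> np.ndarray:
    """Pack a (samples x columns) boolean matrix into per-column uint64
    bitset rows of shape (columns, W)."""
    bt = np.ascontiguousarray(bits.T)
    packed = np.packbits(bt, axis=1)
    pad = (-packed.shape[1]) % 8
    if pad:
        packed = np.pad(packed, ((0, 0), (0, pad)))
    return packed.view(np.uint64)


def _popcount_rows(x: np.ndarray) -> np.ndarray:
    return np.bitwise_count(x).sum(axis=1, dtype=np.int64)


# ---------------------------------------------------------------------------
# gene-set constraint machinery
# ---------------------------------------------------------------------------

def _item_set_masks(
    B: BinaryItemMatrix, gene_map: GeneMap, gene_sets: GeneSetCollection
) -> np.ndarray:
    """Per-item packed membership mask over retained gene sets.

    Bit s of item i's mask is set iff the gene of item i's SNP belongs to
    gene set s; an unmapped SNP gets an all-zero mask and therefore fails
    the constraint at level 1 already.
    """
    set_names = sorted(gene_sets.sets)
    n_sets = len(set_names)
    w = max(1, -(-n_sets // 64))
    gene_mask: dict[str, np.ndarray] = {}
    for s, name in enumerate(set_names):
        for g in gene_sets.sets[name]:
            m = gene_mask.setdefault(g, np.zeros(w, dtype=np.uint64))
            m[s // 64] |= np.uint64(1) << np.uint64(s % 64)
    masks = np.zeros((B.n_items, w), dtype=np.uint64)
    for j, snp in enumerate(B.snp_ids):
        gene = gene_map.gene(snp)
        if gene is not None and gene in gene_mask:
            masks[3 * j : 3 * j + 3] = gene_mask[gene]
    return masks


def apply_geneset_constraint(
    candidates: Sequence[Pattern],
    gene_map: GeneMap,
    sets: GeneSetCollection,
) -> list[Pattern]:
    """Keep a candidate iff the genes of all its SNPs are jointly contained
    in at least one retained gene set (unmapped SNPs fail every set)."""
    out = []
    for p in candidates:
        genes = []
        ok = True
        for snp, _ in p.items:
            g = gene_map.gene(snp)
            if g is None:
                ok = False
                break
            genes.append(g)
        if ok and any(set(genes) <= s for s in sets.sets.values()):
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# core level-wise search
# ---------------------------------------------------------------------------

@dataclass
class _DirectionResult:
    """Raw per-size survivor tables for one enrichment direction.

    items[k]  (n_k, k) global item indices, rows in lexicographic order
    enr[k]    presence counts in the enriched class
    oth[k]    presence counts in the contrast class
    maxo[k]   max size-2 subset presence count in the contrast class
    """

    direction: str
    n_enr: int
    n_oth: int
    items: dict[int, np.ndarray]
    enr: dict[int, np.ndarray]
    oth: dict[int, np.ndarray]
    maxo: dict[int, np.ndarray]
    level_log: list[dict] = field(default_factory=list)

    def supmaxpair(self, k: int) -> np.ndarray:
        return self.enr[k] / self.n_enr - self.maxo[k] / self.n_oth


def _qualifies(enr_cnt, maxo_cnt, n_enr, n_oth, threshold):
    return enr_cnt / n_enr - maxo_cnt / n_oth >= threshold - _EPS


def _search_direction(
    B: BinaryItemMatrix,
    is_case: np.ndarray,
    cfg: MiningConfig,
    direction: str,
    item_masks: np.ndarray | None,
) -> _DirectionResult:
    enr_mask = is_case if direction == CASE_ENRICHED else ~is_case
    oth_mask = ~enr_mask
    n_enr = int(enr_mask.sum())
    n_oth = int(oth_mask.sum())
    bits_enr = B.bits[enr_mask]
    bits_oth = B.bits[oth_mask]
    item_enr = _pack_columns(bits_enr)   # (n_items, We)
    item_oth = _pack_columns(bits_oth)   # (n_items, Wo)
    item_enr_cnt = bits_enr.sum(axis=0, dtype=np.int64)

    res = _DirectionResult(direction, n_enr, n_oth, {}, {}, {}, {})

    # level 1: an item can only appear in a qualifying pattern if its own
    # support in the enriched class meets the threshold (the subtracted pair
    # maximum is never negative)
    keep1 = item_enr_cnt / n_enr >= cfg.threshold - _EPS
    if item_masks is not None:
        keep1 &= item_masks.any(axis=1)
    S = np.flatnonzero(keep1).astype(np.int32)
    res.level_log.append({"size": 1, "candidates": B.n_items, "survivors": len(S)})
    if len(S) < 2:
        return res

    # level 2: dense pairwise co-occurrence via matrix products
    a_enr = bits_enr[:, S].astype(np.float32)
    a_oth = bits_oth[:, S].astype(np.float32)
    co_enr = np.rint(a_enr.T @ a_enr).astype(np.int64)
    co_oth = np.rint(a_oth.T @ a_oth).astype(np.int64)
    snp_of = S // 3
    ok = np.triu(np.ones((len(S), len(S)), dtype=bool), k=1)
    ok &= snp_of[:, None] != snp_of[None, :]
    ok &= _qualifies(co_enr, co_oth, n_enr, n_oth, cfg.threshold)
    if item_masks is not None:
        pair_mask = np.zeros_like(ok)
        m = item_masks[S]
        for w in range(m.shape[1]):
            pair_mask |= (m[:, w][:, None] & m[:, w][None, :]) != 0
        ok &= pair_mask
    ii, jj = np.nonzero(ok)
    n_cand2 = len(S) * (len(S) - 1) // 2
    res.level_log.append({"size": 2, "candidates": n_cand2, "survivors": len(ii)})
    if len(ii) > cfg.candidate_budget:
        raise MiningBudgetError(
            f"{len(ii)} surviving size-2 candidates exceed the budget of "
            f"{cfg.candidate_budget}; raise the SupMaxPair threshold"
        )
    if len(ii) == 0:
        return res

    items = np.stack([S[ii], S[jj]], axis=1).astype(np.int32)
    order = np.lexsort((items[:, 1], items[:, 0]))
    items = items[order]
    enr_bits = item_enr[items[:, 0]] & item_enr[items[:, 1]]
    oth_bits = item_oth[items[:, 0]] & item_oth[items[:, 1]]
    enr_cnt = co_enr[ii, jj][order]
    oth_cnt = co_oth[ii, jj][order]
    maxo = oth_cnt.copy()
    masks = item_masks[items[:, 0]] & item_masks[items[:, 1]] if item_masks is not None else None
    res.items[2], res.enr[2], res.oth[2], res.maxo[2] = items, enr_cnt, oth_cnt, maxo

    # levels >= 3: prefix join of the sorted frontier
    k = 2
    while k < cfg.max_size and len(items) >= 2:
        prefix = items[:, :-1]
        changed = np.any(prefix[1:] != prefix[:-1], axis=1)
        starts = np.concatenate([[0], np.flatnonzero(changed) + 1, [len(items)]])
        new_rows, new_eb, new_ob, new_ec, new_oc, new_mx = [], [], [], [], [], []
        new_masks = []
        n_cand = 0
        survivor_set: set[tuple] | None = None
        for s, e in zip(starts[:-1], starts[1:]):
            g = e - s
            if g < 2:
                continue
            li, lj = np.triu_indices(g, 1)
            li += s
            lj += s
            x = items[li, -1]
            y = items[lj, -1]
            keep = (x // 3) != (y // 3)
            if masks is not None:
                keep &= (masks[li] & masks[lj]).any(axis=1)
            n_cand += g * (g - 1) // 2
            if not keep.any():
                continue
            li, lj, y = li[keep], lj[keep], y[keep]
            eb = enr_bits[li] & enr_bits[lj]
            ec = _popcount_rows(eb)
            po = _popcount_rows(item_oth[items[li, -1]] & item_oth[y])
            mx = np.maximum(np.maximum(maxo[li], maxo[lj]), po)
            q = _qualifies(ec, mx, n_enr, n_oth, cfg.threshold)
            if not q.any():
                continue
            li, lj, y = li[q], lj[q], y[q]
            eb_q, ec_q, mx_q = eb[q], ec[q], mx[q]
            cand = np.concatenate([items[li], y[:, None]], axis=1)
            # all-subsets-survive check (guaranteed by anti-monotonicity;
            # kept as a cheap verification on the few survivors)
            if survivor_set is None:
                survivor_set = {tuple(r) for r in items}
            keep_rows = np.fromiter(
                (
                    all(
                        tuple(np.delete(row, d)) in survivor_set
                        for d in range(len(row) - 2)
                    )
                    for row in cand
                ),
                dtype=bool,
                count=len(cand),
            )
            if not keep_rows.all():  # pragma: no cover - cannot happen
                li, lj = li[keep_rows], lj[keep_rows]
                cand = cand[keep_rows]
                eb_q, ec_q, mx_q = eb_q[keep_rows], ec_q[keep_rows], mx_q[keep_rows]
            ob = oth_bits[li] & oth_bits[lj]
            new_rows.append(cand)
            new_eb.append(eb_q)
            new_ob.append(ob)
            new_ec.append(ec_q)
            new_oc.append(_popcount_rows(ob))
            new_mx.append(mx_q)
            if masks is not None:
                new_masks.append(masks[li] & masks[lj])
        k += 1
        if not new_rows:
            res.level_log.append({"size": k, "candidates": n_cand, "survivors": 0})
            break
        items = np.concatenate(new_rows)
        enr_bits = np.concatenate(new_eb)
        oth_bits = np.concatenate(new_ob)
        enr_cnt = np.concatenate(new_ec)
        oth_cnt = np.concatenate(new_oc)
        maxo = np.concatenate(new_mx)
        masks = np.concatenate(new_masks) if masks is not None else None
        res.level_log.append({"size": k, "candidates": n_cand, "survivors": len(items)})
        if len(items) > cfg.candidate_budget:
            raise MiningBudgetError(
                f"{len(items)} surviving size-{k} candidates exceed the "
                f"budget of {cfg.candidate_budget}; raise the SupMaxPair "
                "threshold"
            )
        res.items[k] = items
        res.enr[k] = enr_cnt
        res.oth[k] = oth_cnt
        res.maxo[k] = maxo
    return res


def _search_all(
    B: BinaryItemMatrix, labels: PhenotypeVector, cfg: MiningConfig
) -> list[_DirectionResult]:
    if B.n_items == 0:
        raise ValueError("empty item matrix")
    if list(B.sample_ids) != list(labels.sample_ids):
        raise ValueError("item matrix and phenotype sample IDs differ")
    item_masks = None
    if cfg.gene_sets is not None:
        item_masks = _item_set_masks(B, cfg.gene_map, cfg.gene_sets)
    return [
        _search_direction(B, labels.is_case, cfg, d, item_masks)
        for d in cfg.directions
    ]


# ---------------------------------------------------------------------------
# jump from survivor tables
# ---------------------------------------------------------------------------

def _item_chi2(B: BinaryItemMatrix, labels: PhenotypeVector) -> np.ndarray:
    """chi-square of every single item under the given labels."""
    a = B.bits[labels.is_case].sum(axis=0, dtype=np.int64)
    b = B.bits[~labels.is_case].sum(axis=0, dtype=np.int64)
    return chi2_df1_counts(a, b, labels.n_case, labels.n_ctrl)


def _jumps_for_direction(
    dres: _DirectionResult,
    chi2_by_size: dict[int, np.ndarray],
    item_chi2: np.ndarray,
) -> dict[int, np.ndarray]:
    """Jump of every survivor, using the fact that all size>=2 proper
    subsets of a survivor are themselves survivors in the same direction."""
    lookup: dict[tuple, float] = {}
    for k, arr in dres.items.items():
        cs = chi2_by_size[k]
        for row, c in zip(arr, cs):
            lookup[tuple(row)] = c
    out: dict[int, np.ndarray] = {}
    for k, arr in dres.items.items():
        own = chi2_by_size[k]
        if k == 2:
            best = np.maximum(item_chi2[arr[:, 0]], item_chi2[arr[:, 1]])
        else:
            best = np.empty(len(arr))
            for i, row in enumerate(arr):
                b = max(item_chi2[j] for j in row)
                for sz in range(2, k):
                    for combo in itertools.combinations(row, sz):
                        b = max(b, lookup[combo])
                best[i] = b
        out[k] = own - best
    return out


# ---------------------------------------------------------------------------
# public mining API
# ---------------------------------------------------------------------------

def _dataset_digest(B: BinaryItemMatrix, labels: PhenotypeVector) -> str:
    h = hashlib.sha256()
    h.update(np.packbits(B.bits).tobytes())
    h.update(labels.is_case.tobytes())
    h.update("\n".join(B.snp_ids).encode())
    return h.hexdigest()[:16]


def mine(
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    cfg: MiningConfig,
) -> MiningResult:
    """Return exactly the patterns of size in [min_size_report, max_size]
    whose SupMaxPair meets the threshold, per configured direction, with
    full statistics, in deterministic (direction, size, item) order."""
    dir_results = _search_all(B, labels, cfg)
    item_chi2 = _item_chi2(B, labels)
    patterns: list[tuple[Pattern, PatternStats]] = []
    level_logs = {}
    for dres in dir_results:
        level_logs[dres.direction] = dres.level_log
        n_case = labels.n_case
        n_ctrl = labels.n_ctrl
        chi2_by_size: dict[int, np.ndarray] = {}
        for k in sorted(dres.items):
            a = dres.enr[k] if dres.direction == CASE_ENRICHED else dres.oth[k]
            b = dres.oth[k] if dres.direction == CASE_ENRICHED else dres.enr[k]
            chi2_by_size[k] = chi2_df1_counts(a, b, n_case, n_ctrl)
        jumps = _jumps_for_direction(dres, chi2_by_size, item_chi2)
        for k in sorted(dres.items):
            if k < cfg.min_size_report:
                continue
            a = dres.enr[k] if dres.direction == CASE_ENRICHED else dres.oth[k]
            b = dres.oth[k] if dres.direction == CASE_ENRICHED else dres.enr[k]
            chi2 = chi2_by_size[k]
            p_chi2 = sps.chi2.sf(chi2, df=1)
            orr, hald = odds_ratio_counts(a, b, n_case, n_ctrl)
            fish = fisher_two_sided_counts(a, b, n_case, n_ctrl)
            smp = dres.supmaxpair(k)
            for i, row in enumerate(dres.items[k]):
                pat = Pattern(tuple(B.item_label(j) for j in row))
                stats = PatternStats(
                    supp_case=a[i] / n_case,
                    supp_ctrl=b[i] / n_ctrl,
                    supmaxpair=float(smp[i]),
                    chi2=float(chi2[i]),
                    p_chi2=float(p_chi2[i]),
                    odds_ratio=float(orr[i]),
                    odds_ratio_haldane=bool(hald[i]),
                    fisher_p=float(fish[i]),
                    jump=float(jumps[k][i]),
                    direction=dres.direction,
                )
                patterns.append((pat, stats))
    provenance = {
        "config_digest": cfg.digest(),
        "dataset_digest": _dataset_digest(B, labels),
        "threshold": cfg.threshold,
        "max_size": cfg.max_size,
        "directions": list(cfg.directions),
        "level_log": level_logs,
    }
    for d, log in level_logs.items():
        for entry in log:
            logger.info(
                "%s size-%d: %d candidates, %d survivors",
                d, entry["size"], entry["candidates"], entry["survivors"],
            )
    return MiningResult(patterns, provenance)


def brute_force_mine(
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    cfg: MiningConfig,
) -> MiningResult:
    """Exhaustive enumeration of every genotype combination up to max_size.

    Deliberately independent of the Apriori machinery (no pruning, no
    incremental bitsets): it enumerates SNP subsets and genotype assignments
    directly and evaluates SupMaxPair from scratch.  Guarded to <= 20 SNPs.
    """
    n_snps = len(B.snp_ids)
    if n_snps > 20:
        raise ValueError("brute_force_mine is guarded to at most 20 SNPs")
    is_case = labels.is_case
    bits = B.bits
    n_items = B.n_items
    # all-pairs presence counts in each class, for the SupMaxPair pair term
    f = bits.astype(np.float32)
    co_case = np.rint(f[is_case].T @ f[is_case]).astype(np.int64)
    co_ctrl = np.rint(f[~is_case].T @ f[~is_case]).astype(np.int64)
    co = {CASE_ENRICHED: co_ctrl, CONTROL_ENRICHED: co_case}
    n_enr = {CASE_ENRICHED: labels.n_case, CONTROL_ENRICHED: labels.n_ctrl}
    n_oth = {CASE_ENRICHED: labels.n_ctrl, CONTROL_ENRICHED: labels.n_case}
    enr_mask = {CASE_ENRICHED: is_case, CONTROL_ENRICHED: ~is_case}

    gm, gs = cfg.gene_map, cfg.gene_sets
    patterns: list[tuple[Pattern, PatternStats]] = []
    from .pattern_stats import compute_stats  # local import to avoid cycle noise

    for k in range(max(2, cfg.min_size_report), cfg.max_size + 1):
        for snps in itertools.combinations(range(n_snps), k):
            for offs in itertools.product(range(3), repeat=k):
                cols = [3 * s + o for s, o in zip(snps, offs)]
                pat = Pattern(tuple(B.item_label(c) for c in cols))
                if gm is not None and not apply_geneset_constraint([pat], gm, gs):
                    continue
                pres = bits[:, cols].all(axis=1)
                for d in cfg.directions:
                    cnt = int(pres[enr_mask[d]].sum())
                    mx = max(
                        int(co[d][cols[i], cols[j]])
                        for i in range(k)
                        for j in range(i + 1, k)
                    )
                    if _qualifies(cnt, mx, n_enr[d], n_oth[d], cfg.threshold):
                        patterns.append((pat, compute_stats(pat, B, labels, d)))
    return MiningResult(patterns, {"oracle": "brute_force"})


def jump_filter(
    result: MiningResult,
    jump_min: float,
    B: BinaryItemMatrix | None = None,
    labels: PhenotypeVector | None = None,
) -> MiningResult:
    """Keep patterns whose jump is at least ``jump_min``.

    Jump is taken from the per-pattern statistics computed during mining; if
    absent (NaN), it is recomputed exhaustively from ``B`` and ``labels``.
    Idempotent and order-independent.
    """
    from .pattern_stats import jump as exhaustive_jump

    kept = []
    for pat, stats in result.patterns:
        j = stats.jump
        if math.isnan(j):
            if B is None or labels is None:
                raise ValueError("jump not available; pass B and labels")
            j = exhaustive_jump(pat, B, labels)
            stats = replace(stats, jump=j)
        if j >= jump_min:
            kept.append((pat, stats))
    prov = dict(result.provenance)
    prov["jump_min"] = jump_min
    return MiningResult(kept, prov)


# ---------------------------------------------------------------------------
# result table I/O
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "pattern", "size", "direction", "supp_case", "supp_ctrl", "supmaxpair",
    "chi2", "p_chi2", "odds_ratio", "odds_ratio_haldane", "fisher_p", "jump",
]


def result_table(result: MiningResult, fdr=None, fdr_upper=None):
    """Mining result as a pandas DataFrame (optionally with FDR columns)."""
    import pandas as pd

    rows = []
    for pat, s in result.patterns:
        rows.append(
            (str(pat), pat.size, s.direction, s.supp_case, s.supp_ctrl,
             s.supmaxpair, s.chi2, s.p_chi2, s.odds_ratio,
             s.odds_ratio_haldane, s.fisher_p, s.jump)
        )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if fdr is not None:
        df["fdr"] = fdr
        df["fdr_upper_bound"] = fdr_upper
    return df


def read_result(path) -> MiningResult:
    """Read a pattern table written by :func:`write_result`."""
    import pandas as pd

    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].rstrip("\n").partition(": ")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    patterns = []
    for row in df.itertuples(index=False):
        pat = Pattern.parse(row.pattern)
        stats = PatternStats(
            supp_case=row.supp_case,
            supp_ctrl=row.supp_ctrl,
            supmaxpair=row.supmaxpair,
            chi2=row.chi2,
            p_chi2=row.p_chi2,
            odds_ratio=row.odds_ratio,
            odds_ratio_haldane=bool(row.odds_ratio_haldane),
            fisher_p=row.fisher_p,
            jump=row.jump,
            direction=row.direction,
        )
        patterns.append((pat, stats))
    return MiningResult(patterns, dict(meta))


def write_result(result: MiningResult, path, fdr=None, fdr_upper=None,
                 header_meta: dict | None = None) -> None:
    df = result_table(result, fdr=fdr, fdr_upper=fdr_upper)
    with open(path, "w") as fh:
        meta = dict(header_meta or {})
        for key in ("config_digest", "dataset_digest"):
            if key in result.provenance:
                meta.setdefault(key, result.provenance[key])
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)
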