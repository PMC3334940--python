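"""Functional coherence of jump groups against a degree-preserving null.

Patterns are split by their jump statistic into a negative, a middle and a
positive group.  Each pattern contributes all unordered gene pairs among
the genes its SNPs map to; pairs are deduplicated within a group.  A
group's coherence is summarised by the fraction of its pairs whose
similarity in a weighted gene-pair network exceeds a binarization cutoff
(default 0.5), and groups are compared with each other and with a null of
randomly rewired pair sets that preserve each gene's occurrence count
(degree-preserving rewiring), using two-sided rank-sum tests with the
normal approximation and tie correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import DataError, GeneMap
from .miner import MiningResult
from .pattern_stats import Pattern

GenePair = frozenset  # frozenset of two gene symbols


@dataclass
class FunctionalNetwork:
    """Symmetric gene-pair similarity weights in [0, 1].

    Pairs absent from the network have similarity 0.  ``cutoff`` is the
    binarization threshold used for the "fraction functionally linked"
    summary.
    """

    weights: dict[GenePair, float]
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        for pair, w in self.weights.items():
            if len(pair) != 2:
                raise DataError("network contains a self-pair")
            if not 0.0 <= w <= 1.0:
                raise DataError(f"similarity {w} outside [0, 1]")

    def similarity(self, g1: str, g2: str) -> float:
        return self.weights.get(frozenset((g1, g2)), 0.0)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for pair in self.weights:
            out |= set(pair)
        return out


def read_network(path, cutoff: float = 0.5) -> FunctionalNetwork:
    """Read a weighted edge list TSV: geneA, geneB, weight in [0, 1]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#", header=None)
    if df.iloc[0, 0] in ("geneA", "gene_a", "gene1"):
        df = df.iloc[1:]
    weights: dict[GenePair, float] = {}
    for g1, g2, w in df.itertuples(index=False):
        if g1 == g2:
            continue
        weights[frozenset((g1, g2))] = float(w)
    return FunctionalNetwork(weights, cutoff=cutoff)


def write_network(net: FunctionalNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tweight\n")
        for pair in sorted(net.weights, key=sorted):
            g1, g2 = sorted(pair)
            fh.write(f"{g1}\t{g2}\t{net.weights[pair]:.6g}\n")


def group_by_jump(
    result, low: float = -5.0, high: float = 5.0
) -> dict[str, list]:
    """Partition patterns into jump groups: neg (jump <= low), mid
    (low < jump < high), pos (jump >= high).  Accepts a MiningResult or an
    FdrAnnotatedResult."""
    if low >= high:
        raise ValueError("need low < high")
    patterns = result.patterns if hasattr(result, "patterns") else list(result)
    groups: dict[str, list] = {"neg": [], "mid": [], "pos": []}
    for pat, stats in patterns:
        if stats.jump <= low:
            groups["neg"].append((pat, stats))
        elif stats.jump >= high:
            groups["pos"].append((pat, stats))
        else:
            groups["mid"].append((pat, stats))
    return groups


def within_pattern_pairs(
    group: list, gene_map: GeneMap
) -> set[GenePair]:
    """Unique unordered within-pattern gene pairs across a pattern group.

    SNPs without a gene assignment are skipped (with a warning); pairs of
    SNPs mapping to the same gene produce no pair.
    """
    pairs: set[GenePair] = set()
    missing: set[str] = set()
    for entry in group:
        pat: Pattern = entry[0] if isinstance(entry, tuple) else entry
        genes = []
        for snp, _ in pat.items:
            g = gene_map.gene(snp)
            if g is None:
                missing.add(snp)
            else:
                genes.append(g)
        for g1, g2 in itertools.combinations(sorted(set(genes)), 2):
            pairs.add(frozenset((g1, g2)))
    if missing:
        warnings.warn(
            f"{len(missing)} SNPs without gene assignment were skipped"
        )
    return pairs


def coherence_null(
    pairs: set[GenePair],
    universe=None,
    n_rep: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[set[GenePair]]:
    """Degree-preserving random rewirings of a gene-pair set.

    Each replicate has the same number of pairs and preserves every gene's
    occurrence count, via random double-edge swaps on the pair graph
    (self-pairs and duplicate pairs are never produced).  ``universe`` is
    accepted for interface symmetry; rewiring keeps the original genes by
    construction.  With fewer than two pairs the pair set is its own only
    degree-preserving configuration and is returned unchanged.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    g0 = nx.Graph()
    # sorted insertion keeps replicates independent of set iteration order
    g0.add_edges_from(sorted(tuple(sorted(p)) for p in pairs))
    m = g0.number_of_edges()
    replicates: list[set[GenePair]] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_rep):
        g = g0.copy()
        if m >= 2:
            try:
                nx.double_edge_swap(
                    g,
                    nswap=swaps_per_edge * m,
                    max_tries=100 * swaps_per_edge * m,
                    seed=int(rng.integers(2**31)),
                )
            except nx.NetworkXAlgorithmError as e:
                raise RuntimeError(
                    "degree-preserving rewiring did not converge within the "
                    "retry budget"
                ) from e
        replicates.append({frozenset(e) for e in g.edges()})
    return replicates


@dataclass
class CoherenceReport:
    """Per-jump-group coherence summary and rank-sum comparisons."""

    cutoff: float
    n_pairs: dict[str, int]
    fraction_above: dict[str, float]
    similarities: dict[str, np.ndarray]
    null_similarities: dict[str, np.ndarray]
    fraction_above_null: dict[str, float]
    group_vs_group_p: dict[tuple[str, str], float]
    group_vs_null_p: dict[str, float]
    notices: list[str] = field(default_factory=list)
    sidedness: str = "two-sided"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.n_pairs:
            rows.append(
                {
                    "group": g,
                    "n_pairs": self.n_pairs[g],
                    "fraction_above_cutoff": self.fraction_above.get(g, np.nan),
                    "null_fraction_above_cutoff": self.fraction_above_null.get(
                        g, np.nan
                    ),
                    "p_vs_null": self.group_vs_null_p.get(g, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value, normal approximation with tie correction."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_groups(
    groups: dict[str, list],
    gene_map: GeneMap,
    network: FunctionalNetwork,
    n_null: int = 100,
    seed: int = 0,
) -> CoherenceReport:
    """Coherence report over jump groups.

    For each group: fraction of unique within-pattern gene pairs with
    similarity above the network cutoff, rank-sum comparisons against every
    other group and against that group's pooled degree-preserving null.
    Groups with fewer than two pairs are summarised but excluded from the
    statistical comparisons (a notice is recorded).
    """
    cutoff = network.cutoff
    sims: dict[str, np.ndarray] = {}
    null_sims: dict[str, np.ndarray] = {}
    n_pairs: dict[str, int] = {}
    frac: dict[str, float] = {}
    frac_null: dict[str, float] = {}
    notices: list[str] = []
    rng = np.random.default_rng(seed)
    for name, group in groups.items():
        pairs = sorted(within_pattern_pairs(group, gene_map), key=sorted)
        n_pairs[name] = len(pairs)
        s = np.array([network.similarity(*sorted(p)) for p in pairs])
        sims[name] = s
        if len(pairs) == 0:
            continue
        frac[name] = float((s > cutoff).mean())
        reps = coherence_null(
            set(pairs), n_rep=n_null, seed=int(rng.integers(2**31))
        )
        ns = np.array(
            [network.similarity(*sorted(p))
             for rep in reps for p in sorted(rep, key=sorted)]
        )
        null_sims[name] = ns
        frac_null[name] = float((ns > cutoff).mean()) if len(ns) else np.nan
    gvg: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        if n_pairs.get(a, 0) < 2 or n_pairs.get(b, 0) < 2:
            notices.append(f"comparison {a} vs {b} skipped (fewer than 2 pairs)")
            continue
        gvg[(a, b)] = _ranksum_p(sims[a], sims[b])
    gvn: dict[str, float] = {}
    for name in groups:
        if n_pairs.get(name, 0) < 2:
            notices.append(f"comparison {name} vs null skipped (fewer than 2 pairs)")
            continue
        gvn[name] = _ranksum_p(sims[name], null_sims[name])
    return CoherenceReport(
        cutoff=cutoff,
        n_pairs=n_pairs,
        fraction_above=frac,
        similarities=sims,
        null_similarities=null_sims,
        fraction_above_null=frac_null,
        group_vs_group_p=gvg,
        group_vs_null_p=gvn,
        notices=notices,
    )
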