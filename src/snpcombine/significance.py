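"""Size-specific permutation-based false-discovery-rate estimation.

Each permutation shuffles the case/control assignment (preserving the
case:control ratio) and reruns the *entire* mining pipeline — same
SupMaxPair threshold, same maximum size, same gene-set constraints, same
jump filter — so that the null patterns are subject to exactly the
selection the real patterns went through.  The chi-square statistics of
null patterns are pooled within each pattern size; for a real size-k
pattern with statistic c,

    FDR = n / (n_perm * m)

where m is the number of real size-k patterns with statistic >= c (at
least 1: the pattern counts itself) and n the number of pooled null size-k
patterns with statistic >= c.  When n = 0 the FDR is reported as 0 with
the upper bound 1 / (n_perm * m): with 500 permutations and m = 1 this is
the "< 0.002" certificate a pattern earns when no permutation ever
produced an equally strong same-size pattern.

FDRs are deliberately stratified by size — larger combinations are ever
harder to discover, and pooling sizes would drown them in the plentiful
small null patterns.  No second-stage correction across sizes is applied;
see the methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import BinaryItemMatrix, PhenotypeVector
from .miner import (
    MiningConfig,
    MiningResult,
    _item_chi2,
    _jumps_for_direction,
    _search_all,
)
from .pattern_stats import CASE_ENRICHED, chi2_df1_counts


@dataclass
class NullDistribution:
    """Pooled null chi-square statistics per pattern size."""

    by_size: dict[int, np.ndarray]
    n_perm: int
    config_digest: str

    def exceedances(self, size: int, c: float) -> int:
        arr = self.by_size.get(size)
        if arr is None or len(arr) == 0:
            return 0
        return int((arr >= c).sum())


@dataclass
class FdrAnnotatedResult:
    """Mining result with per-pattern size-specific FDR annotations.

    ``fdr[i]`` and ``fdr_upper_bound[i]`` align with ``result.patterns[i]``;
    the upper bound equals the FDR except in the zero-exceedance case, where
    the FDR is 0 and the bound is 1 / (n_perm * m).
    """

    result: MiningResult
    fdr: np.ndarray
    fdr_upper_bound: np.ndarray
    null: NullDistribution

    def __len__(self) -> int:
        return len(self.result)

    @property
    def patterns(self):
        return self.result.patterns


def permute_labels(labels: PhenotypeVector, seed) -> PhenotypeVector:
    """Uniformly random reassignment of case/control labels preserving the
    case count.  ``seed`` may be an int or a numpy Generator."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(labels.sample_ids))
    return PhenotypeVector(list(labels.sample_ids), labels.is_case[perm])


def _pipeline_chi2_by_size(
    B: BinaryItemMatrix, labels: PhenotypeVector, cfg: MiningConfig
) -> dict[int, np.ndarray]:
    """chi-square statistics, per size, of every pattern surviving the full
    configured pipeline (mining and, if set, the jump filter) — without
    materialising Pattern objects.  This is the fast path permutation runs
    use; it is asserted against ``mine`` in the test suite."""
    dir_results = _search_all(B, labels, cfg)
    need_jump = cfg.jump_min is not None
    item_chi2 = _item_chi2(B, labels) if need_jump else None
    out: dict[int, list[np.ndarray]] = {}
    for dres in dir_results:
        chi2_by_size: dict[int, np.ndarray] = {}
        for k in sorted(dres.items):
            a = dres.enr[k] if dres.direction == CASE_ENRICHED else dres.oth[k]
            b = dres.oth[k] if dres.direction == CASE_ENRICHED else dres.enr[k]
            chi2_by_size[k] = chi2_df1_counts(a, b, labels.n_case, labels.n_ctrl)
        if need_jump:
            jumps = _jumps_for_direction(dres, chi2_by_size, item_chi2)
        for k, chi2 in chi2_by_size.items():
            if k < cfg.min_size_report:
                continue
            vals = chi2[jumps[k] >= cfg.jump_min] if need_jump else chi2
            out.setdefault(k, []).append(vals)
    return {k: np.concatenate(v) for k, v in out.items()}


def build_null_distribution(
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    cfg: MiningConfig,
    n_perm: int,
    seed: int,
) -> NullDistribution:
    """Pool per-size chi-square statistics over ``n_perm`` label
    permutations, each mined with the identical configuration.

    Per-permutation seeds are spawned from the master seed by permutation
    index, so permutation i is reproducible in isolation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    master = np.random.SeedSequence(seed)
    pooled: dict[int, list[np.ndarray]] = {}
    for child in master.spawn(n_perm):
        rng = np.random.default_rng(child)
        plabels = permute_labels(labels, rng)
        for k, vals in _pipeline_chi2_by_size(B, plabels, cfg).items():
            pooled.setdefault(k, []).append(vals)
    by_size = {k: np.sort(np.concatenate(v)) for k, v in pooled.items()}
    return NullDistribution(by_size, n_perm, cfg.digest())


def annotate_fdr(real: MiningResult, null: NullDistribution) -> FdrAnnotatedResult:
    """Attach size-specific FDRs to an existing mining result."""
    sizes = np.array([p.size for p, _ in real.patterns])
    chi2 = np.array([s.chi2 for _, s in real.patterns])
    fdr = np.zeros(len(real.patterns))
    upper = np.zeros(len(real.patterns))
    n_perm = null.n_perm
    for k in np.unique(sizes):
        sel = sizes == k
        real_k = np.sort(chi2[sel])
        null_k = null.by_size.get(int(k), np.empty(0))
        for i in np.flatnonzero(sel):
            c = chi2[i]
            m = len(real_k) - np.searchsorted(real_k, c, side="left")
            n = len(null_k) - np.searchsorted(null_k, c, side="left")
            if n == 0:
                fdr[i] = 0.0
                upper[i] = 1.0 / (n_perm * m)
            else:
                fdr[i] = n / (n_perm * m)
                upper[i] = fdr[i]
    return FdrAnnotatedResult(real, fdr, upper, null)


def estimate_fdr(
    real: MiningResult,
    B: BinaryItemMatrix,
    labels: PhenotypeVector,
    cfg: MiningConfig,
    n_perm: int = 100,
    seed: int = 0,
) -> FdrAnnotatedResult:
    """Size-specific permutation FDR for a mined (and jump-filtered) result.

    ``real`` must have been produced under ``cfg`` (checked via the config
    digest recorded in its provenance, when present).
    """
    digest = real.provenance.get("config_digest")
    if digest is not None and digest != cfg.digest():
        raise ValueError(
            "mining result was produced under a different configuration; "
            "permutation runs must replicate the real run's setup exactly"
        )
    null = build_null_distribution(B, labels, cfg, n_perm, seed)
    return annotate_fdr(real, null)
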