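"""Gene-set enrichment with phenotype permutation.

Genes are ranked by a class-contrast metric (signal-to-noise ratio or
Welch t) and each gene set is scored by the weighted Kolmogorov-Smirnov
running-sum enrichment score (ES).  Significance is assessed by permuting
the sample labels, with an add-one empirical two-sided p-value and
Benjamini-Hochberg FDR across sets.  Sets significant under BOTH ranking
metrics are called significant; for paired expression/methylation designs
the per-datatype significant lists are unioned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, OmicsMatrix

logger = logging.getLogger(__name__)

#: minimum member genes (after intersection with the matrix) for a set to be scored
MIN_SET_SIZE = 5

_SD_ABS_FLOOR = 1e-8


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment outcome for one ranking metric."""

    pathway: str
    es: float
    p: float
    q: float
    metric: str

    @property
    def direction(self) -> int:
        return 1 if self.es >= 0 else -1


def _floored_sd(values: np.ndarray, axis=-1) -> np.ndarray:
    """Sample sd floored at max(sd, 0.2*|mean|, 1e-8), the usual SNR guard."""
    sd = values.std(axis=axis, ddof=1)
    mu = values.mean(axis=axis)
    return np.maximum(np.maximum(sd, 0.2 * np.abs(mu)), _SD_ABS_FLOOR)


def snr_score(case_values, control_values) -> float:
    """Signal-to-noise ratio (mu_case - mu_ctrl) / (sd_case + sd_ctrl)."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 values")
    return float((a.mean() - b.mean()) / (_floored_sd(a) + _floored_sd(b)))


def tstat_score(case_values, control_values) -> float:
    """Welch two-sample t statistic (case minus control)."""
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >=2 values")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0:
        return 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
    return float((a.mean() - b.mean()) / math.sqrt(se2))


def _metric_rows(values: np.ndarray, is_case: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized per-row class-contrast metric over a genes x samples array."""
    a = values[:, is_case]
    b = values[:, ~is_case]
    if metric == "snr":
        return (a.mean(axis=1) - b.mean(axis=1)) / (_floored_sd(a) + _floored_sd(b))
    if metric == "tstat":
        se2 = a.var(axis=1, ddof=1) / a.shape[1] + b.var(axis=1, ddof=1) / b.shape[1]
        se2 = np.maximum(se2, 1e-300)
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(se2)
    raise ValueError(f"unknown metric {metric!r}")


def gsea_enrichment_score(ranked_genes, metric_values, gene_set,
                          weight_exponent: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score.

    ``ranked_genes`` must be ordered by decreasing metric; hits step up by
    ``|metric|**weight_exponent`` normalized by the total hit weight, misses
    step down by ``1/(N - N_hit)``.  The ES is the running-sum value with
    the largest absolute deviation from zero, keeping its sign.
    """
    genes = list(ranked_genes)
    r = np.asarray(metric_values, dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(r) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member metrics zero: fall back to equal hit weights
        hit_w = hit.astype(float)
        total = float(n_hit)
    step = hit_w / total - (~hit).astype(float) / (len(genes) - n_hit)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_all_sets(metric: np.ndarray, membership: np.ndarray,
                 weight_exponent: float) -> np.ndarray:
    """ES for every set (rows of ``membership``, genes in matrix order)."""
    order = np.argsort(-metric, kind="stable")
    r = metric[order]
    hit = membership[:, order]
    w = np.abs(r) ** weight_exponent
    hit_w = hit * w
    totals = hit_w.sum(axis=1, keepdims=True)
    # degenerate all-zero weights: equal hit weights
    flat = totals[:, 0] == 0
    if flat.any():
        hit_w[flat] = hit[flat].astype(float)
        totals[flat, 0] = hit[flat].sum(axis=1)
    n = metric.size
    n_hit = hit.sum(axis=1, keepdims=True)
    step = hit_w / totals - (~hit) / (n - n_hit)
    running = np.cumsum(step, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), idx]


def permutation_enrichment(matrix: OmicsMatrix, gene_sets: GeneSetCollection,
                           metric: str = "snr", n_perm: int = 1000,
                           seed: int = 0, weight_exponent: float = 1.0,
                           min_set_size: int = MIN_SET_SIZE) -> list[EnrichmentResult]:
    """Score every gene set against phenotype-permutation nulls.

    Two-sided empirical p uses the add-one estimator
    ``(1 + #{|ES_perm| >= |ES_obs|}) / (1 + n_perm)``; q-values are
    Benjamini-Hochberg across sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    restricted = gene_sets.restrict(matrix.genes, min_size=min_set_size)
    if len(restricted) == 0:
        logger.warning("no gene set of size >= %d overlaps the matrix", min_set_size)
        return []
    values = matrix.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    pids = sorted(restricted.sets)
    membership = np.zeros((len(pids), values.shape[0]), dtype=bool)
    for k, pid in enumerate(pids):
        membership[k, [gene_index[g] for g in restricted.sets[pid]]] = True
    if membership.all(axis=1).any():
        raise ValueError("a gene set covers every gene in the matrix")

    is_case = matrix.label_vector()
    n_case = int(is_case.sum())
    n_samples = is_case.size
    n_distinct = math.comb(n_samples, n_case) - 1  # excluding the observed one
    rng = np.random.default_rng(seed)

    obs = _es_all_sets(_metric_rows(values, is_case, metric), membership,
                       weight_exponent)

    if n_distinct < n_perm:
        logger.warning(
            "only %d distinct label permutations exist; using all of them "
            "instead of %d", n_distinct, n_perm,
        )
        from itertools import combinations

        observed = frozenset(np.flatnonzero(is_case).tolist())
        perms = [c for c in combinations(range(n_samples), n_case)
                 if frozenset(c) != observed]
    else:
        perms = [tuple(rng.choice(n_samples, size=n_case, replace=False))
                 for _ in range(n_perm)]

    exceed = np.zeros(len(pids), dtype=int)
    perm_case = np.zeros(n_samples, dtype=bool)
    for c in perms:
        perm_case[:] = False
        perm_case[list(c)] = True
        es_p = _es_all_sets(_metric_rows(values, perm_case, metric), membership,
                            weight_exponent)
        exceed += np.abs(es_p) >= np.abs(obs)
    n_used = len(perms)
    p = (1 + exceed) / (1 + n_used)
    q = multipletests(p, method="fdr_bh")[1]
    return [EnrichmentResult(pid, float(obs[k]), float(p[k]), float(q[k]), metric)
            for k, pid in enumerate(pids)]


def select_significant_pathways(res_snr: list[EnrichmentResult],
                                res_t: list[EnrichmentResult],
                                q_threshold: float = 0.05) -> list[str]:
    """Pathways with FDR q below threshold under BOTH ranking metrics,
    sorted by the larger of the two q-values (most significant first)."""
    q_snr = {r.pathway: r.q for r in res_snr}
    q_t = {r.pathway: r.q for r in res_t}
    common = [p for p in q_snr if p in q_t
              and q_snr[p] < q_threshold and q_t[p] < q_threshold]
    if not common:
        logger.info("no pathway significant under both metrics at q<%g", q_threshold)
    return sorted(common, key=lambda p: (max(q_snr[p], q_t[p]), p))


def union_across_datatypes(expr_sig, meth_sig) -> list[str]:
    """Deduplicated union of two significant-pathway lists, sorted."""
    return sorted(set(expr_sig) | set(meth_sig))
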