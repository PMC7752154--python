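"""Preranked gene-set enrichment of signature-stratified patient groups.

Genes are ranked by a between-group differential metric (mean difference of
normalized expression by default, signal-to-noise optionally), then each gene
set is scored with the weighted Kolmogorov-Smirnov running-sum enrichment
score (weight exponent 1 on |metric|): walking the ranked list, member genes
add |metric|/sum(member |metric|) and non-members subtract 1/(N - m), so the
running sum starts and ends at zero and the ES is its signed extremum.

Significance comes from gene-label permutation — the set's genes are redrawn
uniformly from the ranked list — which stays valid at the small cohort sizes
typical of ICB trials where phenotype permutation runs out of distinct
relabellings. The two-sided permutation p is (1 + #{|ES_perm| >= |ES|}) /
(n_perm + 1); BH adjustment runs across sets, with adjusted p < 0.10 the
conventional reporting threshold for this analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .cohort import GROUP_COLUMN, StratifiedCohort
from .exceptions import ConfigurationError
from .ranking import GeneSetCollection, bh_adjust

logger = logging.getLogger(__name__)


def rank_genes(
    bulk: ad.AnnData,
    strat: StratifiedCohort,
    method: str = "diff",
) -> pd.Series:
    """Rank genes by differential expression between high and low groups.

    ``method='diff'`` uses the difference of group means; ``'s2n'`` the
    signal-to-noise ratio with GSEA's floor on the group standard deviations.
    Requires >= 2 patients per group. Genes with zero variance and equal
    means in both groups get metric 0 (logged). Returns a Series sorted
    descending with ties broken by gene id, so the order is total.
    """
    t = strat.table.set_index("patient_id")
    shared = pd.Index(t.index).intersection(bulk.obs_names)
    if len(shared) < len(t):
        logger.info("rank_genes: %d cohort patients absent from bulk matrix",
                    len(t) - len(shared))
    groups = t.loc[shared, GROUP_COLUMN]
    hi_ids = groups.index[groups == "high"]
    lo_ids = groups.index[groups == "low"]
    if len(hi_ids) < 2 or len(lo_ids) < 2:
        raise ConfigurationError("both groups need >= 2 patients with expression")

    X = pd.DataFrame(np.asarray(bulk.X, dtype=float), index=bulk.obs_names,
                     columns=bulk.var_names)
    hi, lo = X.loc[hi_ids], X.loc[lo_ids]
    m1, m2 = hi.mean(axis=0), lo.mean(axis=0)
    if method == "diff":
        metric = m1 - m2
    elif method == "s2n":
        s1 = np.maximum(hi.std(axis=0, ddof=1), 0.2 * np.abs(m1))
        s2 = np.maximum(lo.std(axis=0, ddof=1), 0.2 * np.abs(m2))
        denom = s1 + s2
        zero = denom == 0
        if zero.any():
            logger.info("rank_genes: %d zero-variance genes set to 0", int(zero.sum()))
        metric = (m1 - m2).where(~zero, 0.0) / denom.replace(0.0, 1.0)
    else:
        raise ConfigurationError(f"unknown ranking method {method!r}")

    order = sorted(metric.index, key=lambda g: (-metric[g], g))
    return metric.loc[order].astype(float)


def enrichment_score(metric: np.ndarray, member_mask: np.ndarray,
                     weight: float = 1.0) -> tuple[float, int]:
    """Weighted KS running-sum ES for one set on a ranked metric vector.

    Returns ``(es, extremum_position)``. Member steps are |metric|^weight
    normalized to sum 1; non-member steps are -1/(N-m). If every member
    metric is zero, members fall back to equal steps 1/m.
    """
    n = len(metric)
    m = int(member_mask.sum())
    if m == 0 or m == n:
        raise ConfigurationError("set must hit neither none nor all ranked genes")
    w = np.abs(metric) ** weight
    hit = np.where(member_mask, w, 0.0)
    total = hit.sum()
    if total == 0:
        hit = member_mask / m
    else:
        hit = hit / total
    steps = hit - (~member_mask) / (n - m)
    running = np.cumsum(steps)
    imax, imin = int(np.argmax(running)), int(np.argmin(running))
    # signed extremum; ties in magnitude (within fp tolerance) go positive
    if running[imax] >= abs(running[imin]) - 1e-12:
        return float(running[imax]), imax
    return float(running[imin]), imin


@dataclass
class EnrichmentResult:
    """One gene set's preranked GSEA outcome."""

    set_name: str
    es: float
    nes: float
    p: float
    size: int
    leading_edge: list[str] = field(default_factory=list)
    p_adj: float = float("nan")


def gsea_preranked(
    ranked: pd.Series,
    gsc: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 3,
) -> list[EnrichmentResult]:
    """Score every gene set against a ranked list with a permutation null.

    Sets intersecting the list in fewer than ``min_size`` genes are skipped
    (logged). The null redraws each set's positions uniformly without
    replacement, seeded; NES is ES over the mean |permutation ES|. BH runs
    across the returned sets.
    """
    if n_perm <= 0:
        raise ConfigurationError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation p")
    metric = ranked.values.astype(float)
    genes = np.asarray(ranked.index)
    n = len(genes)
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    for name, members in gsc.sets.items():
        mask = np.isin(genes, list(members))
        m = int(mask.sum())
        if m < min_size or n - m < 1:
            logger.info("gsea: skipping %s (%d genes in list)", name, m)
            continue
        es, pos = enrichment_score(metric, mask, weight)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=m, replace=False)] = True
            perm_es[b], _ = enrichment_score(metric, pmask, weight)
        p = (1.0 + float((np.abs(perm_es) >= abs(es)).sum())) / (n_perm + 1.0)
        denom = float(np.abs(perm_es).mean())
        nes = es / denom if denom > 0 else float("nan")

        if es >= 0:
            lead = genes[: pos + 1][mask[: pos + 1]]
        else:
            lead = genes[pos:][mask[pos:]]
        results.append(EnrichmentResult(set_name=name, es=es, nes=nes, p=p,
                                        size=m, leading_edge=list(lead)))

    adj = bh_adjust(np.array([r.p for r in results]))
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set": r.set_name, "es": r.es, "nes": r.nes, "p": r.p,
        "p_adj": r.p_adj, "size": r.size,
        "leading_edge": ",".join(r.leading_edge),
    } for r in results])
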