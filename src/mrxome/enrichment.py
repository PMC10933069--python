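"""Per-sample set enrichment scoring and two-group enrichment testing.

``ssgsea_score`` implements the single-sample score: genes are rank-ordered
within each sample from largest to smallest expression, and the score is the
integrated difference between a weighted in-set ECDF and the uniform
out-of-set ECDF. ``gsea_two_group`` is the classical two-phenotype
permutation procedure with a signal-to-noise ranking metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .summary_io import ExpressionStudy, GeneSetCollection

if TYPE_CHECKING:  # pragma: no cover
    from .gene_screen import GeneMRTable

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentScores:
    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray  # set x sample
    method: str = "ssgsea"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: self.values[i] for i, name in enumerate(self.set_names)}


@dataclass(frozen=True)
class GroupComparison:
    set_name: str
    median_a: float
    median_b: float
    statistic: float
    pval: float


@dataclass(frozen=True)
class GseaSetResult:
    set_name: str
    es: float
    nes: float
    perm_pval: float


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------


def _sample_orders(study: ExpressionStudy) -> np.ndarray:
    """Per-sample gene orderings, descending by expression.

    Ties are broken by lexicographic gene id so that scoring is deterministic
    even on degenerate (constant) samples. Returns an array of shape
    (n_samples, n_genes) of gene indices, best rank first.
    """
    lex_rank = np.argsort(np.argsort(np.asarray(study.gene_ids, dtype=object)))
    orders = np.empty((len(study.sample_ids), len(study.gene_ids)), dtype=np.intp)
    for j in range(len(study.sample_ids)):
        # lexsort: last key is primary
        orders[j] = np.lexsort((lex_rank, -study.values[:, j]))
    return orders


def _ssgsea_walk(
    in_set_sorted: np.ndarray, rank_weights: np.ndarray
) -> float:
    """Integrated ECDF difference for one sample and one set.

    ``in_set_sorted`` is the boolean in-set indicator along the ranked gene
    list (best first); ``rank_weights`` the rank magnitudes raised to alpha.
    """
    n = in_set_sorted.shape[0]
    n_in = int(in_set_sorted.sum())
    w = np.where(in_set_sorted, rank_weights, 0.0)
    denom_in = w.sum()
    ecdf_in = np.cumsum(w) / denom_in
    n_out = n - n_in
    if n_out == 0:
        return float(np.sum(ecdf_in))
    ecdf_out = np.cumsum(~in_set_sorted) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def ssgsea_score(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    alpha: float = 0.25,
) -> EnrichmentScores:
    """Single-sample enrichment scores for every set, samples independent.

    Rank magnitudes are the rank-normalized positions (n for the top gene,
    1 for the bottom), raised to ``alpha``. Sets with no gene in the study
    are skipped with a warning; genes absent from the study never affect a
    set's score.
    """
    if alpha < 0:
        raise EnrichmentError(f"alpha must be >= 0, got {alpha}")
    n = len(study.gene_ids)
    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    orders = _sample_orders(study)
    rank_weights = (np.arange(n, 0, -1, dtype=float)) ** alpha

    usable: list[str] = []
    indicator_by_set: dict[str, np.ndarray] = {}
    for name, genes in sets.sets.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            logger.warning("set %s has no genes in the study; skipped", name)
            continue
        ind = np.zeros(n, dtype=bool)
        ind[idx] = True
        usable.append(name)
        indicator_by_set[name] = ind

    values = np.empty((len(usable), len(study.sample_ids)))
    for j in range(len(study.sample_ids)):
        order = orders[j]
        for i, name in enumerate(usable):
            values[i, j] = _ssgsea_walk(indicator_by_set[name][order], rank_weights)
    return EnrichmentScores(usable, list(study.sample_ids), values, "ssgsea")


def risk_protective_scores(
    study: ExpressionStudy, gene_table: "GeneMRTable", alpha: float = 0.25
) -> tuple[EnrichmentScores, EnrichmentScores]:
    """ssGSEA score vectors for the risk and the protective gene sets."""
    risk = gene_table.risk_genes()
    protective = gene_table.protective_genes()
    if not risk and not protective:
        raise EnrichmentError("no risk or protective genes in the table")
    present = set(study.gene_ids)
    out: list[EnrichmentScores] = []
    for name, genes in (("risk", risk), ("protective", protective)):
        usable = [g for g in genes if g in present]
        if genes and not usable:
            raise EnrichmentError(
                f"{name} genes absent from the study: {sorted(genes)[:10]}"
            )
        if not usable:
            raise EnrichmentError(f"empty {name} gene list")
        coll = GeneSetCollection({name: usable})
        out.append(ssgsea_score(study, coll, alpha=alpha))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(
    scores: EnrichmentScores,
    study: ExpressionStudy,
    group_a: str = "active",
    group_b: str = "inactive",
) -> list[GroupComparison]:
    """Two-sided Wilcoxon rank-sum comparison of each set's scores.

    Exact null distribution when the smaller group has <=10 samples and
    there are no ties; normal approximation with continuity correction
    otherwise.
    """
    col = {s: j for j, s in enumerate(scores.sample_ids)}
    idx_a = [col[s] for s in study.samples_with(group_a)]
    idx_b = [col[s] for s in study.samples_with(group_b)]
    if not idx_a or not idx_b:
        missing = group_a if not idx_a else group_b
        raise EnrichmentError(f"group {missing!r} has no samples")
    results = []
    for i, name in enumerate(scores.set_names):
        a, b = scores.values[i, idx_a], scores.values[i, idx_b]
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (min(len(a), len(b)) <= 10 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        results.append(
            GroupComparison(
                set_name=name,
                median_a=float(np.median(a)),
                median_b=float(np.median(b)),
                statistic=float(res.statistic),
                pval=float(min(res.pvalue, 1.0)),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Two-group GSEA
# ---------------------------------------------------------------------------


def signal_to_noise(
    values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray
) -> np.ndarray:
    """Per-gene (mean_a - mean_b) / (sd_a + sd_b) with a small sd floor."""
    a, b = values[:, mask_a], values[:, mask_b]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    denom = np.maximum(sa + sb, 1e-8)
    return (ma - mb) / denom


def _gsea_es(metric_order: np.ndarray, metric: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score (weight p=1)."""
    ranked_in = in_set[metric_order]
    ranked_metric = np.abs(metric[metric_order])
    nr = ranked_metric[ranked_in].sum()
    n_out = len(metric) - int(ranked_in.sum())
    if nr == 0 or n_out == 0:
        return 0.0
    hit = np.where(ranked_in, ranked_metric / nr, 0.0)
    miss = np.where(ranked_in, 0.0, 1.0 / n_out)
    running = np.cumsum(hit - miss)
    return float(running[np.argmax(np.abs(running))])


def gsea_two_group(
    study: ExpressionStudy,
    pathway_sets: GeneSetCollection,
    group_a: str = "active",
    group_b: str = "inactive",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaSetResult]:
    """Classical two-phenotype GSEA with sample-label permutation nulls.

    Genes are ranked by signal-to-noise between the groups; the null is
    built by permuting sample labels; NES is the observed ES normalized by
    the mean same-signed permuted ES, and the p-value comes from the
    same-signed permutation tail.
    """
    if n_perm < 100:
        raise EnrichmentError("n_perm must be >= 100")
    labels = np.array([study.phenotype[s] for s in study.sample_ids])
    mask_a, mask_b = labels == group_a, labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise EnrichmentError("each group needs >=2 samples for signal-to-noise")

    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    indicators: dict[str, np.ndarray] = {}
    for name, genes in pathway_sets.sets.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            logger.warning("pathway %s has no genes in the study; skipped", name)
            continue
        ind = np.zeros(len(study.gene_ids), dtype=bool)
        ind[idx] = True
        indicators[name] = ind

    sub = study.values[:, mask_a | mask_b]
    n_a = int(mask_a.sum())
    sub_mask_a = np.concatenate(
        [np.ones(n_a, bool), np.zeros(int(mask_b.sum()), bool)]
    )
    # reorder columns so group A comes first
    cols = np.concatenate([np.flatnonzero(mask_a), np.flatnonzero(mask_b)])
    sub = study.values[:, cols]

    obs_metric = signal_to_noise(sub, sub_mask_a, ~sub_mask_a)
    obs_order = np.argsort(-obs_metric, kind="stable")
    obs_es = {
        name: _gsea_es(obs_order, obs_metric, ind) for name, ind in indicators.items()
    }

    rng = np.random.default_rng(seed)
    n_cols = sub.shape[1]
    perm_es = {name: np.empty(n_perm) for name in indicators}
    for p in range(n_perm):
        perm = rng.permutation(n_cols)
        pm_a = np.zeros(n_cols, bool)
        pm_a[perm[:n_a]] = True
        metric = signal_to_noise(sub, pm_a, ~pm_a)
        order = np.argsort(-metric, kind="stable")
        for name, ind in indicators.items():
            perm_es[name][p] = _gsea_es(order, metric, ind)

    results = []
    for name, es in obs_es.items():
        null = perm_es[name]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0:
            nes, pval = np.sign(es) * np.inf if es != 0 else 0.0, 1.0 / (n_perm + 1)
        else:
            mean_same = np.mean(np.abs(same_sign))
            nes = es / mean_same if mean_same > 0 else 0.0
            pval = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
        results.append(GseaSetResult(name, float(es), float(nes), float(pval)))
    return results
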