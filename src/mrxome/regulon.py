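"""Transcriptional-network layer.

Regulons (a TF's signed target set) are inferred from expression by
mutual information with three pruning stages: permutation significance,
bootstrap stability, and data-processing-inequality (DPI) removal of
indirect edges. Regulon activity is a signed two-arm single-sample
enrichment walk, and regulon-phenotype association is tested with one- or
two-tailed permutation GSEA.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enrichment import _gsea_es, _sample_orders, _ssgsea_walk, signal_to_noise
from .summary_io import ExpressionStudy

logger = logging.getLogger(__name__)


class RegulonError(ValueError):
    pass


@dataclass
class Regulon:
    tf_id: str
    #: gene_id -> (mutual information, sign from Spearman correlation)
    targets: dict[str, tuple[float, int]] = field(default_factory=dict)

    def positive_targets(self) -> list[str]:
        return [g for g, (_, s) in self.targets.items() if s > 0]

    def negative_targets(self) -> list[str]:
        return [g for g, (_, s) in self.targets.items() if s < 0]


@dataclass
class RegulonActivity:
    tf_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # tf x sample
    method: str = "two_arm_ssgsea"


@dataclass(frozen=True)
class PhenotypeTestResult:
    tf_id: str
    statistic: float
    pval: float
    direction: str | None = None  # two-tailed only: "positive" | "negative"


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign each value to one of ``bins`` near-equal-count bins by rank."""
    n = x.shape[-1]
    ranks = np.argsort(np.argsort(x, axis=-1, kind="stable"), axis=-1, kind="stable")
    return (ranks * bins) // n


def default_bins(n: int) -> int:
    """Cube-root rule: enough resolution to see dependence, small enough
    that the plug-in bias stays negligible."""
    return max(2, int(np.floor(np.cbrt(n))))


def _entropy_from_counts(counts: np.ndarray, n: int, axis=None) -> np.ndarray:
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=axis)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) on equal-frequency-binned values.

    The default bin count is max(2, floor(n^(1/3))), which keeps the
    plug-in bias of order (bins-1)^2/(2n) well below the signal for the
    sample sizes this layer sees. For y identical to x the estimate equals
    log(bins) when bins divides n.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise RegulonError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 8:
        raise RegulonError(f"need >=8 observations, got {n}")
    if bins is None:
        bins = default_bins(n)
    bx, by = _equal_frequency_bins(x, bins), _equal_frequency_bins(y, bins)
    if bx.tobytes() > by.tobytes():  # canonical order: exact symmetry
        bx, by = by, bx
    joint = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    h_x = _entropy_from_counts(joint.sum(axis=1), n)
    h_y = _entropy_from_counts(joint.sum(axis=0), n)
    h_xy = _entropy_from_counts(joint, n)
    return float(max(h_x + h_y - h_xy, 0.0))


def _mi_vs_all(bx: np.ndarray, B: np.ndarray, bins: int) -> np.ndarray:
    """Vectorized MI of one binned vector against many binned rows."""
    g, n = B.shape
    offsets = (np.arange(g) * bins * bins)[:, None]
    flat = (offsets + B * bins + bx[None, :]).ravel()
    joint = np.bincount(flat, minlength=g * bins * bins).reshape(g, bins, bins)
    # joint[g, i, j]: i = gene bin, j = regulator bin
    h_gene = _entropy_from_counts(joint.sum(axis=2), n, axis=-1)
    h_reg = _entropy_from_counts(joint.sum(axis=1), n, axis=-1)
    h_joint = _entropy_from_counts(joint.reshape(g, -1), n, axis=-1)
    return np.maximum(h_gene + h_reg - h_joint, 0.0)


def _tf_rng(seed: int, tf_id: str, salt: str = "") -> np.random.Generator:
    digest = hashlib.sha256(f"{salt}:{tf_id}".encode()).digest()
    sub = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


# ---------------------------------------------------------------------------
# Regulon inference
# ---------------------------------------------------------------------------


def infer_regulons(
    study: ExpressionStudy,
    tf_ids: list[str],
    n_perm: int = 1000,
    alpha: float = 0.01,
    n_boot: int = 100,
    boot_consensus: float = 0.75,
    dpi_tol: float = 0.0,
    seed: int = 0,
    bins: int | None = None,
) -> list[Regulon]:
    """Infer one regulon per TF in three stages.

    (a) permutation significance: sample-shuffle nulls of the TF profile,
    per-gene p < alpha; (b) bootstrap stability: the edge's MI must exceed
    the permutation threshold in >= ``boot_consensus`` of resamples;
    (c) DPI pruning: in every TF1-TF2-target MI triangle the weakest edge is
    removed when it is below the minimum of the other two minus ``dpi_tol``.
    Target signs come from Spearman correlation. Deterministic given seed,
    independent of gene and TF input order.

    ``bins`` defaults to the cube-root rule (see ``mutual_information``);
    coarser binning trades resolution for detection power.
    """
    n = len(study.sample_ids)
    if n < 8:
        raise RegulonError(f"MI inference needs >=8 samples, got {n}")
    gene_set = set(study.gene_ids)
    missing = [t for t in tf_ids if t not in gene_set]
    if missing:
        raise RegulonError(f"TFs not in study: {missing[:5]}")

    if bins is None:
        bins = default_bins(n)
    if bins < 2:
        raise RegulonError("bins must be >= 2")
    tf_ids = sorted(set(tf_ids))
    gene_ids = list(study.gene_ids)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    B = _equal_frequency_bins(study.values, bins)  # all genes, binned

    regulons: dict[str, Regulon] = {}
    mi_cache: dict[tuple[str, str], float] = {}

    for tf in tf_ids:
        x = study.values[gidx[tf]]
        bx = B[gidx[tf]]
        candidates = [g for g in gene_ids if g != tf]
        cand_idx = np.array([gidx[g] for g in candidates])
        obs = _mi_vs_all(bx, B[cand_idx], bins)

        rng = _tf_rng(seed, tf, "perm")
        null = np.empty((n_perm, len(candidates)))
        for p in range(n_perm):
            null[p] = _mi_vs_all(bx[rng.permutation(n)], B[cand_idx], bins)
        pvals = (1 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1)
        thresholds = np.quantile(null, 1 - alpha, axis=0)
        sig = pvals < alpha
        if not sig.any():
            regulons[tf] = Regulon(tf)
            continue

        sig_pos = np.flatnonzero(sig)
        brng = _tf_rng(seed, tf, "boot")
        hits = np.zeros(sig_pos.size)
        for _ in range(n_boot):
            take = brng.integers(0, n, n)
            xb = _equal_frequency_bins(x[take], bins)
            Bb = _equal_frequency_bins(study.values[cand_idx[sig_pos]][:, take], bins)
            hits += _mi_vs_all(xb, Bb, bins) >= thresholds[sig_pos]
        stable = sig_pos[hits / n_boot >= boot_consensus]

        targets: dict[str, tuple[float, int]] = {}
        for j in stable:
            gene = candidates[j]
            rho = stats.spearmanr(x, study.values[gidx[gene]]).statistic
            sign = 1 if (np.isnan(rho) or rho >= 0) else -1
            targets[gene] = (float(obs[j]), sign)
            mi_cache[(tf, gene)] = float(obs[j])
        regulons[tf] = Regulon(tf, targets)

    _dpi_prune(study, regulons, tf_ids, bins, dpi_tol, mi_cache, gidx)
    return [regulons[tf] for tf in tf_ids]


def _dpi_prune(
    study: ExpressionStudy,
    regulons: dict[str, Regulon],
    tf_ids: list[str],
    bins: int,
    dpi_tol: float,
    mi_cache: dict[tuple[str, str], float],
    gidx: dict[str, int],
) -> None:
    """Remove likely-indirect edges via the data processing inequality."""
    if not np.isfinite(dpi_tol):
        return
    B = _equal_frequency_bins(study.values, bins)
    to_remove: set[tuple[str, str]] = set()
    for i, tf1 in enumerate(tf_ids):
        for tf2 in tf_ids[i + 1:]:
            shared = set(regulons[tf1].targets) & set(regulons[tf2].targets)
            # TF-TF edge may itself be a regulon edge; otherwise compute MI
            mi_tt = mi_cache.get((tf1, tf2)) or mi_cache.get((tf2, tf1))
            if mi_tt is None:
                mi_tt = float(
                    _mi_vs_all(B[gidx[tf1]], B[gidx[tf2]][None, :], bins)[0]
                )
            for g in shared:
                e1 = regulons[tf1].targets[g][0]
                e2 = regulons[tf2].targets[g][0]
                edges = [(e1, (tf1, g)), (e2, (tf2, g)), (mi_tt, None)]
                edges.sort(key=lambda t: t[0])
                weakest_mi, weakest_edge = edges[0]
                if weakest_edge is not None and weakest_mi < min(
                    edges[1][0], edges[2][0]
                ) - dpi_tol:
                    to_remove.add(weakest_edge)
    for tf, g in to_remove:
        regulons[tf].targets.pop(g, None)


# ---------------------------------------------------------------------------
# Regulon activity
# ---------------------------------------------------------------------------


def regulon_activity(
    study: ExpressionStudy, regulons: list[Regulon], alpha: float = 0.25
) -> RegulonActivity:
    """Per-sample signed two-arm enrichment activity.

    activity(sample, TF) = walk score of the positive-target arm minus walk
    score of the negative-target arm over the sample's descending gene
    ranking: a sample over-expressing positive targets and under-expressing
    negative targets scores high.
    """
    if not regulons:
        raise RegulonError("no regulons supplied")
    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    n = len(study.gene_ids)
    orders = _sample_orders(study)
    rank_weights = np.arange(n, 0, -1, dtype=float) ** alpha

    usable: list[Regulon] = []
    for reg in regulons:
        if not any(g in gene_index for g in reg.targets):
            logger.warning("regulon %s has no usable targets; skipped", reg.tf_id)
            continue
        usable.append(reg)

    values = np.zeros((len(usable), len(study.sample_ids)))
    for i, reg in enumerate(usable):
        arms = []
        for genes in (reg.positive_targets(), reg.negative_targets()):
            idx = [gene_index[g] for g in genes if g in gene_index]
            ind = np.zeros(n, bool)
            ind[idx] = True
            arms.append(ind if idx else None)
        pos, neg = arms
        for j in range(len(study.sample_ids)):
            order = orders[j]
            score = 0.0
            if pos is not None:
                score += _ssgsea_walk(pos[order], rank_weights)
            if neg is not None:
                score -= _ssgsea_walk(neg[order], rank_weights)
            values[i, j] = score
    return RegulonActivity(
        [r.tf_id for r in usable], list(study.sample_ids), values
    )


# ---------------------------------------------------------------------------
# Regulon-phenotype association
# ---------------------------------------------------------------------------


def regulon_phenotype_test(
    study: ExpressionStudy,
    regulons: list[Regulon],
    group_a: str = "active",
    group_b: str = "inactive",
    tails: str = "two",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PhenotypeTestResult]:
    """Association of each regulon with the phenotype contrast.

    Genes are ranked by signal-to-noise between the groups. One-tailed: the
    whole target set is tested at the top of the ranking. Two-tailed: the
    positive and negative arms are tested at opposite ends; the statistic is
    ES(positive arm) - ES(negative arm) and direction reports whether the
    positive arm tracks the active group. Label-permutation p-values.
    """
    if tails not in ("one", "two"):
        raise RegulonError(f"unknown tail mode {tails!r}")
    labels = np.array([study.phenotype[s] for s in study.sample_ids])
    mask_a, mask_b = labels == group_a, labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise RegulonError("each group needs >=2 samples")

    gene_index = {g: i for i, g in enumerate(study.gene_ids)}
    n_genes = len(study.gene_ids)
    cols = np.concatenate([np.flatnonzero(mask_a), np.flatnonzero(mask_b)])
    sub = study.values[:, cols]
    n_a = int(mask_a.sum())
    base_mask = np.zeros(cols.size, bool)
    base_mask[:n_a] = True

    def _stat(metric: np.ndarray, reg: Regulon) -> float:
        order = np.argsort(-metric, kind="stable")
        if tails == "one":
            idx = [gene_index[g] for g in reg.targets if g in gene_index]
            ind = np.zeros(n_genes, bool)
            ind[idx] = True
            return _gsea_es(order, metric, ind)
        score = 0.0
        for genes, sgn in ((reg.positive_targets(), 1.0), (reg.negative_targets(), -1.0)):
            idx = [gene_index[g] for g in genes if g in gene_index]
            if not idx:
                continue
            ind = np.zeros(n_genes, bool)
            ind[idx] = True
            score += sgn * _gsea_es(order, metric, ind)
        return score

    for reg in regulons:
        if not any(g in gene_index for g in reg.targets):
            raise RegulonError(f"regulon {reg.tf_id} disjoint from the ranked gene list")

    obs_metric = signal_to_noise(sub, base_mask, ~base_mask)
    obs = {reg.tf_id: _stat(obs_metric, reg) for reg in regulons}

    rng = np.random.default_rng(seed)
    null = {reg.tf_id: np.empty(n_perm) for reg in regulons}
    for p in range(n_perm):
        perm = rng.permutation(cols.size)
        pm = np.zeros(cols.size, bool)
        pm[perm[:n_a]] = True
        metric = signal_to_noise(sub, pm, ~pm)
        for reg in regulons:
            null[reg.tf_id][p] = _stat(metric, reg)

    results = []
    for reg in regulons:
        o, nl = obs[reg.tf_id], null[reg.tf_id]
        if tails == "one":
            pval = float((1 + np.sum(nl >= o)) / (n_perm + 1))
            direction = None
        else:
            pval = float((1 + np.sum(np.abs(nl) >= abs(o))) / (n_perm + 1))
            direction = "positive" if o >= 0 else "negative"
        results.append(PhenotypeTestResult(reg.tf_id, float(o), pval, direction))
    return results
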