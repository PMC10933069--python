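"""Gene-level screen: moderated differential expression, per-gene QTL MR
against the outcome, and odds-ratio-based risk/protective classification.

The DE model is a per-gene two-group linear model with empirical-Bayes
variance moderation: the posterior variance is a precision-weighted blend
of the gene's own variance and a prior fitted by moment matching on the
distribution of log sample variances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .instruments import (
    HarmonizedSet,
    InstrumentError,
    harmonize,
    select_instruments,
)
from .mr import MREngineError, ivw, wald_ratio
from .summary_io import ExpressionStudy, LDMatrix, SummaryStats

logger = logging.getLogger(__name__)


class GeneScreenError(ValueError):
    pass


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log_fc: float
    moderated_t: float
    pval: float
    adj_pval: float


@dataclass
class GeneMRTable:
    """Per-gene MR results with risk/protective labels."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "n_snps", "method", "beta", "or_", "pval", "label", "reason"]
        )
    )

    def risk_genes(self) -> list[str]:
        return self.rows.loc[self.rows["label"] == "risk", "gene_id"].tolist()

    def protective_genes(self) -> list[str]:
        return self.rows.loc[self.rows["label"] == "protective", "gene_id"].tolist()


def classify(or_: float, pval: float, p_threshold: float = 0.05) -> str:
    """Risk if significant and OR>1, protective if significant and OR<1,
    excluded otherwise (including OR exactly 1)."""
    if pval < p_threshold and or_ > 1:
        return "risk"
    if pval < p_threshold and or_ < 1:
        return "protective"
    return "excluded"


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Moderated differential expression
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed log sample variances. Returns (d0, s0sq); d0 may be inf."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    resid_var = e_var - float(special.polygamma(1, df / 2))
    if resid_var <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s0sq = math.exp(
        e_mean + special.digamma(d0 / 2) - math.log(d0 / 2)
    )
    return d0, s0sq


def moderated_de(
    study: ExpressionStudy, contrast: tuple[str, str] = ("active", "inactive")
) -> list[DEResult]:
    """Per-gene moderated two-group test with BH adjustment across genes.

    log_fc is mean(group A) - mean(group B). The moderated t statistic uses
    the posterior variance s~^2 = (d0*s0^2 + dg*sg^2)/(d0+dg) with dg+d0
    degrees of freedom.
    """
    lab_a, lab_b = contrast
    idx = {s: j for j, s in enumerate(study.sample_ids)}
    cols_a = [idx[s] for s in study.samples_with(lab_a)]
    cols_b = [idx[s] for s in study.samples_with(lab_b)]
    for lab, cols in ((lab_a, cols_a), (lab_b, cols_b)):
        if len(cols) < 2:
            raise GeneScreenError(f"contrast level {lab!r} has <2 samples")
    a, b = study.values[:, cols_a], study.values[:, cols_b]
    na, nb = a.shape[1], b.shape[1]
    dg = na + nb - 2
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / dg

    d0, s0sq = fit_variance_prior(s2, dg)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    denom = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, log_fc / denom, 0.0)
    if math.isinf(df_total):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df=df_total)
    adj = bh_adjust(pvals)
    return [
        DEResult(g, float(log_fc[i]), float(t[i]), float(pvals[i]), float(adj[i]))
        for i, g in enumerate(study.gene_ids)
    ]


# ---------------------------------------------------------------------------
# Per-gene QTL MR screen
# ---------------------------------------------------------------------------


def _screen_one_gene(
    gene: str,
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    p_exposure: float,
    r2_max: float,
    p_outcome_max: float,
    f_min: float,
) -> dict:
    try:
        h = harmonize(exposure, outcome)
    except InstrumentError:
        return dict(gene_id=gene, n_snps=0, method="none", beta=np.nan,
                    or_=np.nan, pval=np.nan, label="excluded", reason="no_shared_variants")
    try:
        # no fallback tier in the per-gene screen
        sel = select_instruments(
            h, ld, p_primary=p_exposure, r2_primary=r2_max,
            p_outcome_max=p_outcome_max, f_min=f_min, allow_fallback=False,
        )
    except InstrumentError:
        reason = "weak_instrument" if any(
            r.pval_exposure < p_exposure and r.f_stat < f_min for r in h.records
        ) else "no_instruments"
        return dict(gene_id=gene, n_snps=0, method="none", beta=np.nan,
                    or_=np.nan, pval=np.nan, label="excluded", reason=reason)
    try:
        res = wald_ratio(sel.records[0]) if len(sel.records) == 1 else ivw(sel)
    except MREngineError as exc:
        return dict(gene_id=gene, n_snps=len(sel.records), method="none", beta=np.nan,
                    or_=np.nan, pval=np.nan, label="excluded", reason=str(exc))
    return dict(
        gene_id=gene, n_snps=res.n_snps, method=res.method, beta=res.beta,
        or_=res.or_, pval=res.pval, label=classify(res.or_, res.pval), reason="",
    )


def qtl_mr_screen(
    catalog: dict[str, SummaryStats],
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    p_exposure: float = 5e-8,
    r2_max: float = 0.001,
    p_outcome_max: float = 5e-6,
    f_min: float = 10.0,
) -> GeneMRTable:
    """Per-gene MR: each gene's QTL table is one exposure against the outcome.

    Single surviving instrument -> Wald ratio; several -> IVW. Genes with no
    surviving instruments are labeled excluded with a reason. Classification
    uses the raw p-value at 0.05 with OR>1 risk / OR<1 protective.
    """
    if not catalog:
        raise GeneScreenError("empty QTL catalog")
    if not outcome.records:
        raise GeneScreenError("empty outcome table")
    if ld is None:
        all_ids = sorted({r.variant_id for s in catalog.values() for r in s.records})
        ld = LDMatrix.identity(all_ids)
    rows = [
        _screen_one_gene(g, catalog[g], outcome, ld,
                         p_exposure, r2_max, p_outcome_max, f_min)
        for g in catalog
    ]
    return GeneMRTable(pd.DataFrame(rows))


def pqtl_verify(
    protein_catalog: dict[str, SummaryStats],
    outcome: SummaryStats,
    eqtl_table: GeneMRTable | None = None,
    ld: LDMatrix | None = None,
    **thresholds,
) -> GeneMRTable:
    """Protein-level verification with the same machinery as the eQTL screen.

    When an eQTL table is supplied, genes significant in both screens are
    flagged ``concordant`` when their effect directions agree.
    """
    if not protein_catalog:
        return GeneMRTable()
    table = qtl_mr_screen(protein_catalog, outcome, ld=ld, **thresholds)
    table.rows["level"] = "protein"
    if eqtl_table is not None and not eqtl_table.rows.empty:
        elabels = eqtl_table.rows.set_index("gene_id")["label"]
        def _concord(row) -> bool:
            if row["label"] == "excluded":
                return False
            other = elabels.get(row["gene_id"])
            return other == row["label"]
        table.rows["concordant"] = table.rows.apply(_concord, axis=1)
    return table


def intersect_with_de(mr: GeneMRTable, de: list[DEResult]) -> pd.DataFrame:
    """Annotate MR rows with DE direction and cross-tabulate label x direction."""
    de_by_gene = {d.gene_id: d for d in de}
    rows = mr.rows.copy()
    rows["log_fc"] = [
        de_by_gene[g].log_fc if g in de_by_gene else np.nan for g in rows["gene_id"]
    ]
    rows["direction"] = [
        ("up" if de_by_gene[g].log_fc > 0 else "down") if g in de_by_gene else "na"
        for g in rows["gene_id"]
    ]
    counts = {
        f"{lab}_{dirn}": int(
            ((rows["label"] == lab) & (rows["direction"] == dirn)).sum()
        )
        for lab in ("risk", "protective")
        for dirn in ("up", "down")
    }
    rows.attrs["crosstab"] = counts
    return rows
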