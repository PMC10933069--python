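"""Causal estimators and pleiotropy diagnostics for two-sample MR.

Estimators: Wald ratio (single variant), fixed-effect inverse-variance
weighting (primary), Egger regression. Diagnostics: Cochran's Q, a
simulation-based residual-sum-of-squares outlier test (global / per-variant
outlier / distortion components), and leave-one-out sensitivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from .instruments import HarmonizedRecord, HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = 1.96


class MREngineError(ValueError):
    pass


@dataclass(frozen=True)
class MRResult:
    """One causal estimate on the log-odds scale, with OR and 95% CI."""

    method: str  # wald_ratio | ivw | egger_slope
    beta: float
    se: float
    pval: float
    n_snps: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(or_=self.or_, ci_low=self.ci_low, ci_high=self.ci_high)
        return d


@dataclass
class PleiotropyReport:
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    cochran_q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LeaveOneOut:
    """Per-variant IVW refits, each excluding one variant."""

    excluded_ids: list[str]
    betas: list[float]
    ses: list[float]
    pvals: list[float]

    def to_dict(self) -> dict:
        return asdict(self)


def _arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([r.beta_exposure for r in h.records])
    by = np.array([r.beta_outcome for r in h.records])
    sy = np.array([r.se_outcome for r in h.records])
    return bx, by, sy


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def wald_ratio(r: HarmonizedRecord) -> MRResult:
    """Single-variant causal estimate: outcome beta / exposure beta.

    SE by the first-order delta method, |se_outcome / beta_exposure|.
    """
    if r.beta_exposure == 0:
        raise MREngineError(f"{r.variant_id}: exposure beta is zero")
    beta = r.beta_outcome / r.beta_exposure
    se = abs(r.se_outcome / r.beta_exposure)
    return MRResult("wald_ratio", beta, se, _norm_p(beta / se), 1)


def ivw(h: HarmonizedSet) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); se = sum(bx^2/sy^2)^(-1/2).
    Equivalent to weighted least squares of by on bx through the origin with
    weights 1/sy^2. Reduces exactly to the Wald ratio for a single variant.
    """
    if len(h.records) == 0:
        raise MREngineError("empty harmonized set")
    if len(h.records) == 1:  # exact single-variant reduction
        wr = wald_ratio(h.records[0])
        return MRResult("ivw", wr.beta, wr.se, wr.pval, 1)
    bx, by, sy = _arrays(h)
    if np.any(sy <= 0):
        raise MREngineError("non-positive outcome SE")
    w = sy ** -2.0
    denom = float(np.sum(bx ** 2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = denom ** -0.5
    return MRResult("ivw", beta, se, _norm_p(beta / se), len(h.records))


def egger(h: HarmonizedSet) -> tuple[MRResult, PleiotropyReport]:
    """Egger regression: weighted fit of by on bx with a free intercept.

    The intercept tests directional pleiotropy. Standard errors carry a
    multiplicative overdispersion factor max(1, residual SE); p-values use
    the t distribution with K-2 df.
    """
    k = len(h.records)
    if k < 3:
        raise MREngineError(f"Egger regression needs >=3 variants, got {k}")
    bx, by, sy = _arrays(h)
    # orient so all exposure effects are positive (InSIDE convention)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = sy ** -2.0
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    phi = float(np.sum(w * resid ** 2) / (k - 2))
    scale = max(1.0, phi)
    cov = np.linalg.inv(xtwx) * scale
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    tdist = stats.t(df=k - 2)
    p_slope = float(2 * tdist.sf(abs(slope / se_slope)))
    p_inter = float(2 * tdist.sf(abs(inter / se_inter)))
    result = MRResult("egger_slope", slope, se_slope, p_slope, k)
    report = PleiotropyReport(
        egger_intercept=inter, egger_intercept_se=se_inter, egger_intercept_p=p_inter
    )
    return result, report


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity across per-variant ratio estimates.

    Q = sum_k w_k (ratio_k - beta_ivw)^2 with w_k = bx_k^2 / sy_k^2;
    chi-square with K-1 df under homogeneity.
    """
    k = len(h.records)
    if k < 2:
        raise MREngineError(f"Cochran's Q needs >=2 variants, got {k}")
    bx, by, sy = _arrays(h)
    if np.any(bx == 0):
        raise MREngineError("zero exposure beta; ratio undefined")
    w = bx ** 2 / sy ** 2
    ratios = by / bx
    beta = ivw(h).beta
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW estimate excluding each variant in turn (closed form)."""
    num, den = np.sum(bx * by * w), np.sum(bx ** 2 * w)
    return (num - bx * by * w) / (den - bx ** 2 * w)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    alpha_outlier: float = 0.05,
    seed: int | None = None,
) -> PleiotropyReport:
    """Simulation-based pleiotropy residual test.

    Global test: the observed weighted RSS of leave-one-out-predicted outcome
    betas is ranked against ``n_sim`` parametric simulations drawing
    by_k ~ Normal(beta_ivw(-k) * bx_k, sy_k). Outlier test: per-variant
    observed squared residual vs its simulated distribution, Bonferroni
    adjusted. Distortion test: the estimate shift after removing outliers is
    compared against removals of random variant subsets of the same size.
    """
    k = len(h.records)
    if k < 4:
        raise MREngineError(f"outlier RSS test needs >=4 variants, got {k}")
    if seed is None:
        raise MREngineError("seed is mandatory for the simulation-based test")
    rng = np.random.default_rng(seed)
    bx, by, sy = _arrays(h)
    w = sy ** -2.0

    loo = _loo_betas(bx, by, w)
    obs_resid2 = ((by - loo * bx) / sy) ** 2
    obs_rss = float(np.sum(obs_resid2))

    # simulated datasets: (n_sim, k)
    by_sim = loo * bx + rng.standard_normal((n_sim, k)) * sy
    num = np.sum(bx * by_sim * w, axis=1, keepdims=True)
    den = float(np.sum(bx ** 2 * w))
    loo_sim = (num - bx * by_sim * w) / (den - bx ** 2 * w)
    sim_resid2 = ((by_sim - loo_sim * bx) / sy) ** 2
    sim_rss = np.sum(sim_resid2, axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    report = PleiotropyReport(presso_global_p=global_p)
    pvals = (1 + np.sum(sim_resid2 >= obs_resid2, axis=0)) / (n_sim + 1)
    adj = np.minimum(pvals * k, 1.0)  # Bonferroni
    outlier_mask = adj < alpha_outlier
    report.presso_outliers = [
        h.records[i].variant_id for i in np.flatnonzero(outlier_mask)
    ]

    if report.presso_outliers and k - len(report.presso_outliers) >= 2 and k >= 5:
        keep = ~outlier_mask
        beta_all = ivw(h).beta
        beta_clean = float(
            np.sum(bx[keep] * by[keep] * w[keep]) / np.sum(bx[keep] ** 2 * w[keep])
        )
        if beta_clean != 0:
            obs_dist = abs((beta_all - beta_clean) / beta_clean)
            n_out = len(report.presso_outliers)
            dist_sims = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                m = np.ones(k, bool)
                m[drop] = False
                b = np.sum(bx[m] * by[m] * w[m]) / np.sum(bx[m] ** 2 * w[m])
                dist_sims[i] = abs((beta_all - b) / b) if b != 0 else np.inf
            report.presso_distortion_p = float(
                (1 + np.sum(dist_sims >= obs_dist)) / (n_sim + 1)
            )
    return report


def leave_one_out(h: HarmonizedSet) -> LeaveOneOut:
    """One IVW refit per excluded variant, in input order."""
    k = len(h.records)
    if k < 2:
        raise MREngineError(f"leave-one-out needs >=2 variants, got {k}")
    bx, by, sy = _arrays(h)
    w = sy ** -2.0
    den = np.sum(bx ** 2 * w) - bx ** 2 * w
    betas = _loo_betas(bx, by, w)
    ses = den ** -0.5
    pvals = 2 * stats.norm.sf(np.abs(betas / ses))
    return LeaveOneOut(
        excluded_ids=[r.variant_id for r in h.records],
        betas=betas.tolist(),
        ses=ses.tolist(),
        pvals=pvals.tolist(),
    )


def full_mr_report(
    h: HarmonizedSet, seed: int
) -> tuple[MRResult, PleiotropyReport, LeaveOneOut | None]:
    """Primary estimate plus every diagnostic available at the given K.

    Primary is IVW (Wald ratio at K=1). Diagnostics requiring more variants
    than available are skipped with a note.
    """
    k = len(h.records)
    if k == 0:
        raise MREngineError("empty harmonized set")
    primary = wald_ratio(h.records[0]) if k == 1 else ivw(h)
    report = PleiotropyReport()
    loo = None
    if k >= 3:
        _, egger_rep = egger(h)
        report.egger_intercept = egger_rep.egger_intercept
        report.egger_intercept_se = egger_rep.egger_intercept_se
        report.egger_intercept_p = egger_rep.egger_intercept_p
    else:
        report.notes.append(f"egger skipped (K={k} < 3)")
    if k >= 2:
        report.cochran_q, report.q_df, report.q_pval = cochran_q(h)
        loo = leave_one_out(h)
    else:
        report.notes.append(f"cochran_q and leave-one-out skipped (K={k} < 2)")
    if k >= 4:
        presso = mr_presso(h, seed=seed)
        report.presso_global_p = presso.presso_global_p
        report.presso_outliers = presso.presso_outliers
        report.presso_distortion_p = presso.presso_distortion_p
    else:
        report.notes.append(f"outlier RSS test skipped (K={k} < 4)")
    return primary, report, loo
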