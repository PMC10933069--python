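"""Immune-cell layer: signature-based cell-type scores with spillover
correction, univariate screening against disease activity, L1-penalized
logistic selection, and risk-gene x cell-type correlation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .enrichment import ssgsea_score
from .summary_io import ExpressionStudy, GeneSetCollection, SignatureCollection

logger = logging.getLogger(__name__)


class CellScoreError(ValueError):
    pass


@dataclass
class CellScoreMatrix:
    cell_types: list[str]
    sample_ids: list[str]
    values: np.ndarray  # cell_type x sample
    provenance: str = "raw"  # raw | spillover_corrected

    def row(self, cell_type: str) -> np.ndarray:
        return self.values[self.cell_types.index(cell_type)]


@dataclass
class SelectionResult:
    screened: list[tuple[str, float]]           # (cell_type, univariate p)
    selected: list[tuple[str, float]]           # (cell_type, coefficient)
    lambda_chosen: float
    seed: int
    path_lambdas: list[float] = field(default_factory=list)
    path_active_counts: list[int] = field(default_factory=list)


def score_cell_types(
    study: ExpressionStudy, signatures: SignatureCollection, alpha: float = 0.25
) -> CellScoreMatrix:
    """Single-sample score per signature, then unweighted mean per cell type.

    Cell types whose signatures all miss the study's genes are dropped with
    a warning.
    """
    sets = GeneSetCollection({name: genes for name, genes in signatures.signatures.items()})
    scores = ssgsea_score(study, sets, alpha=alpha)
    score_of = scores.as_dict()
    cell_types, rows = [], []
    for cell, sigs in sorted(signatures.by_cell_type().items()):
        usable = [s for s in sigs if s in score_of]
        if not usable:
            logger.warning("cell type %s has no usable signatures; dropped", cell)
            continue
        cell_types.append(cell)
        rows.append(np.mean([score_of[s] for s in usable], axis=0))
    if not cell_types:
        raise CellScoreError("no cell type has a usable signature")
    return CellScoreMatrix(cell_types, list(study.sample_ids), np.vstack(rows), "raw")


def spillover_correct(raw: CellScoreMatrix, spillover: pd.DataFrame) -> CellScoreMatrix:
    """Compensate signature cross-reactivity by per-sample linear least squares.

    Solves spillover @ corrected = raw for each sample; negative solutions
    are clipped to zero.
    """
    missing = [c for c in raw.cell_types if c not in spillover.index]
    if missing:
        raise CellScoreError(f"cell types missing from spillover matrix: {missing}")
    sp = spillover.loc[raw.cell_types, raw.cell_types].to_numpy(float)
    if np.linalg.cond(sp) > 1e12:
        raise CellScoreError("spillover matrix is singular or near-singular")
    corrected, *_ = np.linalg.lstsq(sp, raw.values, rcond=None)
    return CellScoreMatrix(
        list(raw.cell_types),
        list(raw.sample_ids),
        np.clip(corrected, 0.0, None),
        "spillover_corrected",
    )


def _binary_labels(
    scores: CellScoreMatrix, phenotype: dict[str, str], group_a: str, group_b: str
) -> tuple[np.ndarray, np.ndarray]:
    keep = [
        j for j, s in enumerate(scores.sample_ids)
        if phenotype.get(s) in (group_a, group_b)
    ]
    y = np.array(
        [1.0 if phenotype[scores.sample_ids[j]] == group_a else 0.0 for j in keep]
    )
    return np.array(keep), y


def univariate_screen(
    scores: CellScoreMatrix,
    phenotype: dict[str, str],
    group_a: str = "active",
    group_b: str = "inactive",
) -> list[tuple[str, float]]:
    """Per cell type: logistic regression of the activity indicator on the
    score, Wald p for the slope. Complete-separation or non-converged fits
    fall back to a rank-sum p with a logged notice."""
    cols, y = _binary_labels(scores, phenotype, group_a, group_b)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 3:
        raise CellScoreError("need >=3 samples in each group")
    out = []
    for i, cell in enumerate(scores.cell_types):
        x = scores.values[i, cols]
        p = _logistic_wald_p(x, y)
        if p is None:
            logger.info("cell type %s: separation; falling back to rank-sum", cell)
            p = float(
                stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").pvalue
            )
        out.append((cell, float(p)))
    return out


def _logistic_wald_p(x: np.ndarray, y: np.ndarray) -> float | None:
    """Wald p for the slope of a univariate logistic fit; None when the fit
    is unusable (separation / huge SE)."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None
    se = fit.bse[1]
    if not np.isfinite(se) or se > 1e3 * (np.std(x) + 1e-12) ** -1:
        return None
    return float(fit.pvalues[1])


def lasso_select(
    scores: CellScoreMatrix,
    phenotype: dict[str, str],
    screened: list[tuple[str, float]] | None = None,
    p_screen: float = 0.05,
    group_a: str = "active",
    group_b: str = "inactive",
    n_folds: int = 10,
    n_lambdas: int = 50,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic selection over the screened cell types.

    The penalty grid is log-spaced from the smallest lambda that zeroes every
    coefficient down to lambda_max/1000; lambda is chosen by cross-validated
    binomial deviance with the 1-SE rule; ``selected`` holds the nonzero
    coefficients of the full-data refit at that lambda. Fold assignment is
    seeded, so the result is deterministic.
    """
    if screened is None:
        screened = univariate_screen(scores, phenotype, group_a, group_b)
    kept = [c for c, p in screened if p < p_screen]
    if len(kept) < 2:
        raise CellScoreError(f"need >=2 screened cell types, got {len(kept)}")
    cols, y = _binary_labels(scores, phenotype, group_a, group_b)
    n = len(cols)
    if n < 10:
        raise CellScoreError(f"need >=10 samples, got {n}")
    rows = [scores.cell_types.index(c) for c in kept]
    X = scores.values[np.ix_(rows, cols)].T  # samples x features
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    # lambda_max: smallest penalty that zeroes all coefficients
    resid0 = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ resid0)) / n)
    lambdas = np.geomspace(lam_max, lam_max / 1000.0, n_lambdas)

    folds = min(n_folds, int(min((y == 1).sum(), (y == 0).sum())))
    if folds < n_folds:
        logger.warning("reducing folds from %d to %d", n_folds, folds)
    if folds < 2:
        raise CellScoreError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def _fit(Xtr, ytr, lam):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (lam * len(ytr)), solver="liblinear",
            max_iter=5000, tol=1e-8,
        )
        clf.fit(Xtr, ytr)
        return clf

    eps = 1e-12
    dev = np.zeros((folds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        for j, lam in enumerate(lambdas):
            clf = _fit(Xs[tr], y[tr], lam)
            prob = np.clip(clf.predict_proba(Xs[te])[:, 1], eps, 1 - eps)
            dev[f, j] = -2 * np.mean(y[te] * np.log(prob) + (1 - y[te]) * np.log(1 - prob))
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(mean_dev))
    cutoff = mean_dev[j_min] + se_dev[j_min]
    j_1se = int(np.flatnonzero(mean_dev <= cutoff)[0])  # largest lambda within 1 SE
    lam_chosen = float(lambdas[j_1se])

    path_counts = []
    for lam in lambdas:
        clf = _fit(Xs, y, lam)
        path_counts.append(int(np.sum(np.abs(clf.coef_[0]) > 1e-10)))

    final = _fit(Xs, y, lam_chosen)
    coefs = final.coef_[0] / sd  # back to the original scale
    selected = [
        (kept[i], float(coefs[i]))
        for i in range(len(kept))
        if abs(final.coef_[0][i]) > 1e-10
    ]
    return SelectionResult(
        screened=screened,
        selected=selected,
        lambda_chosen=lam_chosen,
        seed=seed,
        path_lambdas=[float(l) for l in lambdas],
        path_active_counts=path_counts,
    )


def correlate_genes_cells(
    study: ExpressionStudy,
    scores: CellScoreMatrix,
    gene_ids: list[str] | None = None,
    method: str = "pearson",
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Correlation of each (risk) gene with each cell-type score.

    Returns (r matrix, p matrix, per-gene count of significant cell types).
    Zero-variance genes or scores give missing correlations with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise CellScoreError(f"unknown method {method!r}")
    genes = gene_ids if gene_ids is not None else list(study.gene_ids)
    col = {s: j for j, s in enumerate(study.sample_ids)}
    cols = [col[s] for s in scores.sample_ids]
    if len(cols) < 3:
        raise CellScoreError(f"need >=3 samples, got {len(cols)}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = pd.DataFrame(index=genes, columns=scores.cell_types, dtype=float)
    p = pd.DataFrame(index=genes, columns=scores.cell_types, dtype=float)
    for g in genes:
        gv = study.gene_row(g)[cols]
        for i, cell in enumerate(scores.cell_types):
            cv = scores.values[i]
            if np.std(gv) == 0 or np.std(cv) == 0:
                logger.warning("zero variance for (%s, %s); correlation undefined", g, cell)
                continue
            res = corr(gv, cv)
            r.loc[g, cell], p.loc[g, cell] = float(res.statistic), float(res.pvalue)
    sig_counts = {g: int((p.loc[g] < p_threshold).sum()) for g in genes}
    return r, p, sig_counts
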