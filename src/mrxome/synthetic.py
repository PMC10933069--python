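"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of its config (seed included): identical
config gives bit-identical output. Truth objects are returned alongside the
data so recovery tests never re-derive ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import (
    ExpressionStudy,
    LDMatrix,
    SummaryStats,
    VariantRecord,
)

#: allele pairs used for simulated variants; none are palindromic so that
#: harmonization keeps every variant regardless of eaf
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


class SyntheticConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GWAS exposure/outcome pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasSimConfig:
    """Config for one exposure/outcome summary-statistics pair.

    Instrument strength is parameterized through a target F statistic
    (``f_target``, mean of the per-variant F) rather than a raw effect SD,
    so tests can straddle the F=10 weak-instrument filter deliberately.
    """

    n_variants: int
    beta_causal: float = 0.0
    pleiotropy_frac: float = 0.0
    pleiotropy_sd: float = 0.0
    balanced: bool = True
    het_sd: float = 0.0
    exposure_se_scale: float = 0.02
    outcome_se_scale: float = 0.05
    f_target: float = 100.0
    seed: int = 0
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    n_exposure: int = 50_000
    n_outcome: int = 50_000

    def validate(self) -> None:
        if self.n_variants < 1:
            raise SyntheticConfigError("n_variants must be >= 1")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise SyntheticConfigError("pleiotropy_frac must be in [0,1]")
        for name in ("pleiotropy_sd", "het_sd", "exposure_se_scale",
                     "outcome_se_scale"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if self.ld_block_size < 1 or not (0 <= self.ld_block_r2 <= 1):
            raise SyntheticConfigError("invalid LD block settings")


@dataclass
class GwasTruth:
    gamma: np.ndarray          # true exposure effects
    alpha: np.ndarray          # direct (pleiotropic) outcome effects
    pleiotropic: np.ndarray    # boolean mask
    beta_causal: float


def simulate_gwas_pair(
    cfg: GwasSimConfig,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, GwasTruth]:
    """Simulate an exposure/outcome GWAS pair under a causal model.

    Per variant k: observed exposure effect = gamma_k + N(0, se_x^2) with
    gamma_k sized to hit ``f_target`` on average; observed outcome effect =
    beta_causal*gamma_k + alpha_k (for pleiotropic variants)
    + N(0, se_y^2 + het_sd^2). The LD matrix is identity unless correlated
    blocks are requested.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_variants

    se_x = cfg.exposure_se_scale * rng.uniform(0.8, 1.2, k)
    se_y = cfg.outcome_se_scale * rng.uniform(0.8, 1.2, k)
    # per-variant F drawn around the target; signs random
    f_k = cfg.f_target * rng.uniform(0.7, 1.3, k)
    signs = rng.choice([-1.0, 1.0], k)
    gamma = signs * se_x * np.sqrt(f_k)

    pleio = np.zeros(k, bool)
    n_pleio = int(round(cfg.pleiotropy_frac * k))
    if n_pleio:
        pleio[rng.choice(k, n_pleio, replace=False)] = True
    alpha = np.zeros(k)
    if n_pleio and cfg.pleiotropy_sd > 0:
        draw = rng.normal(0.0, cfg.pleiotropy_sd, n_pleio)
        if not cfg.balanced:
            draw = np.abs(draw)  # directional pleiotropy
        alpha[pleio] = draw

    bx = gamma + rng.normal(0.0, se_x)
    tot_sd = np.sqrt(se_y ** 2 + cfg.het_sd ** 2)
    by = cfg.beta_causal * gamma + alpha + rng.normal(0.0, tot_sd)

    eaf = rng.uniform(0.1, 0.9, k)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), k)

    def _records(beta: np.ndarray, se: np.ndarray, n: int) -> list[VariantRecord]:
        pvals = 2 * stats.norm.sf(np.abs(beta / se))
        return [
            VariantRecord(
                variant_id=f"rs{i + 1}",
                effect_allele=_ALLELE_PAIRS[pair_idx[i]][0],
                other_allele=_ALLELE_PAIRS[pair_idx[i]][1],
                beta=float(beta[i]),
                se=float(se[i]),
                pval=float(max(pvals[i], 5e-324)),
                eaf=float(eaf[i]),
                n=n,
            )
            for i in range(k)
        ]

    exposure = SummaryStats("sim_exposure", _records(bx, se_x, cfg.n_exposure))
    outcome = SummaryStats("sim_outcome", _records(by, se_y, cfg.n_outcome))

    ids = [f"rs{i + 1}" for i in range(k)]
    if cfg.ld_block_size > 1 and cfg.ld_block_r2 > 0:
        vals = np.eye(k)
        for start in range(0, k, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, k)
            vals[start:stop, start:stop] = cfg.ld_block_r2
            np.fill_diagonal(vals[start:stop, start:stop], 1.0)
        ld = LDMatrix(ids, vals)
    else:
        ld = LDMatrix.identity(ids)

    return exposure, outcome, ld, GwasTruth(gamma, alpha, pleio, cfg.beta_causal)


# ---------------------------------------------------------------------------
# Per-gene cis-QTL catalogs
# ---------------------------------------------------------------------------


@dataclass
class QtlCatalogTruth:
    causal: dict[str, bool]
    theta: dict[str, float]  # true gene-on-outcome effect (log-odds)


def simulate_eqtl_catalog(
    n_genes: int,
    snps_per_gene: int,
    frac_causal: float,
    or_range: tuple[float, float] = (1.2, 2.0),
    seed: int = 0,
    qtl_se: float = 0.01,
    outcome_se: float = 0.02,
    f_target: float = 400.0,
    gene_ids: list[str] | None = None,
) -> tuple[dict[str, SummaryStats], SummaryStats, QtlCatalogTruth]:
    """Simulate per-gene QTL exposures plus one shared outcome table.

    A ``frac_causal`` subset of genes gets a non-null effect on the outcome
    with magnitude drawn from ``log(or_range)`` and random sign, so both
    OR>1 and OR<1 genes exist. Each gene's instruments are distinct variants,
    strong by construction.
    """
    if snps_per_gene < 1:
        raise SyntheticConfigError("snps_per_gene must be >= 1")
    if not (0 <= frac_causal <= 1):
        raise SyntheticConfigError("frac_causal must be in [0,1]")
    if gene_ids is not None and len(gene_ids) != n_genes:
        raise SyntheticConfigError("gene_ids length must equal n_genes")
    rng = np.random.default_rng(seed)
    lo, hi = math.log(or_range[0]), math.log(or_range[1])

    catalog: dict[str, SummaryStats] = {}
    outcome_records: list[VariantRecord] = []
    causal: dict[str, bool] = {}
    theta: dict[str, float] = {}

    n_causal = int(round(frac_causal * n_genes))
    causal_idx = set(rng.choice(n_genes, n_causal, replace=False).tolist())

    for g in range(n_genes):
        gene = gene_ids[g] if gene_ids is not None else f"G{g + 1:04d}"
        is_causal = g in causal_idx
        th = float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)) if is_causal else 0.0
        causal[gene], theta[gene] = is_causal, th

        records = []
        for s in range(snps_per_gene):
            vid = f"rs_g{g + 1:04d}_{s + 1}"
            se_x = qtl_se * float(rng.uniform(0.8, 1.2))
            gam = float(rng.choice([-1.0, 1.0])) * se_x * math.sqrt(
                f_target * float(rng.uniform(0.7, 1.3))
            )
            bx = gam + float(rng.normal(0.0, se_x))
            se_y = outcome_se * float(rng.uniform(0.8, 1.2))
            by = th * gam + float(rng.normal(0.0, se_y))
            pair = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
            eaf = float(rng.uniform(0.1, 0.9))
            px = float(max(2 * stats.norm.sf(abs(bx / se_x)), 5e-324))
            py = float(max(2 * stats.norm.sf(abs(by / se_y)), 5e-324))
            records.append(
                VariantRecord(vid, pair[0], pair[1], bx, se_x, px, eaf=eaf)
            )
            outcome_records.append(
                VariantRecord(vid, pair[0], pair[1], by, se_y, py, eaf=eaf)
            )
        catalog[gene] = SummaryStats(gene, records)

    outcome = SummaryStats("sim_outcome", outcome_records)
    return catalog, outcome, QtlCatalogTruth(causal, theta)


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TfSpec:
    tf_id: str
    target_ids: tuple[str, ...]
    effect_strength: float


@dataclass(frozen=True)
class CellSpec:
    cell_type: str
    signature_genes: tuple[str, ...]
    #: phenotype label -> additive abundance shift for signature genes
    abundance: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class ExprSimConfig:
    n_genes: int
    n_active: int
    n_inactive: int
    n_control: int = 0
    risk_gene_ids: tuple[str, ...] = ()
    protective_gene_ids: tuple[str, ...] = ()
    activity_effect: float = 0.0
    tf_specs: tuple[TfSpec, ...] = ()
    cell_specs: tuple[CellSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        risk, prot = set(self.risk_gene_ids), set(self.protective_gene_ids)
        tfs = {t.tf_id for t in self.tf_specs}
        if risk & prot:
            raise SyntheticConfigError("risk and protective gene sets overlap")
        if tfs & (risk | prot):
            raise SyntheticConfigError("TF ids overlap planted risk/protective sets")
        for t in self.tf_specs:
            if t.tf_id in t.target_ids:
                raise SyntheticConfigError(f"TF {t.tf_id} targets itself")
        if self.n_genes < 1 or self.n_active < 0 or self.n_inactive < 0:
            raise SyntheticConfigError("invalid counts")


@dataclass
class ExprTruth:
    risk_genes: tuple[str, ...]
    protective_genes: tuple[str, ...]
    tf_targets: dict[str, tuple[str, ...]]
    cell_signatures: dict[str, tuple[str, ...]]


def gene_names(n_genes: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n_genes)]


def simulate_expression(cfg: ExprSimConfig) -> tuple[ExpressionStudy, ExprTruth]:
    """Simulate a whole-blood-like expression study.

    Baseline values are i.i.d. normal (array-style continuous data). Risk
    genes are shifted up and protective genes down by ``activity_effect`` SD
    in active samples; TF targets are generated as
    tf_value*effect_strength + noise so the dependence is detectable by
    mutual information; cell signature genes get per-group abundance shifts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    gene_set = set(genes)
    for name, ids in (
        ("risk", cfg.risk_gene_ids),
        ("protective", cfg.protective_gene_ids),
    ):
        unknown = set(ids) - gene_set
        if unknown:
            raise SyntheticConfigError(f"{name} genes not in study: {sorted(unknown)[:5]}")

    labels = (
        ["active"] * cfg.n_active
        + ["inactive"] * cfg.n_inactive
        + ["control"] * cfg.n_control
    )
    samples = [f"S{i + 1:03d}" for i in range(len(labels))]
    phenotype = dict(zip(samples, labels))
    active_mask = np.array([lab == "active" for lab in labels])

    gidx = {g: i for i, g in enumerate(genes)}
    values = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, len(samples)))

    for g in cfg.risk_gene_ids:
        values[gidx[g], active_mask] += cfg.activity_effect
    for g in cfg.protective_gene_ids:
        values[gidx[g], active_mask] -= cfg.activity_effect

    for spec in cfg.cell_specs:
        shift = dict(spec.abundance)
        for g in spec.signature_genes:
            if g not in gidx:
                raise SyntheticConfigError(f"cell signature gene {g} not in study")
            row = gidx[g]
            for j, lab in enumerate(labels):
                values[row, j] += shift.get(lab, 0.0)

    # TF targets overwrite baseline: target = tf*strength + noise
    for spec in cfg.tf_specs:
        if spec.tf_id not in gidx:
            raise SyntheticConfigError(f"TF {spec.tf_id} not in study")
        tf_row = values[gidx[spec.tf_id]]
        for tgt in spec.target_ids:
            if tgt not in gidx:
                raise SyntheticConfigError(f"TF target {tgt} not in study")
            noise = rng.normal(0.0, cfg.noise_sd, len(samples))
            values[gidx[tgt]] = tf_row * spec.effect_strength + noise

    study = ExpressionStudy(genes, samples, values, phenotype)
    truth = ExprTruth(
        risk_genes=tuple(cfg.risk_gene_ids),
        protective_genes=tuple(cfg.protective_gene_ids),
        tf_targets={t.tf_id: tuple(t.target_ids) for t in cfg.tf_specs},
        cell_signatures={c.cell_type: tuple(c.signature_genes) for c in cfg.cell_specs},
    )
    return study, truth


# ---------------------------------------------------------------------------
# Full on-disk input bundle
# ---------------------------------------------------------------------------


def write_study_bundle(out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic input bundle shaped like the study:
    3 exposure / 2 outcome GWAS pairs, a per-gene QTL catalog with a shared
    outcome, and an expression study with active/inactive/control groups,
    planted risk genes, TF regulons and cell signatures. Returns the file
    manifest."""
    from pathlib import Path

    from .summary_io import (
        GeneSetCollection,
        write_expression,
        write_gmt,
        write_ld_matrix,
        write_summary_stats,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"exposures": [], "outcomes": []}

    # trait-level GWAS pairs: one simulated cohort per exposure, two outcomes
    for i in range(3):
        cfg = GwasSimConfig(
            n_variants=60, beta_causal=0.3, seed=seed + 101 * (i + 1)
        )
        exposure, outcome, ld, _ = simulate_gwas_pair(cfg)
        exposure = SummaryStats(f"exposure_{i + 1}", exposure.records)
        epath = out / f"exposure_{i + 1}.tsv"
        write_summary_stats(exposure, epath)
        manifest["exposures"].append(str(epath))
        if i < 2:
            outcome = SummaryStats(f"outcome_{i + 1}", outcome.records)
            opath = out / f"outcome_{i + 1}.tsv"
            write_summary_stats(outcome, opath)
            manifest["outcomes"].append(str(opath))
        if i == 0:
            write_ld_matrix(ld, out / "ld.tsv")
            manifest["ld"] = str(out / "ld.tsv")

    # per-gene QTL catalog sharing the expression study's gene namespace;
    # well-powered instruments so the screen recovers the planted signs
    genes = gene_names(300)
    catalog, qtl_outcome, truth = simulate_eqtl_catalog(
        n_genes=60, snps_per_gene=3, frac_causal=0.6, or_range=(1.5, 2.5),
        seed=seed + 7, qtl_se=0.002, outcome_se=0.009, gene_ids=genes[:60],
    )
    qtl_dir = out / "eqtls"
    qtl_dir.mkdir(exist_ok=True)
    for gene, ss in catalog.items():
        write_summary_stats(ss, qtl_dir / f"{gene}.tsv")
    write_summary_stats(qtl_outcome, qtl_dir / "outcome.tsv")
    manifest["eqtl_dir"] = str(qtl_dir)

    # expression study planting the catalog's true risk/protective genes
    risk = tuple(g for g in genes[:60] if truth.causal[g] and truth.theta[g] > 0)
    protective = tuple(g for g in genes[:60] if truth.causal[g] and truth.theta[g] < 0)
    tf = TfSpec(genes[100], tuple(genes[101:113]), 1.5)
    cell = CellSpec(
        "planted_cell", tuple(genes[120:132]),
        (("active", 1.0), ("inactive", 0.0), ("control", 0.0)),
    )
    cfg = ExprSimConfig(
        n_genes=300, n_active=12, n_inactive=12, n_control=10,
        risk_gene_ids=risk, protective_gene_ids=protective,
        activity_effect=1.0, tf_specs=(tf,), cell_specs=(cell,),
        seed=seed + 13,
    )
    study, _ = simulate_expression(cfg)
    write_expression(study, out / "expression.tsv", out / "phenotype.tsv")
    manifest["expression"] = str(out / "expression.tsv")
    manifest["phenotype"] = str(out / "phenotype.tsv")

    write_gmt(
        GeneSetCollection({
            "planted_pathway": list(risk),
            "null_pathway": list(genes[150:170]),
        }),
        out / "pathways.gmt",
    )
    manifest["pathway_gmt"] = str(out / "pathways.gmt")

    sig_sets = GeneSetCollection({
        "planted_cell_sig1": list(genes[120:126]),
        "planted_cell_sig2": list(genes[126:132]),
        "other_cell_sig1": list(genes[200:210]),
    })
    write_gmt(sig_sets, out / "signatures.gmt")
    with open(out / "cellmap.tsv", "w") as fh:
        fh.write("signature\tcell_type\n")
        fh.write("planted_cell_sig1\tplanted_cell\n")
        fh.write("planted_cell_sig2\tplanted_cell\n")
        fh.write("other_cell_sig1\tother_cell\n")
    manifest["signature_gmt"] = str(out / "signatures.gmt")
    manifest["signature_cellmap"] = str(out / "cellmap.tsv")

    (out / "tfs.txt").write_text(tf.tf_id + "\n")
    manifest["tf_list"] = str(out / "tfs.txt")
    return manifest
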