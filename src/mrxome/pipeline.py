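"""Config-driven orchestration of the three analysis arcs.

Arc 1 (trait MR): every configured exposure x outcome pair through
harmonization, instrument selection and the full MR report. Arc 2 (gene
arc): differential expression, per-gene QTL MR, risk/protective scores and
group comparison. Arc 3 (activity arc): regulons, regulon activity and
phenotype tests, pathway GSEA, cell scoring and selection, gene-cell
correlation. All randomness derives from one global seed via stage-name
hashing so individual stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell_scores as cs
from . import enrichment as en
from . import gene_screen as gs
from . import regulon as rg
from .instruments import InstrumentError, harmonize, select_instruments
from .mr import full_mr_report
from .summary_io import (
    LDMatrix,
    read_expression,
    read_gmt,
    read_ld_matrix,
    read_signatures,
    read_square_matrix,
    read_summary_stats,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    exposures: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    ld_matrix: str | None = None
    exclusion_list: str | None = None
    expression: str | None = None
    phenotype: str | None = None
    eqtl_dir: str | None = None
    pathway_gmt: str | None = None
    signature_gmt: str | None = None
    signature_cellmap: str | None = None
    spillover: str | None = None
    tf_list: str | None = None
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        cfg = cls(**raw)
        for name in ("exposures", "outcomes"):
            for p in getattr(cfg, name):
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} file missing: {p}")
        return cfg


def _load_exclusions(path: str | None) -> frozenset[str]:
    if not path:
        return frozenset()
    return frozenset(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )


def run_trait_mr(config: PipelineConfig) -> dict:
    """Full MR over the Cartesian product of exposures and outcomes.

    Per-pair failures are recorded and the run continues.
    """
    if not config.exposures or not config.outcomes:
        raise ValueError("need at least one exposure and one outcome")
    ld = read_ld_matrix(config.ld_matrix) if config.ld_matrix else None
    exclusions = _load_exclusions(config.exclusion_list)
    th = config.thresholds
    rows, details = [], {}
    for epath in config.exposures:
        exposure = read_summary_stats(epath)
        for opath in config.outcomes:
            outcome = read_summary_stats(opath)
            key = f"{exposure.trait_id}__{outcome.trait_id}"
            try:
                h = harmonize(exposure, outcome)
                pair_ld = ld if ld is not None else LDMatrix.identity(h.variant_ids())
                sel = select_instruments(
                    h, pair_ld, exclusion_list=exclusions,
                    **{k: th[k] for k in (
                        "p_primary", "p_fallback", "r2_primary", "r2_fallback",
                        "min_iv", "p_outcome_max", "f_min") if k in th},
                )
                primary, pleio, loo = full_mr_report(
                    sel, seed=stage_seed(config.seed, f"trait_mr:{key}")
                )
            except (InstrumentError, ValueError) as exc:
                rows.append(dict(exposure=exposure.trait_id, outcome=outcome.trait_id,
                                 status="failed", error=str(exc)))
                continue
            rows.append(dict(
                exposure=exposure.trait_id, outcome=outcome.trait_id, status="ok",
                method=primary.method, n_snps=primary.n_snps, pval=primary.pval,
                or_=primary.or_, ci_low=primary.ci_low, ci_high=primary.ci_high,
            ))
            details[key] = dict(
                primary=primary.to_dict(), pleiotropy=pleio.to_dict(),
                leave_one_out=loo.to_dict() if loo else None,
                audit=sel.audit, notes=sel.notes,
            )
    report = dict(table=rows, details=details)
    _persist(config, "trait_mr", report, table_rows=rows)
    return report


def run_gene_arc(config: PipelineConfig) -> dict:
    """DE -> per-gene QTL MR -> risk/protective scores -> group comparison."""
    study = read_expression(config.expression, config.phenotype)
    de = gs.moderated_de(study, contrast=("active", "control"))
    catalog = {
        p.stem: read_summary_stats(p)
        for p in sorted(Path(config.eqtl_dir).glob("*.tsv"))
        if p.stem != "outcome"
    }
    outcome = read_summary_stats(Path(config.eqtl_dir) / "outcome.tsv")
    table = gs.qtl_mr_screen(catalog, outcome)
    annotated = gs.intersect_with_de(table, de)
    risk_scores, prot_scores = en.risk_protective_scores(study, table)
    comparisons = en.compare_groups(risk_scores, study) + en.compare_groups(
        prot_scores, study
    )
    report = dict(
        n_de_genes=int(sum(d.adj_pval < 0.05 for d in de)),
        gene_table=table.rows.to_dict(orient="records"),
        crosstab=annotated.attrs["crosstab"],
        comparisons=[c.__dict__ for c in comparisons],
    )
    _persist(config, "gene_arc", report)
    return report


def run_activity_arc(config: PipelineConfig) -> dict:
    """Regulons + activity + phenotype tests, pathway GSEA, cell selection."""
    study = read_expression(config.expression, config.phenotype)
    seed = config.seed
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    report: dict = {}

    if config.tf_list:
        tfs = [t for t in Path(config.tf_list).read_text().split() if t]
        regs = rg.infer_regulons(
            study, tfs, seed=stage_seed(seed, "regulon_infer")
        )
        nonempty = [r for r in regs if r.targets]
        report["regulons"] = {
            r.tf_id: {g: {"mi": mi, "sign": s} for g, (mi, s) in r.targets.items()}
            for r in regs
        }
        if nonempty:
            activity = rg.regulon_activity(study, nonempty)
            tests = rg.regulon_phenotype_test(
                study, nonempty, tails="two",
                seed=stage_seed(seed, "regulon_test"),
            )
            report["phenotype_tests"] = [t.__dict__ for t in tests]
            pd.DataFrame(
                activity.values, index=activity.tf_ids, columns=activity.sample_ids
            ).to_csv(Path(config.out_dir) / "regulon_activity.tsv", sep="\t")

    if config.pathway_gmt:
        pathways = read_gmt(config.pathway_gmt)
        gsea = en.gsea_two_group(
            study, pathways, seed=stage_seed(seed, "gsea")
        )
        report["gsea"] = [r.__dict__ for r in gsea]

    if config.signature_gmt and config.signature_cellmap:
        sigs = read_signatures(config.signature_gmt, config.signature_cellmap)
        raw = cs.score_cell_types(study, sigs)
        scores = raw
        if config.spillover:
            scores = cs.spillover_correct(raw, read_square_matrix(config.spillover))
        screened = cs.univariate_screen(scores, study.phenotype)
        report["cell_screen"] = screened
        try:
            sel = cs.lasso_select(
                scores, study.phenotype, screened=screened,
                seed=stage_seed(seed, "lasso"),
            )
            report["cell_selection"] = dict(
                selected=sel.selected, lambda_chosen=sel.lambda_chosen
            )
        except cs.CellScoreError as exc:
            report["cell_selection"] = dict(error=str(exc))
        risk_path = Path(config.out_dir) / "gene_arc.json"
        if risk_path.exists():
            gene_report = json.loads(risk_path.read_text())
            risk = [r["gene_id"] for r in gene_report["gene_table"] if r["label"] == "risk"]
            risk = [g for g in risk if g in set(study.gene_ids)]
            if risk:
                _, pmat, counts = cs.correlate_genes_cells(study, scores, risk)
                report["gene_cell_significant_counts"] = counts

    _persist(config, "activity_arc", report)
    return report


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _persist(config: PipelineConfig, name: str, report: dict, table_rows=None) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{name}.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, cls=_JsonEncoder)
    )
    if table_rows:
        pd.DataFrame(table_rows).to_csv(out / f"{name}.tsv", sep="\t", index=False)
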