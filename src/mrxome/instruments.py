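"""Instrumental-variable selection and harmonization.

Pipeline: harmonize exposure/outcome tables onto a common effect allele,
drop outcome-associated variants, threshold on exposure p-value with LD
clumping (with a fallback tier when too few instruments survive), filter
weak instruments by F statistic, and apply a confounder exclusion list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .summary_io import LDMatrix, SummaryStats

logger = logging.getLogger(__name__)

#: eaf window in which a palindromic variant's strand cannot be resolved
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


class InstrumentError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure and outcome effects for one variant on a shared effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    pval_exposure: float
    pval_outcome: float

    @property
    def f_stat(self) -> float:
        return f_statistic(self.beta_exposure, self.se_exposure)


@dataclass
class HarmonizedSet:
    exposure_id: str
    outcome_id: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    #: per-stage drop counts, in pipeline order
    audit: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, (beta/se)^2."""
    if se <= 0:
        raise InstrumentError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def harmonize(exposure: SummaryStats, outcome: SummaryStats) -> HarmonizedSet:
    """Merge two summary tables on variant id onto the exposure's effect allele.

    Outcome rows whose alleles are swapped relative to the exposure get their
    beta negated (and eaf complemented, implicitly). Palindromic variants
    (A/T, C/G) are dropped when either eaf is missing or inside the ambiguity
    window. Variants with incompatible alleles are dropped and audited.
    """
    out_by_id = outcome.by_id()
    records: list[HarmonizedRecord] = []
    audit = {"absent_from_outcome": 0, "allele_mismatch": 0, "palindromic_ambiguous": 0}
    lo, hi = PALINDROMIC_EAF_WINDOW
    for exp in exposure.records:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            audit["absent_from_outcome"] += 1
            continue
        if exp.is_palindromic:
            eafs = (exp.eaf, out.eaf)
            if any(e is None or lo <= e <= hi for e in eafs):
                audit["palindromic_ambiguous"] += 1
                continue
        if (exp.effect_allele, exp.other_allele) == (out.effect_allele, out.other_allele):
            beta_out = out.beta
        elif (exp.effect_allele, exp.other_allele) == (out.other_allele, out.effect_allele):
            beta_out = -out.beta
        else:
            audit["allele_mismatch"] += 1
            continue
        records.append(
            HarmonizedRecord(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                pval_exposure=exp.pval,
                pval_outcome=out.pval,
            )
        )
    if not records:
        raise InstrumentError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        records=records,
        audit=audit,
    )


def clump(candidates: HarmonizedSet, ld: LDMatrix, r2_max: float) -> HarmonizedSet:
    """Greedy LD clumping.

    Repeatedly keep the remaining variant with the lowest exposure p-value
    (ties broken by variant id) and discard everything with r^2 above
    ``r2_max`` to it. Output order is deterministic and independent of input
    row order.
    """
    pool = sorted(candidates.records, key=lambda r: (r.pval_exposure, r.variant_id))
    kept: list[HarmonizedRecord] = []
    while pool:
        lead = pool.pop(0)
        kept.append(lead)
        pool = [r for r in pool if ld.r2(lead.variant_id, r.variant_id) <= r2_max]
    return replace(
        candidates,
        records=kept,
        audit={**candidates.audit, "clumped": len(candidates.records) - len(kept)},
    )


def select_instruments(
    h: HarmonizedSet,
    ld: LDMatrix,
    p_primary: float = 5e-8,
    p_fallback: float = 5e-6,
    r2_primary: float = 0.001,
    r2_fallback: float = 0.01,
    min_iv: int = 20,
    p_outcome_max: float = 5e-6,
    f_min: float = 10.0,
    exclusion_list: frozenset[str] | set[str] = frozenset(),
    allow_fallback: bool = True,
) -> HarmonizedSet:
    """Full instrument selection pipeline, in fixed order.

    1. drop variants directly associated with the outcome
       (``pval_outcome < p_outcome_max``) — removed first;
    2. exposure p threshold + LD clumping at the primary tier;
    3. if fewer than ``min_iv`` survive (and fallback allowed), redo step 2
       at the fallback tier;
    4. drop weak instruments with F below ``f_min``;
    5. drop confounder-associated variants from the exclusion list.
    """
    audit: dict[str, int] = {}
    notes = list(h.notes)
    n0 = len(h.records)

    stage1 = [r for r in h.records if r.pval_outcome >= p_outcome_max]
    audit["outcome_associated"] = n0 - len(stage1)

    def tier(p_max: float, r2_max: float) -> tuple[list[HarmonizedRecord], int]:
        passing = [r for r in stage1 if r.pval_exposure < p_max]
        n_below_threshold = len(stage1) - len(passing)
        tmp = HarmonizedSet(h.exposure_id, h.outcome_id, passing)
        clumped = clump(tmp, ld, r2_max)
        return clumped.records, n_below_threshold

    stage2, n_thresh = tier(p_primary, r2_primary)
    if allow_fallback and len(stage2) < min_iv:
        stage2, n_thresh = tier(p_fallback, r2_fallback)
        notes.append(
            f"fallback engaged: p<{p_fallback:g}, r2<{r2_fallback:g} "
            f"(primary tier yielded <{min_iv} instruments)"
        )
    audit["below_exposure_threshold"] = n_thresh
    audit["clumped"] = len(stage1) - n_thresh - len(stage2)

    stage3 = [r for r in stage2 if r.f_stat >= f_min]
    audit["weak_instrument"] = len(stage2) - len(stage3)

    stage4 = [r for r in stage3 if r.variant_id not in exclusion_list]
    audit["confounder_excluded"] = len(stage3) - len(stage4)

    if not stage4:
        raise InstrumentError(
            "no instruments survived selection; consider relaxing thresholds "
            f"(audit: {audit})"
        )
    return HarmonizedSet(
        exposure_id=h.exposure_id,
        outcome_id=h.outcome_id,
        records=stage4,
        audit=audit,
        notes=notes,
    )
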