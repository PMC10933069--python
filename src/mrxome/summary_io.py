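"""Readers and writers for every on-disk artifact the pipeline consumes.

All formats are plain text: summary statistics as TSV with dialect-mapped
headers, gene sets and signatures as GMT, expression matrices as TSV
(genes x samples), LD and spillover matrices as labelled square TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: sentinel used on disk for missing optional numeric fields
_NA = "NA"


class SummaryIOError(ValueError):
    """Raised for malformed or unreadable pipeline artifacts."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One variant's association with one trait.

    ``beta`` is always stored on the log-odds scale for binary traits; odds
    ratios are derived at reporting time as ``exp(beta)``.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> str | None:
        """Return a reason string if the record is invalid, else ``None``."""
        if self.effect_allele not in _VALID_ALLELES:
            return f"bad effect allele {self.effect_allele!r}"
        if self.other_allele not in _VALID_ALLELES:
            return f"bad other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "effect allele equals other allele"
        if not (self.se > 0 and math.isfinite(self.se)):
            return f"se not positive ({self.se})"
        if not (0 < self.pval <= 1):
            return f"pval outside (0,1] ({self.pval})"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return f"eaf outside (0,1) ({self.eaf})"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStats:
    """One trait's per-variant association table."""

    trait_id: str
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({v for v in ids if ids.count(v) > 1})
            raise SummaryIOError(
                f"duplicate variant ids in {self.trait_id}: {dup[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantRecord]:
        return {r.variant_id: r for r in self.records}


@dataclass
class LDMatrix:
    """Pairwise squared correlations between variants, unit diagonal."""

    variant_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.variant_ids)
        if v.shape != (n, n):
            raise SummaryIOError(f"LD matrix shape {v.shape} != ({n},{n})")
        if not np.allclose(v, v.T, atol=1e-8):
            raise SummaryIOError("LD matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise SummaryIOError("LD matrix diagonal not 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise SummaryIOError("LD r^2 values outside [0,1]")
        self.values = v
        self._index = {vid: i for i, vid in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants; identity assumed (and
        logged once) when either variant is absent from the matrix."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            logger.debug("LD lookup miss for (%s, %s); assuming r2=0", a, b)
            return 1.0 if a == b else 0.0
        return float(self.values[ia, ib])

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))


@dataclass
class ExpressionStudy:
    """Genes x samples expression matrix with phenotype labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: dict[str, str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise SummaryIOError(
                f"expression shape {v.shape} != "
                f"({len(self.gene_ids)},{len(self.sample_ids)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SummaryIOError("duplicate gene ids")
        if not np.all(np.isfinite(v)):
            raise SummaryIOError("expression matrix contains non-finite values")
        missing = [s for s in self.sample_ids if s not in self.phenotype]
        if missing:
            raise SummaryIOError(f"samples without phenotype label: {missing[:5]}")
        self.values = v
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def samples_with(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype[s] == label]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionStudy":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionStudy(
            list(gene_ids), list(self.sample_ids), self.values[idx], dict(self.phenotype)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT on disk)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise SummaryIOError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise SummaryIOError(f"gene set {name!r} has duplicate genes")


@dataclass
class SignatureCollection:
    """Cell-type signatures: each signature belongs to exactly one cell type."""

    signatures: dict[str, list[str]]
    cell_of: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.signatures) - set(self.cell_of)
        if missing:
            raise SummaryIOError(f"signatures without cell type: {sorted(missing)[:5]}")

    def by_cell_type(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sig in self.signatures:
            out.setdefault(self.cell_of[sig], []).append(sig)
        return out


# ---------------------------------------------------------------------------
# Summary-statistics TSV
# ---------------------------------------------------------------------------

#: canonical column names -> per-dialect header names
DIALECTS: dict[str, dict[str, str]] = {
    "plain": {
        "variant_id": "variant_id",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "pval",
        "n": "n",
    },
    "ieu": {
        "variant_id": "SNP",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "pval",
        "n": "samplesize",
    },
}

_REQUIRED = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


def read_summary_stats(
    path: str | Path,
    dialect: str | Mapping[str, str] = "plain",
    trait_id: str | None = None,
    or_scale: bool = False,
) -> SummaryStats:
    """Read a summary-statistics TSV.

    Rows failing validation are dropped with a logged count. With
    ``or_scale=True`` the beta column holds odds ratios and is converted to
    log-odds on load.
    """
    path = Path(path)
    colmap = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for canon in _REQUIRED:
        col = colmap.get(canon, canon)
        if col not in df.columns:
            raise SummaryIOError(f"missing required column {col!r} in {path}")

    def _col(canon: str) -> pd.Series | None:
        col = colmap.get(canon, canon)
        return df[col] if col in df.columns else None

    records: list[VariantRecord] = []
    n_dropped = 0
    eaf_s, n_s = _col("eaf"), _col("n")
    for i in range(len(df)):
        try:
            beta = float(_col("beta").iloc[i])
            if or_scale:
                beta = math.log(beta)
            eaf_raw = None if eaf_s is None else eaf_s.iloc[i]
            n_raw = None if n_s is None else n_s.iloc[i]
            rec = VariantRecord(
                variant_id=str(_col("variant_id").iloc[i]),
                effect_allele=str(_col("effect_allele").iloc[i]).upper(),
                other_allele=str(_col("other_allele").iloc[i]).upper(),
                beta=beta,
                se=float(_col("se").iloc[i]),
                pval=float(_col("pval").iloc[i]),
                eaf=None if eaf_raw in (None, _NA) or pd.isna(eaf_raw) else float(eaf_raw),
                n=None if n_raw in (None, _NA) or pd.isna(n_raw) else int(float(n_raw)),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.validate() is not None:
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path, n_dropped)
    if not records:
        raise SummaryIOError(f"no valid rows in {path}")
    return SummaryStats(trait_id=trait_id or path.stem, records=records)


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a plain-dialect TSV; round-trips exactly through the reader."""
    if not stats.records:
        raise SummaryIOError("refusing to write empty summary statistics")
    rows = []
    for r in stats.records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": _NA if r.eaf is None else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.pval),
                "n": _NA if r.n is None else str(r.n),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets / signatures
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SummaryIOError(f"{path}: line {lineno} has <3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s line %d: de-duplicated %d genes in set %s",
                    path, lineno, len(genes) - len(deduped), name,
                )
            sets[name] = deduped
            descriptions[name] = desc
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_signatures(gmt_path: str | Path, cellmap_path: str | Path) -> SignatureCollection:
    """Signatures as GMT plus a two-column TSV mapping signature -> cell type."""
    sets = read_gmt(gmt_path)
    cellmap = pd.read_csv(cellmap_path, sep="\t", dtype=str)
    if cellmap.shape[1] < 2:
        raise SummaryIOError("cell map must have two columns: signature, cell_type")
    cell_of = dict(zip(cellmap.iloc[:, 0], cellmap.iloc[:, 1]))
    return SignatureCollection(signatures=dict(sets.sets), cell_of=cell_of)


# ---------------------------------------------------------------------------
# Expression, LD and spillover matrices
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, phenotype_path: str | Path) -> ExpressionStudy:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = np.argwhere(~np.isfinite(df.to_numpy(dtype=float, na_value=np.nan)))
    if bad.size:
        g, s = bad[0]
        raise SummaryIOError(
            f"non-numeric/missing cell at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    pheno_df = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    phenotype = dict(zip(pheno_df.iloc[:, 0], pheno_df.iloc[:, 1]))
    matrix_samples, label_samples = set(df.columns), set(phenotype)
    if matrix_samples != label_samples:
        raise SummaryIOError(
            f"sample mismatch: only-in-matrix={sorted(matrix_samples - label_samples)[:5]} "
            f"only-in-labels={sorted(label_samples - matrix_samples)[:5]}"
        )
    return ExpressionStudy(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        phenotype=phenotype,
    )


def write_expression(
    study: ExpressionStudy, path: str | Path, phenotype_path: str | Path
) -> None:
    pd.DataFrame(study.values, index=study.gene_ids, columns=study.sample_ids).to_csv(
        path, sep="\t"
    )
    pd.DataFrame(
        {"sample_id": study.sample_ids,
         "phenotype": [study.phenotype[s] for s in study.sample_ids]}
    ).to_csv(phenotype_path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SummaryIOError("LD matrix row and column ids differ")
    return LDMatrix(variant_ids=[str(v) for v in df.index], values=df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.values, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    """Labelled square matrix (e.g. spillover, cell x cell)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SummaryIOError(f"matrix in {path} is not square: {df.shape}")
    return df.astype(float)
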