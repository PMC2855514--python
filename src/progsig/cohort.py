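"""Cohort data model and readers/writers.

A cohort couples a log-scale expression matrix (genes x samples) with a
per-sample phenotype table carrying the extreme-design outcome (lethal /
indolent / excluded), follow-up, age, grouped Gleason score and ERG
rearrangement status.  Readers cover GCT 1.2, plain TSV matrices, a fixed
phenotype TSV schema and the GEO series-matrix text dialect.

Expression values are consumed as-is: they are assumed already log-scale
and normalized, and missing entries are explicit (NaN), never sentinel
numbers.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_LEVELS = ("lethal", "indolent", "excluded")
GLEASON_LEVELS = ("G4_6", "G7", "G8_10", "unknown")
ERG_LEVELS = ("rearranged", "negative", "unknown")

#: columns a phenotype TSV must provide
PHENOTYPE_COLUMNS = (
    "sample_id",
    "outcome",
    "death_from_cancer",
    "followup_years",
    "age_at_diagnosis",
    "gleason_category",
    "erg_status",
)
_MANDATORY_COLUMNS = ("sample_id", "outcome", "death_from_cancer", "followup_years")

#: text precision for round-trippable expression output
FLOAT_DIGITS = 10


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


class SchemaError(ValueError):
    """A table is missing mandatory structure or violates an invariant."""


class AlignmentError(ValueError):
    """Expression and phenotype share no samples."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples log-intensity table; missing entries are NaN."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids, float

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if arr.size and np.isinf(arr).any():
            raise SchemaError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def drop_missing_genes(self) -> "ExpressionMatrix":
        """Drop genes with any missing value (logged), for operations that
        cannot tolerate missingness (t-tests, distances)."""
        mask = self.values.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.warning("dropping %d genes with missing values", n_dropped)
        return ExpressionMatrix(self.values.loc[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)])


@dataclass
class PhenotypeTable:
    """Per-sample clinical/outcome records with fixed categorical levels."""

    table: pd.DataFrame  # one row per sample, columns PHENOTYPE_COLUMNS

    def __post_init__(self) -> None:
        df = self.table
        for col in PHENOTYPE_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"phenotype table missing column {col!r}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate sample_id: {dup.iloc[0]!r}")
        for col, levels in (
            ("outcome", OUTCOME_LEVELS),
            ("gleason_category", GLEASON_LEVELS),
            ("erg_status", ERG_LEVELS),
        ):
            bad = set(df[col]) - set(levels)
            if bad:
                raise SchemaError(f"unknown {col} level(s): {sorted(bad)}")
        lethal = df["outcome"] == "lethal"
        if len(df) and not df.loc[lethal, "death_from_cancer"].astype(bool).all():
            raise SchemaError("outcome=lethal requires death_from_cancer=True")
        fup = df["followup_years"].to_numpy(dtype=float)
        if len(df) and np.nanmin(fup) < 0:
            raise SchemaError("followup_years must be non-negative")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def outcomes(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.table.set_index("sample_id")["outcome"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        indexed = self.table.set_index("sample_id", drop=False)
        return PhenotypeTable(indexed.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class CohortDataset:
    """An expression matrix plus its phenotype; alignment is explicit."""

    expression: ExpressionMatrix
    phenotype: PhenotypeTable
    annotations: pd.DataFrame | None = field(default=None)

    def require_aligned(self) -> None:
        if set(self.expression.sample_ids) != set(self.phenotype.sample_ids):
            raise AlignmentError("expression and phenotype sample sets differ")

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortDataset":
        return CohortDataset(
            self.expression.subset_samples(sample_ids),
            self.phenotype.subset(sample_ids),
        )


# ---------------------------------------------------------------------------
# expression readers / writers

def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from GCT 1.2 or a plain TSV.

    TSV layout: first column gene ids, header row sample ids.  Empty cells
    and ``NA`` become missing values; any other non-numeric cell is a parse
    error naming its coordinates.
    """
    path = Path(path)
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = lines[0].split("\t")
        sample_ids = header[1:]
        return _parse_matrix_rows(lines[1:], sample_ids, path, gene_col=0)
    raise ValueError(f"unknown expression format {format!r}")


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3 or not lines[0].startswith("#1.2"):
        raise FormatError(f"{path}: not a GCT 1.2 file (missing '#1.2' header)")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except ValueError as exc:
        raise FormatError(f"{path}: bad GCT dimensions line: {lines[1]!r}") from exc
    header = lines[2].split("\t")
    sample_ids = header[2:]
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes or len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: GCT header declares {n_genes}x{n_samples} but file has "
            f"{len(data_lines)} data rows and {len(sample_ids)} sample columns"
        )
    return _parse_matrix_rows(data_lines, sample_ids, path, gene_col=0, skip_cols=2)


def _parse_matrix_rows(
    lines: list[str],
    sample_ids: list[str],
    path: Path,
    gene_col: int,
    skip_cols: int | None = None,
) -> ExpressionMatrix:
    if skip_cols is None:
        skip_cols = gene_col + 1
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(lines):
        if not ln.strip():
            continue
        cells = ln.split("\t")
        gene_ids.append(cells[gene_col])
        vals = cells[skip_cols:]
        if len(vals) != len(sample_ids):
            raise FormatError(
                f"{path}: row {i + 1} has {len(vals)} values, expected {len(sample_ids)}"
            )
        row: list[float] = []
        for j, cell in enumerate(vals):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at data row {i + 1}, "
                    f"column {sample_ids[j]!r}"
                ) from exc
        rows.append(row)
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(values)


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    fmt = f"%.{FLOAT_DIGITS}g"

    def cell(v: float) -> str:
        return "" if np.isnan(v) else fmt % v

    with open(path, "w", encoding="utf-8") as fh:
        if format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for gid, row in zip(matrix.gene_ids, matrix.values.to_numpy()):
                fh.write(gid + "\tna\t" + "\t".join(cell(v) for v in row) + "\n")
        elif format == "tsv":
            fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
            for gid, row in zip(matrix.gene_ids, matrix.values.to_numpy()):
                fh.write(gid + "\t" + "\t".join(cell(v) for v in row) + "\n")
        else:
            raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# phenotype reader / writer

_GLEASON_SCORE_MAP = {  # numeric Gleason scores grouped 4-6 / 7 / 8-10
    **{str(s): "G4_6" for s in range(2, 7)},
    "7": "G7",
    **{str(s): "G8_10" for s in range(8, 11)},
}

_TRUTHY = {"true", "1", "yes", "y"}
_FALSY = {"false", "0", "no", "n"}


def _parse_gleason(raw: str) -> str:
    raw = raw.strip()
    if raw in GLEASON_LEVELS:
        return raw
    if raw in _GLEASON_SCORE_MAP:
        return _GLEASON_SCORE_MAP[raw]
    return ""


def read_phenotype(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV with the documented header.

    Mandatory columns: sample_id, outcome, death_from_cancer, followup_years.
    Unparsable optional fields fall back to the explicit ``unknown`` level
    with a logged warning count; unknown levels in mandatory categoricals
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    n_warn = 0
    records: list[dict] = []
    for idx, row in df.iterrows():
        outcome = row["outcome"].strip().lower()
        if outcome not in OUTCOME_LEVELS:
            raise SchemaError(f"{path}: row {idx}: unknown outcome {row['outcome']!r}")
        dfc_raw = row["death_from_cancer"].strip().lower()
        if dfc_raw in _TRUTHY:
            dfc = True
        elif dfc_raw in _FALSY:
            dfc = False
        else:
            raise SchemaError(
                f"{path}: row {idx}: unparsable death_from_cancer {dfc_raw!r}"
            )
        try:
            fup = float(row["followup_years"])
        except ValueError as exc:
            raise SchemaError(
                f"{path}: row {idx}: unparsable followup_years"
            ) from exc
        age_raw = row.get("age_at_diagnosis", "")
        try:
            age = float(age_raw)
        except (TypeError, ValueError):
            age = np.nan
            n_warn += 1
        gleason = _parse_gleason(row.get("gleason_category", ""))
        if not gleason:
            gleason = "unknown"
            n_warn += 1
        erg = row.get("erg_status", "").strip().lower()
        if erg not in ERG_LEVELS:
            erg = "unknown"
            n_warn += 1
        records.append(
            dict(
                sample_id=row["sample_id"],
                outcome=outcome,
                death_from_cancer=dfc,
                followup_years=fup,
                age_at_diagnosis=age,
                gleason_category=gleason,
                erg_status=erg,
            )
        )
    if n_warn:
        logger.warning("%s: %d optional field(s) fell back to unknown", path, n_warn)
    return PhenotypeTable(pd.DataFrame(records, columns=list(PHENOTYPE_COLUMNS)))


def write_phenotype(pheno: PhenotypeTable, path: str | Path) -> None:
    df = pheno.table.copy()
    df["death_from_cancer"] = df["death_from_cancer"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{FLOAT_DIGITS}g")


# ---------------------------------------------------------------------------
# GEO series-matrix importer

#: default mapping from GEO characteristic keys to phenotype fields; the
#: deposited record's labels are not standardized, so this ships editable.
DEFAULT_GEO_KEY_MAPPING: Mapping[str, str] = {
    "outcome": "outcome",
    "status": "outcome",
    "followup": "followup_years",
    "fup": "followup_years",
    "followup_years": "followup_years",
    "fup_year": "followup_years",
    "age": "age_at_diagnosis",
    "age_at_diagnosis": "age_at_diagnosis",
    "gleason": "gleason_category",
    "gleason_score": "gleason_category",
    "gleason_category": "gleason_category",
    "erg": "erg_status",
    "erg_status": "erg_status",
    "erg_fusion": "erg_status",
}

_OUTCOME_SYNONYMS = {
    "lethal": "lethal",
    "indolent": "indolent",
    "excluded": "excluded",
    "dead": "lethal",
    "alive": "indolent",
}

_ERG_SYNONYMS = {
    "rearranged": "rearranged",
    "positive": "rearranged",
    "fusion": "rearranged",
    "negative": "negative",
    "unknown": "unknown",
    "na": "unknown",
}


def import_geo_series_matrix(
    path: str | Path,
    key_mapping: Mapping[str, str] | None = None,
) -> CohortDataset:
    """Import a GEO series-matrix text file (optionally gzipped).

    Sample characteristics (``key: value`` entries) are mapped onto
    phenotype fields via ``key_mapping`` (case-folded keys); unmapped keys
    are retained as opaque annotations.  Samples lacking a mapped outcome
    get ``outcome=excluded``.
    """
    path = Path(path)
    mapping = {k.lower(): v for k, v in (key_mapping or DEFAULT_GEO_KEY_MAPPING).items()}
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:  # type: ignore[operator]
        lines = fh.read().splitlines()

    meta: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    for ln in lines:
        if ln.startswith("!series_matrix_table_begin"):
            in_table, saw_begin = True, True
            continue
        if ln.startswith("!series_matrix_table_end"):
            in_table, saw_end = False, True
            continue
        if in_table:
            if ln.strip():
                table_lines.append(ln)
        elif ln.startswith("!"):
            key, _, rest = ln[1:].partition("\t")
            meta.setdefault(key, []).append(
                [c.strip().strip('"') for c in rest.split("\t")]
            )
    if not (saw_begin and saw_end):
        raise FormatError(f"{path}: missing series_matrix_table_begin/end delimiters")
    if not table_lines:
        raise FormatError(f"{path}: empty expression table")

    header = [c.strip('"') for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    expr = _parse_matrix_rows(table_lines[1:], sample_ids, path, gene_col=0)
    expr = ExpressionMatrix(
        pd.DataFrame(
            expr.values.to_numpy(),
            index=[g.strip('"') for g in expr.gene_ids],
            columns=sample_ids,
        )
    )

    fields: dict[str, dict[str, str]] = {sid: {} for sid in sample_ids}
    annotations: dict[str, dict[str, str]] = {sid: {} for sid in sample_ids}
    char_rows = [
        row for key, rows in meta.items()
        if key.lower().startswith("sample_characteristics") for row in rows
    ]
    for row in char_rows:
        for sid, cell in zip(sample_ids, row):
            if not cell:
                continue
            key, sep, value = cell.partition(":")
            if not sep:
                continue
            key, value = key.strip().lower(), value.strip()
            target = mapping.get(key)
            if target:
                fields[sid][target] = value
            else:
                annotations[sid][key] = value
    if not char_rows:
        logger.warning("%s: no sample characteristics lines found", path)

    records = []
    for sid in sample_ids:
        f = fields[sid]
        outcome = _OUTCOME_SYNONYMS.get(f.get("outcome", "").strip().lower(), "excluded")
        try:
            fup = float(f.get("followup_years", "nan"))
        except ValueError:
            fup = np.nan
        try:
            age = float(f.get("age_at_diagnosis", "nan"))
        except ValueError:
            age = np.nan
        gleason = _parse_gleason(f.get("gleason_category", "")) or "unknown"
        erg = _ERG_SYNONYMS.get(f.get("erg_status", "").strip().lower(), "unknown")
        records.append(
            dict(
                sample_id=sid,
                outcome=outcome,
                death_from_cancer=outcome == "lethal",
                followup_years=0.0 if np.isnan(fup) else fup,
                age_at_diagnosis=age,
                gleason_category=gleason,
                erg_status=erg,
            )
        )
    pheno = PhenotypeTable(pd.DataFrame(records, columns=list(PHENOTYPE_COLUMNS)))
    ann = pd.DataFrame.from_dict(annotations, orient="index")
    return CohortDataset(expr, pheno, annotations=ann if ann.size else None)


# ---------------------------------------------------------------------------
# alignment

def align(dataset: CohortDataset) -> tuple[CohortDataset, dict[str, list[str]]]:
    """Restrict both tables to their shared samples, in expression order.

    Returns the aligned dataset and a report of dropped ids per side.
    """
    expr_ids = dataset.expression.sample_ids
    pheno_ids = set(dataset.phenotype.sample_ids)
    common = [s for s in expr_ids if s in pheno_ids]
    if not common:
        raise AlignmentError("no samples shared between expression and phenotype")
    dropped = {
        "expression_only": [s for s in expr_ids if s not in pheno_ids],
        "phenotype_only": [s for s in dataset.phenotype.sample_ids if s not in set(expr_ids)],
    }
    if dropped["expression_only"] or dropped["phenotype_only"]:
        logger.info(
            "align dropped %d expression-only and %d phenotype-only samples",
            len(dropped["expression_only"]), len(dropped["phenotype_only"]),
        )
    aligned = CohortDataset(
        dataset.expression.subset_samples(common),
        dataset.phenotype.subset(common),
        annotations=dataset.annotations,
    )
    return aligned, dropped
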