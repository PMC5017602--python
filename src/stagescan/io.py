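"""Reading, writing and validation of expression matrices, sample annotations
and GMT gene-set files.

All tabular formats are tab-delimited UTF-8.  Expression values are assumed to
be on log2 scale already; :func:`read_expression_matrix` can apply a
``log2(x + 1)`` transform for raw-scale input.  Lines starting with ``#`` are
treated as comments in all TSV readers (pipeline outputs carry a config-hash
comment line).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "OutcomeRecord",
    "SampleAnnotation",
    "MatrixParseError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
]


class MatrixParseError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Parameters
    ----------
    data
        DataFrame with gene ids as the index and sample ids as the columns.
        Ids must be unique and every value finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise MatrixParseError("empty expression matrix")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MatrixParseError("non-numeric values in expression matrix")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixParseError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples (order preserved)."""
        data = self.data
        if genes is not None:
            data = data.loc[list(genes)]
        if samples is not None:
            data = data[list(samples)]
        return ExpressionMatrix(data.copy())


@dataclass
class OutcomeRecord:
    """Clinical outcome of one sample: MRD day-29 status and survival times.

    ``efs_*`` is event-free survival, ``os_*`` overall survival; times are in
    days from diagnosis.  A time must be present iff its event flag is.
    """

    mrd29_positive: bool | None = None
    efs_time: float | None = None
    efs_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        for prefix in ("efs", "os"):
            t = getattr(self, f"{prefix}_time")
            e = getattr(self, f"{prefix}_event")
            if (t is None) != (e is None):
                raise ValueError(
                    f"{prefix}_time and {prefix}_event must be present together"
                )
            if t is not None and t < 0:
                raise ValueError(f"negative {prefix}_time: {t}")


@dataclass
class SampleAnnotation:
    """Group label (healthy stage or leukemia subtype) and optional outcome."""

    sample_id: str
    group: str
    outcome: OutcomeRecord | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("empty sample_id")
        if not self.group:
            raise ValueError(f"empty group for sample {self.sample_id!r}")


def read_expression_matrix(path: str | Path, log2: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column holds gene ids, the header row holds sample ids.  Duplicate
    gene ids are collapsed by keeping the row with the highest mean.  With
    ``log2=True`` a ``log2(x + 1)`` transform is applied (raw-scale input).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#", dtype=str, na_filter=False
        )
    except pd.errors.EmptyDataError:
        raise MatrixParseError(f"{path}: empty file or missing header") from None
    if df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no sample columns (missing header?)")
    if df.shape[0] == 0:
        raise MatrixParseError(f"{path}: no gene rows")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: one for the header line, one for 1-based numbering
            raise MatrixParseError(
                f"{path}: non-numeric cell {df[col].iloc[row]!r} in column "
                f"{col!r}, line {row + 2}"
            )
        numeric[col] = converted
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        first_order = numeric.index.drop_duplicates().tolist()
        rows = {}
        for gid, sub in numeric.groupby(level=0, sort=False):
            rows[gid] = sub.iloc[int(np.argmax(sub.mean(axis=1).to_numpy()))]
        numeric = pd.DataFrame([rows[g] for g in first_order], index=first_order)
        numeric.columns = df.columns
        logger.warning(
            "%s: collapsed %d duplicate gene rows (kept highest-mean row)",
            path,
            n_before - len(numeric),
        )
    if log2:
        if (numeric.to_numpy() < 0).any():
            raise MatrixParseError(f"{path}: negative values under --log2")
        numeric = np.log2(numeric + 1.0)
    return ExpressionMatrix(numeric)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene_id")


_OUTCOME_COLUMNS = ("mrd29_positive", "efs_time", "efs_event", "os_time", "os_event")
_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_bool(value: str, column: str, line: int) -> bool:
    low = value.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise MatrixParseError(f"line {line}: invalid boolean {value!r} in {column!r}")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample annotation table (columns ``sample_id``, ``group`` and
    optional outcome columns; unknown columns are ignored with a warning)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, na_filter=False)
    except pd.errors.EmptyDataError:
        raise MatrixParseError(f"{path}: empty file or missing header") from None
    for required in ("sample_id", "group"):
        if required not in df.columns:
            raise MatrixParseError(f"{path}: missing required column {required!r}")
    unknown = [
        c for c in df.columns if c not in ("sample_id", "group") + _OUTCOME_COLUMNS
    ]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise MatrixParseError(f"{path}: duplicated sample_id {dups[:5]}")
    annotations: list[SampleAnnotation] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        sample_id = row["sample_id"].strip()
        group = row["group"].strip()
        if not sample_id:
            raise MatrixParseError(f"{path}: line {line}: missing sample_id")
        fields: dict[str, object] = {}
        for col in _OUTCOME_COLUMNS:
            if col not in df.columns:
                continue
            raw = str(row[col]).strip()
            if raw == "" or raw.upper() in ("NA", "NAN", "NONE"):
                continue
            if col.endswith("_time"):
                try:
                    fields[col] = float(raw)
                except ValueError:
                    raise MatrixParseError(
                        f"{path}: line {line}: non-numeric {col} {raw!r}"
                    ) from None
            else:
                fields[col] = _parse_bool(raw, col, line)
        outcome = None
        if fields:
            try:
                outcome = OutcomeRecord(**fields)
            except ValueError as exc:
                raise MatrixParseError(f"{path}: line {line}: {exc}") from None
        annotations.append(SampleAnnotation(sample_id, group, outcome))
    return annotations


def write_annotations(
    annotations: Iterable[SampleAnnotation],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    rows = []
    for ann in annotations:
        row: dict[str, object] = {"sample_id": ann.sample_id, "group": ann.group}
        if ann.outcome is not None:
            for col in _OUTCOME_COLUMNS:
                value = getattr(ann.outcome, col)
                if value is None:
                    row[col] = ""
                elif isinstance(value, bool):
                    row[col] = int(value)
                else:
                    row[col] = value
        rows.append(row)
    df = pd.DataFrame(rows).fillna("")
    # keep booleans as 0/1 even when other rows leave the column empty
    for col in df.columns:
        if col.endswith(("_positive", "_event")):
            df[col] = df[col].map(
                lambda v: "" if v == "" else str(int(float(v)))
            )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene sets from a GMT file (name, description, member genes).

    Duplicate genes within a set are removed (first occurrence kept) with a
    warning.
    """
    path = Path(path)
    signatures: list[GeneSignature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MatrixParseError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            name, description = parts[0], parts[1]
            genes = [g.strip() for g in parts[2:] if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: removed duplicate genes in set "
                    f"{name!r}",
                    stacklevel=2,
                )
            signatures.append(
                GeneSignature(
                    name=name,
                    genes=unique,
                    source_group=description,
                    n_requested=len(unique),
                )
            )
    return signatures


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.source_group or ".", *sig.genes]) + "\n")
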