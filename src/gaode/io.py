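"""Tabular input/output: the AttributeTable container, TSV/CSV readers and
result writers.

Attribute data is held in a pandas DataFrame of floats where NaN marks a
missing cell.  Class labels and pass-through ID columns are kept separate
from the numeric attributes so the model never sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = ["AttributeTable", "read_table", "write_table", "write_results", "read_results"]

#: Cell contents treated as missing on input (case-insensitive).
DEFAULT_MISSING_MARKERS = ("na", "", "nan")


@dataclass
class AttributeTable:
    """Rows of continuous attribute values with explicit missingness.

    Attributes
    ----------
    data:
        Float DataFrame; one column per attribute, NaN for missing cells.
    labels:
        Optional per-row class labels (pandas Series of str), aligned to
        ``data``.
    ids:
        Optional pass-through identifier columns (DataFrame), aligned to
        ``data``.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    ids: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise SchemaError("duplicate attribute names")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.any(np.isinf(vals)):
            raise ValidationError("attribute values must be finite or missing")
        if self.labels is not None:
            if len(self.labels) != len(self.data):
                raise ValidationError("labels must align with rows")
            if self.labels.name in self.data.columns:
                raise SchemaError("label column name collides with an attribute")
            self.labels = self.labels.reset_index(drop=True).astype(str)
        if self.ids is not None and len(self.ids) != len(self.data):
            raise ValidationError("id columns must align with rows")
        self.data = self.data.reset_index(drop=True)
        if self.ids is not None:
            self.ids = self.ids.reset_index(drop=True)

    @property
    def attribute_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def present_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_attributes) array; True where a value is present."""
        return ~np.isnan(self.data.to_numpy())

    def subset(self, row_indexer) -> "AttributeTable":
        """A new table restricted to the given rows (boolean mask or indices)."""
        idx = np.arange(self.n_rows)[row_indexer]
        return AttributeTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            labels=None if self.labels is None else self.labels.iloc[idx].reset_index(drop=True),
            ids=None if self.ids is None else self.ids.iloc[idx].reset_index(drop=True),
        )

    def class_labels(self) -> list[str]:
        if self.labels is None:
            raise SchemaError("table has no class-label column")
        return sorted(self.labels.unique())


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise SchemaError(f"{path}: empty file")


def read_table(
    path,
    class_column: str | None = None,
    missing_markers=DEFAULT_MISSING_MARKERS,
    delimiter: str | None = None,
    id_columns: list[str] | None = None,
) -> AttributeTable:
    """Read a delimited text table into an :class:`AttributeTable`.

    The delimiter is sniffed from {tab, comma} unless forced.  Cells equal
    (case-insensitively) to one of ``missing_markers`` become missing; every
    other attribute cell must parse as a number, and a cell that does not is
    reported with its row and column.
    """
    sep = delimiter or _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)
                break
    if len(header) != len(set(header)):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise SchemaError(f"{path}: duplicate header column(s) {dupes}")
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#", keep_default_na=False)

    id_columns = list(id_columns or [])
    for col in id_columns + ([class_column] if class_column else []):
        if col not in raw.columns:
            raise SchemaError(f"{path}: column {col!r} not found")

    labels = raw[class_column].astype(str) if class_column else None
    ids = raw[id_columns].copy() if id_columns else None
    attr_cols = [c for c in raw.columns if c != class_column and c not in id_columns]

    markers = {m.lower() for m in missing_markers}
    data = {}
    for col in attr_cols:
        cells = raw[col].str.strip()
        is_missing = cells.str.lower().isin(markers).to_numpy()
        parsed = np.full(len(cells), np.nan)
        present = np.flatnonzero(~is_missing)
        # float() per cell is a correctly-rounded parse, so write/read
        # round trips are bitwise-lossless
        for row in present:
            try:
                parsed[row] = float(cells.iloc[row])
            except ValueError:
                raise SchemaError(
                    f"{path}: cell {cells.iloc[row]!r} in column {col!r}, "
                    f"data row {row} is not numeric"
                ) from None
        data[col] = parsed
    return AttributeTable(data=pd.DataFrame(data), labels=labels, ids=ids)


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return repr(float(x))


def write_table(table: AttributeTable, path, label_column: str = "class") -> None:
    """Write an AttributeTable as TSV with 'NA' missing markers.

    Values are written with ``repr`` so that a read/write round trip is
    lossless to full double precision.
    """
    frames = []
    if table.ids is not None:
        frames.append(table.ids)
    body = table.data.map(_fmt)
    frames.append(body)
    if table.labels is not None:
        frames.append(table.labels.rename(label_column))
    pd.concat(frames, axis=1).to_csv(path, sep="\t", index=False)


def write_results(records, table: AttributeTable, path, timestamp: bool = False) -> None:
    """Write classification records aligned to ``table`` as a TSV file.

    Columns: pass-through IDs, one ``prob_<class>`` column per class, then
    ``srs``, ``n_present`` and ``abstained``.  Abstained rows with no
    posterior are written as "NA".  A header comment line ``#model=<hash>``
    embeds the fingerprint of the model that produced the scores, so that
    downstream shift tests can refuse to mix scores across models.
    """
    from .classify import ClassificationRecord  # local to avoid cycle

    records = list(records)
    if len(records) != table.n_rows:
        raise ValidationError("records are not aligned to the table rows")
    fingerprints = {r.model_fingerprint for r in records}
    if len(fingerprints) > 1:
        raise ValidationError("records stem from more than one model")
    fingerprint = next(iter(fingerprints)) if records else ""
    class_labels = records[0].class_labels if records else []

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#model={fingerprint}\n")
        if timestamp:
            import datetime

            fh.write(f"#written={datetime.datetime.now().isoformat()}\n")
        cols = []
        if table.ids is not None:
            cols.extend(table.ids.columns.astype(str))
        cols += [f"prob_{c}" for c in class_labels] + ["srs", "n_present", "abstained"]
        fh.write("\t".join(cols) + "\n")
        for i, rec in enumerate(records):
            row = []
            if table.ids is not None:
                row.extend(str(v) for v in table.ids.iloc[i])
            if rec.posteriors is None:
                row.extend("NA" for _ in class_labels)
            else:
                row.extend(repr(float(p)) for p in rec.posteriors)
            row.append("NA" if rec.srs is None else repr(float(rec.srs)))
            row.append(str(rec.n_present))
            row.append("true" if rec.abstained else "false")
            fh.write("\t".join(row) + "\n")


def read_results(path):
    """Read a results TSV back into a list of ClassificationRecords.

    Returns the records; the model fingerprint is restored from the
    ``#model=`` header line.
    """
    from .classify import ClassificationRecord

    fingerprint = ""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    header_idx = 0
    for i, line in enumerate(lines):
        if line.startswith("#model="):
            fingerprint = line.strip()[len("#model=") :]
        elif not line.startswith("#"):
            header_idx = i
            break
    else:
        raise SchemaError(f"{path}: no header row")
    header = lines[header_idx].rstrip("\n").split("\t")
    prob_cols = [(j, c[len("prob_") :]) for j, c in enumerate(header) if c.startswith("prob_")]
    try:
        srs_col = header.index("srs")
        np_col = header.index("n_present")
        ab_col = header.index("abstained")
    except ValueError as exc:
        raise SchemaError(f"{path}: missing required results column: {exc}") from exc

    class_labels = [c for _, c in prob_cols]
    records = []
    for line in lines[header_idx + 1 :]:
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if not prob_cols or cells[prob_cols[0][0]] == "NA":
            posteriors = None
        else:
            posteriors = np.array([float(cells[j]) for j, _ in prob_cols])
        srs = None if cells[srs_col] == "NA" else float(cells[srs_col])
        records.append(
            ClassificationRecord(
                posteriors=posteriors,
                srs=srs,
                n_present=int(cells[np_col]),
                abstained=cells[ab_col] == "true",
                class_labels=class_labels,
                model_fingerprint=fingerprint,
            )
        )
    return records
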