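"""Reading and writing labeled numeric tables.

Raw sheets come from Excel workbooks (.xlsx; zip-based .xls files also load),
tab-separated or comma-separated text.  A rectangular :class:`RawSheet` keeps
every cell as parsed text-or-number; an :class:`AreaSelection` (1-based
inclusive spreadsheet coordinates, matching how users read a sheet) carves the
numeric data area out of it and attaches axis titles, yielding an
:class:`ExpressionTable`.

Conventions
-----------
* Sheet coordinates are 1-based inclusive at this module's boundary only;
  everything downstream is 0-based.
* Numeric parsing accepts integer, decimal and scientific notation with ``.``
  as the decimal mark.  No locale handling.
* Blank or textual cells inside a selected data area are a hard error (with
  the offending 1-based coordinate), never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

DIALECTS = ("xls", "xlsx", "tsv", "csv")

_EXT_TO_DIALECT = {
    ".xls": "xls",
    ".xlsx": "xlsx",
    ".tsv": "tsv",
    ".tab": "tsv",
    ".txt": "tsv",
    ".csv": "csv",
}

Cell = str | float


def parse_cell(text: str) -> Cell:
    """Parse a raw text cell: numeric-looking cells become floats, everything
    else (including the empty string) stays text."""
    stripped = text.strip()
    if not stripped:
        return text
    try:
        return float(stripped)
    except ValueError:
        return text


@dataclass
class RawSheet:
    """A rectangular grid of text-or-numeric cells, rows padded to equal length."""

    cells: list[list[Cell]]
    source_path: str = ""
    dialect: str = "csv"

    def __post_init__(self) -> None:
        if not self.cells or not any(len(r) for r in self.cells):
            raise FormatError(f"sheet has no cells: {self.source_path!r}")
        width = max(len(r) for r in self.cells)
        self.cells = [list(r) + [""] * (width - len(r)) for r in self.cells]

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0])


@dataclass(frozen=True)
class AreaSelection:
    """1-based inclusive data-area coordinates plus optional title row/column.

    ``title_row`` supplies X-axis (column) titles; ``title_col`` supplies
    Y-axis (row) titles.  When set, each must lie outside the data area.
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int
    title_row: int | None = None
    title_col: int | None = None

    def validate(self, sheet: RawSheet) -> None:
        if not (1 <= self.row_start <= self.row_end <= sheet.n_rows):
            raise ValidationError(
                f"row selection {self.row_start}..{self.row_end} outside sheet "
                f"with {sheet.n_rows} rows"
            )
        if not (1 <= self.col_start <= self.col_end <= sheet.n_cols):
            raise ValidationError(
                f"column selection {self.col_start}..{self.col_end} outside sheet "
                f"with {sheet.n_cols} columns"
            )
        if self.title_row is not None:
            if not 1 <= self.title_row <= sheet.n_rows:
                raise ValidationError(f"title_row {self.title_row} outside sheet")
            if self.row_start <= self.title_row <= self.row_end:
                raise ValidationError(
                    f"title_row {self.title_row} lies inside the data area"
                )
        if self.title_col is not None:
            if not 1 <= self.title_col <= sheet.n_cols:
                raise ValidationError(f"title_col {self.title_col} outside sheet")
            if self.col_start <= self.title_col <= self.col_end:
                raise ValidationError(
                    f"title_col {self.title_col} lies inside the data area"
                )


@dataclass
class ExpressionTable:
    """An R x C matrix of finite numbers with row (Y-axis) and column (X-axis)
    labels.  Duplicate labels are preserved verbatim — gene lists legitimately
    repeat symbols."""

    values: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must form a 2-D matrix")
        r, c = self.values.shape
        if not self.row_labels:
            self.row_labels = [f"R{i + 1}" for i in range(r)]
        if not self.col_labels:
            self.col_labels = [f"C{j + 1}" for j in range(c)]
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValidationError(
                f"label counts ({len(self.row_labels)}, {len(self.col_labels)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {i + 1}, column {j + 1}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in DIALECTS:
            raise FormatError(
                f"unknown dialect {dialect!r}; expected one of {', '.join(DIALECTS)}"
            )
        return dialect
    ext = path.suffix.lower()
    if ext not in _EXT_TO_DIALECT:
        raise FormatError(
            f"cannot infer format from extension {ext!r} of {path}; "
            f"pass an explicit dialect"
        )
    return _EXT_TO_DIALECT[ext]


def _read_delimited(path: Path, delimiter: str) -> list[list[Cell]]:
    rows: list[list[Cell]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        if delimiter == "\t":
            # TSV has no quoting convention: fields are split on literal tabs.
            for line in fh:
                rows.append([parse_cell(tok) for tok in line.rstrip("\r\n").split("\t")])
        else:
            for record in csv.reader(fh):
                rows.append([parse_cell(tok) for tok in record])
    return rows


def _read_excel(path: Path) -> list[list[Cell]]:
    try:
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:  # zip/XML errors for legacy BIFF .xls files
        raise FormatError(
            f"cannot open {path} as an Excel workbook ({exc}); legacy binary "
            f".xls should be re-saved as .xlsx"
        ) from exc
    ws = wb.worksheets[0]
    rows: list[list[Cell]] = []
    for record in ws.iter_rows(values_only=True):
        parsed: list[Cell] = []
        for v in record:
            if v is None:
                parsed.append("")
            elif isinstance(v, (int, float)) and not isinstance(v, bool):
                parsed.append(float(v))
            else:
                parsed.append(parse_cell(str(v)))
        rows.append(parsed)
    wb.close()
    return rows


def read_sheet(path: str | Path, dialect: str | None = None) -> RawSheet:
    """Read a raw sheet from CSV/TSV/Excel, inferring the format from the
    extension when ``dialect`` is omitted.

    Ragged delimited rows are padded with empty cells to the widest row.
    An empty file raises :class:`FormatError`.
    """
    path = Path(path)
    fmt = _infer_dialect(path, dialect)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if fmt in ("xls", "xlsx"):
            cells = _read_excel(path)
        elif fmt == "tsv":
            cells = _read_delimited(path, "\t")
        else:
            cells = _read_delimited(path, ",")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not cells:
        raise FormatError(f"empty sheet: {path}")
    return RawSheet(cells=cells, source_path=str(path), dialect=fmt)


def select_area(sheet: RawSheet, sel: AreaSelection) -> ExpressionTable:
    """Extract the numeric data area described by ``sel`` and attach titles.

    Labels come from the title row/column when given, otherwise they are
    synthesized as ``R1..Rn`` / ``C1..Cn``.  Any non-numeric cell inside the
    data area raises :class:`ValidationError` naming its 1-based coordinate.
    """
    sel.validate(sheet)
    r0, r1 = sel.row_start - 1, sel.row_end
    c0, c1 = sel.col_start - 1, sel.col_end
    values = np.empty((r1 - r0, c1 - c0), dtype=float)
    for i in range(r0, r1):
        for j in range(c0, c1):
            cell = sheet.cells[i][j]
            if not isinstance(cell, float):
                raise ValidationError(
                    f"non-numeric cell {cell!r} at row {i + 1}, column {j + 1} "
                    f"inside the selected data area"
                )
            values[i - r0, j - c0] = cell

    def _as_label(cell: Cell) -> str:
        if isinstance(cell, float):
            return repr(cell) if not cell.is_integer() else str(int(cell))
        return cell

    col_labels: list[str] = []
    row_labels: list[str] = []
    if sel.title_row is not None:
        trow = sheet.cells[sel.title_row - 1]
        col_labels = [_as_label(trow[j]) for j in range(c0, c1)]
    if sel.title_col is not None:
        col = sel.title_col - 1
        row_labels = [_as_label(sheet.cells[i][col]) for i in range(r0, r1)]
    return ExpressionTable(values=values, row_labels=row_labels, col_labels=col_labels)


def auto_fill(sheet: RawSheet) -> ExpressionTable:
    """Treat the first row as X-axis titles and the first column as Y-axis
    titles; the remaining block is the data area.  Requires at least 2x2."""
    if sheet.n_rows < 2 or sheet.n_cols < 2:
        raise ValidationError(
            f"auto-fill needs at least a 2x2 sheet, got "
            f"{sheet.n_rows}x{sheet.n_cols}"
        )
    sel = AreaSelection(
        row_start=2,
        row_end=sheet.n_rows,
        col_start=2,
        col_end=sheet.n_cols,
        title_row=1,
        title_col=1,
    )
    return select_area(sheet, sel)


def _format_value(v: float) -> str:
    # repr() of a float is the shortest string that round-trips exactly.
    return str(int(v)) if v.is_integer() and abs(v) < 1e16 else repr(v)


def write_table(table: ExpressionTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a table as delimited text in the auto-fill convention: a header
    row of column labels (leading cell blank) then one label-prefixed row per
    matrix row.  Values are written to full precision so that
    ``auto_fill(read_sheet(path))`` recovers the table exactly."""
    if dialect not in ("tsv", "csv"):
        raise ValidationError(f"write dialect must be tsv or csv, got {dialect!r}")
    path = Path(path)
    rows = [[""] + list(table.col_labels)]
    for label, vrow in zip(table.row_labels, table.values):
        rows.append([label] + [_format_value(float(v)) for v in vrow])
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            if dialect == "csv":
                csv.writer(fh).writerows(rows)
            else:
                for record in rows:
                    for tok in record:
                        if "\t" in tok or "\n" in tok:
                            raise ValidationError(
                                f"field {tok!r} contains a tab or newline and "
                                f"cannot be written as TSV"
                            )
                    fh.write("\t".join(record) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
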