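"""Relational (SQLite) and spreadsheet (XLSX) persistence of datasets.

One table / one worksheet per data-scheme section, with the canonical
column layout::

    intermolecular: tag, ID1, p1..p4, ref
    bond:           tag1, order, tag2, ID2, p1..p4, ref
    angle:          tag1, order1, tag2, order2, tag3, ID3, p1..p9, ref
    torsion:        tag1, order1, .., tag4, ID4, p1..p12, ref
    improper:       tag0, order1, tag1, order2, tag2, order3, tag3, ID5, p1, p2, ref
    1n_potential:   n, scaling1, scaling2, ref
    special:        tag1, dist, tag2, ID7, p1, p2, ref

Wildcards are the literal ``X`` (in tag parts and in order columns); rigid
entries carry the literal ``none`` in their ID column.  The parameter
columns have a fixed width (the maximum arity of the section's function
registry); cells beyond a function's arity stay empty/NULL.  Database ↔
dataset ↔ workbook round trips are lossless at the record level, with rows
written in deterministic key-sorted order.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import openpyxl

from .errors import DatasetValidationError, FormatError
from .potentials import Section
from .records import (
    PARAM_WIDTHS,
    AngleRecord,
    BondRecord,
    ForceFieldDataset,
    ImproperRecord,
    InterRecord,
    OneNRecord,
    SpecialRecord,
    TorsionRecord,
    errors_only,
    validate_dataset,
)
from .tags import WILDCARD, format_tag, parse_tag

SECTION_ORDER = [
    Section.INTERMOLECULAR, Section.BOND, Section.ANGLE, Section.TORSION,
    Section.IMPROPER, Section.ONE_N, Section.SPECIAL,
]

_P = {s: [f"p{i}" for i in range(1, PARAM_WIDTHS[s] + 1)] for s in PARAM_WIDTHS}

COLUMNS = {
    Section.INTERMOLECULAR: ["tag", "ID1", *_P[Section.INTERMOLECULAR], "ref"],
    Section.BOND: ["tag1", "order", "tag2", "ID2", *_P[Section.BOND], "ref"],
    Section.ANGLE: ["tag1", "order1", "tag2", "order2", "tag3", "ID3",
                    *_P[Section.ANGLE], "ref"],
    Section.TORSION: ["tag1", "order1", "tag2", "order2", "tag3", "order3", "tag4",
                      "ID4", *_P[Section.TORSION], "ref"],
    Section.IMPROPER: ["tag0", "order1", "tag1", "order2", "tag2", "order3", "tag3",
                       "ID5", *_P[Section.IMPROPER], "ref"],
    Section.ONE_N: ["n", "scaling1", "scaling2", "ref"],
    Section.SPECIAL: ["tag1", "dist", "tag2", "ID7", *_P[Section.SPECIAL], "ref"],
}

_RECORD_CLS = {
    Section.INTERMOLECULAR: InterRecord,
    Section.BOND: BondRecord,
    Section.ANGLE: AngleRecord,
    Section.TORSION: TorsionRecord,
    Section.IMPROPER: ImproperRecord,
    Section.ONE_N: OneNRecord,
    Section.SPECIAL: SpecialRecord,
}


# --------------------------------------------------------------------------
# cell codecs

def _order_cell(o):
    return "X" if o is WILDCARD else int(o)


def _id_cell(fid):
    return "none" if fid is None else int(fid)


def _coerce_int(value, what, where):
    """Lenient integer coercion: ints, integral floats, and digit strings."""
    if isinstance(value, bool) or value is None:
        raise FormatError(f"{where}: {what} must be an integer, got {value!r}")
    if isinstance(value, int):
        return value
    if isinstance(value, float) and value.is_integer():
        return int(value)
    if isinstance(value, str):
        try:
            return int(value.strip())
        except ValueError:
            pass
    raise FormatError(f"{where}: {what} must be an integer, got {value!r}")


def _coerce_float(value, what, where):
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value.strip())
        except ValueError:
            pass
    raise FormatError(f"{where}: {what} must be a number, got {value!r}")


def _parse_order(value, where):
    if isinstance(value, str) and value.strip() == "X":
        return WILDCARD
    return _coerce_int(value, "bond order", where)


def _parse_id(value, where):
    if isinstance(value, str) and value.strip().lower() == "none":
        return None
    return _coerce_int(value, "function ID", where)


def _parse_tag_cell(value, where):
    if not isinstance(value, str):
        raise FormatError(f"{where}: tag cell must be text, got {value!r}")
    try:
        return parse_tag(value)
    except Exception as exc:
        raise FormatError(f"{where}: {exc}") from None


def _is_empty(v):
    return v is None or (isinstance(v, str) and not v.strip())


def encode_record(section: Section, rec) -> list:
    """Record -> flat row of cells following COLUMNS[section]."""
    width = PARAM_WIDTHS.get(section, 0)
    if section is Section.ONE_N:
        return [int(rec.n), float(rec.scaling1), float(rec.scaling2), rec.ref]
    params = list(rec.params) + [None] * (width - len(rec.params))
    if section is Section.INTERMOLECULAR:
        return [format_tag(rec.tag), int(rec.id1), *params, rec.ref]
    if section is Section.BOND:
        return [format_tag(rec.tag1), _order_cell(rec.order), format_tag(rec.tag2),
                _id_cell(rec.id2), *params, rec.ref]
    if section is Section.ANGLE:
        return [format_tag(rec.tag1), _order_cell(rec.order1), format_tag(rec.tag2),
                _order_cell(rec.order2), format_tag(rec.tag3), _id_cell(rec.id3),
                *params, rec.ref]
    if section is Section.TORSION:
        return [format_tag(rec.tag1), _order_cell(rec.order1), format_tag(rec.tag2),
                _order_cell(rec.order2), format_tag(rec.tag3), _order_cell(rec.order3),
                format_tag(rec.tag4), _id_cell(rec.id4), *params, rec.ref]
    if section is Section.IMPROPER:
        return [format_tag(rec.tag0), _order_cell(rec.order1), format_tag(rec.tag1),
                _order_cell(rec.order2), format_tag(rec.tag2), _order_cell(rec.order3),
                format_tag(rec.tag3), _id_cell(rec.id5), *params, rec.ref]
    if section is Section.SPECIAL:
        return [format_tag(rec.tag1), int(rec.dist), format_tag(rec.tag2),
                _id_cell(rec.id7), *params, rec.ref]
    raise FormatError(f"unknown section {section!r}")


def decode_row(section: Section, cells, where: str):
    """Flat row of cells -> record; raises FormatError with row context."""
    cells = list(cells)
    expected = len(COLUMNS[section])
    if len(cells) != expected:
        raise FormatError(f"{where}: expected {expected} cells, got {len(cells)}")

    def ref_of(v):
        return "" if _is_empty(v) else str(v)

    if section is Section.ONE_N:
        return OneNRecord(
            n=_coerce_int(cells[0], "n", where),
            scaling1=_coerce_float(cells[1], "scaling1", where),
            scaling2=_coerce_float(cells[2], "scaling2", where),
            ref=ref_of(cells[3]),
        )

    width = PARAM_WIDTHS[section]
    raw_params = cells[-1 - width:-1]
    params = []
    for j, v in enumerate(raw_params, start=1):
        if _is_empty(v):
            params.append(None)
        else:
            params.append(_coerce_float(v, f"p{j}", where))
    # trim trailing NULLs; interior NULLs are an arity error caught by validation
    while params and params[-1] is None:
        params.pop()
    if any(p is None for p in params):
        raise FormatError(f"{where}: parameter columns have an interior gap")
    params = tuple(params)
    ref = ref_of(cells[-1])

    if section is Section.INTERMOLECULAR:
        return InterRecord(_parse_tag_cell(cells[0], where),
                           _coerce_int(cells[1], "ID1", where), params, ref)
    if section is Section.BOND:
        return BondRecord(_parse_tag_cell(cells[0], where), _parse_order(cells[1], where),
                          _parse_tag_cell(cells[2], where), _parse_id(cells[3], where),
                          params, ref)
    if section is Section.ANGLE:
        return AngleRecord(_parse_tag_cell(cells[0], where), _parse_order(cells[1], where),
                           _parse_tag_cell(cells[2], where), _parse_order(cells[3], where),
                           _parse_tag_cell(cells[4], where), _parse_id(cells[5], where),
                           params, ref)
    if section is Section.TORSION:
        return TorsionRecord(_parse_tag_cell(cells[0], where), _parse_order(cells[1], where),
                             _parse_tag_cell(cells[2], where), _parse_order(cells[3], where),
                             _parse_tag_cell(cells[4], where), _parse_order(cells[5], where),
                             _parse_tag_cell(cells[6], where), _parse_id(cells[7], where),
                             params, ref)
    if section is Section.IMPROPER:
        return ImproperRecord(_parse_tag_cell(cells[0], where), _parse_order(cells[1], where),
                              _parse_tag_cell(cells[2], where), _parse_order(cells[3], where),
                              _parse_tag_cell(cells[4], where), _parse_order(cells[5], where),
                              _parse_tag_cell(cells[6], where), _parse_id(cells[7], where),
                              params, ref)
    if section is Section.SPECIAL:
        return SpecialRecord(_parse_tag_cell(cells[0], where),
                             _coerce_int(cells[1], "dist", where),
                             _parse_tag_cell(cells[2], where), _parse_id(cells[3], where),
                             params, ref)
    raise FormatError(f"unknown section {section!r}")


def _gate(dataset: ForceFieldDataset):
    errs = errors_only(validate_dataset(dataset))
    if errs:
        raise DatasetValidationError(errs)


# --------------------------------------------------------------------------
# SQLite

def write_database(dataset: ForceFieldDataset, path) -> None:
    """Write a validated dataset to a single-file SQLite database.

    Rows go out in deterministic key-sorted order; a ``metadata`` table
    carries the dataset name and unit-profile marker.
    """
    _gate(dataset)
    ds = dataset.sorted()
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        for section in SECTION_ORDER:
            cols = ", ".join(f'"{c}"' for c in COLUMNS[section])
            cur.execute(f'CREATE TABLE "{section.value}" ({cols})')
            rows = [encode_record(section, r) for r in ds.sections()[section]]
            if rows:
                ph = ", ".join("?" * len(COLUMNS[section]))
                cur.executemany(f'INSERT INTO "{section.value}" VALUES ({ph})', rows)
        cur.execute('CREATE TABLE "metadata" ("key", "value")')
        cur.executemany('INSERT INTO "metadata" VALUES (?, ?)',
                        [("name", ds.name), ("unit_profile", ds.unit_profile)])
        con.commit()
    finally:
        con.close()


def read_database(path) -> ForceFieldDataset:
    """Read a dataset from a seven-table SQLite database."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such database file: {path}")
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        present = {r[0] for r in cur.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        for section in SECTION_ORDER:
            if section.value not in present:
                raise FormatError(f"database {path} is missing table {section.value!r}")
        ds = ForceFieldDataset()
        for section in SECTION_ORDER:
            ncols = len(COLUMNS[section])
            rows = cur.execute(f'SELECT * FROM "{section.value}"').fetchall()
            out = ds.sections()[section]
            for i, row in enumerate(rows):
                if len(row) != ncols:
                    raise FormatError(
                        f"table {section.value!r} row {i}: expected {ncols} columns, "
                        f"got {len(row)}")
                out.append(decode_row(section, row, f"table {section.value!r} row {i}"))
        if "metadata" in present:
            meta = dict(cur.execute('SELECT * FROM "metadata"').fetchall())
            ds.name = str(meta.get("name", ""))
            ds.unit_profile = str(meta.get("unit_profile", ds.unit_profile))
        return ds
    finally:
        con.close()


# --------------------------------------------------------------------------
# XLSX workbook

def write_workbook(dataset: ForceFieldDataset, path) -> None:
    """Write a validated dataset to an XLSX workbook, one sheet per section."""
    _gate(dataset)
    ds = dataset.sorted()
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for section in SECTION_ORDER:
        sheet = wb.create_sheet(title=section.value)
        sheet.append(COLUMNS[section])
        for rec in ds.sections()[section]:
            sheet.append(encode_record(section, rec))
    meta = wb.create_sheet(title="metadata")
    meta.append(["key", "value"])
    meta.append(["name", ds.name])
    meta.append(["unit_profile", ds.unit_profile])
    wb.save(Path(path))


def read_workbook(path) -> ForceFieldDataset:
    """Read a dataset from an XLSX workbook (one sheet per section)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such workbook file: {path}")
    try:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:
        raise FormatError(f"cannot open workbook {path}: {exc}") from None
    try:
        ds = ForceFieldDataset()
        for section in SECTION_ORDER:
            if section.value not in wb.sheetnames:
                raise FormatError(f"workbook {path} is missing sheet {section.value!r}")
            sheet = wb[section.value]
            rows = sheet.iter_rows(values_only=True)
            header = next(rows, None)
            header = [h for h in (header or ()) if h is not None]
            if list(header) != COLUMNS[section]:
                missing = [c for c in COLUMNS[section] if c not in (header or ())]
                if missing:
                    raise FormatError(
                        f"sheet {section.value!r} is missing column(s) "
                        f"{', '.join(repr(m) for m in missing)}")
                raise FormatError(
                    f"sheet {section.value!r} header {list(header)!r} does not match "
                    f"{COLUMNS[section]!r}")
            out = ds.sections()[section]
            ncols = len(COLUMNS[section])
            for i, row in enumerate(rows):
                row = list(row)[:ncols]
                row += [None] * (ncols - len(row))
                if all(_is_empty(v) for v in row):
                    continue
                out.append(decode_row(section, row, f"sheet {section.value!r} row {i}"))
        if "metadata" in wb.sheetnames:
            meta = {}
            rows = wb["metadata"].iter_rows(values_only=True)
            next(rows, None)
            for row in rows:
                if row and row[0] is not None:
                    meta[str(row[0])] = "" if len(row) < 2 or row[1] is None else str(row[1])
            ds.name = meta.get("name", "")
            ds.unit_profile = meta.get("unit_profile", ds.unit_profile)
        return ds
    finally:
        wb.close()


# --------------------------------------------------------------------------
# pretty print

def to_text(dataset: ForceFieldDataset) -> str:
    """Tab-delimited dump of all seven sections, for diffing and display."""
    ds = dataset.sorted()
    lines = [f"# dataset: {ds.name}  (unit profile: {ds.unit_profile})"]
    for section in SECTION_ORDER:
        records = ds.sections()[section]
        lines.append(f"## {section.value} ({len(records)} records)")
        lines.append("\t".join(COLUMNS[section]))
        for rec in records:
            cells = encode_record(section, rec)
            lines.append("\t".join("" if c is None else str(c) for c in cells))
    return "\n".join(lines) + "\n"
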