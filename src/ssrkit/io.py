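"""Readers and writers for genotype tables.

Two dialects are supported:

* ``tidy`` — one row per sample with columns
  ``sample_id,cultivar,locality,sex,<locus>_1,<locus>_2`` per locus.
  Missing calls are empty cells (both of the pair).
* ``genalex`` — the GenAlEx codominant CSV layout: row 1 holds
  ``n_loci,n_samples,n_pops`` followed by the population sizes; row 2
  holds a title followed by the population names; row 3 holds the locus
  names over paired allele columns; each data row is
  ``sample,pop,allele pairs``.  Missing alleles are coded 0.  The writer
  reproduces this layout bit-exactly.

All writers emit UTF-8, comma-separated files with deterministic column
order.  The GenAlEx dialect carries only one grouping label (the pop),
stored here as the cultivar; locality and sex round-trip only through the
tidy dialect.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .model import (
    UNKNOWN,
    GenotypeCall,
    GenotypeTable,
    Locus,
    MISSING_CALL,
    ParseError,
    SampleRecord,
    ValidationError,
)

DIALECTS = ("tidy", "genalex")


def read_genotypes(path: str | Path, dialect: str = "tidy", bin_width: int = 0) -> GenotypeTable:
    """Read a genotype table; ``bin_width`` > 0 snaps sizes to that grid."""
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if dialect == "tidy":
        table = _read_tidy(rows)
    else:
        table = _read_genalex(rows)
    if bin_width > 0:
        table = _bin_alleles(table, bin_width)
    _check_unique_ids(table)
    return table


def write_genotypes(table: GenotypeTable, path: str | Path, dialect: str = "tidy") -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect == "tidy":
            _write_tidy(table, writer)
        else:
            _write_genalex(table, writer)


def _check_unique_ids(table: GenotypeTable) -> None:
    seen: set[str] = set()
    for s in table.samples:
        if s.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)


def _parse_size(text: str, row: int, col: int) -> int:
    try:
        value = int(text)
    except ValueError:
        raise ParseError(
            f"row {row}, column {col}: non-integer allele size {text!r}"
        ) from None
    return value


def _bin_alleles(table: GenotypeTable, width: int) -> GenotypeTable:
    def snap(a: int) -> int:
        return int(round(a / width)) * width

    samples = []
    for s in table.samples:
        calls = {}
        for name, call in s.calls.items():
            if call.is_missing:
                calls[name] = MISSING_CALL
            else:
                calls[name] = GenotypeCall(snap(call.allele_a), snap(call.allele_b))
        samples.append(SampleRecord(s.sample_id, s.cultivar, s.locality, s.sex, calls))
    return GenotypeTable.from_samples(samples, table.locus_names)


# -- tidy dialect -----------------------------------------------------------

_TIDY_FIXED = ["sample_id", "cultivar", "locality", "sex"]


def _read_tidy(rows: list[list[str]]) -> GenotypeTable:
    if not rows:
        raise ParseError("empty file")
    header = rows[0]
    if header[: len(_TIDY_FIXED)] != _TIDY_FIXED:
        raise ParseError(
            f"row 1: tidy header must start with {','.join(_TIDY_FIXED)}"
        )
    locus_cols = header[len(_TIDY_FIXED):]
    if len(locus_cols) % 2 != 0:
        raise ParseError("row 1: odd number of allele columns; loci must be paired")
    locus_names: list[str] = []
    for k in range(0, len(locus_cols), 2):
        a, b = locus_cols[k], locus_cols[k + 1]
        if not (a.endswith("_1") and b.endswith("_2") and a[:-2] == b[:-2]):
            raise ParseError(
                f"row 1, columns {len(_TIDY_FIXED) + k + 1}-{len(_TIDY_FIXED) + k + 2}: "
                f"expected <locus>_1,<locus>_2 pair, got {a!r},{b!r}"
            )
        locus_names.append(a[:-2])
    samples = []
    for r, row in enumerate(rows[1:], start=2):
        if not row or all(not c for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(f"row {r}: expected {len(header)} columns, got {len(row)}")
        sample_id, cultivar, locality, sex = row[:4]
        calls: dict[str, GenotypeCall] = {}
        for k, name in enumerate(locus_names):
            ca, cb = row[4 + 2 * k], row[4 + 2 * k + 1]
            if ca == "" and cb == "":
                calls[name] = MISSING_CALL
                continue
            if ca == "" or cb == "":
                raise ParseError(
                    f"row {r}, locus {name}: half-missing call {ca!r}/{cb!r}"
                )
            calls[name] = GenotypeCall(
                _parse_size(ca, r, 5 + 2 * k), _parse_size(cb, r, 6 + 2 * k)
            )
        samples.append(
            SampleRecord(
                sample_id=sample_id,
                cultivar=cultivar or UNKNOWN,
                locality=locality or UNKNOWN,
                sex=sex or "unknown",
                calls=calls,
            )
        )
    return GenotypeTable.from_samples(samples, locus_names)


def _write_tidy(table: GenotypeTable, writer) -> None:
    header = list(_TIDY_FIXED)
    for name in table.locus_names:
        header += [f"{name}_1", f"{name}_2"]
    writer.writerow(header)
    for s in table.samples:
        row = [s.sample_id, s.cultivar, s.locality, s.sex]
        for name in table.locus_names:
            call = s.call(name)
            if call.is_missing:
                row += ["", ""]
            else:
                row += [str(call.allele_a), str(call.allele_b)]
        writer.writerow(row)


# -- GenAlEx dialect --------------------------------------------------------


def _read_genalex(rows: list[list[str]]) -> GenotypeTable:
    if len(rows) < 3:
        raise ParseError("GenAlEx file needs at least 3 header rows")
    head = rows[0]
    try:
        n_loci, n_samples, n_pops = (int(head[k]) for k in range(3))
        pop_sizes = [int(x) for x in head[3 : 3 + n_pops]]
    except (ValueError, IndexError):
        raise ParseError("row 1: expected n_loci,n_samples,n_pops,<pop sizes>") from None
    pop_names = [c for c in rows[1][3 : 3 + n_pops]]
    if len(pop_names) != n_pops or any(not p for p in pop_names):
        raise ParseError(f"row 2: expected {n_pops} population names from column 4")
    locus_row = rows[2]
    locus_names = []
    for k in range(n_loci):
        col = 2 + 2 * k
        if col >= len(locus_row) or not locus_row[col]:
            raise ParseError(f"row 3, column {col + 1}: missing locus name")
        locus_names.append(locus_row[col])
    data = [r for r in rows[3:] if r and any(c for c in r)]
    if len(data) != n_samples:
        raise ParseError(
            f"declared sample count {n_samples} but found {len(data)} data rows"
        )
    if sum(pop_sizes) != n_samples:
        raise ParseError(
            f"row 1: pop sizes sum to {sum(pop_sizes)}, expected {n_samples}"
        )
    samples = []
    for r, row in enumerate(data, start=4):
        if len(row) < 2 + 2 * n_loci:
            raise ParseError(f"row {r}: expected {2 + 2 * n_loci} columns, got {len(row)}")
        sample_id, pop = row[0], row[1]
        calls: dict[str, GenotypeCall] = {}
        for k, name in enumerate(locus_names):
            a = _parse_size(row[2 + 2 * k], r, 3 + 2 * k)
            b = _parse_size(row[3 + 2 * k], r, 4 + 2 * k)
            if a == 0 and b == 0:
                calls[name] = MISSING_CALL
            elif a == 0 or b == 0:
                raise ParseError(f"row {r}, locus {name}: half-missing call {a}/{b}")
            else:
                calls[name] = GenotypeCall(a, b)
        samples.append(
            SampleRecord(sample_id=sample_id, cultivar=pop or UNKNOWN, calls=calls)
        )
    return GenotypeTable.from_samples(samples, locus_names)


def _write_genalex(table: GenotypeTable, writer) -> None:
    pops: dict[str, int] = {}
    for s in table.samples:
        pops[s.cultivar] = pops.get(s.cultivar, 0) + 1
    pop_names = list(pops)
    writer.writerow(
        [str(len(table.loci)), str(table.n_samples), str(len(pop_names))]
        + [str(pops[p]) for p in pop_names]
    )
    writer.writerow(["ssrkit export", "", ""] + pop_names)
    locus_row = ["Sample", "Pop"]
    for name in table.locus_names:
        locus_row += [name, ""]
    writer.writerow(locus_row)
    # GenAlEx groups samples by pop; emit in pop order for a layout GenAlEx accepts
    for pop in pop_names:
        for s in table.samples:
            if s.cultivar != pop:
                continue
            row = [s.sample_id, s.cultivar]
            for name in table.locus_names:
                call = s.call(name)
                if call.is_missing:
                    row += ["0", "0"]
                else:
                    row += [str(call.allele_a), str(call.allele_b)]
            writer.writerow(row)
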