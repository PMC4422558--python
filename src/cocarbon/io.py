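"""CSV ingestion and serialization for growth tables and C-line data.

Two-file dialect for growth studies:

* ``singles.csv`` — header ``substrate,rate_per_h``; one row per substrate.
* ``pairs.csv`` — header ``substrate_1,substrate_2,rate_per_h,group``; one
  row per unordered substrate pair, group ``A`` or ``B``.

C-line expression data use a single file with header
``condition,rate_per_h,expression``.

Rates are written with ``repr`` (shortest exact decimal) so a write/read
round trip is lossless at double precision.  Unordered duplicate pairs are collapsed on
ingest with a logged warning; every parse error names the file, line number
and offending value.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .analysis import GrowthTable, PairObservation
from .cline import CLinePoint

__all__ = [
    "read_growth_table",
    "write_growth_table",
    "read_cline_csv",
    "write_cline_csv",
]

logger = logging.getLogger(__name__)

SINGLES_HEADER = ["substrate", "rate_per_h"]
PAIRS_HEADER = ["substrate_1", "substrate_2", "rate_per_h", "group"]
CLINE_HEADER = ["condition", "rate_per_h", "expression"]


class TableFormatError(ValueError):
    """A growth-table or C-line CSV file violates the documented dialect."""


def _open_rows(path: str | Path, expected_header: list[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise TableFormatError(f"{path.name}: file is empty, expected header "
                               f"{','.join(expected_header)}")
    header = [c.strip().lower() for c in rows[0]]
    if header != expected_header:
        raise TableFormatError(
            f"{path.name} line 1: malformed header {','.join(rows[0])!r}, "
            f"expected {','.join(expected_header)}"
        )
    return path, rows[1:]


def _parse_rate(raw: str, where: str) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise TableFormatError(f"{where}: non-numeric rate {raw!r}") from None
    if not value > 0:
        raise TableFormatError(f"{where}: rate must be > 0, got {raw!r}")
    return value


def read_growth_table(singles_path: str | Path, pairs_path: str | Path) -> GrowthTable:
    """Read and validate a growth study from ``singles.csv`` + ``pairs.csv``.

    Raises :class:`TableFormatError` with a file/line-numbered message for
    any malformed row, unknown substrate, or non-positive rate.  Unordered
    duplicate pairs are collapsed (first occurrence wins) with a warning.
    """
    spath, srows = _open_rows(singles_path, SINGLES_HEADER)
    singles: dict[str, float] = {}
    for lineno, row in enumerate(srows, start=2):
        where = f"{spath.name} line {lineno}"
        if len(row) != 2:
            raise TableFormatError(f"{where}: expected 2 columns, got {len(row)}")
        name = row[0].strip()
        if not name:
            raise TableFormatError(f"{where}: empty substrate name")
        if name in singles:
            raise TableFormatError(f"{where}: duplicate substrate {name!r}")
        singles[name] = _parse_rate(row[1], where)

    ppath, prows = _open_rows(pairs_path, PAIRS_HEADER)
    pairs: list[PairObservation] = []
    seen: dict[frozenset[str], int] = {}
    for lineno, row in enumerate(prows, start=2):
        where = f"{ppath.name} line {lineno}"
        if len(row) != 4:
            raise TableFormatError(f"{where}: expected 4 columns, got {len(row)}")
        s1, s2 = row[0].strip(), row[1].strip()
        for s in (s1, s2):
            if s not in singles:
                raise TableFormatError(
                    f"{where}: unknown substrate {s!r} (no single rate declared)"
                )
        rate = _parse_rate(row[2], where)
        group = row[3].strip().upper()
        if group not in ("A", "B"):
            raise TableFormatError(f"{where}: group must be A or B, got {row[3]!r}")
        key = frozenset((s1, s2))
        if key in seen:
            logger.warning(
                "%s: unordered pair %s+%s already read at line %d; keeping first",
                where, s1, s2, seen[key],
            )
            continue
        seen[key] = lineno
        pairs.append(PairObservation(substrate_1=s1, substrate_2=s2, rate=rate, group=group))
    return GrowthTable(singles=singles, pairs=tuple(pairs))


def write_growth_table(
    table: GrowthTable, singles_path: str | Path, pairs_path: str | Path
) -> None:
    """Write a growth table in the same dialect :func:`read_growth_table` reads."""
    with Path(singles_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(SINGLES_HEADER)
        for name, rate in table.singles.items():
            w.writerow([name, repr(float(rate))])
    with Path(pairs_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PAIRS_HEADER)
        for p in table.pairs:
            w.writerow([p.substrate_1, p.substrate_2, repr(float(p.rate)), p.group])


def read_cline_csv(path: str | Path) -> list[CLinePoint]:
    """Read C-line points from ``condition,rate_per_h,expression`` CSV."""
    cpath, rows = _open_rows(path, CLINE_HEADER)
    points: list[CLinePoint] = []
    for lineno, row in enumerate(rows, start=2):
        where = f"{cpath.name} line {lineno}"
        if len(row) != 3:
            raise TableFormatError(f"{where}: expected 3 columns, got {len(row)}")
        rate = _parse_rate(row[1], where)
        try:
            expression = float(row[2])
        except ValueError:
            raise TableFormatError(f"{where}: non-numeric expression {row[2]!r}") from None
        if expression < 0:
            raise TableFormatError(f"{where}: expression must be >= 0, got {row[2]!r}")
        points.append(CLinePoint(rate=rate, expression=expression, condition=row[0].strip()))
    return points


def write_cline_csv(points: list[CLinePoint], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CLINE_HEADER)
        for p in points:
            w.writerow([p.condition, repr(float(p.rate)), repr(float(p.expression))])
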