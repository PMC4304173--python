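"""Readers and writers for the plain-text exchange formats.

All inputs are tab-delimited UTF-8 text with a header row:

* annotation table  — ``symbol  chromosome  start  end  [cytoband]``
* probe map         — ``platform_id  probe_id  symbol`` (empty symbol = unmapped)
* sample matrix     — ``probe_id`` plus one column per sample (GEO
  series-matrix style); blank cells or the literal ``NA`` are missing values.

Coordinates are 1-based and inclusive throughout.  Probe-level values are
kept raw here; scale conversion happens in :mod:`txmap.normalization`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: accepted spellings of a missing cell in a sample matrix
MISSING_TOKENS = {"", "NA", "NaN", "nan", "null", "NULL"}

#: marker used for probes that do not map to any locus
UNMAPPED = "unmapped"

SCALE_TAGS = ("linear", "log2", "log10", "ln")


@dataclass(frozen=True)
class LocusAnnotation:
    """Genomic identity of one mappable locus (gene or EST cluster)."""

    symbol: str
    chromosome: str
    start: int
    end: int
    cytoband: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValidationError("locus symbol must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"locus {self.symbol}: require 1 <= start <= end, "
                f"got start={self.start} end={self.end}"
            )


@dataclass(frozen=True)
class ProbeAssignment:
    """One probe's locus assignment on one platform."""

    platform_id: str
    probe_id: str
    symbol: str  # locus symbol, or UNMAPPED

    @property
    def is_mapped(self) -> bool:
        return self.symbol != UNMAPPED


@dataclass
class SampleDataset:
    """One sample's probe-level values on one platform.

    ``values`` maps probe_id to a float; missing measurements are NaN.
    ``scale`` declares how the deposited numbers encode intensity.
    """

    sample_id: str
    pool_id: str
    platform_id: str
    values: dict[str, float]
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALE_TAGS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown scale {self.scale!r}; "
                f"expected one of {SCALE_TAGS}"
            )


@dataclass
class LocusDataPoints:
    """All data points measuring one locus: (sample_id, value) pairs."""

    symbol: str
    points: list[tuple[str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)


def _open_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        yield from csv.reader(fh, delimiter="\t")


def read_annotation(path: str | Path) -> list[LocusAnnotation]:
    """Read a locus annotation table.

    Raises :class:`ParseError` on malformed rows and :class:`ValidationError`
    on duplicate symbols or inverted coordinates (with the line number).
    """
    rows = iter(_open_rows(path))
    try:
        header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected a header row") from None
    required = ["symbol", "chromosome", "start", "end"]
    if [h.strip().lower() for h in header[:4]] != required:
        raise ParseError(
            f"{path}: header must begin with {required}, got {header[:4]}"
        )
    has_cytoband = len(header) >= 5 and header[4].strip().lower() == "cytoband"

    out: list[LocusAnnotation] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 4:
            raise ParseError(f"{path}:{lineno}: expected >= 4 columns, got {len(row)}")
        symbol = row[0].strip()
        if symbol in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate symbol {symbol!r}")
        seen.add(symbol)
        try:
            start, end = int(row[2]), int(row[3])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric coordinate {row[2]!r}/{row[3]!r}"
            ) from None
        if start > end:
            raise ValidationError(
                f"{path}:{lineno}: start {start} > end {end} for {symbol!r}"
            )
        cytoband = row[4].strip() if has_cytoband and len(row) > 4 else ""
        out.append(LocusAnnotation(symbol, row[1].strip(), start, end, cytoband))
    return out


def write_annotation(loci: Sequence[LocusAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["symbol", "chromosome", "start", "end", "cytoband"])
        for loc in loci:
            w.writerow([loc.symbol, loc.chromosome, loc.start, loc.end, loc.cytoband])


def read_probe_map(
    path: str | Path, annotation: Sequence[LocusAnnotation]
) -> list[ProbeAssignment]:
    """Read a probe→locus map and validate symbols against ``annotation``.

    An empty symbol cell marks an unmapped probe (control spots etc.); these
    are retained with symbol :data:`UNMAPPED` and counted in the log.
    """
    known = {a.symbol for a in annotation}
    rows = iter(_open_rows(path))
    try:
        header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected a header row") from None
    required = ["platform_id", "probe_id", "symbol"]
    if [h.strip().lower() for h in header[:3]] != required:
        raise ParseError(f"{path}: header must be {required}, got {header[:3]}")

    out: list[ProbeAssignment] = []
    seen: set[tuple[str, str]] = set()
    n_unmapped = 0
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
        platform, probe = row[0].strip(), row[1].strip()
        key = (platform, probe)
        if key in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate probe {probe!r} on platform {platform!r}"
            )
        seen.add(key)
        symbol = row[2].strip() if len(row) > 2 else ""
        if not symbol:
            symbol = UNMAPPED
            n_unmapped += 1
        elif symbol not in known:
            raise ValidationError(
                f"{path}:{lineno}: symbol {symbol!r} absent from annotation"
            )
        out.append(ProbeAssignment(platform, probe, symbol))
    if n_unmapped:
        logger.info("%s: %d unmapped probes retained", path, n_unmapped)
    return out


def write_probe_map(assignments: Sequence[ProbeAssignment], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["platform_id", "probe_id", "symbol"])
        for a in assignments:
            w.writerow([a.platform_id, a.probe_id, "" if not a.is_mapped else a.symbol])


def _parse_cell(cell: str, path, lineno: int, colname: str) -> float:
    text = cell.strip()
    if text in MISSING_TOKENS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric value {cell!r} in column {colname!r}"
        ) from None


def read_sample_matrix(
    path: str | Path, platform_id: str, pool_id: str, scale: str = "linear"
) -> list[SampleDataset]:
    """Read a probe × sample matrix into one :class:`SampleDataset` per column.

    Values are kept raw; linearization is deferred to the normalization stage.
    """
    rows = iter(_open_rows(path))
    try:
        header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file, expected a header row") from None
    sample_ids = [h.strip() for h in header[1:]]
    if not sample_ids:
        raise ParseError(f"{path}: no sample columns (header-only probe column)")
    width = len(header)

    values: list[dict[str, float]] = [dict() for _ in sample_ids]
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row, expected {width} cells got {len(row)}"
            )
        probe = row[0].strip()
        for j, cell in enumerate(row[1:]):
            values[j][probe] = _parse_cell(cell, path, lineno, sample_ids[j])

    return [
        SampleDataset(sample_id=sid, pool_id=pool_id, platform_id=platform_id,
                      values=vals, scale=scale)
        for sid, vals in zip(sample_ids, values)
    ]


def write_sample_matrix(
    datasets: Sequence[SampleDataset], path: str | Path,
    float_format: str = "{:.6g}",
) -> None:
    """Write datasets (all on one platform) as a probe × sample matrix."""
    if not datasets:
        raise ValidationError("write_sample_matrix: no datasets")
    platforms = {d.platform_id for d in datasets}
    if len(platforms) != 1:
        raise ValidationError(f"one platform per matrix file, got {sorted(platforms)}")
    probes: list[str] = []
    seen: set[str] = set()
    for d in datasets:
        for p in d.values:
            if p not in seen:
                seen.add(p)
                probes.append(p)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["probe_id"] + [d.sample_id for d in datasets])
        for probe in probes:
            row = [probe]
            for d in datasets:
                v = d.values.get(probe, math.nan)
                row.append("" if math.isnan(v) else float_format.format(v))
            w.writerow(row)


def decode_probes(
    dataset: SampleDataset,
    probe_map: Sequence[ProbeAssignment],
    strict: bool = False,
) -> list[LocusDataPoints]:
    """Decode one sample's probe values to per-locus data points.

    A mapped probe with a measured (non-missing) value contributes exactly one
    data point under its locus; unmapped probes and missing values contribute
    nothing.  Probes absent from the map raise in ``strict`` mode and are
    skipped with a logged count otherwise.  Output is sorted by symbol.
    """
    mapping: dict[str, str] = {
        a.probe_id: a.symbol
        for a in probe_map
        if a.platform_id == dataset.platform_id
    }
    buckets: dict[str, list[tuple[str, float]]] = {}
    n_unknown = 0
    for probe, value in dataset.values.items():
        symbol = mapping.get(probe)
        if symbol is None:
            if strict:
                raise ValidationError(
                    f"sample {dataset.sample_id}: probe {probe!r} absent from "
                    f"the {dataset.platform_id} probe map"
                )
            n_unknown += 1
            continue
        if symbol == UNMAPPED or math.isnan(value):
            continue
        buckets.setdefault(symbol, []).append((dataset.sample_id, value))
    if n_unknown:
        logger.info(
            "sample %s: skipped %d probes absent from the probe map",
            dataset.sample_id, n_unknown,
        )
    return [LocusDataPoints(sym, pts) for sym, pts in sorted(buckets.items())]
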