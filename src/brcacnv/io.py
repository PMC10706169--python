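"""Readers and writers for the panel, coverage and cluster files.

File dialects (all UTF-8, tab-delimited, ``#`` comment lines ignored):

* region file — BED-like TSV with at least four columns
  ``chrom  start  end  name`` where ``name`` is ``GENE|EXONS[|POOL]``,
  e.g. ``BRCA1|ex10|p1`` or ``BRCA1|ex3-ex4|p2`` for a region spanning
  two exons.  Coordinates are 0-based half-open.
* coverage table — TSV, first column the region name, header row of
  sample IDs, one row per region.
* cluster file — two columns ``sample  cluster``.
"""
from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GENES, CoverageTable, Panel, PanelError, TargetRegion


class ParseError(ValueError):
    pass


def _parse_name(name: str, lineno: int) -> tuple[str, tuple[str, ...], str | None]:
    # GENE|EXONS[|POOL[|TAG]]; TAG only disambiguates multi-amplicon exons
    parts = name.split("|")
    if len(parts) not in (2, 3, 4):
        raise ParseError(
            f"line {lineno}: region name {name!r} is not GENE|EXONS[|POOL[|TAG]]"
        )
    gene = parts[0]
    if gene not in GENES:
        raise ParseError(
            f"line {lineno}: unknown gene {gene!r}; expected one of {GENES}"
        )
    exons = tuple(x for x in parts[1].split("-") if x)
    if not exons:
        raise ParseError(f"line {lineno}: region name {name!r} lists no exons")
    pool = parts[2] if len(parts) >= 3 and parts[2] else None
    return gene, exons, pool


def read_regions(path: str | Path) -> Panel:
    """Parse the target-region coordinate file into a :class:`Panel`."""
    regions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"line {lineno}: expected >=4 tab-separated columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            gene, exons, pool = _parse_name(name, lineno)
            try:
                regions.append(
                    TargetRegion(chrom, start, end, gene, exons, pool, name=name)
                )
            except PanelError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return Panel(regions)


def read_coverage_table(path: str | Path, panel: Panel) -> CoverageTable:
    """Read the coverage TSV and align its rows to panel order.

    Rows may appear in any order; they are joined on the region name.
    Absent cells, negative values and duplicate sample IDs are errors.
    """
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        rows: dict[str, list[str]] = {}
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if len(set(header)) != len(header):
                    raise ParseError("duplicate sample IDs in coverage header")
                continue
            name = fields[0]
            if name in rows:
                raise ParseError(f"line {lineno}: duplicate region row {name!r}")
            rows[name] = fields[1:]
    if header is None:
        raise ParseError("coverage table has no header row")
    if set(rows) != set(panel.names):
        missing = sorted(set(panel.names) - set(rows))
        extra = sorted(set(rows) - set(panel.names))
        raise ParseError(
            f"coverage rows do not match the panel "
            f"(missing: {missing[:5]}, unknown: {extra[:5]})"
        )
    depth = np.empty((len(panel), len(header)), dtype=float)
    for i, name in enumerate(panel.names):
        vals = rows[name]
        if len(vals) != len(header):
            raise ParseError(
                f"region {name!r}: {len(vals)} cells for {len(header)} samples"
            )
        for j, (sample, cell) in enumerate(zip(header, vals)):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric depth for region {name!r}, sample {sample!r}: {cell!r}"
                ) from exc
            if not np.isfinite(v):
                raise ParseError(f"missing depth for region {name!r}, sample {sample!r}")
            if v < 0:
                raise ParseError(
                    f"negative depth for region {name!r}, sample {sample!r}: {v}"
                )
            depth[i, j] = v
    return CoverageTable(panel=panel, samples=list(header), depth=depth)


def write_coverage_table(table: CoverageTable, path: str | Path) -> None:
    """Write a coverage table in the dialect read_coverage_table accepts.

    Depths are written with repr-roundtrip precision so that write/read
    reproduces the matrix exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("region\t" + "\t".join(table.samples) + "\n")
        for i, name in enumerate(table.panel.names):
            cells = "\t".join(repr(float(v)) for v in table.depth[i])
            fh.write(f"{name}\t{cells}\n")


DEFAULT_CLUSTER = "cluster0"


def read_clusters(path: str | Path, samples: list[str]) -> dict[str, str]:
    """Read the optional sample->cluster assignment file.

    Samples absent from the file fall into one common default cluster; a
    file row naming an unknown sample is an error.
    """
    assigned: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected 'sample<TAB>cluster'")
            sample, cluster = fields[0], fields[1]
            if sample not in samples:
                raise ParseError(
                    f"line {lineno}: sample {sample!r} not present in the coverage table"
                )
            assigned[sample] = cluster
    return {s: assigned.get(s, DEFAULT_CLUSTER) for s in samples}
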