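"""Gene annotation parsing and capture-panel construction.

A capture panel is the per-gene union of all annotated transcript exons,
merged into disjoint intervals.  All interval arithmetic here is 0-based
half-open; GTF input/output uses the standard 1-based inclusive convention.
"""

from __future__ import annotations

import re
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "DEFAULT_PANEL_GENES",
    "GeneModel",
    "TargetPanel",
    "GeneIndex",
    "GtfParseError",
    "read_gene_models",
    "merge_exons",
    "merge_intervals",
    "write_panel_bed",
    "read_panel_bed",
]

#: Default capture panel gene symbols (kinase fusion targets).
DEFAULT_PANEL_GENES = ("ABL2", "CSF1R", "PDGFRB", "JAK2", "ABL1", "EPOR", "CRLF2")

Interval = tuple[int, int]


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass
class GeneModel:
    """One gene: identity plus the pooled exons of all its transcripts."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"gene {self.gene_id}: bad exon interval [{s},{e})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or book-ended intervals into a minimal disjoint set."""
    ivls = sorted(intervals)
    if not ivls:
        return []
    merged = [ivls[0]]
    for s, e in ivls[1:]:
        ps, pe = merged[-1]
        if s <= pe:  # book-ended intervals are merged: contiguous capture DNA
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def merge_exons(gene: GeneModel) -> list[Interval]:
    """Merged, disjoint, sorted exon union for one gene."""
    return merge_intervals(gene.exons)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gene_models(source: str | Path | TextIO) -> list[GeneModel]:
    """Parse a GTF stream into one :class:`GeneModel` per ``gene_id``.

    Only ``exon`` features contribute; duplicate exons (same interval) are
    pooled once.  Genes that never appear with an exon feature are dropped.
    Malformed lines raise :class:`GtfParseError` naming the line number.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle = source
    exons: dict[str, set[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (name, chrom, strand)
    order: list[str] = []
    exonless: set[str] = set()
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                gid = _parse_attributes(attrs).get("gene_id")
                if gid and gid not in exons:
                    exonless.add(gid)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GtfParseError(f"line {lineno}: bad coordinates {start_s}..{end_s}")
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            if gene_id not in exons:
                exons[gene_id] = set()
                order.append(gene_id)
                meta[gene_id] = (attributes.get("gene_name", gene_id), chrom, strand)
            exons[gene_id].add((start - 1, end))  # GTF is 1-based inclusive
    finally:
        if close:
            handle.close()
    for gid in sorted(exonless - set(exons)):
        warnings.warn(f"gene {gid} has no exon features; excluded", stacklevel=2)
    return [
        GeneModel(gene_id=g, gene_name=meta[g][0], chrom=meta[g][1],
                  strand=meta[g][2], exons=sorted(exons[g]))
        for g in order
    ]


@dataclass
class TargetPanel:
    """A set of genes with their merged capture regions."""

    genes: list[GeneModel]
    regions: dict[str, list[Interval]]  # gene_id -> merged disjoint sorted intervals
    total_target_bases: int

    @classmethod
    def build(
        cls,
        genes: Iterable[GeneModel],
        panel_gene_names: Iterable[str] | None = DEFAULT_PANEL_GENES,
    ) -> "TargetPanel":
        """Restrict *genes* to *panel_gene_names* (by symbol; ``None`` keeps all)
        and merge each gene's exons into capture regions."""
        genes = list(genes)
        if panel_gene_names is not None:
            wanted = set(panel_gene_names)
            genes = [g for g in genes if g.gene_name in wanted or g.gene_id in wanted]
        regions = {g.gene_id: merge_exons(g) for g in genes}
        total = sum(e - s for ivls in regions.values() for s, e in ivls)
        return cls(genes=genes, regions=regions, total_target_bases=total)

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def gene_ids(self) -> set[str]:
        return set(self.regions)


class GeneIndex:
    """Interval index over a panel's merged regions.

    Query results are identical to a brute-force scan over every region;
    internally intervals are binary-searched on start with a running-max-end
    array to bound the scan.
    """

    def __init__(self) -> None:
        # chrom -> (starts, running_max_end, entries); entries sorted by start
        self._by_chrom: dict[str, tuple[list[int], list[int], list[tuple[int, int, str]]]] = {}

    @classmethod
    def build(cls, panel: TargetPanel) -> "GeneIndex":
        idx = cls()
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene in panel.genes:
            for s, e in panel.regions[gene.gene_id]:
                per_chrom.setdefault(gene.chrom, []).append((s, e, gene.gene_id))
        for chrom, entries in per_chrom.items():
            entries.sort()
            starts = [s for s, _, _ in entries]
            run_max: list[int] = []
            cur = 0
            for _, e, _ in entries:
                cur = max(cur, e)
                run_max.append(cur)
            idx._by_chrom[chrom] = (starts, run_max, entries)
        return idx

    def query(self, chrom: str, start: int, end: int) -> list[tuple[str, int]]:
        """Genes whose regions overlap ``[start, end)`` with total overlap bp.

        Unknown chromosomes yield an empty result. Results sorted by gene_id.
        """
        if chrom not in self._by_chrom or start >= end:
            return []
        starts, run_max, entries = self._by_chrom[chrom]
        hi = bisect_left(starts, end)
        lo = bisect_right(run_max, start, 0, hi)
        overlaps: dict[str, int] = {}
        for s, e, gene_id in entries[lo:hi]:
            ov = min(e, end) - max(s, start)
            if ov > 0:
                overlaps[gene_id] = overlaps.get(gene_id, 0) + ov
        return sorted(overlaps.items())


def write_panel_bed(panel: TargetPanel, path: str | Path) -> None:
    """Write merged capture regions as 4-column BED (0-based half-open)."""
    with open(path, "w") as out:
        for gene in panel.genes:
            for s, e in panel.regions[gene.gene_id]:
                out.write(f"{gene.chrom}\t{s}\t{e}\t{gene.gene_id}\n")


def read_panel_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a 4-column BED back as gene_id -> [(chrom, start, end), ...]."""
    regions: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, s, e, gene_id = line.rstrip("\n").split("\t")[:4]
            regions.setdefault(gene_id, []).append((chrom, int(s), int(e)))
    return regions
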