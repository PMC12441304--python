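"""Panel capture/coverage metrics and summary statistics.

Depth counts reference-aligned bases (CIGAR M/=/X) once per alignment
record, supplementary records included; deletions and intron skips (D/N)
do not contribute.  Capture rate is the fraction of all aligned bases that
fall inside the panel's merged target regions.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping

import numpy as np
import pysam

from .panel import TargetPanel

__all__ = [
    "PanelDepth",
    "PanelQC",
    "FusionYield",
    "EnrichmentResult",
    "depth_profile",
    "breadth",
    "capture_rate",
    "normalized_depth_1000x",
    "expression_outlier_flags",
    "enrichment_fold",
    "panel_qc",
]


@dataclass
class PanelDepth:
    """Per-base depth over every target region, plus aligned-base tallies."""

    # (gene_id, region_index) -> depth array over that region
    arrays: dict[tuple[str, int], np.ndarray]
    regions: dict[tuple[str, int], tuple[str, int, int]]  # -> (chrom, start, end)
    total_aligned_bases: int
    on_target_aligned_bases: int

    def gene_arrays(self, gene_id: str) -> list[np.ndarray]:
        return [a for (g, _), a in sorted(self.arrays.items()) if g == gene_id]

    def all_depths(self) -> np.ndarray:
        if not self.arrays:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([a for _, a in sorted(self.arrays.items())])

    def gene_mean_depth(self, gene_id: str) -> float:
        arrays = self.gene_arrays(gene_id)
        total = sum(a.size for a in arrays)
        if total == 0:
            return 0.0
        return float(sum(a.sum() for a in arrays) / total)

    @property
    def panel_mean_depth(self) -> float:
        depths = self.all_depths()
        return float(depths.mean()) if depths.size else 0.0


class _RegionLookup:
    """bisect-backed lookup of target regions overlapping a reference interval."""

    def __init__(self, panel: TargetPanel):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[tuple[int, int, str, int]]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str, int]]] = {}
        for gene in panel.genes:
            for ridx, (s, e) in enumerate(panel.regions[gene.gene_id]):
                per_chrom.setdefault(gene.chrom, []).append((s, e, gene.gene_id, ridx))
        for chrom, entries in per_chrom.items():
            entries.sort()
            starts = [s for s, _, _, _ in entries]
            run_max, cur = [], 0
            for _, e, _, _ in entries:
                cur = max(cur, e)
                run_max.append(cur)
            self._by_chrom[chrom] = (starts, run_max, entries)

    def overlapping(self, chrom: str, start: int, end: int):
        if chrom not in self._by_chrom:
            return
        starts, run_max, entries = self._by_chrom[chrom]
        hi = bisect_left(starts, end)
        lo = bisect_right(run_max, start, 0, hi)
        for s, e, gene_id, ridx in entries[lo:hi]:
            if min(e, end) > max(s, start):
                yield s, e, gene_id, ridx


def _ref_blocks(rec: pysam.AlignedSegment) -> Iterable[tuple[int, int]]:
    """Reference intervals consumed by M/=/X ops (D and N advance only)."""
    pos = rec.reference_start
    for op, length in rec.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            yield pos, pos + length
            pos += length
        elif op in (2, 3):  # D, N
            pos += length


def depth_profile(
    sam: str | Path | Iterable[pysam.AlignedSegment], panel: TargetPanel
) -> PanelDepth:
    """Per-base depth over all target regions from primary + supplementary
    records (secondary and unmapped are skipped)."""
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as handle:
            return depth_profile(list(handle), panel)
    lookup = _RegionLookup(panel)
    arrays: dict[tuple[str, int], np.ndarray] = {}
    regions: dict[tuple[str, int], tuple[str, int, int]] = {}
    for gene in panel.genes:
        for ridx, (s, e) in enumerate(panel.regions[gene.gene_id]):
            arrays[(gene.gene_id, ridx)] = np.zeros(e - s, dtype=np.int64)
            regions[(gene.gene_id, ridx)] = (gene.chrom, s, e)
    total = 0
    on_target = 0
    for rec in sam:
        if rec.is_unmapped or rec.is_secondary:
            continue
        for bs, be in _ref_blocks(rec):
            total += be - bs
            for s, e, gene_id, ridx in lookup.overlapping(rec.reference_name, bs, be):
                lo, hi = max(s, bs), min(e, be)
                on_target += hi - lo
                arrays[(gene_id, ridx)][lo - s : hi - s] += 1
    return PanelDepth(
        arrays=arrays,
        regions=regions,
        total_aligned_bases=total,
        on_target_aligned_bases=on_target,
    )


def breadth(profile: PanelDepth | np.ndarray, threshold: int) -> float:
    """Fraction of target bases covered at depth >= *threshold*."""
    depths = profile.all_depths() if isinstance(profile, PanelDepth) else np.asarray(profile)
    if depths.size == 0:
        raise ValueError("breadth is undefined over an empty target")
    return float((depths >= threshold).mean())


def capture_rate(profile: PanelDepth) -> float | None:
    """On-target aligned bases / all aligned bases; ``None`` with no alignment."""
    if profile.total_aligned_bases == 0:
        return None
    return profile.on_target_aligned_bases / profile.total_aligned_bases


def normalized_depth_1000x(gene_mean_depth: float, panel_mean_depth: float) -> float:
    """1000 x gene mean depth / panel mean depth."""
    if panel_mean_depth <= 0:
        raise ValueError("panel mean depth must be positive")
    return 1000.0 * gene_mean_depth / panel_mean_depth


def expression_outlier_flags(
    normalized_depths: Mapping[str, float], k: float = 5.0
) -> dict[str, bool]:
    """Flag genes whose normalized depth exceeds *k* times the median
    normalized depth of the other panel genes (elevated-expression signal,
    e.g. a rearrangement whose partner is invisible to mRNA capture)."""
    if len(normalized_depths) < 2:
        raise ValueError("need at least two genes to flag outliers")
    flags: dict[str, bool] = {}
    for gene, value in normalized_depths.items():
        others = [v for g, v in normalized_depths.items() if g != gene]
        flags[gene] = value > k * median(others)
    return flags


@dataclass
class FusionYield:
    """Fusion-supporting read count and QC-passed megabases of one library."""

    n_fusion_support_reads: int
    qc_bases_mb: float

    def __post_init__(self) -> None:
        if self.n_fusion_support_reads < 0 or self.qc_bases_mb < 0:
            raise ValueError("yields must be non-negative")


@dataclass
class EnrichmentResult:
    fold: float | None  # None == NA (no background fusion reads)

    @property
    def is_na(self) -> bool:
        return self.fold is None


def enrichment_fold(targeted: FusionYield, background: FusionYield) -> EnrichmentResult:
    """Fusion-supporting reads per megabase, targeted over background."""
    if targeted.qc_bases_mb == 0 or background.qc_bases_mb == 0:
        raise ValueError("QC bases must be positive for both libraries")
    if background.n_fusion_support_reads == 0:
        return EnrichmentResult(fold=None)
    rate_t = targeted.n_fusion_support_reads / targeted.qc_bases_mb
    rate_b = background.n_fusion_support_reads / background.qc_bases_mb
    return EnrichmentResult(fold=rate_t / rate_b)


@dataclass
class PanelQC:
    capture_rate: float | None
    breadth_1x: float
    breadth_500x: float
    per_gene_mean_depth: dict[str, float]
    panel_mean_depth: float
    normalized_depth_1000x: dict[str, float]
    outlier_flags: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "capture_rate": self.capture_rate,
            "breadth_1x": self.breadth_1x,
            "breadth_500x": self.breadth_500x,
            "per_gene_mean_depth": self.per_gene_mean_depth,
            "panel_mean_depth": self.panel_mean_depth,
            "normalized_depth_1000x": self.normalized_depth_1000x,
            "outlier_flags": self.outlier_flags,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(self.to_dict(), out, indent=2)
            out.write("\n")


def panel_qc(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    panel: TargetPanel,
    outlier_k: float = 5.0,
) -> PanelQC:
    """Full panel QC report from one alignment set."""
    profile = depth_profile(sam, panel)
    per_gene = {g.gene_id: profile.gene_mean_depth(g.gene_id) for g in panel.genes}
    panel_mean = profile.panel_mean_depth
    if panel_mean > 0:
        norm = {g: normalized_depth_1000x(d, panel_mean) for g, d in per_gene.items()}
    else:
        norm = {g: 0.0 for g in per_gene}
    flags = (
        expression_outlier_flags(norm, k=outlier_k)
        if len(norm) >= 2
        else {g: False for g in norm}
    )
    return PanelQC(
        capture_rate=capture_rate(profile),
        breadth_1x=breadth(profile, 1),
        breadth_500x=breadth(profile, 500),
        per_gene_mean_depth=per_gene,
        panel_mean_depth=panel_mean,
        normalized_depth_1000x=norm,
        outlier_flags=flags,
    )
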