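"""Gene fusion detection from splice-aware long-read alignments.

A chimeric read aligns as a primary record plus one or more supplementary
records.  The caller reconstructs each read's ordered segment chain in
original-read (query) coordinates, labels segments with the gene of maximal
reference overlap, emits an ordered ``gene5::gene3`` candidate for every
adjacent pair of distinct gene labels, clusters per-read breakpoints by
single linkage, and then applies a switchable false-positive filter stack:

1. ``panel_anchor``   — at least one partner must be a capture-panel gene;
2. ``min_support``    — enough supporting reads;
3. ``read_through``   — nearby same-chromosome, same-strand gene pairs are
   transcriptional read-through artifacts unless both partners are panel genes;
4. ``overlapping_genes`` — partners whose merged regions intersect;
5. ``min_segment``    — a supporting read counts only if both of its
   gene-side segments align enough reference bases.

Breakpoints are reported 1-based: for each gene-side segment the reference
coordinate of the aligned base adjacent to the query-space junction
(orientation-aware, so for a ``-`` strand 5' segment this is its lower
reference coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import pysam

from .panel import GeneIndex, GeneModel, TargetPanel

__all__ = [
    "AlignedSegment",
    "ReadChain",
    "SupportRead",
    "FusionCandidate",
    "FusionCall",
    "CallerParams",
    "parse_alignments",
    "assign_genes",
    "call_candidates",
    "filter_candidates",
    "fusion_frequency",
    "call_fusions",
    "write_calls_tsv",
]

_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M, I, S, =, X
_CLIP_OPS = {4, 5}  # S, H


@dataclass
class AlignedSegment:
    """One alignment record mapped back into original-read coordinates."""

    read_id: str
    query_start: int  # 0-based half-open on the original (pre-clip) read
    query_end: int
    ref_chrom: str
    ref_start: int  # 0-based half-open on the reference
    ref_end: int
    strand: str
    mapq: int
    is_supplementary: bool
    aligned_ref_bases: int  # M/=/X reference bases

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end or self.ref_start >= self.ref_end:
            raise ValueError(f"read {self.read_id}: empty alignment interval")
        if self.aligned_ref_bases > self.ref_end - self.ref_start:
            raise ValueError(f"read {self.read_id}: aligned bases exceed reference span")


@dataclass
class ReadChain:
    """All of one read's segments, sorted by query start, with gene labels."""

    read_id: str
    segments: list[AlignedSegment]
    gene_labels: list[str | None] = field(default_factory=list)

    def sort(self) -> None:
        self.segments.sort(key=lambda s: (s.query_start, s.query_end))


def _segment_from_record(rec: pysam.AlignedSegment) -> AlignedSegment:
    cigar = rec.cigartuples
    if cigar is None:
        raise ValueError(f"read {rec.query_name}: missing CIGAR")
    lead = 0
    for op, length in cigar:
        if op not in _CLIP_OPS:
            break
        lead += length
    trail = 0
    for op, length in reversed(cigar):
        if op not in _CLIP_OPS:
            break
        trail += length
    aligned_query = sum(l for op, l in cigar if op in (0, 1, 7, 8))
    # map back to original-read orientation: a reverse record's leading clip
    # corresponds to the 3' end of the read as sequenced
    if rec.is_reverse:
        q_start, q_end = trail, trail + aligned_query
    else:
        q_start, q_end = lead, lead + aligned_query
    return AlignedSegment(
        read_id=rec.query_name,
        query_start=q_start,
        query_end=q_end,
        ref_chrom=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        is_supplementary=rec.is_supplementary,
        aligned_ref_bases=sum(l for op, l in cigar if op in (0, 7, 8)),
    )


def parse_alignments(sam: str | Path | Iterable[pysam.AlignedSegment]) -> list[ReadChain]:
    """Group primary + supplementary records into one :class:`ReadChain` per read.

    Secondary (flag 256) and unmapped records are dropped.  Chains are
    returned sorted by read_id; segments within a chain by query start.
    """
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as handle:
            return parse_alignments(list(handle))
    chains: dict[str, ReadChain] = {}
    for rec in sam:
        if rec.is_unmapped or rec.is_secondary:
            continue
        seg = _segment_from_record(rec)
        chains.setdefault(seg.read_id, ReadChain(seg.read_id, [])).segments.append(seg)
    out = [chains[rid] for rid in sorted(chains)]
    for chain in out:
        chain.sort()
    return out


def assign_genes(chain: ReadChain, index: GeneIndex, min_overlap: int = 100) -> ReadChain:
    """Label each segment with the gene of maximal reference-base overlap.

    Overlap below *min_overlap* leaves the segment unassigned; ties break by
    (larger overlap, then lexicographic gene_id).
    """
    labels: list[str | None] = []
    for seg in chain.segments:
        hits = index.query(seg.ref_chrom, seg.ref_start, seg.ref_end)
        best: str | None = None
        if hits:
            gene_id, overlap = min(hits, key=lambda h: (-h[1], h[0]))
            if overlap >= min_overlap:
                best = gene_id
        labels.append(best)
    chain.gene_labels = labels
    return chain


def _junction_edges(seg5: AlignedSegment, seg3: AlignedSegment) -> tuple[int, int]:
    """1-based reference coordinates of the segment edges flanking the junction."""
    # 5' partner: junction sits at the segment's query END
    bp5 = seg5.ref_end if seg5.strand == "+" else seg5.ref_start + 1
    # 3' partner: junction sits at the segment's query START
    bp3 = seg3.ref_start + 1 if seg3.strand == "+" else seg3.ref_end
    return bp5, bp3


@dataclass(frozen=True)
class SupportRead:
    """One read's evidence for an ordered gene pair."""

    read_id: str
    bp5: int  # 1-based
    bp3: int
    seg5_ref_bases: int
    seg3_ref_bases: int


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    breakpoint5: int  # 1-based cluster representative (median)
    breakpoint3: int
    support: list[SupportRead]
    breakpoint_cluster_span: int

    @property
    def supporting_reads(self) -> set[str]:
        return {s.read_id for s in self.support}

    @property
    def n_support(self) -> int:
        return len(self.support)


def _single_linkage_clusters(
    records: Sequence[SupportRead], window: int
) -> list[list[SupportRead]]:
    """Union-find single linkage: records link when both breakpoints are
    within *window* bp of each other."""
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(records[i].bp5 - records[j].bp5) <= window
                and abs(records[i].bp3 - records[j].bp3) <= window
            ):
                parent[find(j)] = find(i)
    groups: dict[int, list[SupportRead]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), []).append(rec)
    return sorted(groups.values(), key=lambda g: (min(r.bp5 for r in g), min(r.bp3 for r in g)))


def call_candidates(chains: Iterable[ReadChain], cluster_window: int = 50) -> list[FusionCandidate]:
    """Emit one candidate per ordered gene pair and breakpoint cluster.

    Every adjacent pair of distinct gene labels along a chain (in query
    order) contributes one support record; the 5' partner is the gene of the
    earlier query interval.
    """
    by_pair: dict[tuple[str, str, str, str], list[SupportRead]] = {}
    for chain in sorted(chains, key=lambda c: c.read_id):
        labeled = [
            (seg, label)
            for seg, label in zip(chain.segments, chain.gene_labels)
            if label is not None
        ]
        for (seg5, g5), (seg3, g3) in zip(labeled, labeled[1:]):
            if g5 == g3:
                continue
            bp5, bp3 = _junction_edges(seg5, seg3)
            key = (g5, g3, seg5.ref_chrom, seg3.ref_chrom)
            by_pair.setdefault(key, []).append(
                SupportRead(chain.read_id, bp5, bp3, seg5.aligned_ref_bases, seg3.aligned_ref_bases)
            )
    candidates: list[FusionCandidate] = []
    for (g5, g3, c5, c3), records in sorted(by_pair.items()):
        for cluster in _single_linkage_clusters(records, cluster_window):
            bp5s = [r.bp5 for r in cluster]
            bp3s = [r.bp3 for r in cluster]
            span = max(max(bp5s) - min(bp5s), max(bp3s) - min(bp3s))
            candidates.append(
                FusionCandidate(
                    gene5=g5,
                    gene3=g3,
                    chrom5=c5,
                    chrom3=c3,
                    breakpoint5=int(median(bp5s)),
                    breakpoint3=int(median(bp3s)),
                    support=cluster,
                    breakpoint_cluster_span=span,
                )
            )
    return candidates


@dataclass
class CallerParams:
    min_overlap: int = 100
    cluster_window: int = 50
    min_support: int = 3
    min_segment: int = 100
    readthrough_distance: int = 100_000
    locus_window: int = 50
    enabled_filters: tuple[str, ...] = (
        "panel_anchor",
        "min_support",
        "read_through",
        "overlapping_genes",
        "min_segment",
    )


@dataclass
class FusionCall:
    candidate: FusionCandidate
    n_support: int
    fusion_frequency: float | None
    status: str  # "PASS" or "FILTERED:<reason>"
    filters_passed: list[str]

    @property
    def is_pass(self) -> bool:
        return self.status == "PASS"

    @property
    def name(self) -> str:
        return f"{self.candidate.gene5}::{self.candidate.gene3}"


def _gene_distance(a: GeneModel, b: GeneModel) -> int | None:
    if a.chrom != b.chrom:
        return None
    a_s, a_e = a.span
    b_s, b_e = b.span
    return max(b_s - a_e, a_s - b_e, 0)


def _regions_intersect(ra: list[tuple[int, int]], rb: list[tuple[int, int]]) -> bool:
    for s1, e1 in ra:
        for s2, e2 in rb:
            if min(e1, e2) > max(s1, s2):
                return True
    return False


def filter_candidates(
    candidates: Iterable[FusionCandidate],
    annotation: TargetPanel,
    panel_gene_ids: set[str],
    params: CallerParams | None = None,
) -> list[FusionCall]:
    """Apply the false-positive filter stack, in order, to every candidate.

    *annotation* must cover all genes that may appear as labels (build it
    with ``panel_gene_names=None``); *panel_gene_ids* is the capture subset.
    """
    params = params or CallerParams()
    genes = annotation.genes_by_id
    enabled = set(params.enabled_filters)
    calls: list[FusionCall] = []
    for cand in candidates:
        passed: list[str] = []
        status = "PASS"
        n_support = cand.n_support
        g5, g3 = genes.get(cand.gene5), genes.get(cand.gene3)

        def fails(name: str, condition: bool) -> bool:
            nonlocal status
            if name not in enabled:
                return False
            if condition:
                status = f"FILTERED:{name}"
                return True
            passed.append(name)
            return False

        while True:  # single pass; `break` after first failing filter
            if fails(
                "panel_anchor",
                cand.gene5 not in panel_gene_ids and cand.gene3 not in panel_gene_ids,
            ):
                break
            if fails("min_support", n_support < params.min_support):
                break
            both_panel = cand.gene5 in panel_gene_ids and cand.gene3 in panel_gene_ids
            dist = _gene_distance(g5, g3) if g5 and g3 else None
            if fails(
                "read_through",
                g5 is not None
                and g3 is not None
                and not both_panel
                and g5.strand == g3.strand
                and dist is not None
                and dist < params.readthrough_distance,
            ):
                break
            if fails(
                "overlapping_genes",
                g5 is not None
                and g3 is not None
                and g5.chrom == g3.chrom
                and _regions_intersect(
                    annotation.regions[cand.gene5], annotation.regions[cand.gene3]
                ),
            ):
                break
            if "min_segment" in enabled:
                qualified = [
                    s
                    for s in cand.support
                    if s.seg5_ref_bases >= params.min_segment
                    and s.seg3_ref_bases >= params.min_segment
                ]
                if len(qualified) < params.min_support:
                    status = "FILTERED:min_segment"
                    break
                passed.append("min_segment")
                n_support = len(qualified)
            break
        calls.append(
            FusionCall(
                candidate=cand,
                n_support=n_support,
                fusion_frequency=None,
                status=status,
                filters_passed=passed,
            )
        )
    return calls


def fusion_frequency(
    call: FusionCall,
    chains: Iterable[ReadChain],
    panel_gene_ids: set[str],
    window: int = 50,
) -> float | None:
    """Supporting reads as a fraction of all reads overlapping the panel-gene
    breakpoint window (``None`` when no read overlaps the locus)."""
    cand = call.candidate
    if cand.gene5 in panel_gene_ids:
        chrom, bp = cand.chrom5, cand.breakpoint5
    elif cand.gene3 in panel_gene_ids:
        chrom, bp = cand.chrom3, cand.breakpoint3
    else:
        chrom, bp = cand.chrom5, cand.breakpoint5
    lo, hi = bp - 1 - window, bp + window  # 0-based half-open window
    n_locus = 0
    for chain in chains:
        for seg in chain.segments:
            if seg.ref_chrom == chrom and seg.ref_start < hi and seg.ref_end > lo:
                n_locus += 1
                break
    if n_locus == 0:
        return None
    return call.n_support / n_locus


def call_fusions(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    genes: list[GeneModel],
    panel_gene_names: Iterable[str] | None = None,
    params: CallerParams | None = None,
) -> tuple[list[FusionCall], list[ReadChain]]:
    """End-to-end convenience: parse, label, call, filter, and annotate
    fusion frequency.  Returns (all calls, labeled chains)."""
    from .panel import DEFAULT_PANEL_GENES

    params = params or CallerParams()
    annotation = TargetPanel.build(genes, panel_gene_names=None)
    capture = TargetPanel.build(
        genes, panel_gene_names=panel_gene_names or DEFAULT_PANEL_GENES
    )
    index = GeneIndex.build(annotation)
    chains = parse_alignments(sam)
    for chain in chains:
        assign_genes(chain, index, min_overlap=params.min_overlap)
    candidates = call_candidates(chains, cluster_window=params.cluster_window)
    calls = filter_candidates(candidates, annotation, capture.gene_ids(), params)
    for call in calls:
        if call.is_pass:
            call.fusion_frequency = fusion_frequency(
                call, chains, capture.gene_ids(), window=params.locus_window
            )
    return calls, chains


def write_calls_tsv(calls: Iterable[FusionCall], path: str | Path) -> None:
    cols = "gene5 gene3 chrom5 bp5 chrom3 bp3 n_support fusion_frequency status filters".split()
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for call in calls:
            c = call.candidate
            freq = "NA" if call.fusion_frequency is None else f"{call.fusion_frequency:.6f}"
            out.write(
                "\t".join(
                    [
                        c.gene5,
                        c.gene3,
                        c.chrom5,
                        str(c.breakpoint5),
                        c.chrom3,
                        str(c.breakpoint3),
                        str(call.n_support),
                        freq,
                        call.status,
                        ",".join(call.filters_passed) or "-",
                    ]
                )
                + "\n"
            )
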