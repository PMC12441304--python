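"""Fully synthetic targeted-capture nanopore RNA experiments.

Generates a toy genome, gene annotation and capture panel, builds wild-type
and fusion transcripts, fragments them with an RNA-integrity-driven
degradation model, adds nanopore-like substitution/insertion/deletion
errors, and emits truth alignments (primary + supplementary for junction
spanning reads) so the whole pipeline runs without any external aligner or
downloads.

Degradation model: each internal transcript position is cut independently
with probability ``c / rin**2`` (default c = 0.002), so low-RIN samples
yield short fragments; fragments below ``min_fragment`` are discarded.

Determinism: everything derives from ``SimConfig.seed``; identical configs
produce byte-identical FASTA/GTF/BED/FASTQ/SAM/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .panel import DEFAULT_PANEL_GENES, GeneModel, TargetPanel, write_panel_bed
from .qc import Read, write_fastq

__all__ = [
    "FusionSpec",
    "ReadthroughSpec",
    "SimConfig",
    "Reference",
    "Transcript",
    "ReadTruth",
    "TruthSet",
    "SimResult",
    "make_reference",
    "make_fusion_transcript",
    "degrade",
    "add_errors",
    "simulate_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# uint8 ASCII -> base index (unknowns treated as A for substitution purposes)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class FusionSpec:
    """Fusion transcript: exons 1..exon5 of gene5 joined to exons exon3..last
    of gene3 (1-based exon ranks over each gene's merged exons)."""

    gene5: str
    exon5: int
    gene3: str
    exon3: int
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("fusion frequency must be in [0, 1]")


@dataclass(frozen=True)
class ReadthroughSpec:
    """Transcriptional read-through chimera joining two full adjacent genes."""

    gene_a: str
    gene_b: str
    frequency: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    chrom: str = "chrS"  # panel genes live here
    off_chrom: str = "chrT"  # off-panel genes (fusion partners, decoys) here
    panel_gene_names: tuple[str, ...] = DEFAULT_PANEL_GENES
    n_genes: int = 10  # panel genes first, then off-target genes G1..Gk
    # non-panel decoys placed on the panel chromosome (read-through partners)
    n_decoy_genes: int = 0
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (200, 1500)
    intergenic: tuple[int, int] = (2000, 8000)
    fusion_specs: list[FusionSpec] = field(default_factory=list)
    readthrough_specs: list[ReadthroughSpec] = field(default_factory=list)
    n_reads: int = 1000
    rin: float = 10.0
    sub_rate: float = 0.02
    ins_rate: float = 0.01
    del_rate: float = 0.01
    on_target_fraction: float = 0.9
    min_fragment: int = 200
    degrade_c: float = 0.002
    mean_q_mu: float = 12.0
    mean_q_sd: float = 2.0
    mean_q_range: tuple[float, float] = (4.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if not 0.0 <= getattr(self, name) <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")
        if not 1.0 <= self.rin <= 10.0:
            raise ValueError("rin must be in [1, 10]")
        if not 0.0 <= self.on_target_fraction <= 1.0:
            raise ValueError("on_target_fraction must be in [0, 1]")
        if self.n_genes < len(self.panel_gene_names):
            raise ValueError("n_genes must cover at least the panel genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("exons_per_gene", "exon_len", "intron_len", "intergenic",
                    "mean_q_range", "panel_gene_names"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        raw["fusion_specs"] = [FusionSpec(**d) for d in raw.get("fusion_specs", [])]
        raw["readthrough_specs"] = [
            ReadthroughSpec(**d) for d in raw.get("readthrough_specs", [])
        ]
        return cls(**raw)


@dataclass
class Transcript:
    """A spliced transcript with its genomic block map.

    ``blocks`` are 0-based half-open genomic exon intervals in transcript
    order; for chimeric transcripts ``junction`` is the transcript offset of
    the 3'-partner start and ``n_blocks5`` the number of 5'-side blocks.
    The two sides of a chimera may live on different chromosomes.
    """

    name: str
    chrom5: str
    blocks: list[tuple[int, int]]
    seq: str
    gene5: str
    gene3: str | None = None  # set for fusion / read-through transcripts
    chrom3: str | None = None
    kind: str = "wildtype"  # wildtype | fusion | readthrough
    junction: int | None = None  # transcript coordinate of the junction
    n_blocks5: int | None = None
    bp5: int | None = None  # 1-based genomic junction edges
    bp3: int | None = None

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def cumlens(self) -> list[int]:
        out, acc = [], 0
        for s, e in self.blocks:
            acc += e - s
            out.append(acc)
        return out


@dataclass
class Reference:
    genome: dict[str, str]  # chrom -> sequence
    genes: list[GeneModel]
    panel: TargetPanel

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def _rng_from(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_reference(config: SimConfig, rng: np.random.Generator | None = None) -> Reference:
    """Lay out non-overlapping genes and draw chromosome sequences.

    Panel genes are placed on ``config.chrom``; all remaining (off-panel)
    genes on ``config.off_chrom``, so genuine cross-chromosome fusions are
    distinguishable from same-chromosome read-through artifacts.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    panel_names = list(config.panel_gene_names[: config.n_genes])
    decoy_names = [f"D{i + 1}" for i in range(config.n_decoy_genes)]
    off_names = [f"G{i + 1}" for i in range(config.n_genes - len(panel_names))]
    genes: list[GeneModel] = []
    genome: dict[str, str] = {}
    for chrom, names in (
        (config.chrom, panel_names + decoy_names),
        (config.off_chrom, off_names),
    ):
        if not names:
            continue
        cursor = int(rng.integers(*config.intergenic))
        for name in names:
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons: list[tuple[int, int]] = []
            for i in range(n_exons):
                if i:
                    cursor += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                length = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
                exons.append((cursor, cursor + length))
                cursor += length
            genes.append(GeneModel(name, name, chrom, "+", exons))
            cursor += int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))
        genome[chrom] = _BASES[rng.integers(0, 4, size=cursor)].tobytes().decode("ascii")
    panel = TargetPanel.build(genes, panel_gene_names=config.panel_gene_names)
    return Reference(genome=genome, genes=genes, panel=panel)


def _wildtype_transcript(ref: Reference, gene: GeneModel) -> Transcript:
    from .panel import merge_exons

    blocks = merge_exons(gene)
    chrom_seq = ref.genome[gene.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in blocks)
    return Transcript(name=gene.gene_id, chrom5=gene.chrom, blocks=blocks,
                      seq=seq, gene5=gene.gene_id)


def make_fusion_transcript(ref: Reference, spec: FusionSpec) -> Transcript:
    """Concatenate gene5 exons 1..exon5 with gene3 exons exon3..last."""
    from .panel import merge_exons

    genes = ref.genes_by_id
    for g in (spec.gene5, spec.gene3):
        if g not in genes:
            raise ValueError(f"unknown gene {g!r}")
    ex5 = merge_exons(genes[spec.gene5])
    ex3 = merge_exons(genes[spec.gene3])
    if not 1 <= spec.exon5 <= len(ex5):
        raise ValueError(f"{spec.gene5}: exon {spec.exon5} out of range (1..{len(ex5)})")
    if not 1 <= spec.exon3 <= len(ex3):
        raise ValueError(f"{spec.gene3}: exon {spec.exon3} out of range (1..{len(ex3)})")
    blocks5 = ex5[: spec.exon5]
    blocks3 = ex3[spec.exon3 - 1 :]
    seq5 = ref.genome[genes[spec.gene5].chrom]
    seq3 = ref.genome[genes[spec.gene3].chrom]
    seq = "".join(seq5[s:e] for s, e in blocks5) + "".join(seq3[s:e] for s, e in blocks3)
    junction = sum(e - s for s, e in blocks5)
    return Transcript(
        name=f"{spec.gene5}::{spec.gene3}",
        chrom5=genes[spec.gene5].chrom,
        blocks=blocks5 + blocks3,
        seq=seq,
        gene5=spec.gene5,
        gene3=spec.gene3,
        chrom3=genes[spec.gene3].chrom,
        kind="fusion",
        junction=junction,
        n_blocks5=len(blocks5),
        bp5=blocks5[-1][1],  # 1-based last aligned base of the 5' side
        bp3=blocks3[0][0] + 1,
    )


def _readthrough_transcript(ref: Reference, spec: ReadthroughSpec) -> Transcript:
    t = make_fusion_transcript(
        ref,
        FusionSpec(
            gene5=spec.gene_a,
            exon5=len(_merged(ref, spec.gene_a)),
            gene3=spec.gene_b,
            exon3=1,
        ),
    )
    t.kind = "readthrough"
    t.name = f"{spec.gene_a}--{spec.gene_b}"
    return t


def _merged(ref: Reference, gene_id: str) -> list[tuple[int, int]]:
    from .panel import merge_exons

    return merge_exons(ref.genes_by_id[gene_id])


def _cut_intervals(
    length: int, rin: float, min_fragment: int, rng: np.random.Generator, c: float
) -> list[tuple[int, int]]:
    """Fragment [0, length) at Bernoulli(c/rin^2) internal cut points."""
    if length <= 0:
        return []
    p = min(1.0, c / (rin * rin))
    n_cuts = int(rng.binomial(length - 1, p)) if length > 1 and p > 0 else 0
    if n_cuts:
        cuts = np.sort(rng.choice(length - 1, size=n_cuts, replace=False)) + 1
        bounds = [0, *cuts.tolist(), length]
    else:
        bounds = [0, length]
    return [
        (s, e)
        for s, e in zip(bounds, bounds[1:])
        if e - s >= min_fragment
    ]


def degrade(
    transcript: str,
    rin: float,
    min_fragment: int,
    seed: int | np.random.Generator = 0,
    c: float = 0.002,
) -> list[str]:
    """Fragment a transcript sequence; fragments below *min_fragment* are lost."""
    rng = _rng_from(seed)
    return [transcript[s:e] for s, e in _cut_intervals(len(transcript), rin, min_fragment, rng, c)]


def add_errors(
    sequence: str,
    sub_rate: float = 0.0,
    ins_rate: float = 0.0,
    del_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    mean_q: float | None = None,
    read_id: str = "read",
) -> Read:
    """Apply independent per-base substitution/insertion/deletion errors and
    draw a quality string around a per-read mean Q."""
    rng = _rng_from(seed)
    if mean_q is None:
        mean_q = float(np.clip(rng.normal(12.0, 2.0), 4.0, 20.0))
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if n and (sub_rate or ins_rate or del_rate):
        r = rng.random(n)
        del_mask = r < del_rate
        sub_mask = (r >= del_rate) & (r < del_rate + sub_rate)
        n_sub = int(sub_mask.sum())
        if n_sub:
            shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
            arr[sub_mask] = _BASES[(_BASE_INDEX[arr[sub_mask]] + shift) % 4]
        ins_mask = rng.random(n) < ins_rate
        counts = (~del_mask).astype(np.int64) + ins_mask
        out = np.repeat(arr, counts)
        slots = np.cumsum(counts) - 1  # index of each input base's last copy
        ins_slots = slots[ins_mask & (counts > 0)]
        if ins_slots.size:
            out[ins_slots] = _BASES[rng.integers(0, 4, size=ins_slots.size)]
        arr = out
    m = arr.size
    quals = np.clip(np.rint(rng.normal(mean_q, 2.0, size=m)), 2, 40).astype(np.int64)
    return Read(read_id, arr.tobytes().decode("ascii"), quals)


# ---------------------------------------------------------------------------
# truth alignments

def _fragment_blocks(
    blocks: Sequence[tuple[int, int]], cumlens: Sequence[int], f0: int, f1: int
) -> list[tuple[int, int]]:
    """Genomic blocks covered by transcript interval [f0, f1)."""
    out: list[tuple[int, int]] = []
    prev = 0
    for (gs, ge), cum in zip(blocks, cumlens):
        lo, hi = max(f0, prev), min(f1, cum)
        if hi > lo:
            out.append((gs + (lo - prev), gs + (hi - prev)))
        prev = cum
        if prev >= f1:
            break
    return out


def _cigar_for_blocks(blocks: Sequence[tuple[int, int]]) -> str:
    parts: list[str] = []
    prev_end: int | None = None
    for s, e in blocks:
        if prev_end is not None:
            parts.append(f"{s - prev_end}N")
        parts.append(f"{e - s}M")
        prev_end = e
    return "".join(parts)


def _sam_records_for_read(
    read_id: str, transcript: Transcript, f0: int, f1: int
) -> list[str]:
    """Idealized aligner output: CIGARs from the error-free origin, a
    supplementary record (hard-clipped) for the post-junction portion of
    chimeric reads."""
    cums = transcript.cumlens
    seq = transcript.seq[f0:f1]
    records: list[str] = []
    j = transcript.junction
    if transcript.gene3 is not None and j is not None and f0 < j < f1:
        len_a, len_b = j - f0, f1 - j
        blocks_a = _fragment_blocks(transcript.blocks, cums, f0, j)
        blocks_b = _fragment_blocks(transcript.blocks, cums, j, f1)
        cigar_a = _cigar_for_blocks(blocks_a) + f"{len_b}S"
        records.append(
            f"{read_id}\t0\t{transcript.chrom5}\t{blocks_a[0][0] + 1}\t60\t{cigar_a}"
            f"\t*\t0\t0\t{seq}\t*"
        )
        cigar_b = f"{len_a}H" + _cigar_for_blocks(blocks_b)
        records.append(
            f"{read_id}\t2048\t{transcript.chrom3}\t{blocks_b[0][0] + 1}\t60\t{cigar_b}"
            f"\t*\t0\t0\t{seq[len_a:]}\t*"
        )
    else:
        # fragment entirely on one side of (or without) a junction
        chrom = transcript.chrom5
        if transcript.gene3 is not None and j is not None and f0 >= j:
            chrom = transcript.chrom3 or chrom
        blocks = _fragment_blocks(transcript.blocks, cums, f0, f1)
        cigar = _cigar_for_blocks(blocks)
        records.append(
            f"{read_id}\t0\t{chrom}\t{blocks[0][0] + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    return records


def emit_truth_alignments(
    truth_reads: Iterable["ReadTruth"],
    transcripts: dict[str, Transcript],
    reference: Reference,
    path: str | Path,
) -> None:
    """Write a SAM file of idealized alignments for every truth read."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in reference.genome.items():
            out.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")
        for tr in truth_reads:
            t = transcripts[tr.source]
            for line in _sam_records_for_read(tr.read_id, t, tr.frag_start, tr.frag_end):
                out.write(line + "\n")


# ---------------------------------------------------------------------------
# whole-sample simulation

@dataclass
class ReadTruth:
    read_id: str
    source: str  # transcript name
    frag_start: int  # transcript coordinates of the error-free fragment
    frag_end: int
    kind: str  # wildtype | fusion | readthrough
    on_target: bool


@dataclass
class TrueFusion:
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    bp5: int
    bp3: int
    n_reads: int


@dataclass
class TruthSet:
    reads: list[ReadTruth]
    fusions: list[TrueFusion]

    def write_reads_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("read_id\tsource\tfrag_start\tfrag_end\tkind\ton_target\n")
            for r in self.reads:
                out.write(
                    f"{r.read_id}\t{r.source}\t{r.frag_start}\t{r.frag_end}\t"
                    f"{r.kind}\t{int(r.on_target)}\n"
                )

    def write_fusions_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("gene5\tgene3\tchrom5\tchrom3\tbp5\tbp3\tn_reads\n")
            for f in self.fusions:
                out.write(
                    f"{f.gene5}\t{f.gene3}\t{f.chrom5}\t{f.chrom3}\t"
                    f"{f.bp5}\t{f.bp3}\t{f.n_reads}\n"
                )


@dataclass
class SimResult:
    reference: Reference
    transcripts: dict[str, Transcript]
    reads: list[Read]
    truth: TruthSet
    paths: dict[str, Path] = field(default_factory=dict)


def _write_fasta(ref: Reference, path: Path) -> None:
    with open(path, "w") as out:
        for chrom, seq in ref.genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                out.write(seq[i : i + 60] + "\n")


def _write_gtf(ref: Reference, path: Path) -> None:
    with open(path, "w") as out:
        for gene in ref.genes:
            s, e = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";'
            out.write(
                f"{gene.chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            tattrs = attrs + f' transcript_id "{gene.gene_id}.t1";'
            for xs, xe in gene.exons:
                out.write(
                    f"{gene.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{gene.strand}\t.\t{tattrs}\n"
                )


def simulate_sample(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Draw a full synthetic sample: reference files, FASTQ reads, truth
    alignments, and truth tables, all deterministic under ``config.seed``."""
    ref_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    read_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ref = make_reference(config, ref_rng)

    transcripts: dict[str, Transcript] = {
        g.gene_id: _wildtype_transcript(ref, g) for g in ref.genes
    }
    fusion_by_gene5: dict[str, tuple[Transcript, float]] = {}
    for spec in config.fusion_specs:
        t = make_fusion_transcript(ref, spec)
        transcripts[t.name] = t
        fusion_by_gene5[spec.gene5] = (t, spec.frequency)
    rt_by_gene: dict[str, tuple[Transcript, float]] = {}
    for rspec in config.readthrough_specs:
        t = _readthrough_transcript(ref, rspec)
        transcripts[t.name] = t
        rt_by_gene[rspec.gene_a] = (t, rspec.frequency)

    panel_ids = sorted(ref.panel.gene_ids())
    off_ids = sorted(g.gene_id for g in ref.genes if g.gene_id not in set(panel_ids))

    reads: list[Read] = []
    truth_reads: list[ReadTruth] = []
    fusion_read_counts: dict[str, int] = {}
    for i in range(config.n_reads):
        on_target = bool(off_ids) is False or read_rng.random() < config.on_target_fraction
        pool = panel_ids if on_target else off_ids
        gene = pool[int(read_rng.integers(len(pool)))]
        transcript = transcripts[gene]
        if gene in fusion_by_gene5:
            ft, freq = fusion_by_gene5[gene]
            if read_rng.random() < freq:
                transcript = ft
        if transcript.kind == "wildtype" and gene in rt_by_gene:
            rt, freq = rt_by_gene[gene]
            if read_rng.random() < freq:
                transcript = rt
        intervals = _cut_intervals(
            transcript.length, config.rin, config.min_fragment, read_rng, config.degrade_c
        )
        if not intervals:
            intervals = [(0, transcript.length)]
        f0, f1 = intervals[int(read_rng.integers(len(intervals)))]
        read_id = f"r{i:06d}"
        reads.append(
            add_errors(
                transcript.seq[f0:f1],
                sub_rate=config.sub_rate,
                ins_rate=config.ins_rate,
                del_rate=config.del_rate,
                seed=read_rng,
                read_id=read_id,
            )
        )
        truth_reads.append(
            ReadTruth(read_id, transcript.name, f0, f1, transcript.kind, on_target)
        )
        if transcript.kind == "fusion" and transcript.junction is not None and f0 < transcript.junction < f1:
            fusion_read_counts[transcript.name] = fusion_read_counts.get(transcript.name, 0) + 1

    fusions = [
        TrueFusion(
            gene5=transcripts[name].gene5,
            gene3=transcripts[name].gene3 or "",
            chrom5=transcripts[name].chrom5,
            chrom3=transcripts[name].chrom3 or "",
            bp5=transcripts[name].bp5 or 0,
            bp3=transcripts[name].bp3 or 0,
            n_reads=count,
        )
        for name, count in sorted(fusion_read_counts.items())
    ]
    truth = TruthSet(reads=truth_reads, fusions=fusions)
    result = SimResult(reference=ref, transcripts=transcripts, reads=reads, truth=truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "gtf": outdir / "genes.gtf",
            "bed": outdir / "panel.bed",
            "fastq": outdir / "reads.fastq",
            "sam": outdir / "alignments.sam",
            "truth_reads": outdir / "truth_reads.tsv",
            "truth_fusions": outdir / "truth_fusions.tsv",
        }
        _write_fasta(ref, paths["fasta"])
        _write_gtf(ref, paths["gtf"])
        write_panel_bed(ref.panel, paths["bed"])
        write_fastq(reads, paths["fastq"])
        emit_truth_alignments(truth_reads, transcripts, ref, paths["sam"])
        truth.write_reads_tsv(paths["truth_reads"])
        truth.write_fusions_tsv(paths["truth_fusions"])
        result.paths = paths
    return result
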