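import pytest

from nanofuse.caller import (
    AlignedSegment,
    CallerParams,
    FusionCandidate,
    ReadChain,
    SupportRead,
    assign_genes,
    call_candidates,
    call_fusions,
    filter_candidates,
    fusion_frequency,
    parse_alignments,
)
from nanofuse.panel import GeneIndex, GeneModel, TargetPanel

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


def sam_file(tmp_path, records, name="aln.sam"):
    path = tmp_path / name
    path.write_text(SAM_HEADER + "".join(r + "\n" for r in records))
    return path


def seg(read_id="r", qs=0, qe=100, chrom="chr1", rs=0, re_=100, strand="+",
        supp=False, ref_bases=None):
    return AlignedSegment(
        read_id=read_id, query_start=qs, query_end=qe, ref_chrom=chrom,
        ref_start=rs, ref_end=re_, strand=strand, mapq=60,
        is_supplementary=supp, aligned_ref_bases=ref_bases or (re_ - rs),
    )


class TestParseAlignments:
    def test_primary_plus_supplementary_grouped_and_ordered(self, tmp_path):
        records = [
            "R\t0\tchr1\t1001\t60\t300M200S\t*\t0\t0\t" + "A" * 500 + "\t*",
            "R\t2048\tchr2\t5001\t60\t300H200M\t*\t0\t0\t" + "A" * 200 + "\t*",
        ]
        (chain,) = parse_alignments(sam_file(tmp_path, records))
        assert chain.read_id == "R"
        assert [(s.query_start, s.query_end) for s in chain.segments] == [(0, 300), (300, 500)]
        assert chain.segments[1].is_supplementary

    def test_secondary_records_excluded(self, tmp_path):
        records = [
            "R\t0\tchr1\t1001\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*",
            "R\t256\tchr2\t1\t0\t100M\t*\t0\t0\t*\t*",
        ]
        (chain,) = parse_alignments(sam_file(tmp_path, records))
        assert len(chain.segments) == 1

    def test_unmapped_records_excluded(self, tmp_path):
        records = ["R\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*"]
        assert parse_alignments(sam_file(tmp_path, records)) == []

    def test_reverse_supplementary_hard_clip_query_coordinates(self, tmp_path):
        # Original read length 1500. Record is reverse strand with CIGAR
        # 1000H400M100S in record orientation; the 1000H sits at the 3' end
        # of the original read, so the aligned part occupies original-read
        # coordinates [100, 500) (manual CIGAR arithmetic oracle).
        records = [
            "R\t0\tchr1\t1001\t60\t100M1400S\t*\t0\t0\t" + "A" * 1500 + "\t*",
            "R\t2064\tchr2\t2001\t60\t1000H400M100S\t*\t0\t0\t" + "A" * 500 + "\t*",
        ]
        (chain,) = parse_alignments(sam_file(tmp_path, records))
        supp = [s for s in chain.segments if s.is_supplementary][0]
        assert (supp.query_start, supp.query_end) == (100, 500)
        assert supp.strand == "-"
        assert supp.ref_start == 2000 and supp.ref_end == 2400

    def test_aligned_ref_bases_excludes_indels_and_introns(self, tmp_path):
        records = ["R\t0\tchr1\t1001\t60\t50M10I50M1000N30M5D20M\t*\t0\t0\t" + "A" * 160 + "\t*"]
        (chain,) = parse_alignments(sam_file(tmp_path, records))
        s = chain.segments[0]
        assert s.aligned_ref_bases == 150
        assert s.ref_end - s.ref_start == 50 + 50 + 1000 + 30 + 5 + 20


class TestAssignGenes:
    @pytest.fixture
    def index(self):
        genes = [
            GeneModel("geneA", "geneA", "chr1", "+", [(1000, 2000)]),
            GeneModel("geneB", "geneB", "chr1", "+", [(1800, 3000)]),
        ]
        return GeneIndex.build(TargetPanel.build(genes, panel_gene_names=None))

    def test_clear_overlap_assigned(self, index):
        chain = ReadChain("r", [seg(rs=1100, re_=1500)])
        assert assign_genes(chain, index).gene_labels == ["geneA"]

    def test_below_min_overlap_unassigned(self, index):
        chain = ReadChain("r", [seg(rs=1000, re_=1060)])
        assert assign_genes(chain, index, min_overlap=100).gene_labels == [None]

    def test_max_overlap_wins(self, index):
        # 150 bp in geneA-only space, 300 bp inside geneB
        chain = ReadChain("r", [seg(rs=1650, re_=2100)])
        labels = assign_genes(chain, index).gene_labels
        # brute force: overlap A = 2000-1650 = 350, overlap B = 2100-1800 = 300
        assert labels == ["geneA"]
        chain2 = ReadChain("r", [seg(rs=1850, re_=2400)])
        # overlap A = 150, overlap B = 550
        assert assign_genes(chain2, index).gene_labels == ["geneB"]


class TestCallCandidates:
    def chain_pair(self, rid, bp5_end, bp3_start):
        segs = [
            seg(rid, qs=0, qe=300, chrom="chr1", rs=bp5_end - 300, re_=bp5_end),
            seg(rid, qs=300, qe=600, chrom="chr2", rs=bp3_start, re_=bp3_start + 300, supp=True),
        ]
        chain = ReadChain(rid, segs)
        chain.gene_labels = ["geneA", "geneB"]
        return chain

    def test_identical_junctions_form_one_candidate(self):
        chains = [self.chain_pair(f"r{i}", 5000, 7000) for i in range(5)]
        (cand,) = call_candidates(chains)
        assert (cand.gene5, cand.gene3) == ("geneA", "geneB")
        assert cand.n_support == 5
        assert cand.breakpoint_cluster_span == 0
        assert cand.breakpoint5 == 5000 and cand.breakpoint3 == 7001

    def test_single_gene_chain_yields_nothing(self):
        chain = ReadChain("r", [seg()])
        chain.gene_labels = ["geneA"]
        assert call_candidates([chain]) == []

    def test_unassigned_segments_are_skipped(self):
        segs = [seg("r", qs=0, qe=100, rs=0, re_=100),
                seg("r", qs=100, qe=200, rs=5000, re_=5100),
                seg("r", qs=200, qe=400, chrom="chr2", rs=9000, re_=9200)]
        chain = ReadChain("r", segs)
        chain.gene_labels = ["geneA", None, "geneB"]
        (cand,) = call_candidates([chain])
        assert (cand.gene5, cand.gene3) == ("geneA", "geneB")

    def test_breakpoint_clustering_single_linkage(self):
        # breakpoints {1000, 1010, 1045, 1120}, window 50 -> {1000..1045}, {1120}
        chains = [self.chain_pair(f"r{i}", bp, 7000) for i, bp in
                  enumerate([1000, 1010, 1045, 1120])]
        cands = call_candidates(chains, cluster_window=50)
        assert sorted(c.n_support for c in cands) == [1, 3]
        spans = {c.n_support: c.breakpoint_cluster_span for c in cands}
        assert spans[3] == 45 and spans[1] == 0

    def test_deterministic_under_input_order(self):
        chains = [self.chain_pair(f"r{i}", 5000 + i, 7000) for i in range(6)]
        a = call_candidates(chains)
        b = call_candidates(list(reversed(chains)))
        assert [(c.gene5, c.breakpoint5, sorted(c.supporting_reads)) for c in a] == [
            (c.gene5, c.breakpoint5, sorted(c.supporting_reads)) for c in b
        ]


def make_candidate(gene5="P", gene3="Q", chrom5="chr1", chrom3="chr2",
                   n=5, seg_len=300, bp5=5000, bp3=7000):
    support = [SupportRead(f"r{i}", bp5, bp3, seg_len, seg_len) for i in range(n)]
    return FusionCandidate(gene5, gene3, chrom5, chrom3, bp5, bp3, support, 0)


class TestFilterCandidates:
    @pytest.fixture
    def annotation(self):
        genes = [
            GeneModel("P", "P", "chr1", "+", [(4000, 5000)]),
            GeneModel("Q", "Q", "chr2", "+", [(7000, 8000)]),
            GeneModel("N1", "N1", "chr3", "+", [(1000, 2000)]),
            GeneModel("N2", "N2", "chr3", "+", [(42_000, 43_000)]),  # 40 kb from N1
            GeneModel("OV", "OV", "chr1", "+", [(4500, 6000)]),  # overlaps P
        ]
        return TargetPanel.build(genes, panel_gene_names=None)

    def filter_one(self, cand, annotation, panel_ids=frozenset({"P", "Q"}), **kw):
        (call,) = filter_candidates([cand], annotation, set(panel_ids), CallerParams(**kw))
        return call

    def test_clean_cross_chromosome_candidate_passes(self, annotation):
        call = self.filter_one(make_candidate(n=164), annotation)
        assert call.status == "PASS" and call.n_support == 164

    def test_min_support(self, annotation):
        call = self.filter_one(make_candidate(n=2), annotation)
        assert call.status == "FILTERED:min_support"

    def test_panel_anchor(self, annotation):
        cand = make_candidate(gene5="N1", gene3="N2", chrom5="chr3", chrom3="chr3")
        call = self.filter_one(cand, annotation)
        assert call.status == "FILTERED:panel_anchor"

    def test_read_through_same_strand_nearby_genes(self, annotation):
        cand = make_candidate(gene5="N1", gene3="N2", chrom5="chr3", chrom3="chr3", n=10)
        call = self.filter_one(cand, annotation, panel_ids=frozenset({"N1"}))
        assert call.status == "FILTERED:read_through"

    def test_read_through_exempts_double_panel_pairs(self, annotation):
        cand = make_candidate(gene5="N1", gene3="N2", chrom5="chr3", chrom3="chr3", n=10)
        call = self.filter_one(cand, annotation, panel_ids=frozenset({"N1", "N2"}))
        assert call.status == "PASS"

    def test_read_through_distance_threshold(self, annotation):
        cand = make_candidate(gene5="N1", gene3="N2", chrom5="chr3", chrom3="chr3", n=10)
        call = self.filter_one(
            cand, annotation, panel_ids=frozenset({"N1"}), readthrough_distance=30_000
        )
        assert call.status == "PASS"  # 40 kb apart is beyond a 30 kb cutoff

    def test_overlapping_genes_filtered(self, annotation):
        cand = make_candidate(gene5="P", gene3="OV", chrom5="chr1", chrom3="chr1")
        call = self.filter_one(cand, annotation, panel_ids=frozenset({"P", "OV"}))
        assert call.status == "FILTERED:overlapping_genes"

    def test_min_segment_drops_short_evidence(self, annotation):
        support = [SupportRead(f"r{i}", 5000, 7000, 80, 300) for i in range(5)]
        cand = FusionCandidate("P", "Q", "chr1", "chr2", 5000, 7000, support, 0)
        call = self.filter_one(cand, annotation)
        assert call.status == "FILTERED:min_segment"

    def test_min_segment_recounts_support(self, annotation):
        support = [SupportRead(f"r{i}", 5000, 7000, 300, 300) for i in range(4)]
        support += [SupportRead("rshort", 5000, 7000, 50, 300)]
        cand = FusionCandidate("P", "Q", "chr1", "chr2", 5000, 7000, support, 0)
        call = self.filter_one(cand, annotation)
        assert call.status == "PASS" and call.n_support == 4

    def test_filters_individually_switchable(self, annotation):
        cand = make_candidate(gene5="N1", gene3="N2", chrom5="chr3", chrom3="chr3", n=10)
        params = CallerParams(enabled_filters=("min_support",))
        (call,) = filter_candidates([cand], annotation, {"P"}, params)
        assert call.status == "PASS"


class TestFusionFrequency:
    def _call(self, n_support, bp=5000):
        cand = make_candidate(n=n_support, bp5=bp)
        from nanofuse.caller import FusionCall

        return FusionCall(cand, n_support, None, "PASS", [])

    def locus_chains(self, n, chrom="chr1", rs=4800, re_=5100):
        return [ReadChain(f"c{i}", [seg(f"c{i}", chrom=chrom, rs=rs, re_=re_)]) for i in range(n)]

    def test_fraction_of_breakpoint_overlapping_reads(self):
        freq = fusion_frequency(self._call(10), self.locus_chains(100), {"P"})
        assert freq == pytest.approx(0.10)

    def test_all_overlapping_reads_support(self):
        freq = fusion_frequency(self._call(40), self.locus_chains(40), {"P"})
        assert freq == pytest.approx(1.0)

    def test_no_locus_reads_is_undefined(self):
        freq = fusion_frequency(self._call(3), [], {"P"})
        assert freq is None

    def test_reads_outside_window_do_not_count(self):
        chains = self.locus_chains(10) + self.locus_chains(5, rs=9000, re_=9500)
        # relabel to unique ids
        for i, c in enumerate(chains):
            c.read_id = f"u{i}"
        freq = fusion_frequency(self._call(5), chains, {"P"}, window=50)
        assert freq == pytest.approx(0.5)


class TestEndToEnd:
    def test_pass_call_matches_simulation_truth(self, sim_sample):
        cfg, result, genes = sim_sample
        calls, chains = call_fusions(
            result.paths["sam"], genes, panel_gene_names=cfg.panel_gene_names
        )
        passing = [c for c in calls if c.is_pass]
        assert len(passing) == 1
        (call,) = passing
        (truth,) = result.truth.fusions
        assert (call.candidate.gene5, call.candidate.gene3) == (truth.gene5, truth.gene3)
        assert abs(call.candidate.breakpoint5 - truth.bp5) <= 50
        assert abs(call.candidate.breakpoint3 - truth.bp3) <= 50

    def test_no_supplementary_no_candidates(self, sim_sample, tmp_path):
        cfg, result, genes = sim_sample
        with open(result.paths["sam"]) as fh:
            lines = [
                ln for ln in fh
                if ln.startswith("@") or not int(ln.split("\t")[1]) & 2048
            ]
        stripped = tmp_path / "nosupp.sam"
        stripped.write_text("".join(lines))
        calls, _ = call_fusions(stripped, genes, panel_gene_names=cfg.panel_gene_names)
        assert calls == []
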