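"""GFF parsing, read assignment, UMI collapse and matrix construction."""

import itertools
from collections import Counter

import numpy as np
import pysam
import pytest

from ribod.barcode_demux import demux_fastq, read_tag_table
from ribod.feature_counting import (
    CountMatrix,
    Feature,
    FeatureTable,
    assign_read,
    build_matrix,
    classify_biotypes,
    dedup_umis,
    matrix_from_groups,
    mrna_ratio_percent,
    parse_gff,
    read_matrix,
    write_matrix,
)
from ribod.synthetic_data import SimulationParams, simulate_library
from ribod.utils import hamming


def _write_gff(tmp_path, lines):
    p = tmp_path / "test.gff3"
    p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
    return p


def _write_sam(path, reads, contig="c1", length=1000):
    """reads: list of (name, flag, pos0, seq, mapq, [tags])"""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": contig, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for name, flag, pos, seq, mapq, tags in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = name
            a.flag = flag
            a.query_sequence = seq
            if not (flag & 4):
                a.reference_id = 0
                a.reference_start = pos
                a.cigarstring = f"{len(seq)}M"
            a.mapping_quality = mapq
            for k, v in tags:
                a.set_tag(k, v)
            fh.write(a)
    return path


class TestParseGff:
    def test_coordinates_to_half_open(self, tmp_path):
        gff = _write_gff(tmp_path, ["c1\tsrc\tCDS\t11\t20\t.\t+\t.\tID=g1"])
        table = parse_gff(gff)
        f = table.features[0]
        assert (f.start, f.end) == (10, 20)
        assert f.biotype == "mRNA"

    def test_rrna_type_maps_to_rrna_biotype(self, tmp_path):
        gff = _write_gff(
            tmp_path,
            [
                "c1\tsrc\trRNA\t1\t100\t.\t+\t.\tID=rr1",
                "c1\tsrc\ttRNA\t200\t280\t.\t-\t.\tID=tr1",
            ],
        )
        table = parse_gff(gff)
        assert {f.gene_id: f.biotype for f in table.features} == {
            "rr1": "rRNA",
            "tr1": "tRNA",
        }

    def test_opposite_strand_overlap_both_retained(self, tmp_path):
        gff = _write_gff(
            tmp_path,
            [
                "c1\tsrc\tCDS\t1\t100\t.\t+\t.\tID=fwd",
                "c1\tsrc\tCDS\t50\t150\t.\t-\t.\tID=rev",
            ],
        )
        assert len(parse_gff(tmp_path / "test.gff3")) == 2

    def test_gene_biotype_attribute_overrides_type(self, tmp_path):
        gff = _write_gff(
            tmp_path, ["c1\tsrc\tgene\t1\t50\t.\t+\t.\tID=g1;gene_biotype=rRNA"]
        )
        assert parse_gff(gff).features[0].biotype == "rRNA"


def _single_gene_index(strand="+"):
    table = FeatureTable([Feature("g1", "c1", strand, 50, 500, "mRNA")])
    return table, table.build_index()


def _aln(name="r1", flag=0, pos=100, mapq=60, length=50):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 1000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.query_sequence = "A" * length
    if not (flag & 4):
        a.reference_id = 0
        a.reference_start = pos
        a.cigarstring = f"{length}M"
    a.mapping_quality = mapq
    return a


class TestAssignRead:
    def test_contained_read_assigned(self):
        _, index = _single_gene_index()
        assert assign_read(_aln(), index) == ("g1", None)

    def test_two_gene_overlap_is_ambiguous(self):
        table = FeatureTable(
            [
                Feature("g1", "c1", "+", 50, 200, "mRNA"),
                Feature("g2", "c1", "+", 150, 400, "mRNA"),
            ]
        )
        index = table.build_index()
        assert assign_read(_aln(pos=160), index) == (None, "ambiguous")

    def test_antisense_read_is_no_feature_when_stranded(self):
        _, index = _single_gene_index("+")
        gene, reason = assign_read(_aln(flag=16), index, require_same_strand=True)
        assert (gene, reason) == (None, "no_feature")
        gene, _ = assign_read(_aln(flag=16), index, require_same_strand=False)
        assert gene == "g1"

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            ({"flag": 4}, "unmapped"),
            ({"flag": 256}, "secondary"),
            ({"mapq": 3}, "low_mapq"),
            ({"pos": 900}, "no_feature"),
        ],
    )
    def test_rejection_reasons(self, kwargs, reason):
        _, index = _single_gene_index()
        assert assign_read(_aln(**kwargs), index, min_mapq=10) == (None, reason)


def _oracle_directional(counts):
    """Brute-force directional networks: reachability over the merge rule."""
    umis = sorted(counts, key=lambda u: (-counts[u], u))
    merged_into = {}
    visited = set()
    n = 0
    for seed in umis:
        if seed in visited:
            continue
        n += 1
        frontier = [seed]
        visited.add(seed)
        while frontier:
            u = frontier.pop()
            for v in umis:
                if v not in visited and hamming(u, v) == 1 and counts[u] >= 2 * counts[v]:
                    visited.add(v)
                    frontier.append(v)
    return n


class TestDedupUmis:
    def test_exact_counts_distinct_strings(self):
        assert dedup_umis(["AAAA", "AAAA", "CCCC"], "exact") == 2

    def test_directional_merges_low_count_neighbor(self):
        counts = Counter({"AAAA": 9, "AAAT": 1})
        assert dedup_umis(counts, "directional1") == 1

    def test_directional_keeps_balanced_pair(self):
        counts = Counter({"AAAA": 3, "AAAT": 2})  # 3 < 2*2: no merge
        assert dedup_umis(counts, "directional1") == 2

    def test_empty_group_is_zero(self):
        assert dedup_umis([], "exact") == 0
        assert dedup_umis(Counter(), "directional1") == 0

    def test_matches_bruteforce_oracle_on_random_groups(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            length = int(rng.integers(4, 9))
            n_umis = int(rng.integers(1, 21))
            counts = Counter()
            for _ in range(n_umis):
                counts["".join(rng.choice(bases, size=length))] += int(rng.integers(1, 20))
            assert dedup_umis(counts, "directional1") == _oracle_directional(counts)
            assert dedup_umis(counts, "exact") == len(counts)


class TestBuildMatrix:
    def test_toy_sam_three_reads_two_umis(self, tmp_path):
        table = FeatureTable([Feature("g1", "c1", "+", 50, 500, "mRNA")])
        sam = _write_sam(
            tmp_path / "toy.sam",
            [
                ("r1", 0, 100, "A" * 50, 60, [("CB", "1.1.1"), ("UB", "AAAA")]),
                ("r2", 0, 120, "A" * 50, 60, [("CB", "1.1.1"), ("UB", "AAAA")]),
                ("r3", 0, 140, "A" * 50, 60, [("CB", "1.1.1"), ("UB", "CCCC")]),
            ],
        )
        m = build_matrix(sam, table)
        assert m.counts.toarray().tolist() == [[2]]
        assert m.provenance["reads_processed"] == 3
        assert m.provenance["reads_assigned"] == 3
        assert m.provenance["reads_deduplicated"] == 2

    def test_empty_sam_gives_empty_matrix(self, tmp_path):
        table = FeatureTable([Feature("g1", "c1", "+", 50, 500, "mRNA")])
        sam = _write_sam(tmp_path / "empty.sam", [])
        m = build_matrix(sam, table)
        assert m.counts.shape == (0, 1)
        assert m.provenance["reads_processed"] == 0

    def test_missing_tags_is_hard_error(self, tmp_path):
        table = FeatureTable([Feature("g1", "c1", "+", 50, 500, "mRNA")])
        sam = _write_sam(tmp_path / "untagged.sam", [("r1", 0, 100, "A" * 50, 60, [])])
        with pytest.raises(ValueError, match="CB/UB"):
            build_matrix(sam, table)

    def test_header_encoded_tags_accepted(self, tmp_path):
        table = FeatureTable([Feature("g1", "c1", "+", 50, 500, "mRNA")])
        sam = _write_sam(
            tmp_path / "hdr.sam", [("r1|CB:2.3.4|UB:ACGT", 0, 100, "A" * 50, 60, [])]
        )
        m = build_matrix(sam, table)
        assert m.cells == ["2.3.4"]
        assert m.total_umis == 1

    def test_unknown_contig_warns_and_unassigns(self, tmp_path):
        table = FeatureTable([Feature("g1", "c2", "+", 50, 500, "mRNA")])
        sam = _write_sam(
            tmp_path / "contig.sam",
            [("r1", 0, 100, "A" * 50, 60, [("CB", "1.1.1"), ("UB", "AAAA")])],
        )
        with pytest.warns(UserWarning, match="absent from annotation"):
            m = build_matrix(sam, table)
        assert m.provenance["unassigned_no_feature"] == 1

    def test_counter_conservation(self, small_truth):
        m = build_matrix(small_truth.paths["sam"], small_truth.features)
        p = m.provenance
        unassigned = sum(v for k, v in p.items() if str(k).startswith("unassigned_"))
        assert p["reads_assigned"] + unassigned + p["untagged"] == p["reads_processed"]

    def test_zero_error_pipeline_recovers_truth(self, small_truth, tmp_path):
        demux_fastq(
            small_truth.paths["fq1"],
            small_truth.paths["fq2"],
            small_truth.schema,
            tmp_path / "demux",
        )
        tags = read_tag_table(tmp_path / "demux.tags.tsv")
        m = build_matrix(small_truth.paths["sam"], small_truth.features, tags=tags)
        t = small_truth.truth_matrix
        assert m.cells == t.cells and m.genes == t.genes
        assert (m.counts != t.counts).nnz == 0

    def test_barcode_errors_only_perturb_touched_cells(self, tmp_path):
        """Cells whose reads all demultiplexed to the true barcode match truth
        exactly; differences are confined to cells touched by rejected or
        miscorrected reads."""
        params = SimulationParams(
            n_cells=15, n_genes=10, n_rrna_genes=2, barcode_error_rate=0.05, seed=21
        )
        truth = simulate_library(params, tmp_path / "sim")
        demux_fastq(truth.paths["fq1"], truth.paths["fq2"], truth.schema, tmp_path / "demux")
        tags = read_tag_table(tmp_path / "demux.tags.tsv")
        m = build_matrix(truth.paths["sam"], truth.features, tags=tags)
        t = truth.truth_matrix
        affected = set()
        for r in truth.reads:
            tagged = tags.get(r.read_id)
            if tagged is None:
                affected.add(r.cell_id)  # rejected read
            elif tagged[0] != r.cell_id:
                affected.add(r.cell_id)  # miscorrected away from the true cell
                affected.add(tagged[0])  # and into a wrong one
        assert affected  # the scenario must actually exercise the error path
        truth_df = t.to_frame()
        obs_df = m.to_frame()
        for cell in truth_df.index:
            if cell in affected:
                continue
            assert (obs_df.loc[cell] == truth_df.loc[cell]).all(), cell
        # no spurious cells outside the affected set
        assert set(obs_df.index) - set(truth_df.index) <= affected


class TestBiotypesAndIO:
    def test_mrna_ratio_mirrors_undepleted_library(self):
        table = FeatureTable(
            [
                Feature("rr1", "c1", "+", 0, 100, "rRNA"),
                Feature("g1", "c1", "+", 200, 300, "mRNA"),
            ]
        )
        groups = {
            ("1.1.1", "rr1"): Counter({f"U{i:03d}": 1 for i in range(918)}),
            ("1.1.1", "g1"): Counter({f"V{i:03d}": 1 for i in range(82)}),
        }
        m = matrix_from_groups(groups, table)
        assert m.class_totals == {"rRNA": 918, "mRNA": 82}
        assert mrna_ratio_percent(m, table) == pytest.approx(8.2)

    def test_fractions_sum_to_one(self, small_truth):
        df = classify_biotypes(small_truth.truth_matrix, small_truth.features)
        assert df["fraction"].sum() == pytest.approx(1.0, abs=0)

    def test_all_mrna_library_is_100_percent(self):
        table = FeatureTable([Feature("g1", "c1", "+", 0, 100, "mRNA")])
        m = matrix_from_groups({("1.1.1", "g1"): Counter({"AAAA": 1})}, table)
        assert mrna_ratio_percent(m, table) == 100.0

    def test_mtx_round_trip_preserves_everything(self, small_truth, tmp_path):
        t = small_truth.truth_matrix
        write_matrix(t, tmp_path / "mtx")
        back = read_matrix(tmp_path / "mtx")
        assert back.cells == t.cells
        assert back.genes == t.genes
        assert (back.counts != t.counts).nnz == 0

    def test_mtx_header_dimensions(self, tmp_path):
        table = FeatureTable(
            [
                Feature("g1", "c1", "+", 0, 10, "mRNA"),
                Feature("g2", "c1", "+", 20, 30, "mRNA"),
                Feature("g3", "c1", "+", 40, 50, "mRNA"),
            ]
        )
        groups = {
            ("1.1.1", "g1"): Counter({"AAAA": 1}),
            ("1.1.1", "g3"): Counter({"AAAA": 1, "CCCC": 1}),
            ("2.2.2", "g2"): Counter({"AAAA": 1}),
            ("2.2.2", "g3"): Counter({"TTTT": 1}),
        }
        m = matrix_from_groups(groups, table)
        write_matrix(m, tmp_path / "mtx")
        lines = (tmp_path / "mtx" / "matrix.mtx").read_text().splitlines()
        dims = next(l for l in lines if not l.startswith("%"))
        assert dims.split() == ["2", "3", "4"]
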