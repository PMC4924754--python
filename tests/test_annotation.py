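"""Annotation readers, the cross-hyb/univocality filters, and summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from oracles import assign_oracle, bed12_exons_naive

from lncarray import (
    ProbeAlignment,
    TranscriptAnnotation,
    ValidationError,
    assign_probes_univocal,
    filter_crosshyb,
    load_annotation,
    load_probes,
    summarize_by_median,
)
from lncarray.annotation import ProbeLncMap, write_annotation_bed12, write_annotation_gtf


def tx(tid, gene, src, chrom, strand, exons, biotype="lncRNA", parental=None):
    return TranscriptAnnotation(
        transcript_id=tid, gene_id=gene, source=src, biotype=biotype,
        chrom=chrom, strand=strand, exons=exons, parental_gene=parental,
    )


class TestReaders:
    def test_gtf_one_based_inclusive_converted(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        (t,) = load_annotation(path, "ensembl_like", "GTF")
        assert t.exons == [(100, 200)]

    def test_gtf_round_trip(self, tmp_path):
        orig = [
            tx("T1", "G1", "ensembl_like", "chr2", "-", [(10, 50), (80, 120)],
               biotype="pseudogene", parental="G9"),
            tx("T2", "G2", "ensembl_like", "chr2", "+", [(500, 700)]),
        ]
        write_annotation_gtf(orig, tmp_path / "rt.gtf")
        back = load_annotation(tmp_path / "rt.gtf", "ensembl_like", "GTF")
        by_id = {t.transcript_id: t for t in back}
        for t in orig:
            b = by_id[t.transcript_id]
            assert (b.exons, b.strand, b.biotype, b.parental_gene) == (
                t.exons, t.strand, t.biotype, t.parental_gene
            )

    def test_bed12_blocks_match_naive_expansion(self, tmp_path):
        rng = np.random.default_rng(3)
        lines = []
        for k in range(20):
            start = int(rng.integers(0, 10_000))
            n_blocks = int(rng.integers(1, 5))
            sizes, offsets = [], []
            off = 0
            for _ in range(n_blocks):
                sizes.append(int(rng.integers(50, 400)))
                offsets.append(off)
                off += sizes[-1] + int(rng.integers(10, 500))
            end = start + offsets[-1] + sizes[-1]
            lines.append(
                f"chr1\t{start}\t{end}\tlnc-X{k}-1:1\t0\t+\t{start}\t{end}\t0\t"
                f"{n_blocks}\t{','.join(map(str, sizes))}\t{','.join(map(str, offsets))}"
            )
        path = tmp_path / "b.bed12"
        path.write_text("\n".join(lines) + "\n")
        parsed = {t.transcript_id: t.exons for t in load_annotation(path, "lncipedia_like", "BED12")}
        for line in lines:
            name = line.split("\t")[3]
            assert parsed[name] == bed12_exons_naive(line)

    def test_bed12_gene_id_strips_transcript_suffix(self, tmp_path):
        path = tmp_path / "b.bed12"
        path.write_text("chr1\t0\t100\tlnc-FOO-1:2\t0\t+\t0\t100\t0\t1\t100\t0\n")
        (t,) = load_annotation(path, "lncipedia_like", "BED12")
        assert t.gene_id == "lnc-FOO-1" and t.transcript_id == "lnc-FOO-1:2"

    def test_bed12_round_trip(self, tmp_path):
        orig = [tx("lnc-A-1:1", "lnc-A-1", "lncipedia_like", "chrX", "-",
                   [(100, 250), (400, 460)])]
        write_annotation_bed12(orig, tmp_path / "rt.bed12")
        (back,) = load_annotation(tmp_path / "rt.bed12", "lncipedia_like", "BED12")
        assert back.exons == orig[0].exons and back.strand == "-"

    def test_unparsable_file_errors(self, tmp_path):
        empty = tmp_path / "empty.gtf"
        empty.write_text("# only a comment\n")
        with pytest.raises(Exception):
            load_annotation(empty, "ensembl_like", "GTF")
        with pytest.raises(ValidationError):
            load_annotation(empty, "ensembl_like", "VCF")

    def test_probe_bed6_groups_placements_by_name(self, tmp_path):
        path = tmp_path / "p.bed6"
        path.write_text(
            "chr1\t10\t35\tP1\t0\t+\nchr2\t99\t124\tP1\t0\t-\nchr1\t50\t75\tP2\t0\t+\n"
        )
        probes = {p.probe_id: p for p in load_probes(path)}
        assert len(probes["P1"].placements) == 2 and probes["P1"].cross_hyb
        assert not probes["P2"].cross_hyb


class TestCrossHyb:
    def test_multi_placement_excluded_single_kept(self):
        multi = ProbeAlignment("PM", [("chr1", 0, 25, "+"), ("chr2", 0, 25, "+")])
        single = ProbeAlignment("PS", [("chr1", 0, 25, "+")])
        flagged = ProbeAlignment("PF", [("chr1", 50, 75, "+")], flagged_cross_hyb=True)
        kept, excluded = filter_crosshyb([multi, single, flagged])
        assert [p.probe_id for p in kept] == ["PS"]
        assert {p.probe_id for p in excluded} == {"PM", "PF"}

    def test_partition_matches_brute_force_count(self):
        rng = np.random.default_rng(7)
        probes = []
        for i in range(100):
            placements = [("chr1", 100 * i, 100 * i + 25, "+")]
            if rng.random() < 0.1:
                placements.append(("chr2", 100 * i, 100 * i + 25, "+"))
            probes.append(ProbeAlignment(f"P{i}", placements))
        kept, excluded = filter_crosshyb(probes)
        brute = sum(1 for p in probes if len(p.placements) > 1)
        assert len(excluded) == brute
        assert len(kept) + len(excluded) == len(probes)
        assert {p.probe_id for p in kept} | {p.probe_id for p in excluded} == {
            p.probe_id for p in probes
        }


def random_instance(seed, n_probes=200, n_lnc=20, n_ens=10):
    rng = np.random.default_rng(seed)
    strands = ["+", "-"]
    lnc, ens = [], []
    for i in range(n_lnc):
        s = int(rng.integers(0, 50_000))
        lnc.append(tx(f"L{i}:1", f"L{i}", "lncipedia_like", f"chr{rng.integers(1, 3)}",
                      strands[rng.integers(2)], [(s, s + int(rng.integers(100, 800)))]))
    for i in range(n_ens):
        s = int(rng.integers(0, 50_000))
        ens.append(tx(f"E{i}.t", f"E{i}", "ensembl_like", f"chr{rng.integers(1, 3)}",
                      strands[rng.integers(2)],
                      [(s, s + int(rng.integers(100, 800)))], biotype="protein_coding"))
    probes = []
    for i in range(n_probes):
        s = int(rng.integers(0, 51_000))
        probes.append(
            ProbeAlignment(f"P{i}", [(f"chr{rng.integers(1, 3)}", s, s + 25,
                                      strands[rng.integers(2)])])
        )
    return probes, ens, lnc


class TestUnivocalAssignment:
    def test_simple_overlap_assigned(self):
        lnc = [tx("L1:1", "L1", "lncipedia_like", "chr1", "+", [(50, 200)])]
        probe = ProbeAlignment("P1", [("chr1", 100, 125, "+")])
        result = assign_probes_univocal([probe], [], lnc)
        assert result.assignments == {"L1": {"P1"}}

    def test_coding_overlap_excluded(self):
        lnc = [tx("L1:1", "L1", "lncipedia_like", "chr1", "+", [(50, 200)])]
        ens = [tx("E1.t", "E1", "ensembl_like", "chr1", "-", [(110, 400)],
                  biotype="protein_coding")]
        probe = ProbeAlignment("P1", [("chr1", 100, 125, "+")])
        result = assign_probes_univocal([probe], ens, lnc)
        assert result.excluded == {"P1": "overlaps_ensembl"}

    def test_two_lnc_genes_ambiguous(self):
        lnc = [
            tx("L1:1", "L1", "lncipedia_like", "chr1", "+", [(50, 200)]),
            tx("L2:1", "L2", "lncipedia_like", "chr1", "-", [(100, 300)]),
        ]
        probe = ProbeAlignment("P1", [("chr1", 120, 145, "+")])
        result = assign_probes_univocal([probe], [], lnc)
        assert result.excluded == {"P1": "ambiguous_lnc"}

    def test_empty_lnc_set_errors(self):
        with pytest.raises(ValidationError):
            assign_probes_univocal([], [], [])

    @pytest.mark.parametrize("strand_mode", ["ignore", "same", "opposite"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_quadratic_oracle(self, seed, strand_mode):
        probes, ens, lnc = random_instance(seed)
        result = assign_probes_univocal(probes, ens, lnc, strand_mode=strand_mode)
        want_assign, want_excl = assign_oracle(probes, ens, lnc, strand_mode)
        assert result.assignments == want_assign
        assert result.excluded == want_excl

    def test_adding_ensembl_transcript_never_adds_assignments(self):
        probes, ens, lnc = random_instance(5)
        base = assign_probes_univocal(probes, ens, lnc)
        extra = ens + [tx("EX.t", "EX", "ensembl_like", "chr1", "+", [(0, 60_000)],
                          biotype="protein_coding")]
        more = assign_probes_univocal(probes, extra, lnc)
        assert len(more.assigned_probes) <= len(base.assigned_probes)

    def test_partition_property(self):
        probes, ens, lnc = random_instance(9)
        result = assign_probes_univocal(probes, ens, lnc)
        assert result.assigned_probes | set(result.excluded) == {p.probe_id for p in probes}
        assert not (result.assigned_probes & set(result.excluded))

    def test_map_round_trips_through_tsv(self, tmp_path):
        probes, ens, lnc = random_instance(2)
        result = assign_probes_univocal(probes, ens, lnc)
        result.to_tsv(tmp_path / "map.tsv")
        back = ProbeLncMap.from_tsv(tmp_path / "map.tsv")
        assert back.assignments == result.assignments
        assert back.excluded == result.excluded


class TestSummarize:
    def _map(self, assignments):
        return ProbeLncMap(assignments, {})

    def test_median_values(self):
        mat = make_matrix(np.array([[4.0], [5.0], [9.0]]), prefix="P", level="probe")
        pm = self._map({"L1": set(mat.feature_ids)})
        out = summarize_by_median(mat, pm)
        assert out.values.iloc[0, 0] == 5.0

    def test_even_count_midpoint(self):
        mat = make_matrix(np.array([[1.0], [2.0], [3.0], [4.0]]), prefix="P", level="probe")
        out = summarize_by_median(mat, self._map({"L1": set(mat.feature_ids)}))
        assert out.values.iloc[0, 0] == 2.5

    def test_single_probe_identity(self):
        mat = make_matrix(np.array([[1.5, 2.5, 3.5]]), prefix="P", level="probe")
        out = summarize_by_median(mat, self._map({"L1": set(mat.feature_ids)}))
        assert np.array_equal(out.values.to_numpy()[0], mat.values.to_numpy()[0])

    def test_min_probes_threshold_and_validation(self):
        mat = make_matrix(np.ones((3, 2)), prefix="P", level="probe")
        ids = mat.feature_ids
        pm = self._map({"L1": {ids[0]}, "L2": {ids[1], ids[2]}})
        out = summarize_by_median(mat, pm, min_probes=2)
        assert out.feature_ids == ["L2"]
        with pytest.raises(ValidationError):
            summarize_by_median(mat, pm, min_probes=0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.floats(-5, 5))
    def test_probe_permutation_invariance_and_shift_equivariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        mat = make_matrix(rng.normal(size=(5, 4)), prefix="P", level="probe")
        ids = mat.feature_ids
        pm = self._map({"L1": set(ids)})
        base = summarize_by_median(mat, pm).values.to_numpy()
        # permute probe rows
        perm = mat.values.sample(frac=1, random_state=int(seed) % 2**31)
        permuted = summarize_by_median(
            type(mat)(perm, "probe"), pm
        ).values.to_numpy()
        assert np.allclose(base, permuted)
        # add a constant to every probe of the lnc
        shifted = summarize_by_median(
            type(mat)(mat.values + shift, "probe"), pm
        ).values.to_numpy()
        assert np.allclose(shifted, base + shift, atol=1e-9)
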