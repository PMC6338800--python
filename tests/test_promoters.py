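"""Promoter windows, track readers, TSS-relative geometry, annotation."""

import numpy as np
import pytest

from cistandem import promoters as pr
from cistandem import synth


def gene(strand="+", tss=10_000, chrom="chr1", gid="g1"):
    return pr.GeneModel(gene_id=gid, chrom=chrom, strand=strand, tss=tss)


class TestReaders:
    def test_bed6_tss_conventions(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\nchr1\t100\t200\tg2\t0\t-\n")
        models = {g.gene_id: g for g in pr.read_tss_table(p)}
        assert models["g1"].tss == 100
        assert models["g2"].tss == 199

    def test_duplicate_gene_keeps_first(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\nchr2\t500\t900\tg1\t0\t+\n")
        models = pr.read_tss_table(p)
        assert len(models) == 1 and models[0].tss == 100

    def test_refflat_dialect(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("g1\tchr1\t+\t100\t200\ng2\tchr1\t-\t100\t200\n")
        models = {g.gene_id: g for g in pr.read_tss_table(p, dialect="refflat")}
        assert models["g1"].tss == 100
        assert models["g2"].tss == 199

    def test_unknown_strand_raises(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t*\n")
        with pytest.raises(pr.ParseError, match="strand"):
            pr.read_tss_table(p)

    def test_repeatmasker_coordinate_conversion(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW  perc ...\nscore div ...\n\n"
            "  463 11.5  0.0  0.0  chr1  101  400 (0)  +  AluYb8  SINE/Alu  1 300 (0) 1\n"
        )
        ivs = pr.read_repeat_track(p, dialect="repeatmasker_out")
        assert (ivs[0].start, ivs[0].end) == (100, 400)

    def test_family_filter_excludes_line_elements(self, tmp_path):
        p = tmp_path / "rm.out"
        rows = [
            ("chr1", 101, 400, "AluYb8"), ("chr1", 1001, 1300, "L1PA3"),
            ("chr2", 11, 40, "AluSx"), ("chr2", 501, 700, "MIR3"),
            ("chr2", 901, 1200, "AluJb"), ("chr3", 51, 350, "AluY"),
            ("chr3", 401, 600, "L2a"), ("chr3", 701, 720, "MLT1A"),
            ("chr4", 11, 310, "HERVK"), ("chr4", 401, 700, "L1MA4"),
        ]
        p.write_text("h1\nh2\n\n" + "".join(
            f"  10 1.0 0.0 0.0 {c} {b} {e} (0) + {name} X 1 1 (0) {i}\n"
            for i, (c, b, e, name) in enumerate(rows)
        ))
        ivs = pr.read_repeat_track(p, dialect="repeatmasker_out")
        expected = [(c, b - 1, e) for c, b, e, name in rows if name.startswith("Alu")]
        assert [(iv.chrom, iv.start, iv.end) for iv in ivs] == expected
        assert len(ivs) == 4

    def test_narrowpeak_reader(self, tmp_path):
        p = tmp_path / "peaks.narrowPeak"
        p.write_text("chr2\t50\t90\tpeak1\t500\t.\t5.1\t-1\t-1\t20\n")
        ivs = pr.read_peaks(p)
        assert (ivs[0].start, ivs[0].end, ivs[0].label) == (50, 90, "irf_evidence")
        assert ivs[0].metadata[0] == "peak1"

    def test_empty_peak_file(self, tmp_path):
        p = tmp_path / "peaks.bed"
        p.write_text("")
        assert pr.read_peaks(p, dialect="bed") == []


class TestWindows:
    def test_plus_strand(self):
        w = pr.make_promoter_window(gene("+"), up=2500, down=500)
        assert (w.start, w.end) == (7500, 10500)

    def test_minus_strand_mirrored(self):
        w = pr.make_promoter_window(gene("-"), up=2500, down=500)
        assert (w.start, w.end) == (9501, 12501)

    def test_boundary_clip(self):
        w = pr.make_promoter_window(gene("+", tss=100), up=2500, down=500)
        assert (w.start, w.end) == (0, 600)

    def test_window_covers_exactly_relative_range(self):
        for strand in "+-":
            g = gene(strand)
            w = pr.make_promoter_window(g, up=30, down=10)
            rel = sorted(
                (p - g.tss) if strand == "+" else (g.tss - p)
                for p in range(w.start, w.end)
            )
            assert rel == list(range(-30, 10))


class TestTssRelative:
    def test_plus_strand_upstream(self):
        iv = pr.GenomicInterval("chr1", 8800, 9100)
        assert pr.to_tss_relative(iv, gene("+")) == (-1200, -900)

    def test_minus_strand_upstream(self):
        # Covered bases 10100..10399 map to tss - p = -399..-100; the
        # normalised half-open relative interval is therefore (-399, -99).
        iv = pr.GenomicInterval("chr1", 10100, 10400)
        assert pr.to_tss_relative(iv, gene("-")) == (-399, -99)

    def test_spanning_tss_contains_zero(self):
        iv = pr.GenomicInterval("chr1", 9990, 10010)
        for strand in "+-":
            a, b = pr.to_tss_relative(iv, gene(strand))
            assert a <= 0 < b

    def test_chromosome_mismatch(self):
        iv = pr.GenomicInterval("chr2", 0, 10)
        with pytest.raises(ValueError, match="mismatch"):
            pr.to_tss_relative(iv, gene("+"))

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            g = gene(strand, tss=int(rng.integers(5000, 50_000)))
            s = int(rng.integers(0, 40_000))
            iv = pr.GenomicInterval("chr1", s, s + int(rng.integers(1, 500)))
            rel = pr.to_tss_relative(iv, g)
            back = pr.from_tss_relative(rel, g)
            assert (back.start, back.end) == (iv.start, iv.end)


class TestAnnotate:
    def test_direct_overlap_example(self):
        g = gene("+")
        w = pr.make_promoter_window(g, 2500, 500)
        alu = [pr.GenomicInterval("chr1", 8800, 9100, label="AluY")]
        irf = [pr.GenomicInterval("chr1", 9890, 9930, label="irf_evidence")]
        ann = pr.annotate_promoter(g, w, alu, irf)
        assert ann.category == "both"
        assert ann.alu_elements == [(-1200, -900)]
        assert ann.irf_elements == [(-110, -70)]

    def test_single_base_overlap_included(self):
        g = gene("+")
        w = pr.make_promoter_window(g, 2500, 500)  # (7500, 10500)
        touching = [pr.GenomicInterval("chr1", 10499, 10600)]
        outside = [pr.GenomicInterval("chr1", 10500, 10600)]
        assert pr.annotate_promoter(g, w, touching, []).category == "alu_only"
        assert pr.annotate_promoter(g, w, outside, []).category == "none"

    def test_empty_tracks_yield_none(self):
        g = gene("+")
        w = pr.make_promoter_window(g, 2500, 500)
        assert pr.annotate_promoter(g, w, [], []).category == "none"

    def test_indexed_overlap_equals_quadratic_oracle(self, small_dataset):
        """Interval-tree annotation equals all-pairs overlap on 200 promoters."""
        ds = small_dataset
        cfg = ds.config
        anns = pr.annotate_promoters(
            ds.genes, ds.alu_track, ds.irf_track,
            up=cfg.promoter_up, down=cfg.promoter_down,
        )
        for g in ds.genes:
            w = pr.make_promoter_window(g, cfg.promoter_up, cfg.promoter_down)
            expected_alu = sorted(
                pr.to_tss_relative(iv, g)
                for iv in ds.alu_track
                if iv.chrom == g.chrom and iv.start < w.end and iv.end > w.start
            )
            expected_irf = sorted(
                pr.to_tss_relative(iv, g)
                for iv in ds.irf_track
                if iv.chrom == g.chrom and iv.start < w.end and iv.end > w.start
            )
            assert sorted(anns[g.gene_id].alu_elements) == expected_alu
            assert sorted(anns[g.gene_id].irf_elements) == expected_irf


def test_strand_symmetry_of_relative_annotations(small_dataset):
    """Reverse-complementing the genome (flipping all coordinates and
    strands) leaves every TSS-relative annotation unchanged."""
    ds = small_dataset
    cfg = ds.config
    L = cfg.chrom_len

    def flip_gene(g):
        return pr.GeneModel(
            gene_id=g.gene_id, chrom=g.chrom,
            strand="-" if g.strand == "+" else "+", tss=L - 1 - g.tss,
        )

    def flip_iv(iv):
        return pr.GenomicInterval(chrom=iv.chrom, start=L - iv.end, end=L - iv.start,
                                  label=iv.label)

    anns = pr.annotate_promoters(
        ds.genes, ds.alu_track, ds.irf_track, up=cfg.promoter_up, down=cfg.promoter_down
    )
    flipped = pr.annotate_promoters(
        [flip_gene(g) for g in ds.genes],
        [flip_iv(iv) for iv in ds.alu_track],
        [flip_iv(iv) for iv in ds.irf_track],
        up=cfg.promoter_up, down=cfg.promoter_down,
    )
    for gid in anns:
        assert sorted(anns[gid].alu_elements) == sorted(flipped[gid].alu_elements)
        assert sorted(anns[gid].irf_elements) == sorted(flipped[gid].irf_elements)
        assert anns[gid].category == flipped[gid].category


def test_annotation_tsv_round_trip(tmp_path, small_dataset):
    ds = small_dataset
    anns = pr.annotate_promoters(ds.genes, ds.alu_track, ds.irf_track)
    path = tmp_path / "ann.tsv"
    pr.write_annotations_tsv(anns, path)
    back = pr.read_annotations_tsv(path)
    assert set(back) == set(anns)
    for gid in anns:
        assert sorted(back[gid].alu_elements) == sorted(anns[gid].alu_elements)
        assert sorted(back[gid].irf_elements) == sorted(anns[gid].irf_elements)
        assert back[gid].category == anns[gid].category
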