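"""Annotation parsing, exon classification, decoys and fictional genes."""

import warnings

import numpy as np
import pytest

from teexon import annotation as ann


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


GENE_HEADER = "gene_id\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n"


class TestParseGeneTable:
    def test_basic_row(self, tmp_path):
        p = write(tmp_path, "g.tsv",
                  GENE_HEADER + "g1\tchr1\t+\t100\t1000\t100,500,\t200,700,\n")
        genes = ann.parse_gene_table(p)
        assert len(genes) == 1
        g = genes[0]
        assert [(e.interval.start, e.interval.end) for e in g.exons] == \
            [(100, 200), (500, 700)]
        assert g.strand == "+" and not g.fictional

    def test_exon_list_length_mismatch(self, tmp_path):
        p = write(tmp_path, "g.tsv",
                  GENE_HEADER + "g1\tchr1\t+\t100\t400\t100,\t200,300,\n")
        with pytest.raises(ann.ParseError, match="mismatch"):
            ann.parse_gene_table(p)

    def test_header_only(self, tmp_path):
        assert ann.parse_gene_table(write(tmp_path, "g.tsv", GENE_HEADER)) == []

    def test_duplicate_gene_rejected(self, tmp_path):
        row = "g1\tchr1\t+\t100\t400\t100,\t200,\n"
        p = write(tmp_path, "g.tsv", GENE_HEADER + row + row)
        with pytest.raises(ann.ParseError, match="duplicate"):
            ann.parse_gene_table(p)

    def test_inverted_transcript_span(self, tmp_path):
        p = write(tmp_path, "g.tsv",
                  GENE_HEADER + "g1\tchr1\t+\t400\t100\t100,\t200,\n")
        with pytest.raises(ann.ParseError, match="txStart"):
            ann.parse_gene_table(p)

    def test_one_based_dialect_shift(self, tmp_path):
        p = write(tmp_path, "g.tsv",
                  GENE_HEADER + "g1\tchr1\t+\t101\t200\t101,\t200,\n")
        (g,) = ann.parse_gene_table(p, one_based_closed=True)
        assert (g.exons[0].interval.start, g.exons[0].interval.end) == (100, 200)


TE_HEADER = ("exon_id\tchrom\tstart\tend\tstrand\tgene_id\tlocation\tfamily"
             "\tte_nucleotides\test_inclusion\n")


class TestParseTeTable:
    def test_rte_from_nucleotide_count(self, tmp_path):
        p = write(tmp_path, "te.tsv",
                  TE_HEADER + "e1\tchr1\t0\t300\t+\tg1\tCDS\tAlu\t150\t\n")
        _, (feat,) = ann.parse_te_exon_table(p)
        assert feat.rte == pytest.approx(0.5)
        assert feat.eln == 300

    def test_location_alias(self, tmp_path):
        p = write(tmp_path, "te.tsv",
                  TE_HEADER + "e1\tchr1\t0\t300\t+\tg1\t5UTR\tAlu\t10\t\n")
        _, (feat,) = ann.parse_te_exon_table(p)
        assert feat.location == "UTR5" and feat.family == "Alu"

    def test_te_count_exceeding_length(self, tmp_path):
        p = write(tmp_path, "te.tsv",
                  TE_HEADER + "e1\tchr1\t0\t300\t+\tg1\tCDS\tAlu\t400\t\n")
        with pytest.raises(ann.ParseError, match="te_nucleotides"):
            ann.parse_te_exon_table(p)

    def test_unknown_family_lists_allowed(self, tmp_path):
        p = write(tmp_path, "te.tsv",
                  TE_HEADER + "e1\tchr1\t0\t300\t+\tg1\tCDS\tSINE9\t10\t\n")
        with pytest.raises(ann.ParseError, match="Alu"):
            ann.parse_te_exon_table(p)


@pytest.mark.parametrize("te_nt,length,expected",
                         [(150, 300, 0.5), (300, 300, 1.0), (0, 300, 0.0)])
def test_compute_rte(te_nt, length, expected):
    assert ann.compute_rte(te_nt, length) == pytest.approx(expected)


def test_compute_rte_zero_length():
    with pytest.raises(ValueError):
        ann.compute_rte(0, 0)


def _toy_gene(gid="g1", chrom="chr1", strand="+", exons=((100, 200), (500, 700))):
    recs = [ann.ExonRecord(exon_id=f"{chrom}:{s}-{e}",
                           interval=ann.GenomicInterval(chrom, s, e, strand),
                           gene_ids={gid}) for s, e in exons]
    return ann.GeneModel(gene_id=gid,
                         interval=ann.GenomicInterval(
                             chrom, exons[0][0], exons[-1][1], strand),
                         exons=recs)


def _te_entry(chrom, s, e, gid, family="Alu", location="CDS"):
    rec = ann.ExonRecord(exon_id=f"te:{s}-{e}",
                         interval=ann.GenomicInterval(chrom, s, e),
                         gene_ids={gid})
    feat = ann.TEExonFeature(exon_id=rec.exon_id, location=location,
                             family=family, eln=e - s, rte=0.4)
    return rec, feat


class TestClassify:
    def test_class_assignment_rules(self):
        gene = _toy_gene(exons=((100, 200), (500, 700), (900, 950)))
        te_rec, te_feat = _te_entry("chr1", 500, 700, "g1")      # exact match
        c4_rec, c4_feat = _te_entry("chr1", 300, 400, "g1")      # intronic
        alt = [ann.GenomicInterval("chr1", 900, 950)]
        exons, feats = ann.classify_exons([gene], [te_rec, c4_rec],
                                          [te_feat, c4_feat], alt)
        by_class = {e.exon_class: e for e in exons.values()}
        assert by_class["C3"].interval.key == ("chr1", 500, 700)
        assert by_class["C4"].interval.key == ("chr1", 300, 400)
        assert by_class["C2"].interval.key == ("chr1", 900, 950)
        assert by_class["C1"].interval.key == ("chr1", 100, 200)
        assert feats[by_class["C3"].exon_id].annotated
        assert not feats[by_class["C4"].exon_id].annotated

    def test_partition_is_total(self, small_dataset):
        annot = small_dataset.annotation
        real_exon_keys = set()
        for g in annot.genes.values():
            if not g.fictional:
                real_exon_keys.update(e.interval.key for e in g.exons)
        classified = [e for e in annot.exons.values()
                      if e.exon_class in ("C1", "C2", "C3")]
        assert {e.interval.key for e in classified} == real_exon_keys
        # every exon exactly one class
        assert len(classified) == len(real_exon_keys)


class TestSimulatedExons:
    def test_plus_strand_downstream(self):
        gene = _toy_gene(exons=((1000, 1200),), strand="+")
        c4 = ann.ExonRecord("c4", ann.GenomicInterval("chr1", 1000, 1200),
                            {"g1"}, "C4")
        (c5,) = ann.build_simulated_exons([c4], [gene])
        assert (c5.interval.start, c5.interval.end) == (1200, 1400)
        assert c5.exon_id == "c4.sim" and c5.exon_class == "C5"

    def test_minus_strand_reflected(self):
        gene = _toy_gene(exons=((1000, 1200),), strand="-")
        c4 = ann.ExonRecord("c4", ann.GenomicInterval("chr1", 1000, 1200, "-"),
                            {"g1"}, "C4")
        (c5,) = ann.build_simulated_exons([c4], [gene])
        assert (c5.interval.start, c5.interval.end) == (800, 1000)

    def test_strand_ignorant_mode(self):
        gene = _toy_gene(exons=((1000, 1200),), strand="-")
        c4 = ann.ExonRecord("c4", ann.GenomicInterval("chr1", 1000, 1200, "-"),
                            {"g1"}, "C4")
        (c5,) = ann.build_simulated_exons([c4], [gene], strand_aware=False)
        assert (c5.interval.start, c5.interval.end) == (1200, 1400)

    def test_clip_at_chromosome_start(self):
        gene = _toy_gene(exons=((50, 200),), strand="-")
        c4 = ann.ExonRecord("c4", ann.GenomicInterval("chr1", 50, 200, "-"),
                            {"g1"}, "C4")
        with pytest.warns(UserWarning, match="clipped"):
            (c5,) = ann.build_simulated_exons([c4], [gene])
        assert (c5.interval.start, c5.interval.end) == (0, 50)

    def test_pairing_and_lengths(self, small_dataset):
        annot = small_dataset.annotation
        assert len(annot.c5_ids) == len(annot.c4_ids)
        for c4_id, c5_id in zip(annot.c4_ids, annot.c5_ids):
            assert c5_id == c4_id + ".sim"
            assert annot.exons[c4_id].length == annot.exons[c5_id].length


class TestFictionalGenes:
    def _c5_pool(self, n=60):
        return [ann.ExonRecord(f"s{i}",
                               ann.GenomicInterval("chr1", 1000 * i + 10,
                                                   1000 * i + 110),
                               set(), "C5") for i in range(n)]

    def test_membership_bounds_and_determinism(self):
        pool = self._c5_pool()
        genes = ann.build_fictional_genes(pool, n_genes=25, seed=7)
        assert len(genes) == 25
        for g in genes:
            assert 4 <= len(g.exons) <= 40
            ids = [e.exon_id for e in g.exons]
            assert len(set(ids)) == len(ids)        # without replacement
            assert g.fictional
        again = ann.build_fictional_genes(self._c5_pool(), n_genes=25, seed=7)
        assert [[e.exon_id for e in g.exons] for g in genes] == \
            [[e.exon_id for e in g.exons] for g in again]

    def test_too_few_decoys(self):
        with pytest.raises(ValueError, match="at least 4"):
            ann.build_fictional_genes(self._c5_pool(3), n_genes=5)


class TestC5Collisions:
    def _inputs(self):
        gene = _toy_gene(exons=((100, 200), (450, 550)))
        te_rec, te_feat = _te_entry("chr1", 300, 400, "g1")
        return [gene], [te_rec], [te_feat]

    def test_flagged_by_default(self):
        genes, te, feats = self._inputs()
        annot = ann.build_annotation_set(genes, te, feats, [],
                                         n_fictional=1,
                                         fictional_exon_range=(1, 1))
        (c5_id,) = annot.c5_ids
        assert annot.colliding_c5_ids == {c5_id}
        assert annot.exons[c5_id].interval.key == ("chr1", 400, 500)

    def test_shift_mode_clears_overlap(self):
        genes, te, feats = self._inputs()
        annot = ann.build_annotation_set(genes, te, feats, [],
                                         n_fictional=1,
                                         fictional_exon_range=(1, 1),
                                         c5_collision="shift")
        (c5_id,) = annot.c5_ids
        assert not annot.colliding_c5_ids
        assert annot.exons[c5_id].interval.key == ("chr1", 600, 700)


def test_tables_round_trip(small_dataset, tmp_path):
    """parse -> write -> parse is the identity on every table."""
    annot = small_dataset.annotation
    real = [g for g in annot.genes.values() if not g.fictional]
    ann.write_gene_table(real, tmp_path / "genes.tsv")
    back = ann.parse_gene_table(tmp_path / "genes.tsv")
    assert len(back) == len(real)
    for a, b in zip(real, back):
        assert a.gene_id == b.gene_id
        assert [e.interval.key for e in a.exons] == \
            [e.interval.key for e in b.exons]

    te_ids = sorted(annot.te_features)
    te_exons = [annot.exons[e] for e in te_ids]
    feats = [annot.te_features[e] for e in te_ids]
    ann.write_te_exon_table(te_exons, feats, tmp_path / "te.tsv")
    b_exons, b_feats = ann.parse_te_exon_table(tmp_path / "te.tsv")
    assert [e.interval.key for e in b_exons] == \
        [e.interval.key for e in te_exons]
    for a, b in zip(feats, b_feats):
        assert (a.location, a.family, a.eln) == (b.location, b.family, b.eln)
        assert a.rte == pytest.approx(b.rte, abs=1e-12)

    alt = [annot.exons[e].interval for e in annot.exons
           if annot.exons[e].exon_class == "C2"]
    ann.write_alt_table(alt, tmp_path / "alt.bed")
    back_alt = ann.parse_alt_table(tmp_path / "alt.bed")
    assert [iv.key for iv in back_alt] == [iv.key for iv in alt]
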