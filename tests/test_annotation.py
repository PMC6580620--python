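"""Coordinate conventions, GFF3 round-trips, ID correction, indexing,
and cross-version isoform remapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtyper.annotation import (
    AnnotationError,
    AnnotationSet,
    GenomicInterval,
    IsoformRecord,
    build_locus_index,
    correct_duplicate_ids,
    parse_mirbase_gff3,
    remap_isoforms,
    write_mirbase_gff3,
)

MIRBASE_TOY = """\
##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t90\t170\t.\t+\t.\tID=MI0001;Name=mir-1
chr1\t.\tmiRNA\t100\t121\t.\t+\t.\tID=MIMAT0001;Name=miR-1-5p;Derives_from=MI0001
chr1\t.\tmiRNA\t140\t161\t.\t+\t.\tID=MIMAT0002;Name=miR-1-3p;Derives_from=MI0001
chr2\t.\tmiRNA_primary_transcript\t500\t580\t.\t-\t.\tID=MI0002;Name=mir-2
chr2\t.\tmiRNA\t520\t541\t.\t-\t.\tID=MIMAT0003;Name=miR-2-5p;Derives_from=MI0002
"""


class TestCoordinateConventions:
    def test_gff3_inclusive_to_internal(self):
        iv = GenomicInterval.from_gff3("chr1", 100, 121, "+")
        assert (iv.start, iv.end, len(iv)) == (99, 121, 22)
        assert iv.to_gff3() == (100, 121)

    def test_tcga_half_open_to_internal(self):
        # start included, end excluded, 1-based: [100, 122) is 22 nt
        iv = GenomicInterval.from_tcga("chr1", 100, 122, "+")
        assert (iv.start, iv.end, len(iv)) == (99, 121, 22)
        assert iv.to_tcga() == (100, 122)

    @given(start=st.integers(1, 10**8), length=st.integers(1, 1000),
           strand=st.sampled_from("+-"))
    @settings(max_examples=100, deadline=None)
    def test_conversions_are_involutions(self, start, length, strand):
        end = start + length - 1  # GFF3 inclusive end
        iv = GenomicInterval.from_gff3("c", start, end, strand)
        assert GenomicInterval.from_gff3("c", *iv.to_gff3(), strand) == iv
        ts, te = iv.to_tcga()
        assert GenomicInterval.from_tcga("c", ts, te, strand) == iv

    def test_invalid_intervals_rejected(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("c", 10, 10, "+")
        with pytest.raises(AnnotationError):
            GenomicInterval("c", 5, 10, "*")


class TestParse:
    def test_matures_attach_to_precursors(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(MIRBASE_TOY)
        ann = parse_mirbase_gff3(p)
        assert len(ann.precursors) == 2
        assert len(ann.matures) == 3
        for m in ann.matures:
            assert len(m.loci) >= 1
            assert all(pid in ann.precursors for pid in m.precursor_ids)
        m = ann.mature_by_id("MIMAT0003")
        assert m.loci[0].strand == "-"
        assert m.loci[0].start == 519 and m.loci[0].end == 541

    def test_malformed_attribute_names_line(self, tmp_path):
        bad = MIRBASE_TOY.replace(
            "ID=MIMAT0002;Name=miR-1-3p;Derives_from=MI0001",
            "ID=MIMAT0002;broken attribute",
        )
        p = tmp_path / "bad.gff3"
        p.write_text(bad)
        with pytest.raises(AnnotationError, match=r":4:"):
            parse_mirbase_gff3(p)

    def test_unknown_derives_from_lists_id(self, tmp_path):
        bad = MIRBASE_TOY.replace("Derives_from=MI0002", "Derives_from=MI9999")
        p = tmp_path / "bad.gff3"
        p.write_text(bad)
        with pytest.raises(AnnotationError, match="MIMAT0003"):
            parse_mirbase_gff3(p)

    def test_roundtrip_write_then_parse(self, sim_ann, tmp_path):
        p = tmp_path / "rt.gff3"
        write_mirbase_gff3(sim_ann.ann, p)
        seqs = {m.mature_id: m.sequence for m in sim_ann.ann.matures}
        back = parse_mirbase_gff3(p, sequences=seqs, version_tag="sim")
        assert back.precursors == sim_ann.ann.precursors
        orig = {m.mature_id: (m.sequence, sorted(m.loci), sorted(m.precursor_ids))
                for m in sim_ann.ann.matures}
        rt = {m.mature_id: (m.sequence, sorted(m.loci), sorted(m.precursor_ids))
              for m in back.matures}
        assert rt == orig


class TestDuplicateIdCorrection:
    DUP = """\
##gff-version 3
chr2\t.\tmiRNA_primary_transcript\t5000\t5080\t.\t+\t.\tID=MI7777;Name=mir-4477a
chr1\t.\tmiRNA_primary_transcript\t1000\t1080\t.\t+\t.\tID=MI7777;Name=mir-4477a
chr1\t.\tmiRNA\t1010\t1031\t.\t+\t.\tID=MIMAT7777;Name=miR-4477a;Derives_from=MI7777
"""

    def test_shared_id_suffixed_in_coordinate_order(self, tmp_path):
        p = tmp_path / "dup.gff3"
        p.write_text(self.DUP)
        ann = correct_duplicate_ids(parse_mirbase_gff3(p))
        names = sorted(ann.precursor_names.values())
        assert names == ["mir-4477a-1", "mir-4477a-2"]
        # -1 goes to the lower coordinate (chr1 before chr2)
        by_name = {v: k for k, v in ann.precursor_names.items()}
        assert ann.precursors[by_name["mir-4477a-1"]].chrom == "chr1"
        assert ann.precursors[by_name["mir-4477a-2"]].chrom == "chr2"
        assert sorted(ann.precursors) == ["MI7777-1", "MI7777-2"]

    def test_unique_ids_unchanged(self, sim_ann):
        assert correct_duplicate_ids(sim_ann.ann) is sim_ann.ann

    def test_three_loci_ordered_like_bruteforce_grouping(self, tmp_path):
        rows = [("chr2", 300), ("chr1", 900), ("chr1", 200)]
        body = "".join(
            f"{c}\t.\tmiRNA_primary_transcript\t{s}\t{s + 80}\t.\t+\t.\t"
            f"ID=MI8888;Name=mir-x\n"
            for c, s in rows
        )
        p = tmp_path / "dup3.gff3"
        p.write_text("##gff-version 3\n" + body)
        ann = correct_duplicate_ids(parse_mirbase_gff3(p))
        # brute force: sort loci by (chrom, start), then suffix 1..3
        expected = sorted(
            (GenomicInterval.from_gff3(c, s, s + 80, "+") for c, s in rows),
            key=lambda iv: (iv.chrom, iv.start),
        )
        got = [ann.precursors[k] for k in
               sorted(ann.precursors, key=lambda k: ann.precursor_names[k])]
        assert got == expected
        assert sorted(ann.precursor_names.values()) == [
            "mir-x-1", "mir-x-2", "mir-x-3"]


class TestLocusIndex:
    def test_exact_cover_and_strand_contract(self, sim_ann, locus_index):
        m = sim_ann.ann.matures[-1]
        locus = m.loci[0]
        hits = locus_index.query(locus)
        assert any(h.mature_id == m.mature_id for h in hits)
        flipped = GenomicInterval(locus.chrom, locus.start, locus.end,
                                  "-" if locus.strand == "+" else "+")
        assert all(h.interval.strand != locus.strand
                   for h in locus_index.query(flipped))

    def test_1000_random_queries_match_linear_scan(self, sim_ann, locus_index):
        gen = np.random.default_rng(3)
        all_loci = locus_index.loci
        max_pos = max(len(s) for s in sim_ann.genome.values())
        chroms = list(sim_ann.genome)
        for _ in range(1000):
            c = chroms[gen.integers(len(chroms))]
            s = int(gen.integers(0, max_pos - 30))
            e = s + int(gen.integers(1, 60))
            strand = "+-"[gen.integers(2)]
            q = GenomicInterval(c, s, e, strand)
            brute = {
                (ml.mature_id, ml.interval)
                for ml in all_loci
                if ml.interval.chrom == c and ml.interval.strand == strand
                and ml.interval.start < e and s < ml.interval.end
            }
            got = {(ml.mature_id, ml.interval) for ml in locus_index.query(q)}
            assert got == brute


def _brute_remap(records, loci, max_dev):
    """Exhaustive all-locus deviation scan."""
    assigned, dropped = {}, 0
    for rec in records:
        devs = []
        for ml in loci:
            if (ml.interval.chrom, ml.interval.strand) != (
                    rec.interval.chrom, rec.interval.strand):
                continue
            d = (abs(ml.interval.start - rec.interval.start)
                 + abs(ml.interval.end - rec.interval.end))
            if d <= max_dev:
                devs.append((d, ml.mature_id))
        if not devs:
            dropped += rec.read_count
            continue
        best = min(d for d, _ in devs)
        ids = {m for d, m in devs if d == best}
        if len(ids) > 1:
            dropped += rec.read_count
        else:
            mid = ids.pop()
            assigned[(mid, rec.sample_id)] = (
                assigned.get((mid, rec.sample_id), 0) + rec.read_count)
    return assigned, dropped


class TestRemapIsoforms:
    def _record(self, locus, ds=0, de=0, n=5, sample="s1"):
        iv = GenomicInterval(locus.chrom, locus.start + ds, locus.end + de,
                             locus.strand)
        return IsoformRecord(sample_id=sample, interval=iv, read_count=n)

    def test_exact_match_assigned(self, sim_ann):
        m = sim_ann.ann.matures[-1]
        mat, rep = remap_isoforms([self._record(m.loci[0])], sim_ann.ann)
        assert mat.loc[m.mature_id, "s1"] == 5
        assert rep.assigned_reads == 5 and rep.dropped_no_match == 0

    def test_deviation_boundary_at_4(self, sim_ann):
        m = sim_ann.ann.matures[-1]
        ok = self._record(m.loci[0], ds=2, de=2)       # total 4
        bad = self._record(m.loci[0], ds=3, de=2)      # total 5
        mat, rep = remap_isoforms([ok, bad], sim_ann.ann)
        assert mat.loc[m.mature_id, "s1"] == 5
        assert rep.dropped_no_match == 5

    def test_mass_conservation_and_bruteforce_agreement(self, sim_ann,
                                                        locus_index):
        gen = np.random.default_rng(17)
        loci = locus_index.loci
        records = []
        for i in range(50):
            ml = loci[gen.integers(len(loci))]
            ds, de = int(gen.integers(-4, 5)), int(gen.integers(-4, 5))
            records.append(self._record(ml.interval, ds, de,
                                        n=int(gen.integers(1, 20)),
                                        sample=f"s{gen.integers(3)}"))
        mat, rep = remap_isoforms(records, sim_ann.ann)
        brute_assigned, brute_dropped = _brute_remap(records, loci, 4)
        for (mid, sid), n in brute_assigned.items():
            assert mat.loc[mid, sid] == n
        assert int(mat.to_numpy().sum()) == sum(brute_assigned.values())
        total = sum(r.read_count for r in records)
        assert rep.total_reads == total
        assert rep.dropped_no_match + rep.dropped_ambiguous == brute_dropped

    def test_tcga_dialect_round_trips_to_exact_match(self, sim_ann):
        m = sim_ann.ann.matures[-1]
        locus = m.loci[0]
        ts, te = locus.to_tcga()
        rec = IsoformRecord(
            "s1", GenomicInterval.from_tcga(locus.chrom, ts, te, locus.strand), 3
        )
        mat, _ = remap_isoforms([rec], sim_ann.ann)
        assert mat.loc[m.mature_id, "s1"] == 3

    def test_negative_max_dev_rejected(self, sim_ann):
        with pytest.raises(ValueError):
            remap_isoforms([], sim_ann.ann, max_dev=-1)
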