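"""RepeatMasker parsing, element merging and subgroup assignment."""
import numpy as np
import pytest

from rteshift.intervals import GenomicInterval, ValidationError
from rteshift.repeats import (
    MergedElement,
    ParseError,
    RepeatFeature,
    assign_subgroup,
    merge_elements,
    parse_repeatmasker,
    write_bed6,
    write_repeatmasker,
)

HEADER = (
    "   SW   perc perc perc  query     position in query     matching repeat\n"
    "score   div. del. ins.  sequence  begin  end    (left)  repeat class/family begin end (left) ID\n"
    "\n"
)


def _feat(chrom, start, end, strand, family, rclass, rm_id):
    return RepeatFeature(
        GenomicInterval(chrom, start, end, strand), family, rclass, rm_id, 10.0
    )


def write_out(path, rows):
    path.write_text(HEADER + "".join(rows))


class TestParse:
    def test_coordinate_conversion_and_strand(self, tmp_path):
        p = tmp_path / "r.out"
        write_out(p, [
            " 1000 12.3 0.0 0.0 chr6 1000 8000 (0) + HERVE-int LTR/ERV1 1 7000 (0) 5\n",
            " 900 8.1 0.0 0.0 chr6 9000 9450 (0) C LTR2B LTR/ERV1 1 450 (0) 5\n",
        ])
        feats = parse_repeatmasker(p)
        assert len(feats) == 2
        assert feats[0].interval == GenomicInterval("chr6", 999, 8000, "+")
        assert feats[0].family == "HERVE-int" and feats[0].rm_id == 5
        assert feats[1].interval.strand == "-"  # "C" maps to minus

    def test_empty_file_after_header(self, tmp_path):
        p = tmp_path / "empty.out"
        write_out(p, [])
        assert parse_repeatmasker(p) == []

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.out"
        write_out(p, [" 1000 12.3 0.0 0.0 chr6 1000\n"])
        with pytest.raises(ParseError, match="line 4"):
            parse_repeatmasker(p)

    def test_non_numeric_coordinate(self, tmp_path):
        p = tmp_path / "bad.out"
        write_out(p, [" 1000 12.3 0.0 0.0 chr6 xx 8000 (0) + A SINE/Alu 1 10 (0) 1\n"])
        with pytest.raises(ParseError, match="line 4"):
            parse_repeatmasker(p)

    def test_roundtrip_identity(self, tmp_path):
        feats = [
            _feat("chr1", 100, 400, "+", "AluSz", "SINE/Alu", 1),
            _feat("chr1", 900, 2000, "-", "L1PB1", "LINE/L1", 2),
            _feat("chr2", 0, 50, "+", "MIR3", "SINE/MIR", 3),
        ]
        p = tmp_path / "rt.out"
        write_repeatmasker(feats, p)
        back = parse_repeatmasker(p)
        assert [(f.interval, f.family, f.rm_id) for f in back] == [
            (f.interval, f.family, f.rm_id) for f in feats
        ]


class TestMerge:
    def test_shared_rm_id_merges_provirus(self):
        feats = [
            _feat("chr6", 1000, 1450, "+", "LTR2B", "LTR/ERV1", 5),
            _feat("chr6", 1450, 8000, "+", "HERVE-int", "LTR/ERV1", 5),
            _feat("chr6", 8000, 8450, "+", "LTR2B", "LTR/ERV1", 5),
        ]
        (el,) = merge_elements(feats)
        assert (el.interval.start, el.interval.end) == (1000, 8450)
        assert el.name == "HERVE" and el.is_provirus
        assert len(el.members) == 3

    def test_distant_unrelated_features_stay_apart(self):
        feats = [
            _feat("chr1", 100, 400, "+", "AluSz", "SINE/Alu", 1),
            _feat("chr1", 900, 2000, "+", "L1PB1", "LINE/L1", 2),
        ]
        els = merge_elements(feats, max_gap=100)
        assert len(els) == 2
        assert not any(e.is_provirus for e in els)

    def test_adjacency_merges_ltr_and_internal(self):
        # gap 50 <= 100 and internal flanked by an LTR family (rule b)
        feats = [
            _feat("chrX", 0, 450, "+", "LTR7", "LTR/ERV1", 1),
            _feat("chrX", 500, 5000, "+", "HERVH-int", "LTR/ERV1", 2),
        ]
        (el,) = merge_elements(feats, max_gap=100)
        assert el.name == "HERVH" and el.is_provirus
        assert (el.interval.start, el.interval.end) == (0, 5000)

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ValidationError):
            merge_elements([], max_gap=-1)

    def test_opposite_strands_never_merge(self):
        feats = [
            _feat("chr1", 0, 100, "+", "AluSz", "SINE/Alu", 1),
            _feat("chr1", 120, 200, "-", "AluSz", "SINE/Alu", 2),
        ]
        assert len(merge_elements(feats, max_gap=100)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_order_invariant_coverage_conserving(self, seed):
        rng = np.random.default_rng(seed)
        families = [("AluSz", "SINE/Alu"), ("LTR2B", "LTR/ERV1"),
                    ("HERVE-int", "LTR/ERV1"), ("L1PA2", "LINE/L1")]
        feats = []
        pos = 0
        for i in range(40):
            pos += int(rng.integers(10, 400))
            length = int(rng.integers(50, 500))
            fam, rc = families[rng.integers(len(families))]
            strand = "+" if rng.random() < 0.7 else "-"
            feats.append(_feat("chr1", pos, pos + length, strand, fam, rc,
                               int(rng.integers(1, 15))))
            pos += length
        els = merge_elements(feats)

        def key(e):
            return (e.interval.chrom, e.interval.start, e.interval.end, e.name,
                    tuple((m.interval.start, m.family) for m in e.members))

        # every input feature in exactly one element
        all_members = [m for e in els for m in e.members]
        assert sorted(all_members, key=id) and len(all_members) == len(feats)
        assert {id(m) for m in all_members} == {id(f) for f in feats}
        # idempotent: re-merging the members reproduces the elements
        remerged = merge_elements(all_members)
        assert sorted(map(key, remerged)) == sorted(map(key, els))
        # order invariance
        perm = list(feats)
        rng.shuffle(perm)
        assert sorted(map(key, merge_elements(perm))) == sorted(map(key, els))
        # coverage conservation
        def union(ivs):
            points = set()
            for iv in ivs:
                points.update(range(iv.start, iv.end))
            return points
        assert union([f.interval for f in feats]) == union(
            [m.interval for e in els for m in e.members]
        )

    def test_bed6_export(self, tmp_path):
        feats = [_feat("chr6", 1000, 1450, "+", "LTR2B", "LTR/ERV1", 5),
                 _feat("chr6", 1450, 8000, "+", "HERVE-int", "LTR/ERV1", 5)]
        els = merge_elements(feats)
        p = tmp_path / "e.bed"
        write_bed6(els, p)
        assert p.read_text() == "chr6\t1000\t8000\tHERVE\t2\t+\n"


@pytest.mark.parametrize(
    "family,rclass,expected",
    [
        ("AluSx3", "SINE/Alu", "Alu"),
        ("THE1A", "LTR/ERVL-MaLR", "ERV/LTR"),
        ("MamRep137", "DNA/hAT", "other"),
        ("MIRb", "SINE/MIR", "MIR"),
        ("L1PA2", "LINE/L1", "L1"),
        ("L2c", "LINE/L2", "L2"),
        ("SVA_D", "Retroposon/SVA", "SVA"),
    ],
)
def test_assign_subgroup(family, rclass, expected):
    assert assign_subgroup(family, rclass) == expected
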