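"""Unit tests for the 28-category feature encoding and SEG I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnasig import (
    CATALOG,
    CNASegment,
    build_feature_matrix,
    classify_segment,
    log2_to_cn,
    read_features,
    read_seg,
    write_features,
)
from cnasig.cnv_features import FeatureMatrix, SegFormatError


class TestClassify:
    @pytest.mark.parametrize(
        ("cn", "length", "label"),
        [
            (0, 50_000, "HD:0-100Kb"),
            (1, 60_000_000, "LOH:>40Mb"),
            (6, 5_000_000, "gain5-8:1Mb-10Mb"),
            (2, 500_000, "diploid:100Kb-1Mb"),
            # half-open boundaries: the boundary length belongs upward
            (2, 100_000, "diploid:100Kb-1Mb"),
            (2, 99_999, "diploid:0-100Kb"),
            (0, 1_000_000, "HD:>1Mb"),
            (9, 40_000_000, "gain9+:>40Mb"),
            (12, 1, "gain9+:0-100Kb"),
        ],
    )
    def test_examples(self, cn, length, label):
        assert CATALOG.categories[classify_segment(cn, length)] == label

    def test_exhaustive_and_mutually_exclusive(self):
        lengths = [1, 10**5 - 1, 10**5, 10**6, 10**7, 4 * 10**7, 10**8]
        seen = set()
        for cn in range(13):
            for length in lengths:
                idx = classify_segment(cn, length)
                assert 0 <= idx < 28
                seen.add(idx)
        assert seen == set(range(28))
        assert len(CATALOG) == 28

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_segment(2, 0)
        with pytest.raises(ValueError):
            classify_segment(-1, 1000)


class TestLog2ToCn:
    @pytest.mark.parametrize(
        ("seg_mean", "cn"), [(0.0, 2), (1.0, 4), (-1.0, 1), (-3.0, 0), (0.585, 3)]
    )
    def test_examples(self, seg_mean, cn):
        assert log2_to_cn(seg_mean) == cn

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            log2_to_cn(float("nan"))


def _seg(sid, cn, length, chrom="1", start=1):
    return CNASegment(
        sample_id=sid, chromosome=chrom, start_bp=start,
        end_bp=start + length - 1, total_cn=cn,
    )


class TestBuildFeatureMatrix:
    def test_single_segment_single_category(self):
        m = build_feature_matrix([_seg("s1", 3, 5_000_000)])
        row = m.values[0]
        idx = CATALOG.index("gain3-4:1Mb-10Mb")
        assert row[idx] == pytest.approx(1.0)
        assert row.sum() == pytest.approx(1.0)

    def test_equal_split(self):
        segs = [
            _seg("s1", 2, 50_000_000, chrom="1"),
            _seg("s1", 1, 50_000_000, chrom="2"),
        ]
        row = build_feature_matrix(segs).values[0]
        assert row[CATALOG.index("diploid:>40Mb")] == pytest.approx(0.5)
        assert row[CATALOG.index("LOH:>40Mb")] == pytest.approx(0.5)

    def test_log2_derived_copy_number(self):
        seg = CNASegment(
            sample_id="s1", chromosome="1", start_bp=1, end_bp=5_000_000,
            seg_mean=1.0,
        )
        row = build_feature_matrix([seg]).values[0]
        assert row[CATALOG.index("gain3-4:1Mb-10Mb")] == pytest.approx(1.0)

    def test_scale_invariance_within_length_classes(self):
        # lengths deep inside their classes stay in class when scaled by 1.5
        segs = [_seg("s1", 2, 50_000_000), _seg("s1", 4, 2_000_000, chrom="2")]
        scaled = [
            _seg("s1", 2, 75_000_000), _seg("s1", 4, 3_000_000, chrom="2")
        ]
        np.testing.assert_allclose(
            build_feature_matrix(segs).values,
            build_feature_matrix(scaled).values,
            atol=1e-12,
        )

    def test_row_order_is_first_appearance(self):
        segs = [_seg("b", 2, 1000), _seg("a", 2, 1000), _seg("b", 1, 1000)]
        m = build_feature_matrix(segs)
        assert m.sample_ids == ["b", "a"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=12),
                st.integers(min_value=1, max_value=200_000_000),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_rows_sum_to_one(self, cn_lengths):
        segs = [
            _seg("s", cn, length, chrom=str(i + 1))
            for i, (cn, length) in enumerate(cn_lengths)
        ]
        row = build_feature_matrix(segs).values[0]
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(row >= 0)


class TestReadSeg:
    HEADER = "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"

    def _write(self, path, rows):
        path.write_text(self.HEADER + "".join(rows))

    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.seg"
        self._write(p, [
            "s1\t1\t100\t5000\t10\t0.5\n",
            "s1\tchr2\t1\t900\t5\t-0.2\n",
            "s2\tX\t10\t20\t\t0.0\n",
        ])
        segs = read_seg(p)
        assert len(segs) == 3
        assert segs[0].seg_mean == 0.5 and segs[0].total_cn is None
        assert segs[1].chromosome == "2"  # chr prefix stripped
        assert segs[2].chromosome == "X"

    def test_chrom_y_dropped_by_default(self, tmp_path):
        p = tmp_path / "a.seg"
        self._write(p, ["s1\tY\t1\t100\t\t0.0\n", "s1\t1\t1\t100\t\t0.0\n"])
        assert len(read_seg(p)) == 1
        assert len(read_seg(p, drop_chrom_y=False)) == 2

    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text(self.HEADER)
        assert read_seg(p) == []

    def test_end_before_start_names_line(self, tmp_path):
        p = tmp_path / "a.seg"
        self._write(p, ["s1\t1\t100\t5000\t10\t0.5\n", "s1\t1\t900\t100\t5\t0.1\n"])
        with pytest.raises(SegFormatError, match="line 3"):
            read_seg(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\n" + "s1\t1\t1\t10\n")
        with pytest.raises(SegFormatError, match="seg_mean"):
            read_seg(p)

    def test_integer_cn_dialect(self, tmp_path):
        p = tmp_path / "a.seg"
        p.write_text("sample\tchrom\tstart\tend\ttotal_cn\n" + "s1\t1\t1\t2000000\t4\n")
        segs = read_seg(p, dialect="integer_cn")
        assert segs[0].total_cn == 4


class TestFeatureTsvRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.dirichlet(np.ones(28), size=3)
        m = FeatureMatrix(sample_ids=["a", "b", "c"], values=vals)
        p = tmp_path / "f.tsv"
        write_features(m, p)
        m2 = read_features(p)
        assert m2.sample_ids == m.sample_ids
        np.testing.assert_allclose(m2.values, m.values, rtol=1e-11)
        # writing the re-read matrix reproduces the file byte-for-byte
        p2 = tmp_path / "f2.tsv"
        write_features(m2, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_column_mismatch_errors(self, tmp_path):
        p = tmp_path / "f.tsv"
        cols = "\t".join(CATALOG.categories[:-1])
        p.write_text(f"sample\t{cols}\n" + "a\t" + "\t".join(["0"] * 27) + "\n")
        with pytest.raises(SegFormatError):
            read_features(p)

    def test_empty_matrix(self, tmp_path):
        m = FeatureMatrix(sample_ids=[], values=np.zeros((0, 28)))
        p = tmp_path / "f.tsv"
        write_features(m, p)
        m2 = read_features(p)
        assert m2.n_samples == 0
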