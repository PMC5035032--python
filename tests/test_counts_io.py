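"""Allele-count table and pileup parsing."""

import collections

import pytest
from hypothesis import given, settings, strategies as st

from fetalfrac.counts import (
    CountsParseError,
    PileupParseError,
    SnpAlleleCount,
    SnpPanel,
    counts_from_pileup,
    decode_pileup_bases,
    read_counts_table,
    write_counts_table,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "chrom\tpos\tmajor\tminor\tx\ty\n"


class TestCountsTable:
    def test_direct_field_mapping(self, tmp_path):
        p = _write(tmp_path, "c.tsv", HEADER + "chr1\t12345\tA\tG\t95\t5\n")
        assert read_counts_table(p) == [SnpAlleleCount("chr1", 12345, "A", "G", 95, 5)]

    def test_swap_normalization(self, tmp_path):
        p = _write(tmp_path, "c.tsv", HEADER + "chr2\t99\tC\tT\t5\t95\n")
        assert read_counts_table(p) == [SnpAlleleCount("chr2", 99, "T", "C", 95, 5)]

    def test_header_only_gives_empty_list(self, tmp_path):
        assert read_counts_table(_write(tmp_path, "c.tsv", HEADER)) == []

    @pytest.mark.parametrize(
        "row",
        [
            "chr1\t10\tA\tG\t9.5\t5",  # non-integer count
            "chr1\t10\tA\tG\t5",  # wrong column count
            "chr1\t10\tA\tG\t-3\t1",  # negative count
        ],
    )
    def test_malformed_row_names_line(self, tmp_path, row):
        p = _write(tmp_path, "c.tsv", HEADER + row + "\n")
        with pytest.raises(CountsParseError, match="line 2"):
            read_counts_table(p)

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            SnpAlleleCount("chr1", 0, "A", "G", 5, 1)  # pos < 1
        with pytest.raises(ValueError):
            SnpAlleleCount("chr1", 1, "A", "A", 5, 1)  # same base with y > 0


records_strategy = st.lists(
    st.builds(
        lambda chrom, pos, bases, x, y: SnpAlleleCount(
            chrom, pos, bases[0], bases[1] if y > 0 else ".", max(x, y), min(x, y)
        ),
        chrom=st.sampled_from(["chr1", "chr2", "chrX"]),
        pos=st.integers(min_value=1, max_value=10**8),
        bases=st.permutations(["A", "C", "G", "T"]),
        x=st.integers(min_value=0, max_value=10**4),
        y=st.integers(min_value=0, max_value=10**4),
    ),
    max_size=50,
)


@settings(max_examples=50, derandomize=True)
@given(records=records_strategy)
def test_counts_table_round_trip(tmp_path_factory, records):
    """Writing then reading arbitrary valid records is the identity."""
    path = tmp_path_factory.mktemp("rt") / "counts.tsv"
    write_counts_table(records, path)
    assert read_counts_table(path) == records


def _pileup_line(chrom, pos, ref, bases, quals):
    return f"{chrom}\t{pos}\t{ref}\t{len(quals)}\t{bases}\t{quals}\n"


@pytest.fixture
def panel():
    # single interval covering positions 1..1000 of chr1 (0-based half-open)
    return SnpPanel([("chr1", 0, 1000)])


class TestPileup:
    def test_all_reference_case(self, tmp_path, panel):
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 10, "A", "....,", "IIIII"))
        assert counts_from_pileup(p, panel) == [SnpAlleleCount("chr1", 10, "A", ".", 5, 0)]

    def test_two_allele_tally(self, tmp_path, panel):
        bases = "." * 90 + "G" * 10
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 5, "A", bases, "I" * 100))
        assert counts_from_pileup(p, panel) == [SnpAlleleCount("chr1", 5, "A", "G", 90, 10)]

    def test_quality_filter_drops_low_quality_minor(self, tmp_path, panel):
        # 90 A at Q30 ('?') and 10 G at Q10 ('+'); threshold Q20 keeps only A
        bases = "A" * 90 + "G" * 10
        quals = "?" * 90 + "+" * 10
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 7, "C", bases, quals))
        (rec,) = counts_from_pileup(p, panel, min_base_quality=20)
        assert (rec.major_base, rec.x, rec.y) == ("A", 90, 0)

    def test_markers_and_indels_are_skipped(self, tmp_path, panel):
        # read start with mapq char, read end, insertion and deletion runs,
        # and a deletion placeholder (consumes a quality but tallies nothing)
        bases = "^I.$,+2ACt-1a*"  # decodes to the calls A, A, T plus a placeholder
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 3, "A", bases, "IIII"))
        (rec,) = counts_from_pileup(p, panel)
        assert (rec.major_base, rec.minor_base, rec.x, rec.y) == ("A", "T", 2, 1)

    def test_position_outside_panel_is_ignored(self, tmp_path, panel):
        p = _write(tmp_path, "p.txt", _pileup_line("chr2", 10, "A", "...", "III"))
        assert counts_from_pileup(p, panel) == []

    def test_length_mismatch_raises(self, tmp_path, panel):
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 2, "A", "....", "II"))
        with pytest.raises(PileupParseError, match="quality"):
            counts_from_pileup(p, panel)

    def test_unknown_symbol_raises(self, tmp_path, panel):
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 2, "A", "..!", "III"))
        with pytest.raises(PileupParseError, match="unknown symbol"):
            counts_from_pileup(p, panel)

    def test_tie_break_is_lexicographic(self, tmp_path, panel):
        p = _write(tmp_path, "p.txt", _pileup_line("chr1", 4, "T", "GGCC", "IIII"))
        (rec,) = counts_from_pileup(p, panel)
        assert (rec.major_base, rec.minor_base) == ("C", "G")


@settings(max_examples=40, derandomize=True)
@given(
    calls=st.lists(
        st.tuples(st.sampled_from("ACGTN"), st.integers(min_value=0, max_value=40)),
        min_size=1,
        max_size=60,
    ),
    data=st.data(),
)
def test_pileup_tally_matches_brute_force_oracle(tmp_path_factory, calls, data):
    """Decoding+tallying at threshold 0 equals a character-by-character count,
    and raising the threshold never increases the surviving depth."""
    ref = "A"
    # assemble a read-bases string with random structural markers interleaved
    parts, quals = [], []
    for base, q in calls:
        token = "." if base == ref else base
        if data.draw(st.booleans()):
            token = "^~" + token  # read start + mapping quality
        if data.draw(st.booleans()):
            token += "$"
        if data.draw(st.booleans()):
            token += "+2AC"  # insertion run, no quality consumed
        parts.append(token)
        quals.append(chr(q + 33))
    path = tmp_path_factory.mktemp("pp") / "p.txt"
    path.write_text(_pileup_line("chr1", 1, ref, "".join(parts), "".join(quals)))
    panel = SnpPanel([("chr1", 0, 10)])

    # oracle: straight-line tally of the ground-truth calls
    oracle = collections.Counter(
        b for (b, q) in calls if b in "ACGT"
    )
    got = counts_from_pileup(path, panel, min_base_quality=0)
    expected_total = sum(oracle.values())
    if expected_total == 0:
        assert got == []
    else:
        top = oracle.most_common()
        top.sort(key=lambda kv: (-kv[1], kv[0]))
        (rec,) = got
        assert rec.x == top[0][1]
        assert rec.x + rec.y <= expected_total
        assert rec.y == (top[1][1] if len(top) > 1 else 0)

    # monotone filtering
    prev = None
    for thr in (0, 10, 20, 30, 41):
        recs = counts_from_pileup(path, panel, min_base_quality=thr)
        total = recs[0].total if recs else 0
        if prev is not None:
            assert total <= prev
        prev = total


class TestPanel:
    def test_bed_intervals_are_merged_and_converted(self, tmp_path):
        bed = _write(tmp_path, "p.bed", "chr1\t10\t20\nchr1\t15\t30\nchr2\t0\t1\n")
        panel = SnpPanel.from_bed(bed)
        assert panel.intervals == [("chr1", 10, 30), ("chr2", 0, 1)]
        assert panel.contains("chr1", 11)  # 0-based 10 == 1-based 11
        assert panel.contains("chr1", 30)
        assert not panel.contains("chr1", 31)
        assert panel.contains("chr2", 1)
        assert not panel.contains("chr3", 1)

    def test_bad_interval_raises(self):
        with pytest.raises(ValueError):
            SnpPanel([("chr1", 5, 5)])


def test_decode_rejects_bare_indel_marker():
    with pytest.raises(PileupParseError):
        decode_pileup_bases(".+A", "A")
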