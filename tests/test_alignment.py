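"""SAM/BAM/CRAM validation, index companionship, and pysam cross-checks."""

import json

import pysam
import pytest

from seqcheck import bgzf
from seqcheck.detect import detect_file_type, locate_companions
from seqcheck.fixtures import FixtureSpec, make_fixture
from seqcheck.validators.alignment import (
    CRAM_EOF,
    check_alignment_index,
    validate_bam,
    validate_cram,
    validate_sam,
)


def _sam(tmp_path, text, name="a.sam"):
    path = tmp_path / name
    path.write_text(text)
    return path


MINIMAL_SAM = (
    "@HD\tVN:1.6\n"
    "@SQ\tSN:chr1\tLN:100\n"
    "r1\t0\tchr1\t10\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
)


class TestSam:
    def test_minimal_valid(self, tmp_path):
        result, info = validate_sam(_sam(tmp_path, MINIMAL_SAM), thorough=True)
        assert result.passed
        assert info.has_hd and info.hd_version == "1.6"
        assert info.reference_sequences == [("chr1", 100)]
        assert info.read_seen

    def test_header_only_fails_no_reads(self, tmp_path):
        result, info = validate_sam(
            _sam(tmp_path, "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100\n"), thorough=True
        )
        assert not result.passed
        assert "no reads" in result.detail
        assert not info.read_seen

    @pytest.mark.parametrize(
        ("mutation", "fragment"),
        [
            (lambda t: t.replace("ACGT\tIIII", "ACGT\tII"), "QUAL"),
            (lambda t: t.replace("@HD\tVN:1.6", "@XX\tVN:1.6"), "unrecognized header"),
            (lambda t: t.replace("@HD\tVN:1.6", "@HD\tSO:coordinate"), "missing VN"),
            (lambda t: t.replace("LN:100", "LN:0"), "LN must be positive"),
            (lambda t: t.replace("LN:100", "LN:abc"), "LN not an integer"),
            (lambda t: t.replace("\tchr1\t10", "\tchrX\t10"), "not declared"),
            (lambda t: t.replace("\t0\tchr1", "\t70000\tchr1"), "FLAG out of range"),
            (lambda t: t.replace("\t60\t4M", "\t300\t4M"), "MAPQ out of range"),
            (lambda t: t.replace("\tIIII\n", "\n"), "fields"),
        ],
    )
    def test_rule_violations(self, tmp_path, mutation, fragment):
        result, _ = validate_sam(_sam(tmp_path, mutation(MINIMAL_SAM)), thorough=True)
        assert not result.passed
        assert fragment in result.detail

    def test_duplicate_sq_rejected(self, tmp_path):
        text = MINIMAL_SAM.replace(
            "@SQ\tSN:chr1\tLN:100\n",
            "@SQ\tSN:chr1\tLN:100\n@SQ\tSN:chr1\tLN:200\n",
        )
        result, _ = validate_sam(_sam(tmp_path, text), thorough=True)
        assert not result.passed
        assert "duplicate @SQ" in result.detail

    def test_header_after_reads_rejected(self, tmp_path):
        text = MINIMAL_SAM + "@SQ\tSN:chr2\tLN:50\n"
        result, _ = validate_sam(_sam(tmp_path, text), thorough=True)
        assert not result.passed
        assert "header line after alignment" in result.detail

    def test_hd_not_first_rejected(self, tmp_path):
        text = "@SQ\tSN:chr1\tLN:100\n@HD\tVN:1.6\nr1\t0\tchr1\t1\t0\t*\t*\t0\t0\t*\t*\n"
        result, _ = validate_sam(_sam(tmp_path, text), thorough=True)
        assert not result.passed
        assert "@HD must be the first line" in result.detail


class TestBam:
    def test_fixture_round_trip(self, forge):
        bam = forge("bam", seed=7, n_records=3)
        result, info = validate_bam(bam, thorough=True)
        assert result.passed
        assert info.read_seen
        assert info.reference_sequences == [("chr1", 1000), ("chr2", 800)]

    def test_bad_magic_rejected_and_matches_pysam(self, forge):
        bam = forge("bam", seed=7, n_records=3, corruption="BAD_MAGIC")
        result, _ = validate_bam(bam, thorough=True)
        assert not result.passed
        assert "bad BAM magic" in result.detail
        with pytest.raises(Exception):
            with pysam.AlignmentFile(str(bam), "rb") as fh:
                list(fh)

    def test_truncation_reports_offset(self, forge, tmp_path):
        good = forge("bam", seed=8, n_records=30)
        payload = bgzf.decompress(good.read_bytes())
        cut = tmp_path / "cut.bam"
        cut.write_bytes(bgzf.compress(payload[:-37]))  # mid-record truncation
        result, _ = validate_bam(cut, thorough=True)
        assert not result.passed
        assert "overruns data at offset" in result.detail

    def test_zero_reads(self, forge):
        bam = forge("bam", seed=9, n_records=5, corruption="ZERO_READS")
        result, info = validate_bam(bam, thorough=True)
        assert not result.passed
        assert "no reads" in result.detail
        assert not info.read_seen

    def test_sam_and_bam_of_same_records_agree(self, forge):
        sam = forge("sam", seed=21, n_records=15)
        bam = forge("bam", seed=21, n_records=15)
        r_sam, i_sam = validate_sam(sam, thorough=True)
        r_bam, i_bam = validate_bam(bam, thorough=True)
        assert r_sam.passed == r_bam.passed is True
        assert i_sam.reference_sequences == i_bam.reference_sequences

    def test_generator_cross_validates_against_pysam(self, forge):
        bam = forge("bam", seed=13, n_records=25)
        with pysam.AlignmentFile(str(bam), "rb") as fh:
            records = list(fh)
        assert len(records) == 25
        assert records[0].query_name == "read0000"


class TestCram:
    def test_fixture_round_trip(self, forge):
        cram = forge("cram", seed=1, n_records=4)
        assert validate_cram(cram).passed

    def test_plain_text_named_cram(self, tmp_path):
        fake = tmp_path / "x.cram"
        fake.write_text("this is not a cram file")
        result = validate_cram(fake)
        assert not result.passed
        assert "bad CRAM magic" in result.detail

    def test_stripped_eof_container(self, forge):
        cram = forge("cram", seed=1, n_records=4, corruption="STRIP_EOF_BLOCK")
        result = validate_cram(cram)
        assert not result.passed
        assert "missing EOF container" in result.detail

    def test_eof_constant_matches_htslib_output(self):
        # Byte-for-byte the container samtools appends to every CRAM v3 file.
        assert len(CRAM_EOF) == 38
        assert CRAM_EOF[8:13] == b"\x0f\xe0\x45\x4f\x46"  # contains "EOF"


class TestIndexCompanionship:
    def test_present_index_with_magic(self, forge):
        bam = forge("bam", seed=2, n_records=3)
        companions = locate_companions(bam, detect_file_type(bam))
        result = check_alignment_index(bam, companions, thorough=True)
        assert result.passed

    def test_missing_index_is_warning_by_default(self, forge):
        bam = forge("bam", seed=2, n_records=3, corruption="DROP_INDEX")
        companions = locate_companions(bam, detect_file_type(bam))
        relaxed = check_alignment_index(bam, companions, strict=False)
        strict = check_alignment_index(bam, companions, strict=True)
        assert not relaxed.passed and relaxed.severity.value == "warning"
        assert not strict.passed and strict.severity.value == "error"
        assert "no index found" in relaxed.detail

    def test_cram_crai_accepted(self, forge):
        cram = forge("cram", seed=3, n_records=3)
        companions = locate_companions(cram, detect_file_type(cram))
        assert [p.suffix for p in companions.index_files] == [".crai"]
        assert check_alignment_index(cram, companions, thorough=True).passed

    def test_bad_bai_magic_detected_thorough(self, tmp_path, forge):
        bam = forge("bam", seed=4, n_records=3)
        bai = bam.with_name(bam.name + ".bai")
        bai.write_bytes(b"JUNK" + bai.read_bytes()[4:])
        companions = locate_companions(bam, detect_file_type(bam))
        assert check_alignment_index(bam, companions, thorough=False).passed
        assert not check_alignment_index(bam, companions, thorough=True).passed
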