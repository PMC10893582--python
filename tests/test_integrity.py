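"""Universal checks: existence ordering, digests, sidecars, compression walk."""

import gzip
import hashlib

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqcheck import bgzf
from seqcheck.detect import detect_file_type, locate_companions
from seqcheck.integrity import (
    SidecarExistsError,
    SidecarParseError,
    check_compression,
    check_existence,
    compute_digest,
    generate_checksum,
    parse_sidecar,
    verify_checksums,
)
from seqcheck.model import CheckId


class TestExistence:
    def test_ordering_and_short_circuit(self, tmp_path):
        good = tmp_path / "ten.bytes"
        good.write_bytes(b"0123456789")
        ids = [c.check_id for c in check_existence(good)]
        assert ids == [CheckId.EXISTS, CheckId.READABLE, CheckId.NONEMPTY]
        assert all(c.passed for c in check_existence(good))

        missing = check_existence(tmp_path / "missing")
        assert len(missing) == 1
        assert missing[0].check_id is CheckId.EXISTS
        assert not missing[0].passed
        assert missing[0].detail  # failure always carries a reason

    def test_empty_file(self, tmp_path):
        empty = tmp_path / "empty"
        empty.write_bytes(b"")
        results = check_existence(empty)
        assert [c.passed for c in results] == [True, True, False]

    def test_broken_symlink_counts_as_nonexistent(self, tmp_path):
        link = tmp_path / "dangling"
        link.symlink_to(tmp_path / "gone")
        results = check_existence(link)
        assert len(results) == 1 and not results[0].passed


class TestDigests:
    # Expected values computed independently with coreutils md5sum.
    def test_known_digests(self, tmp_path):
        empty = tmp_path / "empty"
        empty.write_bytes(b"")
        assert compute_digest(empty, "md5") == "d41d8cd98f00b204e9800998ecf8427e"
        abc = tmp_path / "abc"
        abc.write_bytes(b"abc")
        assert compute_digest(abc, "md5") == "900150983cd24fb0d6963f7d28e17f72"

    def test_digest_matches_hashlib_on_arbitrary_bytes(self, tmp_path):
        payload = bytes(range(256)) * 17
        f = tmp_path / "blob"
        f.write_bytes(payload)
        assert compute_digest(f, "sha512") == hashlib.sha512(payload).hexdigest()

    def test_digest_is_over_compressed_bytes(self, tmp_path):
        gz = tmp_path / "x.gz"
        gz.write_bytes(gzip.compress(b"payload", mtime=0))
        assert compute_digest(gz, "md5") == hashlib.md5(gz.read_bytes()).hexdigest()


class TestSidecars:
    def test_coreutils_dialect(self, tmp_path):
        sc = tmp_path / "a.md5"
        sc.write_text("d41d8cd98f00b204e9800998ecf8427e  empty.txt\n")
        parsed = parse_sidecar(sc, "md5")
        assert parsed.digest_hex == "d41d8cd98f00b204e9800998ecf8427e"
        assert parsed.referenced_name == "empty.txt"

    def test_bare_dialect_lowercased(self, tmp_path):
        sc = tmp_path / "a.md5"
        sc.write_text("D41D8CD98F00B204E9800998ECF8427E\n")
        parsed = parse_sidecar(sc, "md5")
        assert parsed.digest_hex == "d41d8cd98f00b204e9800998ecf8427e"
        assert parsed.referenced_name == ""

    @pytest.mark.parametrize("content", ["zzzz\n", "beef\n", "", "  \n"])
    def test_malformed_sidecars(self, tmp_path, content):
        sc = tmp_path / "a.md5"
        sc.write_text(content)
        with pytest.raises(SidecarParseError):
            parse_sidecar(sc, "md5")

    def test_generate_verify_round_trip(self, tmp_path):
        f = tmp_path / "data.bin"
        f.write_bytes(b"some bytes")
        sidecar = generate_checksum(f, "sha512")
        assert sidecar.name == "data.bin.sha512"
        assert len(sidecar.read_text().split()[0]) == 128
        companions = locate_companions(f, detect_file_type(f))
        results = verify_checksums(f, companions)
        assert all(r.passed for r in results)

    def test_generate_refuses_to_clobber(self, tmp_path):
        f = tmp_path / "data.bin"
        f.write_bytes(b"some bytes")
        generate_checksum(f, "md5")
        with pytest.raises(SidecarExistsError):
            generate_checksum(f, "md5")
        generate_checksum(f, "md5", overwrite=True)  # explicit overwrite allowed

    def test_no_sidecar_is_pass_with_note(self, tmp_path):
        f = tmp_path / "data.bin"
        f.write_bytes(b"x")
        results = verify_checksums(f, locate_companions(f, detect_file_type(f)))
        assert len(results) == 1
        assert results[0].passed
        assert "no checksum" in results[0].detail

    def test_stale_sidecar_names_both_digests(self, tmp_path):
        f = tmp_path / "data.bin"
        f.write_bytes(b"version 1")
        generate_checksum(f, "md5")
        f.write_bytes(b"version 2")
        results = verify_checksums(f, locate_companions(f, detect_file_type(f)))
        assert not results[0].passed
        assert hashlib.md5(b"version 1").hexdigest() in results[0].detail
        assert hashlib.md5(b"version 2").hexdigest() in results[0].detail

    @settings(max_examples=30, derandomize=True)
    @given(data=st.binary(min_size=1, max_size=400), flip=st.integers(min_value=0))
    def test_any_single_byte_flip_fails_verification(self, tmp_path_factory, data, flip):
        tmp = tmp_path_factory.mktemp("flip")
        f = tmp / "blob"
        f.write_bytes(data)
        generate_checksum(f, "md5")
        mutated = bytearray(data)
        mutated[flip % len(data)] ^= 0xFF
        f.write_bytes(bytes(mutated))
        results = verify_checksums(f, locate_companions(f, detect_file_type(f)))
        assert not all(r.passed for r in results)


class TestCompression:
    def test_valid_gzip_thorough(self, tmp_path):
        gz = tmp_path / "x.fastq.gz"
        gz.write_bytes(gzip.compress(b"@r1\nACGT\n+\nIIII\n", mtime=0))
        result = check_compression(gz, detect_file_type(gz), thorough=True)
        assert result.passed

    def test_multi_member_gzip_is_legal(self, tmp_path):
        gz = tmp_path / "x.fastq.gz"
        gz.write_bytes(
            gzip.compress(b"@r1\nACGT\n+\nIIII\n", mtime=0)
            + gzip.compress(b"@r2\nACGT\n+\nIIII\n", mtime=0)
        )
        assert check_compression(gz, detect_file_type(gz), thorough=True).passed

    def test_truncated_gzip_fails_thorough_and_matches_oracle(self, tmp_path):
        import random
        import zlib

        gz = tmp_path / "x.fastq.gz"
        # Incompressible payload keeps the compressed stream well over the cut.
        payload = random.Random(0).randbytes(4000)
        full = gzip.compress(payload, mtime=0)
        gz.write_bytes(full[:-100])
        result = check_compression(gz, detect_file_type(gz), thorough=True)
        assert not result.passed
        assert "truncat" in result.detail or "corrupt" in result.detail
        with pytest.raises((EOFError, OSError, zlib.error)):
            gzip.decompress(gz.read_bytes())  # reference decompressor agrees

    def test_plain_bytes_under_gz_name_fail(self, tmp_path):
        fake = tmp_path / "x.fastq.gz"
        fake.write_bytes(b"@r1\nACGT\n+\nIIII\n")
        result = check_compression(fake, detect_file_type(fake))
        assert not result.passed

    def test_uncompressed_category_passes_with_note(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n")
        result = check_compression(sam, detect_file_type(sam))
        assert result.passed
        assert result.detail == "not compressed"

    def test_bam_missing_eof_marker_fails_quick(self, forge):
        bam = forge("bam", seed=1, n_records=5, corruption="STRIP_EOF_BLOCK")
        result = check_compression(bam, detect_file_type(bam), thorough=False)
        assert not result.passed
        assert "EOF" in result.detail

    def test_bgzf_crc_corruption_reports_offset(self, forge):
        bam = forge("bam", seed=2, n_records=5, corruption="BYTE_FLIP")
        result = check_compression(bam, detect_file_type(bam), thorough=True)
        assert not result.passed
        assert "offset" in result.detail
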