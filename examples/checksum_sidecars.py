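"""Generate checksum sidecars and detect a stale one.

Writes ``<file>.sha512`` in md5sum/sha512sum dialect, verifies it, then
modifies the file to show how verification names both digests — the situation
after a partial re-download or an in-place edit that forgot the sidecar.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from seqcheck import (
    detect_file_type,
    generate_checksum,
    locate_companions,
    verify_checksums,
)

with TemporaryDirectory() as tmp:
    data = Path(tmp) / "cohort_calls.vcf"
    data.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t100\t.\tA\tT\t50\tPASS\t.\n"
    )
    sidecar = generate_checksum(data, algorithm="sha512")
    print("wrote sidecar:", sidecar.name)
    print("sidecar line:", sidecar.read_text().strip()[:32], "...")

    companions = locate_companions(data, detect_file_type(data))
    for result in verify_checksums(data, companions):
        print("fresh file  :", result.check_id.value, "passed" if result.passed else "FAILED")

    data.write_text(data.read_text() + "chr1\t200\t.\tG\tC\t60\tPASS\t.\n")
    for result in verify_checksums(data, companions):
        print("edited file :", result.check_id.value,
              "passed" if result.passed else f"FAILED — {result.detail[:70]}...")
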