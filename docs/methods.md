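# Methods

## Validation model

`seqcheck` treats a file as sound when it passes a fixed pipeline of named
checks: `EXISTS → READABLE → NONEMPTY → COMPRESSION_OK → CHECKSUM_OK →
FORMAT_OK` (plus `INDEX_PRESENT` for indexed container formats).  The stages
are strictly ordered and short-circuiting: a file that fails compression is
never checksummed or parsed, so the first failed check in a report always
names the outermost layer at which the file is broken.  Results are data
(`CheckResult` records with a check id, pass flag, severity and reason), not
log lines; verdicts derive only from error-severity failures.

Two findings are advisory rather than fatal by default, because the file
itself may be perfectly usable: a missing index companion and a header-only
VCF.  Both are reported at warning severity and upgraded to failures by the
`strict` flag.

### Type detection

Detection is purely name-based: the longest registered suffix wins,
case-insensitively (`.fastq/.fq[.gz]`, `.sam`, `.bam`, `.cram`,
`.vcf[.gz]`, `.zip`).  Content-based inference for unknown extensions is
deliberately not attempted — a pipeline gate should never guess a type and
then hold the file to rules its producer never claimed.  Unknown extensions
still get the universal checks, with compression inferred only from a
trailing `.gz`/`.zip`.  The magic-byte sniff (`PLAIN/GZIP/BGZF/ZIP/EMPTY`)
is a separate classification; name/content disagreement surfaces as a failed
`COMPRESSION_OK`, never an exception.

`.vcf.gz` claims plain GZIP rather than BGZF: gzip-compressed (non-blocked)
VCFs are common, and rejecting them at the container level would be a false
positive.  The BGZF-specific rules (BC subfield, 28-byte EOF marker) are
applied whenever BGZF is claimed by the extension (BAM) *or* detected in the
magic bytes.

### Compression integrity

Quick mode checks magic-byte agreement plus, for BGZF, the EOF marker —
the cheap tests that catch the two overwhelmingly common real-world faults
(wrong/renamed file, interrupted copy).  Thorough mode walks the entire
stream: every gzip member is inflated and its CRC32/ISIZE trailer verified
(concatenated multi-member files are legal), and every BGZF block is parsed
from its BC subfield, inflated raw and checked against its own trailer, so a
failure reports the byte offset of the bad block.  The walk is hand-rolled
(18-byte header parse, raw deflate via zlib) because offsets and per-block
attribution are the point; zlib still does the inflation and CRC arithmetic.

### Checksums

Digests are computed over the raw on-disk bytes, never decompressed content,
matching how `md5sum`/`sha512sum` produce sidecars in transfer workflows.
Sidecars are parsed in the coreutils dialect (`<hex><space><space-or-*><name>`)
or as a bare digest, first non-empty line, case-insensitive hex.  A missing
sidecar is a pass-with-note: checksum presence is auto-detected, so absence
must be tolerated.  `generate_checksum` writes the coreutils dialect and
refuses to clobber without `overwrite`; generate-then-verify is a tested
round-trip invariant.

### Format grammars

The FASTQ/SAM/VCF/ZIP grammars and the BAM container walk are implemented
natively in this package (the library readers pysam/zipfile/gzip serve as
independent oracles in the test suite instead).  Rule sets are kept
deliberately standard and are enumerated in the README table.  Notable
boundaries, chosen where the formats' conventions leave room:

- FASTQ: a non-empty `+` line must repeat the header — the strict reading,
  because it catches interleaving/shuffling corruption the lenient one
  misses.  Quality-encoding detection is out of scope.
- SAM/BAM: "contains sequence data" is operationalized as correct magic plus
  at least one decodable read; `n_ref` must equal the `@SQ` count only when
  the text header declares any `@SQ`.  Sort order and auxiliary tags are not
  validated.
- CRAM: container-level only (magic, version major 1–3, the fixed 38-byte v3
  EOF container, byte-compared against the constant htslib writes).  Full
  CRAM codec parsing is out of proportion to an I/O sanity gate.
- VCF: grammar only, no semantic cross-checks; any `VCFv4.x` accepted, other
  versions noted but not failed.
- ZIP: EOCD located within the trailing 65 KiB + 22 bytes; thorough mode
  re-inflates each entry against its central-directory CRC.  ZIP64 passes
  quick detection but thorough walking of ZIP64 is flagged unsupported
  (desk-scale archives never need it); encrypted entries fail thorough.

Quick mode samples the first 4 records of FASTQ/SAM/VCF (and the first 4 BAM
records) in addition to whole-file structural counts; thorough validates
every record.  The 4-record window is a fixed design choice, small enough to
stay I/O-bound on headers, large enough to catch systematic per-record
damage.

### Orchestration

Multi-file validation is embarrassingly parallel at per-file granularity via
a thread pool (the work is dominated by I/O, zlib and hashing, which release
the GIL).  Reports are collected in input order, so a run with any thread
count is field-for-field identical to a serial run — a tested invariant.
Within-file parallel validation (e.g. index-guided block sharding) is out of
scope.  Exit codes follow the workflow-engine convention: 0 all pass, 1 any
fail, 2 usage/internal error.

Thorough BAM validation reads the decompressed stream into memory; the tool
targets pipeline gating of desk-scale fixtures up to multi-GB production
files, and for the latter the quick mode is the intended default.

## Synthetic data

`seqcheck.fixtures` generates every test input programmatically: seeded
random records (IUPAC sequences of 30–60 bp, qualities in the Illumina
printable range, VCF sites with 0–3 samples, stored-entry ZIP archives),
written bit-deterministically (fixed deflate level, zeroed gzip mtime, fixed
ZIP timestamps) so a spec reproduces a byte-identical file.  BAM fixtures are
produced by encoding the generator's own SAM records into the binary layout
and BGZF blocks — the test suite cross-validates this encoder by having
pysam iterate the result and samtools quickcheck accept it.  Content realism
(read simulators, reference-aware records) is a non-goal; structural
validity is the contract.

Corruption operators inject exactly one named defect each, and a fixed
operator → check-id table declares which check must catch it.  Sidecars are
recomputed after corruption so the targeted check, not `CHECKSUM_OK`, is the
one that fires; `STALE_CHECKSUM` inverts this by regenerating valid content
after the sidecar is written.  Applicability is format-checked, with a few
deliberate exclusions where the outcome would be non-deterministic:
tail-truncation of a *plain* FASTQ can land on a record boundary, zero
records in FASTQ means an empty file (caught by `NONEMPTY` instead), and a
header-only VCF passes by default.  Byte flips are placed inside compressed
payload regions, since a flip in an ignored gzip header byte (MTIME) would
be silent by design.

What passing the fixture matrix does **not** show: behaviour on real-world
oddities the generator does not emulate — multi-line FASTA-style wrapped
records, exotic SAM tags, ZIP64 archives, CRAM codec-level damage, or files
larger than memory.  The oracle-equivalence tests (gzip module, pysam,
zipfile over mixed valid/corrupt sets) are the bridge from the synthetic
corpus to independently implemented readers.

Two scoping notes on those comparisons: BGZF files with a stripped EOF
marker are excluded from the plain-gzip comparison (the marker is a BGZF
convention; a gzip decompressor rightly accepts the stream), and zero-read
BAMs are excluded from the pysam-iteration comparison (iterating zero
records succeeds; the ≥1-read requirement is a policy check, not a walking
failure).

## Problem sizes

Defaults throughout the tests and the acceptance script: 10-record fixtures,
5 seeds per matrix cell (~260 files), ~50 fixtures per oracle comparison,
a 40-file set for parallel determinism, 100 byte-flip trials.  These sizes
were chosen to exercise every code path — multi-record streams, multi-block
containers, mixed verdict sets — while keeping the whole suite near-instant;
the properties measured are size-invariant (per-record grammar, per-block
CRC), and individual tests go up to 500 records where counting conservation
is the point.
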