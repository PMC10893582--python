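# seqcheck

Validation of bioinformatics pipeline files: existence, compression
integrity, checksum sidecars, and format grammars for FASTQ, SAM, BAM, CRAM,
VCF and ZIP — as a Python library and a thin `seqcheck` command.

## The problem

Sequencing workflows chain dozens of tools over large compressed files.  A
truncated BGZF stream, a half-copied FASTQ or a stale `.md5` sidecar rarely
fails loudly at the point of damage; it fails hours later, deep inside an
aligner or variant caller, wasting compute and sometimes corrupting results
silently.  Workflow engines (Nextflow, Snakemake) do not validate files
intrinsically.  `seqcheck` is the one-line gate you put between steps: it
verifies every input or output file and exits nonzero on the first unsound
one.

Every file gets three universal checks, in order:

1. **existence** — the path exists, is readable, and is non-empty;
2. **compression** — the magic bytes match what the extension claims; with
   `--thorough`, every gzip member / BGZF block is inflated and its CRC32 and
   ISIZE trailer verified (BGZF files must also end with the 28-byte EOF
   marker block);
3. **checksums** — any `<file>.md5` / `<file>.sha512` sidecar (coreutils
   dialect) is recomputed over the raw on-disk bytes and compared.

A failure at any stage suppresses the later stages.  Files that survive are
dispatched through an extensible registry to a format validator:

| format | checks |
|---|---|
| FASTQ | 4-line record grammar: `@` header, IUPAC sequence, `+` separator (must repeat the header when non-empty), quality length = sequence length, ASCII 33–126 |
| SAM | header record types, `@HD`/`@SQ` rules, ≥11 fields per read with FLAG/POS/MAPQ ranges, SEQ/QUAL length, RNAME declared, ≥1 read |
| BAM | BGZF container, `BAM\x01` magic, text header + reference directory consistency, ≥1 decodable record; thorough walks every record to the exact end of stream |
| CRAM | `CRAM` magic, plausible version, the fixed 38-byte v3 EOF container |
| VCF | `##fileformat` first, meta-line shape, one `#CHROM` line, per-record field syntax (POS, REF, ALT dialects, QUAL, INFO, FORMAT/sample arity) |
| ZIP | end-of-central-directory located and consistent; thorough re-inflates every entry and compares CRC32 |

Indexed containers (BAM, CRAM, compressed VCF) also get an index-companion
check (`.bai`/`.csi`/`.crai`/`.tbi`), a warning by default and a failure with
`--strict`.  Unknown extensions still receive the three universal checks.

## Worked example

```sh
$ seqcheck validate --thorough reads.fastq aligned.bam interrupted.bam calls.vcf
PASS    reads.fastq     fastq
PASS    aligned.bam     bam
FAIL    interrupted.bam COMPRESSION_OK: missing BGZF EOF marker
FAIL    calls.vcf       FORMAT_OK: POS not a positive integer: '675x' at line 7
passed 2 of 4
```

(Output produced by `python examples/validate_files.py`, which builds these
four files synthetically.)  Each line is the verdict, the path, and either
the detected format or the first failed check with its reason — here a BAM
whose transfer was interrupted before the BGZF EOF block was written, and a
VCF with a corrupt position field on line 7.  The exit code is 0 only when
every file passes (1 = failures, 2 = usage error), so the command can gate a
workflow step directly.

Checksum sidecars:

```sh
seqcheck generate-checksum aligned.bam --type sha512   # writes aligned.bam.sha512
seqcheck validate aligned.bam                          # now also verifies it
```

The same operations are available as a library (`validate_paths`,
`validate_file`, `generate_checksum`, `verify_checksums`, …); the
`examples/` scripts show batch validation, sidecar handling and how to plug
in a new format with two registry calls.

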