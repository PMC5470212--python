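"""Readers and writers for the plain-text formats the toolkit touches.

FASTA, 4-line FASTQ, SAM text, GTF attribute extraction, two-column
transcript->gene maps, Kallisto ``abundance.tsv`` tables and Newick trees.
Parsing here is deliberately strict and bit-faithful: no science happens in
this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "AbundanceRow",
    "SampleMeta",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_abundance",
    "read_transcript_gene_map",
    "extract_unmapped_ids",
    "downsample_fastq",
    "write_newick",
    "read_newick",
]


@dataclass
class SequenceRecord:
    """One FASTA record. ``id`` is the first whitespace-delimited header token."""

    id: str
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")


@dataclass
class AbundanceRow:
    """One line of a Kallisto-dialect abundance table."""

    target_id: str
    length: int
    eff_length: float
    est_counts: float
    tpm: float


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: library type, condition and replicate labels."""

    sample_id: str
    library_type: str  # "polyA" or "ribominus"
    condition: str = "0h"
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.library_type not in ("polyA", "ribominus"):
            raise ValueError(
                f"library_type must be 'polyA' or 'ribominus', got {self.library_type!r}"
            )


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, uppercasing sequence characters.

    Records keep file order; multi-line sequences are concatenated.  Sequence
    data before the first ``>`` header is a parse error naming the line.
    """
    records: list[SequenceRecord] = []
    current: SequenceRecord | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if current is not None:
                    current.sequence = "".join(chunks)
                    records.append(current)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                current = SequenceRecord(
                    id=parts[0], description=parts[1] if len(parts) > 1 else ""
                )
                chunks = []
            else:
                if current is None:
                    raise FastaParseError(
                        f"sequence data before first FASTA header at line {lineno}"
                    )
                chunks.append(line.strip().upper())
    if current is not None:
        current.sequence = "".join(chunks)
        records.append(current)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, max(len(seq), 1), width):
                chunk = seq[i : i + width]
                fh.write(chunk + "\n")


_ABUNDANCE_COLUMNS = ["target_id", "length", "eff_length", "est_counts", "tpm"]


def read_abundance(path: str | Path) -> list[AbundanceRow]:
    """Read a Kallisto-style ``abundance.tsv``.

    The header must be exactly ``target_id length eff_length est_counts tpm``
    (tab-separated); negative TPM values and duplicate target ids are
    validation errors.
    """
    rows: list[AbundanceRow] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ABUNDANCE_COLUMNS:
            raise ValueError(
                f"{path}: expected abundance header {_ABUNDANCE_COLUMNS}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            target_id = fields[0]
            if target_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate target_id {target_id!r}")
            seen.add(target_id)
            row = AbundanceRow(
                target_id=target_id,
                length=int(float(fields[1])),
                eff_length=float(fields[2]),
                est_counts=float(fields[3]),
                tpm=float(fields[4]),
            )
            if row.tpm < 0:
                raise ValueError(f"{path}:{lineno}: negative tpm for {target_id!r}")
            if row.length < 0 or row.eff_length < 0 or row.est_counts < 0:
                raise ValueError(f"{path}:{lineno}: negative field for {target_id!r}")
            rows.append(row)
    return rows


def write_abundance(rows: Iterable[AbundanceRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ABUNDANCE_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.target_id}\t{r.length}\t{r.eff_length:g}\t{r.est_counts:g}\t{r.tpm:g}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcript_gene_map(path: str | Path, format: str = "tsv") -> dict[str, str]:
    """Read a transcript->gene map from a 2-column TSV or a GTF.

    Duplicate transcript rows mapping to conflicting genes are an error; a
    transcript may appear many times (GTF exon lines) as long as the gene
    agrees.
    """
    mapping: dict[str, str] = {}

    def _add(tid: str, gid: str, lineno: int) -> None:
        prev = mapping.get(tid)
        if prev is not None and prev != gid:
            raise ValueError(
                f"{path}:{lineno}: transcript {tid!r} maps to both {prev!r} and {gid!r}"
            )
        mapping[tid] = gid

    with open(path) as fh:
        if format == "tsv":
            for lineno, raw in enumerate(fh, start=1):
                if not raw.strip() or raw.startswith("#"):
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                _add(fields[0], fields[1], lineno)
        elif format == "gtf":
            for lineno, raw in enumerate(fh, start=1):
                if not raw.strip() or raw.startswith("#"):
                    continue
                fields = raw.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
                tid, gid = attrs.get("transcript_id"), attrs.get("gene_id")
                if tid and gid:
                    _add(tid, gid, lineno)
        else:
            raise ValueError(f"unknown map format {format!r}")
    return mapping


def extract_unmapped_ids(sam_path: str | Path) -> set[str]:
    """Return QNAMEs of SAM records whose FLAG has the unmapped bit (0x4) set.

    Mirrors ``samtools view -f 4``; header lines (``@``) are skipped.
    """
    ids: set[str] = set()
    with open(sam_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("@"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{sam_path}:{lineno}: fewer than 11 SAM fields")
            try:
                flag = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{sam_path}:{lineno}: non-integer FLAG {fields[1]!r}") from exc
            if flag & 0x4:
                ids.add(fields[0])
    return ids


_MATE_SUFFIX_RE = re.compile(r"/[12]$")


def _strip_mate_suffix(read_id: str) -> str:
    # "@name/1" and "@name 1:N:0:..." dialects both reduce to "name"
    core = read_id[1:].split()[0] if read_id.startswith("@") else read_id.split()[0]
    return _MATE_SUFFIX_RE.sub("", core)


def _read_fastq_records(path: str | Path) -> list[tuple[str, str, str, str]]:
    records = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: FASTQ line count {len(lines)} is not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ValueError(f"{path}: line {i + 1}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {i + 3}: FASTQ separator must start with '+'")
        records.append((head, seq, plus, qual))
    return records


def sample_indices(total: int, n: int, seed: int) -> np.ndarray:
    """Uniform sample of ``n`` ordinals from ``range(total)`` without replacement."""
    if n > total:
        raise ValueError(f"cannot sample {n} reads from {total}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n, replace=False)
    idx.sort()
    return idx


def downsample_fastq(
    in_paths: Sequence[str | Path],
    out_paths: Sequence[str | Path],
    n: int,
    seed: int,
) -> int:
    """Randomly downsample single or paired FASTQ files to exactly ``n`` reads.

    Selection is uniform without replacement over read ordinals; the same
    seed reproduces the same output bytes, and paired mode picks identical
    indices from both mates (which must be synchronised by read id after
    stripping ``/1``/``/2`` or space-delimited tails).
    """
    if len(in_paths) not in (1, 2) or len(in_paths) != len(out_paths):
        raise ValueError("expected 1 or 2 input FASTQs with matching outputs")
    files = [_read_fastq_records(p) for p in in_paths]
    if len(files) == 2:
        if len(files[0]) != len(files[1]):
            raise ValueError("paired FASTQ files have different read counts")
        for (h1, *_), (h2, *_) in zip(files[0], files[1]):
            if _strip_mate_suffix(h1) != _strip_mate_suffix(h2):
                raise ValueError(f"desynchronized mates: {h1!r} vs {h2!r}")
    idx = sample_indices(len(files[0]), n, seed)
    for recs, out in zip(files, out_paths):
        with open(out, "w") as fh:
            for i in idx:
                fh.write("\n".join(recs[i]) + "\n")
    return len(idx)


def write_newick(tree) -> str:
    """Serialise a scikit-bio ``TreeNode`` to a Newick string with branch lengths."""
    import io as _io

    import skbio

    for tip in tree.tips():
        if not tip.name:
            raise ValueError("unlabelled leaf in tree")
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str):
    """Parse a Newick string into a scikit-bio ``TreeNode``."""
    import io as _io

    import skbio

    return skbio.TreeNode.read(_io.StringIO(newick), format="newick")
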