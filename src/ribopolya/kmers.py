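"""k-mer uniqueness of a reference transcript set.

A pseudoalignment quantifier resolves reads by exact k-mer matches against a
transcript index (k = 31 by default), so the fraction of k-mers unique to a
single transcript bounds how unambiguously reads can be assigned.  Gene
families with near-identical members share most of their k-mers, which is the
rationale for filtering a reference before quantification: removing
transcripts can only increase the uniqueness of what remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_K = 31

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

__all__ = ["DEFAULT_K", "KmerStats", "TranscriptKmerStats", "kmer_set", "index_uniqueness"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_set(sequence: str, k: int = DEFAULT_K, canonical: bool = True) -> set[str]:
    """Distinct k-mers of a sequence; windows containing non-ACGT bases are skipped.

    In canonical mode each k-mer is collapsed with its reverse complement
    (lexicographic minimum), matching double-stranded read mapping.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequence = sequence.upper()
    out: set[str] = set()
    skipped = 0
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if not _VALID.issuperset(window):
            skipped += 1
            continue
        if canonical:
            rc = reverse_complement(window)
            out.add(min(window, rc))
        else:
            out.add(window)
    if skipped:
        logger.debug("skipped %d windows with non-ACGT characters", skipped)
    return out


class TranscriptKmerStats(NamedTuple):
    total_kmers: int      # windows counted with multiplicity (clean windows only)
    distinct_kmers: int
    unique_kmers: int     # distinct k-mers found in no other transcript

    @property
    def unique_fraction(self) -> float:
        return self.unique_kmers / self.distinct_kmers if self.distinct_kmers else 0.0


@dataclass
class KmerStats:
    """Index-level uniqueness summary for a transcript set."""

    k: int
    per_transcript: dict[str, TranscriptKmerStats]
    index_distinct: int
    index_unique: int

    @property
    def index_unique_fraction(self) -> float:
        return self.index_unique / self.index_distinct if self.index_distinct else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\ttotal_kmers\tdistinct_kmers\tunique_kmers\tunique_fraction\n")
            for tid, s in self.per_transcript.items():
                fh.write(f"{tid}\t{s.total_kmers}\t{s.distinct_kmers}\t{s.unique_kmers}"
                         f"\t{s.unique_fraction:.6g}\n")
            fh.write(f"#index\tk={self.k}\tdistinct={self.index_distinct}"
                     f"\tunique={self.index_unique}"
                     f"\tunique_fraction={self.index_unique_fraction:.6g}\n")


def index_uniqueness(
    transcripts: Sequence[SequenceRecord],
    k: int = DEFAULT_K,
    canonical: bool = True,
    group_by: dict[str, str] | None = None,
) -> KmerStats:
    """Count, per transcript, how many of its k-mers occur in no other transcript.

    A k-mer is *unique* iff exactly one transcript contains it; a transcript's
    internal repeats count as a single occurrence source.  ``group_by`` maps
    transcript id -> group id (e.g. gene) to measure uniqueness at gene
    granularity instead, for paralogue analyses.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    per_sets: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for rec in transcripts:
        if rec.id in per_sets:
            raise ValueError(f"duplicate transcript id {rec.id!r}")
        seq = rec.sequence.upper()
        clean_windows = sum(
            1 for i in range(len(seq) - k + 1) if _VALID.issuperset(seq[i : i + k])
        )
        per_sets[rec.id] = kmer_set(seq, k=k, canonical=canonical)
        totals[rec.id] = clean_windows

    # number of distinct source groups (transcripts, or genes) per k-mer
    occurrences: dict[str, int] = {}
    seen_groups: dict[str, set[str]] = {}
    for tid, kmers in per_sets.items():
        group = group_by.get(tid, tid) if group_by else tid
        for km in kmers:
            grp = seen_groups.setdefault(km, set())
            if group not in grp:
                grp.add(group)
    occurrences = {km: len(grps) for km, grps in seen_groups.items()}

    per_transcript = {
        tid: TranscriptKmerStats(
            total_kmers=totals[tid],
            distinct_kmers=len(kmers),
            unique_kmers=sum(1 for km in kmers if occurrences[km] == 1),
        )
        for tid, kmers in per_sets.items()
    }
    index_unique = sum(1 for c in occurrences.values() if c == 1)
    return KmerStats(
        k=k,
        per_transcript=per_transcript,
        index_distinct=len(occurrences),
        index_unique=index_unique,
    )
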