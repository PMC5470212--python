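"""Reference-transcriptome filtering and evidence gates for novel transcripts.

A revised reference transcript set is built by (a) dropping transcripts with
zero expression in every sample, (b) restricting by biotype and transcript
support level (TSL), and (c) admitting de-novo-assembled candidate
transcripts only when external evidence supports a real protein-coding
product: a sufficiently long ORF, a Pfam domain hit, a credible Swiss-Prot
homologue confirmed by a global alignment, and a coding-potential score
above a cutoff.  The assembler, HMMER, BLAST and the coding-potential model
run outside this package; their tabular outputs are consumed here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .expression import ExpressionMatrix
from .io_formats import SequenceRecord
from .kmers import reverse_complement

__all__ = [
    "TranscriptRecord",
    "BlastHit",
    "NovelTranscriptEvidence",
    "FilterReport",
    "GateThresholds",
    "drop_unexpressed",
    "filter_by_biotype",
    "filter_by_tsl",
    "longest_orf",
    "best_protein_hit",
    "global_identity",
    "accept_novel_transcript",
    "assign_symbol",
    "load_evidence_tables",
]

# biotypes of the non-protein-coding transcript classes commonly added
# alongside the protein-coding cDNA set
RNA_GENE_BIOTYPES = frozenset(
    {"lincRNA", "miRNA", "misc_RNA", "Mt_rRNA", "Mt_tRNA", "rRNA", "snoRNA", "snRNA"}
)


@dataclass
class TranscriptRecord:
    id: str
    gene_id: str
    biotype: str
    tsl: int | None = None  # 1..5; absent for single-exon transcripts
    n_exons: int = 1
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.biotype:
            raise ValueError("biotype must be non-empty")
        if self.tsl is not None and not 1 <= self.tsl <= 5:
            raise ValueError(f"tsl must be 1..5, got {self.tsl}")


@dataclass(frozen=True)
class BlastHit:
    subject_acc: str
    subject_symbol: str
    percent_identity: float
    alignment_length: int
    evalue: float
    subject_pe_code: int
    subject_is_fragment: bool


@dataclass
class NovelTranscriptEvidence:
    candidate_id: str
    orf_length_aa: int | None = None
    best_pfam_evalue: float | None = None
    blast_hits: list[BlastHit] = field(default_factory=list)
    needle_identity: float | None = None
    cpat_coding_prob: float | None = None


@dataclass
class FilterReport:
    candidate_id: str
    accepted: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        if self.accepted != (not self.reasons):
            raise ValueError("accepted must mirror empty reasons")


@dataclass
class GateThresholds:
    """Evidence gate cutoffs for admitting a novel transcript.

    Defaults: ORF >= 100 aa; Pfam E-value <= 1e-5; BLAST E-value <= 1e-25
    with identity >= 50%; global-alignment identity >= 50%; coding
    probability >= 0.364 (the human-model cutoff; configurable since other
    assemblies carry their own calibrated cutoff).
    """

    min_orf_aa: int = 100
    max_pfam_evalue: float = 1e-5
    max_blast_evalue: float = 1e-25
    min_identity: float = 50.0
    min_needle_identity: float = 50.0
    min_coding_prob: float = 0.364


# ---------------------------------------------------------------------------
# expression- and annotation-based filters


def drop_unexpressed(matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Split features into (retained, dropped): dropped iff TPM is 0 in every sample."""
    if matrix.values.empty:
        raise ValueError("empty expression matrix")
    expressed = (matrix.values > 0).any(axis=1)
    retained = list(matrix.values.index[expressed])
    dropped = list(matrix.values.index[~expressed])
    return retained, dropped


def filter_by_biotype(
    records: Sequence[TranscriptRecord], allowed: Iterable[str]
) -> list[TranscriptRecord]:
    """Order-preserving subset of records whose biotype is in ``allowed``."""
    allowed = set(allowed)
    return [r for r in records if r.biotype in allowed]


def filter_by_tsl(
    records: Sequence[TranscriptRecord],
    max_level: int = 3,
    require_multiexonic: bool = True,
) -> list[TranscriptRecord]:
    """Keep transcripts with TSL present and <= ``max_level``.

    Transcripts without a TSL (single-exon models are never scored) are
    dropped; ``require_multiexonic`` additionally demands >= 2 exons.
    """
    out = []
    for r in records:
        if r.tsl is None or r.tsl > max_level:
            continue
        if require_multiexonic and r.n_exons < 2:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# ORF finding

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Orf:
    aa_length: int  # excludes the stop codon
    frame: int      # 0..2 on the reported strand
    start: int      # 0-based half-open on the input sequence, stop codon included
    end: int
    strand: str = "+"


def _scan_forward(seq: str, k_frames: int = 3):
    """Yield (aa_len, frame, start, end) for every maximal ATG..stop ORF."""
    n = len(seq)
    for frame in range(k_frames):
        earliest_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if not _BASES.issuperset(codon):
                # codons containing N (or other ambiguity) cannot extend an ORF
                earliest_start = None
                continue
            if codon in _STOPS:
                if earliest_start is not None:
                    aa_len = (pos - earliest_start) // 3
                    yield aa_len, frame, earliest_start, pos + 3
                    earliest_start = None
            elif codon == "ATG" and earliest_start is None:
                earliest_start = pos


def longest_orf(sequence: str, strand_specific: bool = True) -> Orf | None:
    """Longest ATG-initiated, stop-terminated open reading frame.

    Scans the three forward frames (six when ``strand_specific`` is False,
    as for unstranded assemblies); ``aa_length`` excludes the stop codon and
    coordinates are 0-based half-open on the input.  Ties prefer the forward
    strand, then the lower frame, then the smaller start.  Returns ``None``
    when no complete ORF exists.
    """
    seq = sequence.upper()
    candidates: list[Orf] = [
        Orf(aa, fr, s, e, "+") for aa, fr, s, e in _scan_forward(seq)
    ]
    if not strand_specific:
        rc = reverse_complement(seq)  # non-ACGT characters pass through
        L = len(seq)
        for aa, fr, s, e in _scan_forward(rc):
            candidates.append(Orf(aa, fr, L - e, L - s, "-"))
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda o: (o.aa_length, o.strand == "+", -o.frame, -o.start),
    )


# ---------------------------------------------------------------------------
# homology gates


def best_protein_hit(
    hits: Sequence[BlastHit],
    min_identity: float = 50.0,
    max_evalue: float = 1e-25,
) -> BlastHit | None:
    """Best Swiss-Prot hit for a candidate CDS.

    Protein fragments and subjects whose protein-existence (PE) code is not
    1 or 2 are excluded first, then hits with E-value above ``max_evalue``
    or identity below ``min_identity``.  Among survivors the hit with the
    longest alignment wins; ties break to the higher identity, then the
    lexicographically smallest accession.
    """
    survivors = [
        h
        for h in hits
        if not h.subject_is_fragment
        and h.subject_pe_code in (1, 2)
        and h.evalue <= max_evalue
        and h.percent_identity >= min_identity
    ]
    if not survivors:
        return None
    return min(
        survivors,
        key=lambda h: (-h.alignment_length, -h.percent_identity, h.subject_acc),
    )


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _needle_aligner(gap_open: float, gap_extend: float, matrix_name: str):
    from Bio import Align
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(matrix_name)
    if "X" in m.alphabet:
        # ambiguous residues score 0 against everything
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    # first gapped column costs gap_open, each further column gap_extend;
    # end gaps are penalised like internal ones (full-length alignment)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_identity(
    query_aa: str,
    subject_aa: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
    max_cooptimal: int = 1000,
) -> float:
    """Percent identity of an affine-gap global (Needleman-Wunsch) alignment.

    Identity = 100 x exact matches / alignment columns, gaps included in the
    denominator.  When several alignments share the optimal score, the
    highest identity among them (up to ``max_cooptimal`` enumerated) is
    reported.  ``X`` scores 0 against every residue.
    """
    if not query_aa or not subject_aa:
        raise ValueError("empty peptide sequence")
    q, s = query_aa.upper(), subject_aa.upper()
    for pep in (q, s):
        bad = set(pep) - set(_AA20 + "X")
        if bad:
            raise ValueError(f"invalid amino acids: {sorted(bad)}")
    aligner = _needle_aligner(gap_open, gap_extend, matrix)
    best = 0.0
    for i, aln in enumerate(aligner.align(q, s)):
        a, b = str(aln[0]), str(aln[1])
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        best = max(best, 100.0 * matches / len(a))
        if i + 1 >= max_cooptimal:
            break
    return best


def global_alignment_score(
    query_aa: str,
    subject_aa: str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    matrix: str = "BLOSUM62",
) -> float:
    """Optimal affine-gap global alignment score under the needle-style scheme."""
    if not query_aa or not subject_aa:
        raise ValueError("empty peptide sequence")
    aligner = _needle_aligner(gap_open, gap_extend, matrix)
    return float(aligner.score(query_aa.upper(), subject_aa.upper()))


# ---------------------------------------------------------------------------
# the novel-transcript acceptance gate


def accept_novel_transcript(
    evidence: NovelTranscriptEvidence,
    thresholds: GateThresholds | None = None,
) -> FilterReport:
    """Apply the evidence gates to one de-novo-assembled candidate.

    All gates must pass; ``reasons`` enumerates every failed gate.  An absent
    evidence field fails its gate (conservative: an unannotatable candidate
    is not admitted).
    """
    t = thresholds or GateThresholds()
    reasons: list[str] = []

    if evidence.orf_length_aa is None or evidence.orf_length_aa < t.min_orf_aa:
        reasons.append("ORF_SHORT")
    if evidence.best_pfam_evalue is None or evidence.best_pfam_evalue > t.max_pfam_evalue:
        reasons.append("NO_PFAM")

    clean = [
        h
        for h in evidence.blast_hits
        if not h.subject_is_fragment
        and h.subject_pe_code in (1, 2)
        and h.evalue <= t.max_blast_evalue
    ]
    if not clean:
        reasons.append("NO_BLAST_HIT")
    elif best_protein_hit(clean, min_identity=t.min_identity,
                          max_evalue=t.max_blast_evalue) is None:
        reasons.append("LOW_IDENTITY_BLAST")

    if evidence.needle_identity is None or evidence.needle_identity < t.min_needle_identity:
        reasons.append("LOW_IDENTITY_NEEDLE")
    if evidence.cpat_coding_prob is None or evidence.cpat_coding_prob < t.min_coding_prob:
        reasons.append("LOW_CODING_PROB")

    return FilterReport(evidence.candidate_id, accepted=not reasons, reasons=reasons)


def assign_symbol(
    best_hit_symbol: str | None,
    known_symbols: set[str],
    candidate_id: str,
) -> str:
    """Gene symbol for an accepted novel transcript.

    The best-hit symbol is used unless it (or one of its synonyms — the
    caller pre-expands ``known_symbols`` with synonyms) already names a gene
    in the reference annotation, in which case a deterministic
    ``NOVEL_<id>`` placeholder is returned instead of creating a clash.
    """
    if not best_hit_symbol or best_hit_symbol in known_symbols:
        return f"NOVEL_{candidate_id}"
    return best_hit_symbol


# ---------------------------------------------------------------------------
# evidence-table I/O (documented TSV schemas)


def _read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_evidence_tables(
    pfam: str | Path | None = None,
    blast: str | Path | None = None,
    needle: str | Path | None = None,
    cpat: str | Path | None = None,
    orf: str | Path | None = None,
) -> dict[str, NovelTranscriptEvidence]:
    """Assemble per-candidate evidence from precomputed tool outputs.

    Schemas (tab-separated, with header):
      orf:    candidate_id, orf_length_aa
      pfam:   candidate_id, evalue            (best per candidate kept)
      blast:  qseqid, sseqid, symbol, pident, length, evalue, pe_code, is_fragment
      needle: candidate_id, identity
      cpat:   candidate_id, coding_prob
    """
    ev: dict[str, NovelTranscriptEvidence] = {}

    def get(cid: str) -> NovelTranscriptEvidence:
        return ev.setdefault(cid, NovelTranscriptEvidence(candidate_id=cid))

    if orf:
        for row in _read_tsv(orf):
            get(row["candidate_id"]).orf_length_aa = int(row["orf_length_aa"])
    if pfam:
        for row in _read_tsv(pfam):
            e = float(row["evalue"])
            cur = get(row["candidate_id"])
            if cur.best_pfam_evalue is None or e < cur.best_pfam_evalue:
                cur.best_pfam_evalue = e
    if blast:
        for row in _read_tsv(blast):
            get(row["qseqid"]).blast_hits.append(
                BlastHit(
                    subject_acc=row["sseqid"],
                    subject_symbol=row.get("symbol", ""),
                    percent_identity=float(row["pident"]),
                    alignment_length=int(row["length"]),
                    evalue=float(row["evalue"]),
                    subject_pe_code=int(row["pe_code"]),
                    subject_is_fragment=row["is_fragment"].strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    if needle:
        for row in _read_tsv(needle):
            get(row["candidate_id"]).needle_identity = float(row["identity"])
    if cpat:
        for row in _read_tsv(cpat):
            get(row["candidate_id"]).cpat_coding_prob = float(row["coding_prob"])
    return ev


def load_annotation(path: str | Path) -> dict[str, dict]:
    """Read a gene annotation TSV: gene_id, symbol, synonyms (pipe-separated),
    biotype, tsl (empty allowed), n_exons."""
    out: dict[str, dict] = {}
    for row in _read_tsv(path):
        tsl = row.get("tsl", "").strip()
        out[row["gene_id"]] = {
            "symbol": row.get("symbol", ""),
            "synonyms": [s for s in row.get("synonyms", "").split("|") if s],
            "biotype": row.get("biotype", "protein_coding"),
            "tsl": int(tsl) if tsl else None,
            "n_exons": int(row.get("n_exons", 1) or 1),
        }
    return out


def known_symbol_set(annotation: dict[str, dict]) -> set[str]:
    """All symbols plus synonyms present in an annotation table."""
    symbols: set[str] = set()
    for info in annotation.values():
        if info["symbol"]:
            symbols.add(info["symbol"])
        symbols.update(info["synonyms"])
    return symbols
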