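"""Shared builders for novel-transcript evidence fixtures."""

from ribopolya.reference import BlastHit, NovelTranscriptEvidence


def hit(acc="P1", identity=60.0, length=100, evalue=1e-30, pe=1, fragment=False,
        symbol="SYM"):
    return BlastHit(acc, symbol, identity, length, evalue, pe, fragment)


def passing_evidence(cid="c1", **overrides):
    ev = NovelTranscriptEvidence(
        candidate_id=cid,
        orf_length_aa=150,
        best_pfam_evalue=1e-7,
        blast_hits=[hit()],
        needle_identity=72.0,
        cpat_coding_prob=0.9,
    )
    for key, val in overrides.items():
        setattr(ev, key, val)
    return ev
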