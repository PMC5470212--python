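"""Gate de-novo-assembled candidate transcripts through the evidence filters.

A candidate joins the revised reference only if its ORF is >= 100 aa, a Pfam
domain hit reaches E <= 1e-5, a clean Swiss-Prot homologue exists (E <=
1e-25, identity >= 50%, PE code 1/2, not a fragment), the global alignment
to that homologue reaches 50% identity, and the coding probability is >=
0.364.
"""

from ribopolya import NovelTranscriptEvidence, accept_novel_transcript, assign_symbol
from ribopolya.reference import BlastHit

hit = BlastHit("Q12345", "IRG1", percent_identity=63.0, alignment_length=210,
               evalue=1e-60, subject_pe_code=1, subject_is_fragment=False)

candidates = [
    NovelTranscriptEvidence("asm_001", orf_length_aa=180, best_pfam_evalue=3e-12,
                            blast_hits=[hit], needle_identity=61.0,
                            cpat_coding_prob=0.83),
    NovelTranscriptEvidence("asm_002", orf_length_aa=95, best_pfam_evalue=3e-12,
                            blast_hits=[hit], needle_identity=61.0,
                            cpat_coding_prob=0.83),
    NovelTranscriptEvidence("asm_003", orf_length_aa=180, best_pfam_evalue=None,
                            blast_hits=[], needle_identity=None,
                            cpat_coding_prob=0.12),
]

known_symbols = {"ACOD1", "IRG1"}  # annotation symbols pre-expanded with synonyms

for ev in candidates:
    report = accept_novel_transcript(ev)
    verdict = "ACCEPT" if report.accepted else "reject"
    print(f"{ev.candidate_id}: {verdict}  {','.join(report.reasons) or '-'}")
    if report.accepted:
        symbol = assign_symbol(hit.subject_symbol, known_symbols, ev.candidate_id)
        print(f"  assigned symbol: {symbol} (best hit IRG1 already annotated -> placeholder)")
# asm_001 passes every gate; asm_002 fails only the 100-aa ORF gate;
# asm_003 fails every evidence gate and is kept out of the reference.
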