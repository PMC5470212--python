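"""k-mer uniqueness of a reference before and after removing duplicates.

Near-identical paralogues share almost all of their 31-mers, so reads
matching them cannot be assigned unambiguously. Removing redundant
transcripts can only raise the uniqueness of what remains — the rationale
for filtering a reference before pseudoalignment-based quantification.
"""

from ribopolya import generate_toy_transcriptome, index_uniqueness

records = generate_toy_transcriptome(n_transcripts=40, length=500,
                                     n_duplicated_families=5, seed=3)
full = index_uniqueness(records, k=31)
print(f"full reference:     {len(records)} transcripts, "
      f"{full.index_distinct} distinct 31-mers, "
      f"unique fraction {full.index_unique_fraction:.3f}")
for tid in ("T0000", "T0000_dup"):
    s = full.per_transcript[tid]
    print(f"  {tid}: {s.unique_kmers}/{s.distinct_kmers} unique (duplicated family)")

filtered = index_uniqueness([r for r in records if not r.id.endswith("_dup")], k=31)
print(f"after dropping duplicates: unique fraction "
      f"{filtered.index_unique_fraction:.3f}")
# Duplicated transcripts carry zero unique k-mers; dropping one copy per
# family restores a fully unique index.
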