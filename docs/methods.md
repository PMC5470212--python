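# Methods

## The correction model

TPM is a compositional unit: each sample's values sum to 10^6, so the
abundance assigned to one transcript trades off against all others. A
polyA+ library and a ribo-minus library prepared from the same RNA quantify
overlapping but different transcript populations, which acts as a per-gene
multiplicative library effect followed by renormalisation. Under that model
the correction is exact: if ribo-minus TPMs differ from polyA+ TPMs by a
gene-specific factor (capture efficiency, nascent background share,
compositional rescaling), then multiplying each gene's ribo-minus values by

    r_g = median_polyA+(g) / median_ribo-minus(g)

maps them onto the polyA+ scale, and the corrected ribo-minus *median* of
every gene with a nonzero ribo-minus median equals the polyA+ median
identically (`compute_ratios` / `apply_correction`; the suite checks this to
1e-9 at 10,000 genes × 12 samples). Genes whose ribo-minus median is zero
get r_g = 0: there is no information to rescale, and a zero ratio keeps the
output well-defined and non-negative.

Assumptions worth stating:

- The library effect is per-gene multiplicative and stable across the
  libraries pooled into the medians. Condition-dependent capture violates
  this; `pooling="per_condition"` recomputes ratios within conditions.
- Medians are taken across *all* libraries of each type by default, pooling
  conditions. This is deliberately the cruder estimator — per-gene agreement
  within a condition is then near-perfect but not exact, which is why
  pooled-ratio correction yields correlations just below 1 on data with
  condition structure.
- Corrected matrices are **not** renormalised to 10^6. Rescaling columns
  would break the median-equality contract that justifies the method;
  `renormalize_tpm` exists for callers who need strict TPM semantics
  downstream.
- Genes observed in only one library type cannot receive a ratio; they are
  dropped from the shared universe (logged), or zeroed under
  `missing_gene_policy="zero"`.

## Reference filtering

`drop_unexpressed` removes transcripts with zero TPM in every sample —
models that are spurious, tissue-specific for unsampled tissues, or below
detection. Biotype and TSL restriction (`filter_by_biotype`,
`filter_by_tsl`: TSL ≤ 3 and ≥ 2 exons by default; unscored transcripts,
which are the single-exon models, are excluded) narrow the space to
well-supported protein-coding transcripts where annotation quality allows.

Novel (de-novo-assembled) candidates pass through conjunctive evidence
gates (`accept_novel_transcript`): ORF ≥ 100 aa; best Pfam domain E-value
≤ 1e-5; a surviving Swiss-Prot hit (E ≤ 1e-25, identity ≥ 50%, subject not
a fragment, protein-existence code 1 or 2), with the best hit chosen by
longest alignment, ties broken by identity then accession; global-alignment
identity ≥ 50%; coding probability ≥ 0.364. All boundaries are inclusive
(a value exactly at the cutoff passes). The 0.364 cutoff is the calibrated
human-model value and is configurable, since other assemblies carry their
own calibration. Missing evidence fails its gate: an unannotatable
candidate stays out of the reference. The assembler, HMMER, BLAST and the
coding-potential model run externally; this package consumes their tabular
outputs (schemas in `reference.load_evidence_tables`).

The ORF scanner is forward-strand-only by default (matching strand-specific
assembly); a six-frame mode exists. Codons containing N neither start,
extend nor terminate an ORF. The global aligner is affine-gap
Needleman-Wunsch over BLOSUM62 (X scores 0 against everything) via
Biopython's `PairwiseAligner`: the first column of a gap costs the open
penalty (10.0), each further column the extend penalty (0.5), and end gaps
are penalised like internal ones — a full-length alignment convention,
chosen so that identity (matches / all columns, gaps included) reflects
end-to-end agreement. When several alignments are co-optimal, the highest
identity among them (capped enumeration, 1000 alignments) is reported.

## k-mer uniqueness

`index_uniqueness` counts, per transcript, the distinct k-mers (k = 31,
canonical strand-collapsed by default; windows containing N are skipped)
that occur in no other transcript, plus the index-level unique fraction.
A transcript's internal repeats count as a single occurrence source, so
uniqueness measures between-transcript ambiguity, the quantity that governs
how unambiguously a pseudoaligner can assign reads. Removing transcripts
can only increase the remaining unique counts (tested); a gene-granularity
mode pools paralogous transcripts into one source for gene-family analyses.

## Statistics

Correlation, Welch's t (unequal-variance by default; the pooled-variance
flavour is a flag) and Mann-Whitney U wrap scipy. Mann-Whitney uses exact
enumeration for tie-free groups of ≤ 20 and the tie-corrected normal
approximation otherwise. Distribution comparisons between library types are
made on log2(TPM) of genes detected (TPM strictly > 1) in both groups —
binned TPM distributions and their means are only coherent on the log
scale; a flag restores raw TPM. Cliff's delta is computed by exact pair
counting with the consistent variance estimate and the asymmetric
normal-method 95% CI, clipped to [-1, 1]; magnitudes use the conventional
cutoffs (|δ| < 0.147 negligible, 0.147–0.60 intermediate, ≥ 0.60 large).
P-values are reported exactly, never truncated for presentation.

Inducible-set membership requires TPM > 1 at both timepoints and
log2 fold change > 2, all strict inequalities. Venn partitioning assigns
each gene of the union to exactly one membership-signature region.

## Dendrograms

Euclidean distances between per-sample expression vectors are computed on
log2(x+1) values by default — raw-TPM distances are dominated by the few
most abundant genes; `transform="none"` restores the naive behaviour.
Neighbour joining is the classical Saitou-Nei agglomeration with pinned
determinism: Q-matrix ties break to the smallest label-index pair, negative
branch-length estimates are clamped to zero with the residual moved to the
sibling edge (preserving path lengths through the join), and the unrooted
result is serialised with a trifurcating root. On additive matrices the
generating topology and all path lengths are recovered exactly (tested for
4–8 taxa against an independent NJ implementation).

## The synthetic generator

`simulate` emulates the statistical structure of matched macrophage-style
libraries, not their sequences:

- **Abundance truth**: Pareto-law draws with density exponent `powerlaw_alpha`
  (default 1.8, giving a rank-abundance log-log slope of −1/(α−1) = −1.25),
  clipped at 10^5 × the minimum. The clip is a realism choice — the most
  abundant transcripts in real libraries sit around 10^4–10^5 TPM, and an
  unclipped α < 2 law has infinite mean, letting a single draw dominate the
  composition.
- **Classes**: 20% RNA genes; 8% of genes polyA-minus and 5% bimorphic,
  drawn from RNA genes first because non- and partially-polyadenylated
  RNAs are overwhelmingly non-coding. With these defaults the
  ribo-minus-only genes carry a few percent of total TPM, the magnitude at
  which library-type bias is clearly visible but not pathological.
- **Capture**: polyA+ takes full abundance for polyA-plus genes, half
  (`bimorphic_capture`) for bimorphic, zero for polyA-minus; ribo-minus
  takes everything plus a nascent background worth `nascent_background_frac`
  of total mass spread proportionally to abundance. Because base ribo-minus
  weights are already abundance-proportional, this background cancels under
  TPM renormalisation; it is retained as an explicit model term.
- **Noise**: per-replicate multiplicative lognormal noise, sd 0.1 on the
  log2 scale, six replicates per condition (a six-animal design).
- **Induction**: 5% of genes receive a log2 fold change ~ Normal(3, 0.5)
  truncated at 0. Responders are drawn from below the 99th abundance
  percentile: stimulus-inducible genes start from low-to-moderate baseline
  expression, and inducing a top gene of a heavy-tailed law would let one
  gene dominate the post-stimulation composition, compositionally masking
  every other fold change.

The generator is multiplicative-per-gene + compositional renormalisation —
the weakest model under which the median-ratio correction is exactly
correct. Passing tests on it therefore demonstrate the correction's
self-consistency and its behaviour under replicate noise and composition
shifts; they do not capture read-level effects real libraries add (coverage
bias, multi-mapping, fragment/GC bias, between-animal biological variance),
which is why the package's validation is property-based rather than a
reproduction of any particular dataset's printed values.

## Numerical and interface choices

- Detection thresholds are strict (`TPM > 1`), matching the convention of
  reporting "detectable expression (TPM > 1)".
- Medians over even sample counts use the mean of the central pair.
- Gene-level TPM is the sum of transcript TPMs (abundance additivity);
  unmapped transcripts are dropped with a logged count by default, or raise
  under the strict policy.
- FASTQ downsampling samples read ordinals without replacement with a
  seeded PRNG; paired files are checked for mate synchrony (`/1`/`/2` and
  space-tail dialects stripped) and subsampled with identical indices.
  Output is byte-identical for a fixed seed.
- SAM parsing reads only QNAME and FLAG (unmapped = bit 0x4), mirroring
  `samtools view -f 4`; BAM is out of scope.
- The pipeline (`run_integrate`) is deterministic given inputs, config and
  seed; the manifest records a hash of the full configuration.
- Test problem sizes (10,000 genes × 12 samples for the correction
  contract, 5,000-gene simulations elsewhere) were chosen as the smallest
  sizes at which the heavy-tailed composition effects the method targets
  are clearly expressed.

## Known limitations

- The correction transfers the polyA+ scale to ribo-minus data; it cannot
  recover genes absent from the polyA+ side (their ratio is undefined) and
  zeroes genes invisible to ribo-minus medians.
- Ratios estimated from few replicates inherit median sampling noise;
  nothing shrinks or regularises them.
- The evidence gates are conjunctive and conservative; true novel
  transcripts with weak homology evidence are rejected by design.
- No model-based batch correction (ComBat-style), counts-level offsets, or
  read-level simulation.
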