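"""Synthetic paired polyA+/ribo-minus expression data.

The generator emulates the statistical structure of matched macrophage-style
libraries: a heavy-tailed (power-law) abundance truth over protein-coding
and RNA genes; polyA-minus and bimorphic polyadenylation classes that make
the two selection methods sample different transcriptome fractions; nascent
background signal present only in ribo-minus libraries; lognormal replicate
noise; and an LPS-like induced condition.  Library simulation is at the
TPM level — the compositional renormalisation to one million per sample is
exactly what creates the library-type bias the ratio correction removes.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TPM_TOTAL
from .io_formats import SampleMeta, SequenceRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_truth",
    "simulate_libraries",
    "simulate_lps",
    "generate_toy_transcriptome",
    "write_bundle",
]

# abundance draws are clipped at this multiple of the minimum: real top
# transcripts (e.g. spliceosomal RNAs) sit around 1e4-1e5 TPM, and an
# unclipped alpha < 2 power law has infinite mean
ABUNDANCE_CAP = 1e5


@dataclass
class SimulationConfig:
    """Study conditions for the paired-library simulator.

    ``powerlaw_alpha`` is the density exponent of the abundance law;
    ``frac_polya_minus``/``frac_bimorphic`` set the polyadenylation classes
    (polyA-minus genes are drawn preferentially from RNA genes, since
    non-polyadenylated RNAs are mostly non-coding); ``bimorphic_capture`` is
    the fraction of a bimorphic gene's molecules a polyA+ library captures;
    ``nascent_background_frac`` adds ribo-minus-only signal worth that
    fraction of total mass; ``noise_sd_log2`` is the per-replicate lognormal
    noise on the log2 scale; 6 replicates per condition mirrors a
    six-animal design.
    """

    n_genes: int = 10_000
    powerlaw_alpha: float = 1.8
    frac_rna_genes: float = 0.2
    frac_polya_minus: float = 0.08
    frac_bimorphic: float = 0.05
    bimorphic_capture: float = 0.5
    nascent_background_frac: float = 0.05
    n_reps: int = 6
    noise_sd_log2: float = 0.1
    frac_inducible: float = 0.05
    inducible_lfc_mean: float = 3.0
    inducible_lfc_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_rna_genes", "frac_polya_minus", "frac_bimorphic",
                     "bimorphic_capture", "nascent_background_frac", "frac_inducible"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_polya_minus + self.frac_bimorphic > 1.0:
            raise ValueError("polyA-minus and bimorphic fractions exceed 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.powerlaw_alpha <= 1.0:
            raise ValueError("powerlaw_alpha must be > 1")


@dataclass
class SyntheticTruth:
    """Ground truth per gene: relative abundance, polyadenylation class,
    biotype, and the condition effect (0 for non-responders)."""

    table: pd.DataFrame  # index gene_id; columns true_abundance, polya_class, biotype, lps_log2fc

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genes_of_class(self, polya_class: str) -> list[str]:
        return list(self.table.index[self.table["polya_class"] == polya_class])

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _exact_count(frac: float, n: int) -> int:
    return int(round(frac * n))


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw a ground-truth gene table under the configured study conditions.

    Abundances follow a Pareto-type law with density exponent
    ``powerlaw_alpha`` (clipped at ``ABUNDANCE_CAP``); class counts match the
    requested fractions exactly up to integer rounding; everything is
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(n)]

    # density exponent alpha corresponds to Pareto shape a = alpha - 1
    abundance = 1.0 + rng.pareto(config.powerlaw_alpha - 1.0, size=n)
    abundance = np.minimum(abundance, ABUNDANCE_CAP)

    biotype = np.array(["protein_coding"] * n, dtype=object)
    n_rna = _exact_count(config.frac_rna_genes, n)
    rna_idx = rng.choice(n, size=n_rna, replace=False)
    biotype[rna_idx] = "rna_gene"

    polya_class = np.array(["polyA_plus"] * n, dtype=object)
    n_minus = _exact_count(config.frac_polya_minus, n)
    n_bim = _exact_count(config.frac_bimorphic, n)
    # non- and partially-polyadenylated transcripts are overwhelmingly
    # non-coding, so both classes are drawn from RNA genes first and only
    # topped up from protein-coding genes when the RNA-gene pool runs out
    rna_pool = list(rng.permutation(rna_idx))
    other_pool = list(rng.permutation(np.setdiff1d(np.arange(n), rna_idx)))
    pool = rna_pool + other_pool
    minus_idx = np.array(pool[:n_minus], dtype=int)
    bim_idx = np.array(pool[n_minus : n_minus + n_bim], dtype=int)
    polya_class[minus_idx] = "polyA_minus"
    polya_class[bim_idx] = "bimorphic"

    table = pd.DataFrame(
        {
            "true_abundance": abundance,
            "polya_class": polya_class,
            "biotype": biotype,
            "lps_log2fc": np.zeros(n),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticTruth(table)


def simulate_lps(truth: SyntheticTruth, config: SimulationConfig) -> SyntheticTruth:
    """Post-stimulation truth: a seeded fraction of genes gets a log2 fold
    change drawn from Normal(mean, sd) truncated at 0, applied
    multiplicatively to its relative abundance."""
    rng = np.random.default_rng(config.seed + 1)
    table = truth.table.copy()
    n = len(table)
    n_ind = _exact_count(config.frac_inducible, n)
    if n_ind:
        # responders are drawn from below the top abundance percentile:
        # stimulus-inducible genes start from low-to-moderate baseline
        # expression, and inducing a top gene of a heavy-tailed law would
        # let a single gene dominate the post-stimulation composition
        abundance = table["true_abundance"].to_numpy()
        eligible = np.flatnonzero(abundance < np.quantile(abundance, 0.99))
        if len(eligible) < n_ind:
            eligible = np.arange(n)
        idx = rng.choice(eligible, size=n_ind, replace=False)
        lfc = rng.normal(config.inducible_lfc_mean, config.inducible_lfc_sd, size=n_ind)
        lfc = np.maximum(lfc, 0.0)
        col = table["lps_log2fc"].to_numpy().copy()
        col[idx] = lfc
        table["lps_log2fc"] = col
        table["true_abundance"] = table["true_abundance"] * np.exp2(table["lps_log2fc"])
    return SyntheticTruth(table)


def _capture_weights(truth: SyntheticTruth, library_type: str,
                     config: SimulationConfig) -> np.ndarray:
    a = truth.table["true_abundance"].to_numpy(dtype=float)
    cls = truth.table["polya_class"].to_numpy()
    if library_type == "polyA":
        w = np.where(
            cls == "polyA_plus", a,
            np.where(cls == "bimorphic", config.bimorphic_capture * a, 0.0),
        )
    elif library_type == "ribominus":
        w = a.copy()
        # nascent background: extra mass proportional to transcription,
        # spread over all genes in proportion to abundance
        w = w + config.nascent_background_frac * w.sum() * (a / a.sum())
    else:
        raise ValueError(f"unknown library_type {library_type!r}")
    return w


def simulate_libraries(
    truth: SyntheticTruth,
    library_type: str,
    config: SimulationConfig,
    condition: str = "0h",
    seed_offset: int = 0,
) -> ExpressionMatrix:
    """Simulate replicate TPM columns for one library type and condition.

    Capture model: polyA+ libraries take full abundance for polyA-plus
    genes, ``bimorphic_capture`` of it for bimorphic genes and nothing for
    polyA-minus genes; ribo-minus libraries take every class plus the
    nascent background.  Each replicate gets independent multiplicative
    lognormal noise (sd ``noise_sd_log2`` on the log2 scale) and the column
    is renormalised to sum to one million (TPM).
    """
    w = _capture_weights(truth, library_type, config)
    lib_code = {"polyA": 0, "ribominus": 1}[library_type]
    cond_code = sum(ord(c) for c in condition) % (2**16)
    rng = np.random.default_rng((config.seed, 2, lib_code, cond_code, seed_offset))
    cols = {}
    samples = []
    prefix = "P" if library_type == "polyA" else "R"
    for rep in range(1, config.n_reps + 1):
        noisy = w * np.exp2(rng.normal(0.0, config.noise_sd_log2, size=w.size)) \
            if config.noise_sd_log2 > 0 else w.copy()
        total = noisy.sum()
        if total <= 0:
            raise ValueError("library captured no signal")
        sid = f"{prefix}_{condition}_rep{rep}"
        cols[sid] = noisy * (TPM_TOTAL / total)
        samples.append(SampleMeta(sid, library_type, condition, str(rep)))
    values = pd.DataFrame(cols, index=truth.table.index)
    return ExpressionMatrix(values, samples)


_BASE_CHOICES = np.frombuffer(b"ACGT", dtype="S1")


def generate_toy_transcriptome(
    n_transcripts: int,
    length: int = 500,
    n_duplicated_families: int = 0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random transcript sequences with optional identical-pair gene families.

    Each duplicated family contributes a byte-identical copy of one of the
    base transcripts (ids ``T<i>_dup``), for k-mer-uniqueness and paralogue
    tests.  Deterministic given ``seed``.
    """
    if length < 31:
        raise ValueError("length must be >= 31")
    if n_duplicated_families > n_transcripts:
        raise ValueError("more duplicated families than transcripts")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_transcripts):
        seq = "".join(rng.choice(["A", "C", "G", "T"], size=length))
        records.append(SequenceRecord(id=f"T{i:04d}", sequence=seq))
    for i in range(n_duplicated_families):
        src = records[i]
        records.append(SequenceRecord(id=f"{src.id}_dup", sequence=src.sequence))
    return records


def write_bundle(out_dir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Run the full simulation and write a plain-text bundle.

    Produces the pre/post-stimulation truth tables, polyA+ and ribo-minus
    gene matrices over both conditions, a sample sheet, and a toy
    transcriptome FASTA.  Returns the artifact paths.
    """
    from .io_formats import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth0 = generate_truth(config)
    truth7 = simulate_lps(truth0, config)

    mats = {}
    for lib in ("polyA", "ribominus"):
        per_cond = [
            simulate_libraries(truth0, lib, config, condition="0h", seed_offset=0),
            simulate_libraries(truth7, lib, config, condition="7h", seed_offset=1),
        ]
        values = pd.concat([m.values for m in per_cond], axis=1)
        samples = [s for m in per_cond for s in m.samples]
        mats[lib] = ExpressionMatrix(values, samples)

    paths = {
        "truth_pre": out / "truth_0h.tsv",
        "truth_post": out / "truth_7h.tsv",
        "polyA_matrix": out / "polyA_matrix.tsv",
        "ribo_matrix": out / "ribominus_matrix.tsv",
        "sample_sheet": out / "samples.tsv",
        "toy_fasta": out / "toy_transcriptome.fa",
    }
    truth0.to_tsv(paths["truth_pre"])
    truth7.to_tsv(paths["truth_post"])
    mats["polyA"].to_tsv(paths["polyA_matrix"])
    mats["ribominus"].to_tsv(paths["ribo_matrix"])
    sheet = pd.DataFrame(
        [(s.sample_id, s.library_type, s.condition, s.replicate)
         for lib in mats.values() for s in lib.samples],
        columns=["sample_id", "library_type", "condition", "replicate"],
    )
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    write_fasta(generate_toy_transcriptome(50, 500, 2, seed=config.seed), paths["toy_fasta"])
    return paths
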