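"""End-to-end orchestration: from abundance tables to corrected, comparable matrices.

``run_integrate`` wires the stages together: load expression (per-sample
abundance tables summarised to gene level, or precomputed matrices), drop
unexpressed features, optionally restrict by biotype/TSL using an annotation
table, report k-mer uniqueness of the retained reference, compute and apply
the per-gene ratio correction, and emit concordance statistics, inducible
gene sets and a sample dendrogram, with a manifest recording the seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correction import apply_correction, compute_ratios
from .expression import (
    ExpressionMatrix,
    matrix_from_abundances,
    median_profile,
    summarize_to_gene,
)
from .io_formats import SampleMeta, read_abundance, read_fasta, read_transcript_gene_map, write_fasta
from .kmers import index_uniqueness
from .reference import drop_unexpressed
from .stats import (
    cliffs_delta,
    correlate,
    inducible_set,
    mann_whitney,
    paired_log2_values,
    venn_region_counts,
    welch_t,
)
from .trees import euclidean_distances, neighbour_joining
from .io_formats import write_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_integrate"]


@dataclass
class RunConfig:
    """Paths and thresholds for an integration run.

    Expression input is either ``abundance_dir`` (one ``<sample_id>.tsv``
    Kallisto-style table per sample, requiring ``transcript_gene_map``) or
    the pair ``polya_matrix``/``ribo_matrix`` of gene-level TSVs; both forms
    need ``sample_sheet``.  ``fasta`` and ``annotation`` are optional and
    enable the k-mer report and the biotype restriction respectively.
    """

    out_dir: str
    sample_sheet: str
    abundance_dir: str | None = None
    transcript_gene_map: str | None = None
    map_format: str = "tsv"
    polya_matrix: str | None = None
    ribo_matrix: str | None = None
    fasta: str | None = None
    annotation: str | None = None
    allowed_biotypes: tuple[str, ...] | None = None

    tpm_detect: float = 1.0
    lfc_threshold: float = 2.0
    k: int = 31
    pooling: str = "all_samples"
    tree_transform: str = "log2p1"
    seed: int = 0

    def validate(self) -> None:
        if self.tpm_detect < 0:
            raise ValueError("tpm_detect must be >= 0")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pooling not in ("all_samples", "per_condition"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.abundance_dir is None and (self.polya_matrix is None or self.ribo_matrix is None):
            raise ValueError("need abundance_dir or both matrix paths")
        if self.abundance_dir is not None and self.transcript_gene_map is None:
            raise ValueError("abundance_dir requires transcript_gene_map")
        for name in ("sample_sheet", "abundance_dir", "transcript_gene_map",
                     "polya_matrix", "ribo_matrix", "fasta", "annotation"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleMeta(r.sample_id, r.library_type, r.condition, r.replicate)
        for r in sheet.itertuples()
    ]


def _load_matrices(config: RunConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    samples = _read_sample_sheet(config.sample_sheet)
    if config.abundance_dir is not None:
        tg_map = read_transcript_gene_map(config.transcript_gene_map, format=config.map_format)
        tables = {}
        for meta in samples:
            path = Path(config.abundance_dir) / f"{meta.sample_id}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"abundance table for {meta.sample_id}: {path}")
            tables[meta.sample_id] = read_abundance(path)
        tx_matrix = matrix_from_abundances(tables, samples)
        gene = summarize_to_gene(tx_matrix, tg_map, unmapped="drop")
        polya = gene.select_samples(lambda s: s.library_type == "polyA")
        ribo = gene.select_samples(lambda s: s.library_type == "ribominus")
        return polya, ribo
    polya = ExpressionMatrix.from_tsv(config.polya_matrix, config.sample_sheet)
    ribo = ExpressionMatrix.from_tsv(config.ribo_matrix, config.sample_sheet)
    return polya, ribo


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)
    logger.info("stage: %s", name)


def run_integrate(config: RunConfig) -> dict:
    """Run the two-step integration pipeline; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ribopolya",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": [],
        "artifacts": {},
        "complete": False,
    }

    def artifact(key: str, path: Path) -> Path:
        manifest["artifacts"][key] = str(path)
        return path

    try:
        _stage(manifest, "load_expression")
        polya, ribo = _load_matrices(config)

        _stage(manifest, "drop_unexpressed")
        combined = pd.concat([polya.values, ribo.values], axis=1).fillna(0.0)
        expressed = (combined > 0).any(axis=1)
        retained = combined.index[expressed]
        dropped = combined.index[~expressed]
        manifest["n_genes_input"] = int(len(combined.index))
        manifest["n_genes_dropped_unexpressed"] = int(len(dropped))
        polya = ExpressionMatrix(polya.values.loc[polya.values.index.intersection(retained)],
                                 list(polya.samples))
        ribo = ExpressionMatrix(ribo.values.loc[ribo.values.index.intersection(retained)],
                                list(ribo.samples))

        if config.annotation is not None:
            _stage(manifest, "biotype_filter")
            from .reference import load_annotation

            ann = load_annotation(config.annotation)
            allowed = set(config.allowed_biotypes or {"protein_coding"})
            keep = [g for g in retained if ann.get(g, {}).get("biotype") in allowed]
            polya = ExpressionMatrix(polya.values.loc[polya.values.index.intersection(keep)],
                                     list(polya.samples))
            ribo = ExpressionMatrix(ribo.values.loc[ribo.values.index.intersection(keep)],
                                    list(ribo.samples))
            manifest["n_genes_after_biotype"] = int(len(keep))

        if config.fasta is not None:
            _stage(manifest, "kmer_report")
            records = read_fasta(config.fasta)
            stats = index_uniqueness(records, k=config.k)
            stats.to_tsv(artifact("kmer_report", out / "kmer_report.tsv"))
            manifest["index_unique_fraction"] = stats.index_unique_fraction
            write_fasta(records, artifact("revised_fasta", out / "revised_reference.fa"))

        _stage(manifest, "compute_ratios")
        ratios = compute_ratios(polya, ribo, pooling=config.pooling)
        ratios.to_tsv(artifact("ratios", out / "correction_ratios.tsv"))

        _stage(manifest, "apply_correction")
        shared = ribo.values.index.intersection(ratios.ratios.index)
        ribo_shared = ExpressionMatrix(ribo.values.loc[shared], list(ribo.samples))
        corrected = apply_correction(ribo_shared, ratios)
        corrected.to_tsv(artifact("corrected_matrix", out / "ribominus_corrected.tsv"),
                         artifact("corrected_samples", out / "ribominus_samples.tsv"))

        _stage(manifest, "concordance_stats")
        stats_report = _concordance_report(polya, ribo_shared, corrected, config)
        with open(artifact("stats", out / "concordance_stats.json"), "w") as fh:
            json.dump(stats_report, fh, indent=2, sort_keys=True)

        conditions = sorted({s.condition for s in polya.samples})
        if len(conditions) >= 2:
            _stage(manifest, "inducible_sets")
            sets_report = _inducible_report(polya, ribo_shared, corrected, conditions, config)
            with open(artifact("inducible", out / "inducible_sets.json"), "w") as fh:
                json.dump(sets_report, fh, indent=2, sort_keys=True)

        _stage(manifest, "dendrogram")
        tree_matrix = ExpressionMatrix(
            pd.concat([polya.values, corrected.values], axis=1).fillna(0.0),
            list(polya.samples) + list(corrected.samples),
        )
        tree = neighbour_joining(euclidean_distances(tree_matrix, config.tree_transform))
        artifact("tree", out / "samples.nwk").write_text(write_newick(tree) + "\n")

        manifest["complete"] = True
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _concordance_report(polya: ExpressionMatrix, ribo: ExpressionMatrix,
                        corrected: ExpressionMatrix, config: RunConfig) -> dict:
    report: dict = {}
    for cond in sorted({s.condition for s in polya.samples}):
        sel = lambda s, c=cond: s.condition == c
        med_p = median_profile(polya, sel)
        med_r = median_profile(ribo, sel)
        med_c = median_profile(corrected, sel)

        entry: dict = {}
        for tag, med_other in (("uncorrected", med_r), ("corrected", med_c)):
            a, b = paired_log2_values(med_p, med_other, config.tpm_detect)
            if a.size >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
                r, p = correlate(a, b, "pearson")
                t, tp = welch_t(a, b)
                es = cliffs_delta(a, b)
                shared = med_p.index.intersection(med_other.index)
                absdiff = (med_p.loc[shared] - med_other.loc[shared]).abs()
                entry[tag] = {
                    "n_genes": int(a.size),
                    "pearson_r": r,
                    "pearson_p": p,
                    "mean_log2_polyA": float(a.mean()),
                    "mean_log2_other": float(b.mean()),
                    "welch_t": t,
                    "welch_p": tp,
                    "cliffs_delta": es.delta,
                    "delta_magnitude": es.magnitude,
                    "median_abs_diff_tpm": float(absdiff.median()),
                }
        if "uncorrected" in entry and "corrected" in entry:
            shared = med_p.index.intersection(med_r.index)
            d_unc = (med_p.loc[shared] - med_r.loc[shared]).abs()
            d_cor = (med_p.loc[shared] - med_c.loc[shared]).abs()
            u, up = mann_whitney(d_unc.to_numpy(), d_cor.to_numpy())
            entry["abs_diff_mannwhitney_U"] = u
            entry["abs_diff_mannwhitney_p"] = up
        report[cond] = entry
    return report


def _inducible_report(polya: ExpressionMatrix, ribo: ExpressionMatrix,
                      corrected: ExpressionMatrix, conditions: list[str],
                      config: RunConfig) -> dict:
    pre, post = conditions[0], conditions[1]
    profiles = {}
    for name, mat in (("P", polya), ("R", ribo), ("Rc", corrected)):
        profiles[name] = {
            c: median_profile(mat, lambda s, c=c: s.condition == c) for c in (pre, post)
        }
    sets = {
        "P0_P7": inducible_set(profiles["P"][pre], profiles["P"][post],
                               config.tpm_detect, config.lfc_threshold),
        "R0_R7": inducible_set(profiles["Rc"][pre], profiles["Rc"][post],
                               config.tpm_detect, config.lfc_threshold),
        "P0_R7": inducible_set(profiles["P"][pre], profiles["Rc"][post],
                               config.tpm_detect, config.lfc_threshold),
        "R0_P7": inducible_set(profiles["Rc"][pre], profiles["P"][post],
                               config.tpm_detect, config.lfc_threshold),
    }
    venn = venn_region_counts(sets)
    return {
        "set_sizes": {k: len(v) for k, v in sets.items()},
        "venn_regions": {"+".join(sorted(k)): v for k, v in venn.region_counts.items()},
        "intersection_all": venn.region_counts[frozenset(sets)],
        "union": venn.union_size,
    }
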