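"""Gene-level TPM matrices: aggregation, medians, detection and renormalisation.

The central container is :class:`ExpressionMatrix`, a features x samples grid
of non-negative TPM values backed by a pandas DataFrame, together with the
per-sample metadata (library type, condition, replicate) the downstream
correction and statistics need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import AbundanceRow, SampleMeta

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6

__all__ = [
    "ExpressionMatrix",
    "matrix_from_abundances",
    "summarize_to_gene",
    "median_profile",
    "detected_set",
    "renormalize_tpm",
]


@dataclass
class ExpressionMatrix:
    """Features x samples TPM grid with per-sample metadata.

    ``values`` is indexed by feature id with one column per sample id;
    ``samples`` maps each sample id to its :class:`SampleMeta`, in column
    order.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("matrix columns must match sample metadata order")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if len({s.sample_id for s in self.samples}) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select_samples(self, predicate: Callable[[SampleMeta], bool]) -> "ExpressionMatrix":
        kept = [s for s in self.samples if predicate(s)]
        if not kept:
            raise ValueError("sample selection matched no samples")
        return ExpressionMatrix(self.values[[s.sample_id for s in kept]], kept)

    def is_normalized(self, rtol: float = 1e-6) -> bool:
        sums = self.values.sum(axis=0).to_numpy()
        return bool(np.allclose(sums, TPM_TOTAL, rtol=rtol))

    # --- TSV round trip -------------------------------------------------
    def to_tsv(self, matrix_path: str | Path, sample_sheet_path: str | Path | None = None,
               float_format: str = "%.10g") -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(matrix_path, sep="\t", float_format=float_format)
        if sample_sheet_path is not None:
            sheet = pd.DataFrame(
                [(s.sample_id, s.library_type, s.condition, s.replicate) for s in self.samples],
                columns=["sample_id", "library_type", "condition", "replicate"],
            )
            sheet.to_csv(sample_sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 sample_sheet_path: str | Path | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        if sample_sheet_path is not None:
            sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype=str)
            metas = {
                r.sample_id: SampleMeta(r.sample_id, r.library_type, r.condition, r.replicate)
                for r in sheet.itertuples()
            }
            samples = [metas[c] for c in values.columns]
        else:
            samples = [SampleMeta(c, "polyA") for c in values.columns]
        return cls(values.astype(float), samples)


def matrix_from_abundances(
    tables: dict[str, list[AbundanceRow]], samples: Sequence[SampleMeta]
) -> ExpressionMatrix:
    """Assemble a transcript-level matrix from per-sample abundance tables.

    ``tables`` maps sample_id -> rows; the transcript universe is the union,
    with absent transcripts set to 0 TPM.
    """
    by_sample = {sid: {r.target_id: r.tpm for r in rows} for sid, rows in tables.items()}
    ordered = [s for s in samples if s.sample_id in by_sample]
    if len(ordered) != len(by_sample):
        missing = set(by_sample) - {s.sample_id for s in samples}
        raise ValueError(f"abundance tables without sample metadata: {sorted(missing)}")
    universe = sorted(set().union(*[set(d) for d in by_sample.values()]))
    values = pd.DataFrame(
        {s.sample_id: [by_sample[s.sample_id].get(t, 0.0) for t in universe] for s in ordered},
        index=universe,
    )
    return ExpressionMatrix(values, list(ordered))


def summarize_to_gene(
    transcript_matrix: ExpressionMatrix,
    transcript_gene_map: dict[str, str],
    unmapped: str = "drop",
) -> ExpressionMatrix:
    """Sum transcript TPMs to gene level.

    Gene TPM is the sum of its transcripts' TPMs per sample (abundance
    additivity); output gene order is lexicographic.  ``unmapped`` controls
    transcripts absent from the map: ``"drop"`` excludes them with a logged
    count, ``"strict"`` raises listing their ids.
    """
    tids = transcript_matrix.feature_ids
    missing = [t for t in tids if t not in transcript_gene_map]
    if missing:
        if unmapped == "strict":
            raise ValueError(f"unmapped transcripts: {missing[:10]}" +
                             (f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""))
        if unmapped != "drop":
            raise ValueError(f"unknown unmapped policy {unmapped!r}")
        logger.warning("dropping %d unmapped transcripts", len(missing))
    kept = [t for t in tids if t in transcript_gene_map]
    genes = pd.Index([transcript_gene_map[t] for t in kept], name="gene_id")
    summed = transcript_matrix.values.loc[kept].groupby(genes, sort=True).sum()
    return ExpressionMatrix(summed, list(transcript_matrix.samples))


def median_profile(
    matrix: ExpressionMatrix, group: Callable[[SampleMeta], bool] | None = None
) -> pd.Series:
    """Per-feature median TPM over the samples selected by ``group``.

    Even sample counts take the mean of the two central order statistics.
    ``group=None`` selects every sample.
    """
    sub = matrix if group is None else matrix.select_samples(group)
    return sub.values.median(axis=1)


def detected_set(profile: pd.Series, threshold: float = 1.0) -> set[str]:
    """Features with TPM strictly greater than ``threshold`` (default 1)."""
    if threshold < 0:
        raise ValueError("detection threshold must be >= 0")
    return set(profile.index[profile > threshold])


def renormalize_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every column to sum to 1e6 (proper TPM semantics)."""
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero columns cannot be renormalized: {list(zero.index)}")
    values = matrix.values * (TPM_TOTAL / sums)
    return ExpressionMatrix(values, list(matrix.samples))
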