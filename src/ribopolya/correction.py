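"""Per-gene ratio-based correction of rRNA-depleted TPM estimates.

polyA-selected and rRNA-depleted libraries sequence different fractions of
the transcriptome, so the same gene receives systematically different TPM in
the two library types.  The correction multiplies every ribo-minus TPM of a
gene by r_g = median polyA+ TPM / median ribo-minus TPM (the medians taken
across all libraries of each type); when the ribo-minus median is 0 the
ratio is defined as 0.  By construction the corrected ribo-minus median of
every gene with a nonzero ribo-minus median equals the polyA+ median
exactly, which is what makes the two library types directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, median_profile

logger = logging.getLogger(__name__)

__all__ = ["CorrectionRatios", "compute_ratios", "apply_correction"]


@dataclass
class CorrectionRatios:
    """Per-gene non-negative multipliers mapping ribo-minus TPM into polyA+ space.

    ``ratios`` is indexed by gene; when ``pooling="per_condition"`` it has one
    column per condition, otherwise the single column ``"ratio"``.  The
    medians backing each ratio and the sample ids used (provenance) are kept
    for reporting and for the median-equality check.
    """

    ratios: pd.DataFrame
    median_polya: pd.DataFrame
    median_ribo: pd.DataFrame
    polya_samples: list[str]
    ribo_samples: list[str]
    pooling: str = "all_samples"

    def ratio_for(self, condition: str | None = None) -> pd.Series:
        if self.pooling == "all_samples":
            return self.ratios["ratio"]
        if condition is None:
            raise ValueError("per_condition ratios need a condition")
        return self.ratios[condition]

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {
                "ratio": self.ratios,
                "median_polyA": self.median_polya,
                "median_ribo": self.median_ribo,
            },
            axis=1,
        )
        out.columns = ["_".join(c) if c[1] != "ratio" else c[0] for c in out.columns]
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def _safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    ratio = pd.Series(0.0, index=num.index)
    nz = den > 0
    ratio[nz] = num[nz] / den[nz]
    return ratio


def compute_ratios(
    polya: ExpressionMatrix,
    ribo: ExpressionMatrix,
    pooling: str = "all_samples",
) -> CorrectionRatios:
    """Compute per-gene correction ratios from paired library-type matrices.

    The gene universe is the intersection of the two matrices (asymmetric
    genes are logged).  ``pooling="all_samples"`` takes the medians across
    every library of each type regardless of condition; ``"per_condition"``
    computes a ratio per condition from condition-matched libraries.
    """
    shared = polya.values.index.intersection(ribo.values.index).sort_values()
    if shared.empty:
        raise ValueError("no shared genes between polyA and ribo-minus matrices")
    asym = (len(polya.values.index) - len(shared)) + (len(ribo.values.index) - len(shared))
    if asym:
        logger.info("dropping %d genes present in only one library type", asym)
    pv = ExpressionMatrix(polya.values.loc[shared], list(polya.samples))
    rv = ExpressionMatrix(ribo.values.loc[shared], list(ribo.samples))

    if pooling == "all_samples":
        med_p = median_profile(pv).to_frame("ratio")
        med_r = median_profile(rv).to_frame("ratio")
    elif pooling == "per_condition":
        conds = sorted({s.condition for s in polya.samples} & {s.condition for s in ribo.samples})
        if not conds:
            raise ValueError("no shared conditions between matrices")
        med_p = pd.DataFrame(
            {c: median_profile(pv, lambda s, c=c: s.condition == c) for c in conds}
        )
        med_r = pd.DataFrame(
            {c: median_profile(rv, lambda s, c=c: s.condition == c) for c in conds}
        )
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")

    ratios = pd.DataFrame(
        {c: _safe_ratio(med_p[c], med_r[c]) for c in med_p.columns}, index=shared
    )
    return CorrectionRatios(
        ratios=ratios,
        median_polya=med_p,
        median_ribo=med_r,
        polya_samples=pv.sample_ids,
        ribo_samples=rv.sample_ids,
        pooling=pooling,
    )


def apply_correction(
    ribo: ExpressionMatrix,
    ratios: CorrectionRatios,
    missing_gene_policy: str = "error",
) -> ExpressionMatrix:
    """Multiply every ribo-minus TPM by its gene's ratio.

    The output is deliberately *not* renormalised to 1e6: rescaling the
    columns would break the per-gene median-equality contract with the polyA+
    matrix.  Callers needing strict TPM semantics downstream can apply
    :func:`ribopolya.expression.renormalize_tpm` explicitly.  Genes without a
    ratio raise under ``missing_gene_policy="error"`` or are zeroed under
    ``"zero"``.
    """
    missing = ribo.values.index.difference(ratios.ratios.index)
    if len(missing):
        if missing_gene_policy == "error":
            raise ValueError(f"genes without correction ratio: {list(missing[:10])}")
        if missing_gene_policy != "zero":
            raise ValueError(f"unknown missing_gene_policy {missing_gene_policy!r}")

    corrected = ribo.values.copy()
    if ratios.pooling == "all_samples":
        r = ratios.ratio_for().reindex(ribo.values.index, fill_value=0.0)
        corrected = corrected.mul(r, axis=0)
    else:
        for meta in ribo.samples:
            r = ratios.ratio_for(meta.condition).reindex(ribo.values.index, fill_value=0.0)
            corrected[meta.sample_id] = corrected[meta.sample_id] * r
    return ExpressionMatrix(corrected, list(ribo.samples))
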