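"""Proteome-matrix analytics: zero filtering, per-protein fold change,
composition vs total-corrected normalization, overexpression fraction, and
congruence with a response gene set.

A DIA proteomics run yields a protein x sample matrix of nonnegative
signal intensities.  Because one massively overexpressed protein can take
up a large fraction of the signal, two views of the data are useful: the
raw composition (no overall correction; captures how the proteome
composition besides the target changes) and the total-corrected view (each
sample rescaled so its summed signal matches the control, approximating
per-cell amounts).  The conservative preprocessing used here discards any
protein with a zero intensity in any sample, so no imputation or
pseudocount is ever needed downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .errors import UndefinedRatioError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ProteomeMatrix",
    "ProteinFCResult",
    "zero_filter",
    "per_protein_fc",
    "total_correction",
    "overexpression_fraction",
    "congruence_fraction",
]


@dataclass(frozen=True)
class ProteomeMatrix:
    """Protein x sample intensity matrix with sample condition/replicate labels.

    ``intensities`` is a DataFrame indexed by protein_id with one column
    per sample; ``samples`` maps sample name -> (condition, replicate).
    """

    intensities: pd.DataFrame
    samples: dict
    target_protein_id: str | None = None

    def __post_init__(self) -> None:
        df = self.intensities
        if df.index.duplicated().any():
            raise ValidationError("duplicate protein ids")
        if len(set(df.columns)) != len(df.columns):
            raise ValidationError("sample labels must be unique")
        if set(df.columns) != set(self.samples):
            raise ValidationError("samples metadata must cover exactly the matrix columns")
        if (df.to_numpy() < 0).any():
            raise ValidationError("intensities must be nonnegative")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for col in self.intensities.columns:
            cond = self.samples[col][0]
            if cond not in seen:
                seen.append(cond)
        return tuple(seen)

    def condition_samples(self, condition: str) -> list[str]:
        cols = [c for c in self.intensities.columns if self.samples[c][0] == condition]
        if not cols:
            raise ValidationError(
                f"condition {condition!r} has no samples; available: {self.conditions}"
            )
        return cols

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, target_protein_id=None) -> "ProteomeMatrix":
        """Load from a matrix TSV (first column protein_id) plus a samples
        sheet TSV (sample, condition, replicate)."""
        mat = pd.read_csv(matrix_path, sep="\t").set_index("protein_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        required = {"sample", "condition", "replicate"}
        if not required <= set(sheet.columns):
            raise ValidationError(f"samples sheet needs columns {sorted(required)}")
        samples = {
            str(r["sample"]): (str(r["condition"]), int(r["replicate"]))
            for _, r in sheet.iterrows()
        }
        return cls(intensities=mat, samples=samples, target_protein_id=target_protein_id)


@dataclass(frozen=True)
class ProteinFCResult:
    protein_id: str
    mean_log2fc: float
    p_value: float
    fdr: float


def zero_filter(matrix: ProteomeMatrix) -> ProteomeMatrix:
    """Drop every protein with a zero intensity in any sample.

    The conservative alternative to imputation: survivors are strictly
    positive everywhere, so log operations downstream are safe.  Idempotent.
    """
    df = matrix.intensities
    keep = (df > 0).all(axis=1)
    logger.info("zero_filter: %d proteins -> %d survivors", len(df), int(keep.sum()))
    return ProteomeMatrix(
        intensities=df.loc[keep],
        samples=dict(matrix.samples),
        target_protein_id=matrix.target_protein_id,
    )


def per_protein_fc(
    matrix: ProteomeMatrix,
    condition_a: str,
    condition_b: str,
    paired: bool = False,
) -> list[ProteinFCResult]:
    """Per-protein log2 fold change of condition_b over condition_a with
    Welch-test significance and BH FDR across proteins.

    mean_log2fc is mean(log2 intensity_b) - mean(log2 intensity_a) over
    replicates (unpaired; robust to replicate ordering).  ``paired=True``
    instead averages per-replicate-pair log2 ratios, requiring equal
    replicate counts.  Requires a zero-filtered (strictly positive) matrix.
    """
    cols_a = matrix.condition_samples(condition_a)
    cols_b = matrix.condition_samples(condition_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("per_protein_fc requires >= 2 replicates per condition")
    sub = matrix.intensities[cols_a + cols_b]
    if (sub.to_numpy() <= 0).any():
        raise ValidationError(
            "matrix contains zeros; apply zero_filter before fold-change analysis"
        )
    log_a = np.log2(matrix.intensities[cols_a].to_numpy())
    log_b = np.log2(matrix.intensities[cols_b].to_numpy())

    if paired:
        if len(cols_a) != len(cols_b):
            warnings.warn(
                "unequal replicate counts; falling back to unpaired mean of logs",
                stacklevel=2,
            )
            paired = False
    if paired:
        fc = (log_b - log_a).mean(axis=1)
    else:
        fc = log_b.mean(axis=1) - log_a.mean(axis=1)

    t_res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    # constant-in-both-groups proteins give nan p; treat as no evidence
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    return [
        ProteinFCResult(
            protein_id=str(pid),
            mean_log2fc=float(f),
            p_value=float(pv),
            fdr=float(qv),
        )
        for pid, f, pv, qv in zip(matrix.intensities.index, fc, p, q)
    ]


def total_correction(matrix: ProteomeMatrix, reference_condition: str) -> ProteomeMatrix:
    """Rescale each sample so its summed signal equals the reference mean total.

    Reference-condition samples are left untouched; every other sample is
    multiplied by (mean total of reference samples) / (its own total).
    Within-sample proportions are conserved exactly.  Idempotent up to the
    reference samples' own spread around their mean.
    """
    ref_cols = matrix.condition_samples(reference_condition)
    totals = matrix.intensities.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero-total samples: {bad}")
    ref_total = float(totals[ref_cols].mean())
    scaled = matrix.intensities.copy()
    for col in scaled.columns:
        if col in ref_cols:
            continue
        scaled[col] = scaled[col] * (ref_total / float(totals[col]))
    return ProteomeMatrix(
        intensities=scaled,
        samples=dict(matrix.samples),
        target_protein_id=matrix.target_protein_id,
    )


def overexpression_fraction(
    matrix: ProteomeMatrix, target_protein_id: str, condition: str
) -> float:
    """Target protein's share of total signal in a condition, in percent.

    Computed per sample as 100 * target / total and averaged over the
    condition's samples.  An absent target returns 0 with a warning
    (absence is informative, not an error).
    """
    cols = matrix.condition_samples(condition)
    if target_protein_id not in matrix.intensities.index:
        warnings.warn(
            f"target protein {target_protein_id!r} absent from matrix; fraction = 0",
            stacklevel=2,
        )
        return 0.0
    totals = matrix.intensities[cols].sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("sample with zero total intensity")
    target = matrix.intensities.loc[target_protein_id, cols]
    return float((100.0 * target / totals).mean())


def congruence_fraction(
    changed,
    response_set,
    direction_aware: bool = False,
    directions: dict | None = None,
    response_directions: dict | None = None,
) -> float:
    """Percent of changed proteins that belong to a response gene set.

    With ``direction_aware`` the overlap additionally requires the sign of
    change (from ``directions``) to match the response set's sign (from
    ``response_directions``).
    """
    changed = frozenset(changed)
    response = frozenset(response_set)
    if not changed:
        raise UndefinedRatioError("empty changed set; congruence undefined")
    overlap = changed & response
    if direction_aware:
        if directions is None or response_directions is None:
            raise ValidationError(
                "direction_aware congruence requires both sign maps"
            )
        overlap = frozenset(
            p
            for p in overlap
            if np.sign(directions.get(p, 0)) == np.sign(response_directions.get(p, 0))
            and directions.get(p, 0) != 0
        )
    return 100.0 * len(overlap) / len(changed)
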