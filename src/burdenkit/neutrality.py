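"""Neutrality index (NI) and replicate group statistics.

The neutrality index scores how unconstrained an overexpressed protein is:
NI = %MGR x %protein, the product of the construct's maximum growth rate as
a percent of the vector control and its expression level as a percent of
total cellular protein.  A protein that can be expressed at high levels
while growth is maintained scores high (the study's least-constrained
protein reaches NI ~ 2400); a cytotoxic protein whose expression collapses
growth scores near 0.  Curves of constant NI in the (%protein, %MGR) plane
are the hyperbolas x*y = NI.

Group comparisons throughout use Welch's unequal-variance t-test with
Bonferroni correction, mirroring the replicate statistics of burden
experiments (three biological replicates per construct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "NeutralityRecord",
    "neutrality_index",
    "group_stats",
    "GroupComparison",
    "welch_test",
    "ni_isocline",
]


@dataclass(frozen=True)
class NeutralityRecord:
    """Per-construct neutrality index with replicate statistics."""

    construct: str
    pct_mgr: tuple[float, ...]
    pct_protein: tuple[float, ...]
    ni: tuple[float, ...]
    ni_mean: float
    ni_sd: float
    n_replicates: int


def neutrality_index(
    pct_mgr,
    pct_protein,
    construct: str = "",
    mode: str = "mean_of_products",
) -> NeutralityRecord:
    """Compute NI from paired replicate vectors of %MGR and %protein.

    Replicate i of %MGR pairs with replicate i of %protein (same culture);
    the default aggregation is the mean +/- SD of per-replicate products.
    ``mode="product_of_means"`` instead multiplies the two replicate means
    (its SD is propagated from the per-replicate products for reporting).
    """
    mgr = np.asarray(pct_mgr, dtype=float)
    prot = np.asarray(pct_protein, dtype=float)
    if mgr.ndim != 1 or prot.ndim != 1 or mgr.size != prot.size:
        raise ValidationError("pct_mgr and pct_protein must be equal-length vectors")
    if mgr.size < 1:
        raise ValidationError("at least one replicate required")
    if np.any(mgr < 0) or np.any(prot < 0):
        raise ValidationError("percentages must be nonnegative")
    products = mgr * prot
    if mode == "mean_of_products":
        ni_mean = float(np.mean(products))
    elif mode == "product_of_means":
        ni_mean = float(np.mean(mgr) * np.mean(prot))
    else:
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    ni_sd = float(np.std(products, ddof=1)) if products.size > 1 else 0.0
    return NeutralityRecord(
        construct=construct,
        pct_mgr=tuple(mgr),
        pct_protein=tuple(prot),
        ni=tuple(products),
        ni_mean=ni_mean,
        ni_sd=ni_sd,
        n_replicates=int(products.size),
    )


def welch_test(a, b) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances, Welch-Satterthwaite df).

    Returns (t statistic, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Welch's t-test requires >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    """Descriptive statistics per group plus Bonferroni-corrected Welch p-values
    of every non-reference group against the reference."""

    groups: tuple[str, ...]
    means: dict
    sds: dict
    ns: dict
    p_raw: dict
    p_adj: dict
    reference: str
    correction_m: int


def group_stats(
    values_by_group: dict,
    reference: str,
    correction_m: int | None = None,
) -> GroupComparison:
    """Summarise replicate groups and test each against a reference group.

    ``correction_m`` is the Bonferroni family size; it defaults to the
    number of non-reference groups (the comparisons sharing a figure
    panel).  Groups with fewer than two values get descriptive statistics
    but no test (p = NaN, with a warning).
    """
    import warnings

    if reference not in values_by_group:
        raise ValidationError(f"reference group {reference!r} not present")
    names = tuple(values_by_group)
    non_ref = [g for g in names if g != reference]
    m = correction_m if correction_m is not None else max(len(non_ref), 1)
    if m < 1:
        raise ValidationError("correction_m must be >= 1")

    means, sds, ns, p_raw, p_adj = {}, {}, {}, {}, {}
    ref_vals = np.asarray(values_by_group[reference], dtype=float)
    for g in names:
        v = np.asarray(values_by_group[g], dtype=float)
        means[g] = float(np.mean(v))
        sds[g] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        ns[g] = int(v.size)
    for g in non_ref:
        v = np.asarray(values_by_group[g], dtype=float)
        if v.size < 2 or ref_vals.size < 2:
            warnings.warn(
                f"group {g!r} or reference has < 2 replicates; test skipped",
                stacklevel=2,
            )
            p_raw[g] = float("nan")
            p_adj[g] = float("nan")
            continue
        _, p = welch_test(v, ref_vals)
        p_raw[g] = p
        p_adj[g] = min(1.0, m * p)
    return GroupComparison(
        groups=names,
        means=means,
        sds=sds,
        ns=ns,
        p_raw=p_raw,
        p_adj=p_adj,
        reference=reference,
        correction_m=m,
    )


def ni_isocline(ni: float, pct_protein: np.ndarray) -> np.ndarray:
    """%MGR values tracing the constant-NI hyperbola x*y = NI.

    Given %protein grid points x > 0, returns y = NI / x, so that
    x * y == NI identically (the theoretical neutrality regime lines).
    """
    x = np.asarray(pct_protein, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("pct_protein grid must be strictly positive")
    if ni < 0:
        raise ValidationError("NI must be nonnegative")
    return ni / x
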