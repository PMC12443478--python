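"""Gene-category rank-shift enrichment for fold-change tables.

Given a per-gene table of log2 fold changes (with per-gene FDR and
baseline abundance) and a map of functional categories (e.g. KEGG
Orthology level-3 sets read from GMT files), each sufficiently large
category is tested for a shift of its members' fold changes against the
background of genes outside the category, with a two-sided Mann-Whitney U
test and Benjamini-Hochberg control of the false discovery rate across
categories.  Variants cover between-condition comparisons of the same
category, analysis stratified by a gene partition (e.g. rapamycin-
responsive vs non-responsive populations), per-gene response
classification between two conditions, and condition-condition Pearson
correlation.

The Mann-Whitney U statistic counts pairs (x, y) with x from the
in-category sample ranked above y from the background, ties counting 1/2.
Small problems (n_in + n_out <= 12 by default) get an exact two-sided p by
enumerating all labelings; larger ones use the tie-corrected normal
approximation on midranks (no continuity correction).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRatioError, ValidationError

# Largest n_in + n_out for which the exact enumeration is used.
EXACT_ENUMERATION_LIMIT = 12
# "More than 10 gene elements": categories need >= 11 members in the table.
DEFAULT_MIN_SIZE = 11

__all__ = [
    "FoldChangeTable",
    "CategoryMap",
    "EnrichmentResult",
    "read_gmt",
    "mann_whitney",
    "bh_fdr",
    "category_shift_test",
    "between_condition_test",
    "partitioned_test",
    "classify_response",
    "condition_correlation",
    "RESPONSE_CLASSES",
]

RESPONSE_CLASSES = (
    "common_up",
    "common_down",
    "opposite",
    "a_specific",
    "b_specific",
    "ns",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-gene fold changes across conditions.

    ``data`` has one row per gene: gene_id (unique), log10cpm (baseline
    abundance in the control), and per condition a pair of columns
    log2fc_<cond> and fdr_<cond>.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "gene_id" not in df.columns:
            raise ValidationError("fold-change table requires a gene_id column")
        if df["gene_id"].duplicated().any():
            raise ValidationError("gene_id values must be unique")
        for cond in self.conditions:
            fdr = df[f"fdr_{cond}"]
            if ((fdr < 0) | (fdr > 1)).any():
                raise ValidationError(f"fdr_{cond} outside [0, 1]")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(
            c[len("log2fc_"):]
            for c in self.data.columns
            if c.startswith("log2fc_")
        )

    @property
    def gene_ids(self) -> pd.Series:
        return self.data["gene_id"]

    def require_condition(self, condition: str) -> None:
        if condition not in self.conditions:
            raise ValidationError(
                f"condition {condition!r} not in table; available: {self.conditions}"
            )

    def log2fc(self, condition: str) -> pd.Series:
        self.require_condition(condition)
        return self.data.set_index("gene_id")[f"log2fc_{condition}"]

    def fdr(self, condition: str) -> pd.Series:
        self.require_condition(condition)
        return self.data.set_index("gene_id")[f"fdr_{condition}"]

    @classmethod
    def from_tsv(cls, path) -> "FoldChangeTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CategoryMap:
    """Named gene sets; members may overlap across categories."""

    sets: dict
    source: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise ValidationError(f"category {name!r} is empty")
            clean[str(name)] = members
        object.__setattr__(self, "sets", clean)

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """Rank-shift test result for one category."""

    category_id: str
    n_in: int
    n_out: int
    u_statistic: float
    p_value: float
    fdr: float
    direction: int  # sign of median(in) - median(out)
    median_shift: float
    extra: dict = field(default_factory=dict)


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "category_id": r.category_id,
            "n_in": r.n_in,
            "n_out": r.n_out,
            "u_statistic": r.u_statistic,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "direction": r.direction,
            "median_shift": r.median_shift,
            **r.extra,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMT parsing
# ---------------------------------------------------------------------------


def read_gmt(path) -> CategoryMap:
    """Read gene sets from a GMT file (name, description, members...).

    Members are de-duplicated per set; empty sets are skipped with a
    warning; duplicate set names are an error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}: malformed GMT line {lineno}: expected >= 2 fields"
                )
            name = fields[0]
            members = frozenset(m for m in fields[2:] if m)
            if name in sets:
                raise ValidationError(f"{path}: duplicate category name {name!r}")
            if not members:
                warnings.warn(
                    f"{path}: category {name!r} at line {lineno} has no members; skipped",
                    stacklevel=2,
                )
                continue
            sets[name] = members
    return CategoryMap(sets=sets, source=str(path))


# ---------------------------------------------------------------------------
# Rank test and FDR primitives
# ---------------------------------------------------------------------------


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x vs y via midranks: U = R_x - n_x(n_x+1)/2."""
    n_x = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(np.sum(ranks[:n_x]) - n_x * (n_x + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all C(n, n_x) group labelings.

    Handles ties (midrank U takes half-integer values).  The two-sided p
    is the labeling fraction whose |U - n_x n_y / 2| is at least the
    observed one.
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    n_x = x.size
    n_y = y.size
    mu = n_x * n_y / 2.0
    ranks = stats.rankdata(pooled)
    obs_dev = abs(_u_statistic(x, y) - mu)
    rank_offset = n_x * (n_x + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_x):
        u = ranks[list(combo)].sum() - rank_offset
        # 1e-12 guards float midranks when comparing deviations for equality
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(x, y, exact_limit: int = EXACT_ENUMERATION_LIMIT) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of sample x against sample y.

    Returns (U for x, two-sided p).  Exact enumeration when the pooled
    size is at most ``exact_limit``; otherwise the tie-corrected normal
    approximation on midranks without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires nonempty samples")
    u = _u_statistic(x, y)
    if x.size + y.size <= exact_limit:
        return u, _exact_two_sided_p(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every value tied: U is exactly its null mean, no evidence either way
        return u, 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return u, float(res.pvalue)


def bh_fdr(p_values, by: bool = False) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    With ``by=True`` applies the Benjamini-Yekutieli correction factor
    (sum of reciprocals), valid under arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be a 1-D sequence")
    if p.size == 0:
        return np.array([])
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    factor = float(np.sum(1.0 / np.arange(1, m + 1))) if by else 1.0
    q = ranked * m * factor / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downward
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# Category-level workflows
# ---------------------------------------------------------------------------


def _background_universe(
    table: FoldChangeTable, cats: CategoryMap, assigned_only: bool
) -> frozenset:
    genes = frozenset(table.gene_ids)
    if assigned_only:
        return genes & cats.universe
    return genes


def category_shift_test(
    table: FoldChangeTable,
    cats: CategoryMap,
    condition: str,
    min_size: int = DEFAULT_MIN_SIZE,
    assigned_only_background: bool = True,
) -> list[EnrichmentResult]:
    """Test each category for a fold-change shift against the background.

    For every category with at least ``min_size`` members present in the
    table, the members' log2 fold changes under ``condition`` are compared
    with those of the background (by default all genes assigned to at
    least one category, excluding the focal category) by a two-sided
    Mann-Whitney U test.  BH-adjusted FDR is computed across all tested
    categories; results are sorted by FDR, then p, then name.
    """
    table.require_condition(condition)
    fc = table.log2fc(condition)
    universe = _background_universe(table, cats, assigned_only_background)
    if not universe:
        raise ValidationError("background universe is empty")

    tested: list[EnrichmentResult] = []
    for name in sorted(cats.sets):
        members = cats.sets[name] & frozenset(fc.index)
        if len(members) < min_size:
            continue
        out_genes = universe - members
        if not out_genes:
            continue
        x = fc.loc[sorted(members)].to_numpy()
        y = fc.loc[sorted(out_genes)].to_numpy()
        u, p = mann_whitney(x, y)
        shift = float(np.median(x) - np.median(y))
        tested.append(
            EnrichmentResult(
                category_id=name,
                n_in=len(members),
                n_out=len(out_genes),
                u_statistic=u,
                p_value=p,
                fdr=np.nan,
                direction=int(np.sign(shift)),
                median_shift=shift,
            )
        )
    if not tested:
        warnings.warn("no category reaches min_size; empty result", stacklevel=2)
        return []
    q = bh_fdr([r.p_value for r in tested])
    tested = [
        EnrichmentResult(
            category_id=r.category_id,
            n_in=r.n_in,
            n_out=r.n_out,
            u_statistic=r.u_statistic,
            p_value=r.p_value,
            fdr=float(qi),
            direction=r.direction,
            median_shift=r.median_shift,
            extra=r.extra,
        )
        for r, qi in zip(tested, q)
    ]
    return sorted(tested, key=lambda r: (r.fdr, r.p_value, r.category_id))


def between_condition_test(
    table: FoldChangeTable,
    cats: CategoryMap,
    condition_a: str,
    condition_b: str,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[EnrichmentResult]:
    """Test each category's members for a shift between two conditions.

    Per category, the members' log2 fold changes under ``condition_a`` are
    compared with the same members' values under ``condition_b``
    (two-sided Mann-Whitney U, unpaired); BH across categories.  Flags the
    categories whose response differs between the two overexpression
    conditions.
    """
    fc_a = table.log2fc(condition_a)
    fc_b = table.log2fc(condition_b)
    tested: list[EnrichmentResult] = []
    for name in sorted(cats.sets):
        members = sorted(cats.sets[name] & frozenset(fc_a.index))
        if len(members) < min_size:
            continue
        x = fc_a.loc[members].to_numpy()
        y = fc_b.loc[members].to_numpy()
        u, p = mann_whitney(x, y)
        shift = float(np.median(x) - np.median(y))
        tested.append(
            EnrichmentResult(
                category_id=name,
                n_in=len(members),
                n_out=len(members),
                u_statistic=u,
                p_value=p,
                fdr=np.nan,
                direction=int(np.sign(shift)),
                median_shift=shift,
            )
        )
    if not tested:
        warnings.warn("no category reaches min_size; empty result", stacklevel=2)
        return []
    q = bh_fdr([r.p_value for r in tested])
    out = [
        EnrichmentResult(
            category_id=r.category_id,
            n_in=r.n_in,
            n_out=r.n_out,
            u_statistic=r.u_statistic,
            p_value=r.p_value,
            fdr=float(qi),
            direction=r.direction,
            median_shift=r.median_shift,
        )
        for r, qi in zip(tested, q)
    ]
    return sorted(out, key=lambda r: (r.fdr, r.p_value, r.category_id))


def partitioned_test(
    table: FoldChangeTable,
    cats: CategoryMap,
    partition,
    condition: str,
    min_size: int = DEFAULT_MIN_SIZE,
    assigned_only_background: bool = True,
) -> dict:
    """Run the category shift test within a gene partition and its complement.

    ``partition`` is a set of gene ids defining one stratum (e.g. the
    rapamycin-responsive population); the remaining table genes form the
    complementary stratum.  Each stratum is tested independently; the
    per-category split counts across strata (the "12/32"-style counts) are
    attached to each result's ``extra``.

    Returns {"partition": [...], "complement": [...]}; an empty stratum
    yields an empty list.
    """
    partition = frozenset(partition)
    all_genes = frozenset(table.gene_ids)
    strata = {
        "partition": partition & all_genes,
        "complement": all_genes - partition,
    }
    out: dict = {}
    for label, genes in strata.items():
        if not genes:
            out[label] = []
            continue
        sub = FoldChangeTable(
            table.data[table.data["gene_id"].isin(genes)].reset_index(drop=True)
        )
        try:
            results = category_shift_test(
                sub,
                cats,
                condition,
                min_size=min_size,
                assigned_only_background=assigned_only_background,
            )
        except ValidationError:
            results = []
        annotated = []
        for r in results:
            members_total = len(cats.sets[r.category_id] & all_genes)
            annotated.append(
                EnrichmentResult(
                    category_id=r.category_id,
                    n_in=r.n_in,
                    n_out=r.n_out,
                    u_statistic=r.u_statistic,
                    p_value=r.p_value,
                    fdr=r.fdr,
                    direction=r.direction,
                    median_shift=r.median_shift,
                    extra={"stratum": label, "n_stratum_of_total": f"{r.n_in}/{members_total}"},
                )
            )
        out[label] = annotated
    return out


def classify_response(
    table: FoldChangeTable,
    condition_a: str,
    condition_b: str,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """Classify each gene's response across two conditions.

    Labels: common_up / common_down (significant in both, same sign),
    opposite (significant in both, opposite signs), a_specific /
    b_specific (significant in exactly one), ns (neither).
    Significance is fdr < fdr_threshold.
    """
    if not 0 < fdr_threshold <= 1:
        raise ValidationError("fdr_threshold must be in (0, 1]")
    fc_a, fc_b = table.log2fc(condition_a), table.log2fc(condition_b)
    sig_a = table.fdr(condition_a) < fdr_threshold
    sig_b = table.fdr(condition_b) < fdr_threshold

    labels = pd.Series("ns", index=fc_a.index, name="response_class")
    both = sig_a & sig_b
    same_sign = np.sign(fc_a) == np.sign(fc_b)
    labels[both & same_sign & (fc_a > 0)] = "common_up"
    labels[both & same_sign & (fc_a < 0)] = "common_down"
    labels[both & ~same_sign] = "opposite"
    labels[sig_a & ~sig_b] = "a_specific"
    labels[~sig_a & sig_b] = "b_specific"
    return labels


def condition_correlation(
    table: FoldChangeTable, condition_a: str, condition_b: str
) -> float:
    """Pearson correlation of log2 fold changes between two conditions."""
    a = table.log2fc(condition_a).to_numpy()
    b = table.log2fc(condition_b).to_numpy()
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3:
        raise ValidationError("correlation requires >= 3 genes with both values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedRatioError("zero variance in a fold-change vector")
    return float(stats.pearsonr(a, b).statistic)
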