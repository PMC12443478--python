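"""Seeded generators for every input the pipeline consumes, with recorded
ground truth.

A ``BurdenScenario`` describes a simulated overexpression-burden
experiment: constructs with known target-protein fractions, a growth link
that converts expression fraction into a specific growth rate, lane
densitometry with known composition, per-gene fold-change tables with
designed category shifts, and protein x sample intensity matrices with a
dominant target protein, compensatory reduction of the rest, and dropout
zeros.  Every generator is driven by an independent substream of the
scenario seed (fixed spawn keys), so adding or reordering generator calls
never perturbs another generator's draws and identical scenarios are
bit-reproducible.

The growth link mu(f) = mu0 * max(0, 1 - beta * (f - f0)_+) is a
piecewise-linear convention for the test harness: growth is unaffected
until the target fraction passes the burden onset f0 and then declines
linearly.  It is a harness, not a biological model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densitometry import LaneQuant
from .enrichment import FoldChangeTable, CategoryMap, bh_fdr
from .errors import ValidationError
from .growth import GrowthCurve
from .proteome import ProteomeMatrix
from scipy import stats

# Fixed spawn keys: one independent random substream per artifact type.
_KEY_GROWTH = 1
_KEY_LANES = 2
_KEY_FC = 3
_KEY_PROTEOME = 4
_KEY_PARTITION = 5

__all__ = [
    "Construct",
    "BurdenScenario",
    "burden_mu",
    "gen_growth_curves",
    "gen_lane_table",
    "gen_fc_table",
    "gen_proteome",
    "gen_partition",
]


@dataclass(frozen=True)
class Construct:
    """One overexpression construct with its ground-truth composition.

    target_fraction f is the target protein's share of total protein in
    [0, 1); other_scale is the total of the remaining proteins relative to
    the control (None means 1 - f: total protein per cell conserved, the
    behaviour seen for least-constrained proteins).
    """

    name: str
    target_fraction: float = 0.0
    other_scale: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction < 1.0:
            raise ValidationError("target_fraction must lie in [0, 1)")
        if self.other_scale is not None and self.other_scale <= 0:
            raise ValidationError("other_scale must be > 0")

    @property
    def background_scale(self) -> float:
        return (
            1.0 - self.target_fraction if self.other_scale is None else self.other_scale
        )


@dataclass(frozen=True)
class BurdenScenario:
    """Parameters of a simulated burden experiment.

    Growth defaults emulate batch yeast cultures in synthetic medium
    sampled every 10 min (mu0 = 0.35 /h, logistic to K = 2.0 OD); the
    burden link's onset f0 = 0.15 and slope beta = 1.55 place a
    least-constrained construct at f = 0.44 near 55% relative growth
    (analytic NI ~ 2420).  The fold-change design defaults to the scale of
    a yeast transcriptome (6685 genes, 47 categories); the proteome
    design, to a DIA run (4000 background proteins, lognormal intensities,
    per-cell dropout rate 2.7% so that ~85% of proteins survive the
    zero filter across six samples, the survival level seen in real DIA
    matrices of this kind).
    """

    seed: int
    constructs: tuple[Construct, ...] = (
        Construct("Vector", 0.0),
        Construct("moxYG", 0.44),
    )
    replicates: int = 3
    # growth link and logistic curve
    mu0: float = 0.35  # per hour
    beta: float = 1.55
    f0: float = 0.15
    n0: float = 0.05  # inoculation OD
    carrying_capacity: float = 2.0  # final OD
    t_max_min: float = 3000.0
    dt_min: float = 10.0
    # noise levels (coefficients of variation)
    cv_od: float = 0.02
    cv_lane: float = 0.05
    cv_intensity: float = 0.20
    # lane design
    n_background_bands: int = 12
    lane_total: float = 1000.0
    # fold-change table design
    n_genes: int = 6685
    n_categories: int = 47
    category_size: int = 30
    fc_conditions: tuple[str, ...] = ("mox", "moxYG")
    category_shifts: dict = field(default_factory=dict)  # cond -> {category: delta}
    partition_restricted: frozenset = frozenset()  # {(cond, category)} shifted in partition only
    gene_sigma: float = 0.5
    fc_replicates: int = 3
    partition_fraction: float = 0.3
    # proteome design
    n_proteins: int = 4000
    log_mu: float = 8.0
    log_sigma: float = 1.2
    dropout: float = 0.027

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for cv in (self.cv_od, self.cv_lane, self.cv_intensity):
            if cv < 0:
                raise ValidationError("noise CVs must be >= 0")
        if self.n_categories * self.category_size > self.n_genes:
            raise ValidationError("category sizes exceed the gene universe")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must lie in [0, 1)")
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ValidationError("construct names must be unique")

    def construct(self, name: str) -> Construct:
        for c in self.constructs:
            if c.name == name:
                return c
        raise ValidationError(f"unknown construct {name!r}")

    def mu_of(self, f: float) -> float:
        return burden_mu(f, self.mu0, self.beta, self.f0)


def burden_mu(f: float, mu0: float, beta: float, f0: float) -> float:
    """Piecewise-linear burden link: mu0 until f0, then linear decline."""
    return mu0 * max(0.0, 1.0 - beta * max(0.0, f - f0))


def _rng(scenario: BurdenScenario, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=key))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def gen_growth_curves(scenario: BurdenScenario) -> list[GrowthCurve]:
    """Logistic growth curves for every construct x replicate.

    N(t) = K / (1 + (K/N0 - 1) exp(-mu t)) with mu from the burden link,
    multiplied by lognormal noise of CV ``cv_od``.  The true mu (per hour)
    is recorded in each curve's meta under "true_mu".
    """
    times = np.arange(0.0, scenario.t_max_min + scenario.dt_min / 2, scenario.dt_min)
    curves: list[GrowthCurve] = []
    for ci, construct in enumerate(scenario.constructs):
        mu_h = scenario.mu_of(construct.target_fraction)
        mu_min = mu_h / 60.0
        k = scenario.carrying_capacity
        ratio = k / scenario.n0 - 1.0
        clean = k / (1.0 + ratio * np.exp(-mu_min * times))
        for rep in range(scenario.replicates):
            rng = _rng(scenario, _KEY_GROWTH, ci, rep)
            od = clean * _lognoise(rng, scenario.cv_od, times.size)
            curves.append(
                GrowthCurve(
                    times=times,
                    od=od,
                    strain=construct.name,
                    condition="-LeuUra",
                    replicate=rep,
                    meta={"true_mu": mu_h, "target_fraction": construct.target_fraction},
                )
            )
    return curves


# ---------------------------------------------------------------------------
# Lane densitometry
# ---------------------------------------------------------------------------


def gen_lane_table(scenario: BurdenScenario, construct_name: str) -> list[LaneQuant]:
    """Band-intensity lanes for one construct, one lane per replicate.

    The target band carries fraction f of the lane signal; the remaining
    signal is split over ``n_background_bands`` by a fixed random
    partition shared across constructs and replicates (the same cellular
    proteome seen in every lane), scaled by the construct's
    background_scale; every band gets lognormal noise of CV ``cv_lane``.
    """
    construct = scenario.construct(construct_name)
    # shared background partition: one draw, fixed substream
    part_rng = _rng(scenario, _KEY_LANES, 0)
    weights = part_rng.dirichlet(np.full(scenario.n_background_bands, 5.0))

    f = construct.target_fraction
    background_total = construct.background_scale * scenario.lane_total
    target_clean = background_total * f / (1.0 - f) if f > 0 else 0.0

    ci = [c.name for c in scenario.constructs].index(construct_name)
    lanes: list[LaneQuant] = []
    for rep in range(scenario.replicates):
        rng = _rng(scenario, _KEY_LANES, 1 + ci, rep)
        noise = _lognoise(rng, scenario.cv_lane, scenario.n_background_bands + 1)
        bands = [("target", target_clean * noise[0])]
        for b in range(scenario.n_background_bands):
            bands.append((f"bg{b:02d}", background_total * weights[b] * noise[b + 1]))
        lanes.append(
            LaneQuant(
                lane_id=f"{construct_name}_rep{rep}",
                bands=tuple(bands),
                target_band_id="target",
                strain=construct_name,
                condition="-LeuUra",
                replicate=rep,
                od_units_loaded=1.0,
                meta={"true_f": f, "true_background_scale": construct.background_scale},
            )
        )
    return lanes


# ---------------------------------------------------------------------------
# Fold-change tables and partitions
# ---------------------------------------------------------------------------


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def default_category_map(scenario: BurdenScenario) -> CategoryMap:
    """Disjoint categories C00.. of ``category_size`` genes over the
    scenario's gene universe (genes beyond the categories stay unassigned,
    mirroring real category systems that cover only part of a genome)."""
    ids = _gene_ids(scenario.n_genes)
    sets = {}
    for c in range(scenario.n_categories):
        start = c * scenario.category_size
        sets[f"C{c:02d}"] = frozenset(ids[start : start + scenario.category_size])
    return CategoryMap(sets=sets, source="synthetic")


def gen_partition(scenario: BurdenScenario) -> frozenset:
    """A random gene stratum (e.g. a drug-responsive population) of the
    scenario's ``partition_fraction``, drawn from its own substream."""
    rng = _rng(scenario, _KEY_PARTITION)
    ids = np.array(_gene_ids(scenario.n_genes))
    mask = rng.random(ids.size) < scenario.partition_fraction
    return frozenset(ids[mask])


def gen_fc_table(
    scenario: BurdenScenario,
) -> tuple[FoldChangeTable, CategoryMap, dict]:
    """Per-gene fold-change table with designed category shifts.

    Null genes' log2FC is Normal(0, gene_sigma) (averaged over
    ``fc_replicates`` replicate draws); members of a category listed in
    ``category_shifts[condition]`` get their mean shifted by delta, and
    shifts for (condition, category) pairs in ``partition_restricted``
    apply only to genes inside the scenario partition.  Per-gene p-values
    come from the z-test of the replicate mean against the known replicate
    noise, BH-adjusted per condition, so the table's FDR columns are
    internally consistent with its fold changes.

    Returns (table, category map, truth) where truth records the shifted
    categories, their deltas, and the partition.
    """
    cats = default_category_map(scenario)
    partition = gen_partition(scenario)
    ids = _gene_ids(scenario.n_genes)
    idx = {g: i for i, g in enumerate(ids)}
    rng = _rng(scenario, _KEY_FC)

    data = {"gene_id": ids, "log10cpm": rng.normal(2.0, 0.5, scenario.n_genes)}
    se = scenario.gene_sigma / np.sqrt(scenario.fc_replicates)
    truth_shifts: dict = {}
    for cond in scenario.fc_conditions:
        shift = np.zeros(scenario.n_genes)
        for cat, delta in scenario.category_shifts.get(cond, {}).items():
            members = cats.sets[cat]
            if (cond, cat) in scenario.partition_restricted:
                members = members & partition
            for g in members:
                shift[idx[g]] = delta
            truth_shifts.setdefault(cond, {})[cat] = delta
        reps = rng.normal(
            shift[:, None], scenario.gene_sigma, (scenario.n_genes, scenario.fc_replicates)
        )
        observed = reps.mean(axis=1)
        z = observed / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        data[f"log2fc_{cond}"] = observed
        data[f"fdr_{cond}"] = bh_fdr(p)

    table = FoldChangeTable(pd.DataFrame(data))
    truth = {
        "shifted": truth_shifts,
        "partition": partition,
        "partition_restricted": set(scenario.partition_restricted),
        "gene_sigma": scenario.gene_sigma,
    }
    return table, cats, truth


# ---------------------------------------------------------------------------
# Proteome matrices
# ---------------------------------------------------------------------------


def gen_proteome(
    scenario: BurdenScenario, construct_name: str
) -> tuple[ProteomeMatrix, dict]:
    """Protein x sample matrix for a control and one burden condition.

    Background protein abundances are lognormal (log_mu, log_sigma), shared
    between conditions; under burden the background is scaled by the
    construct's background_scale and the target protein is injected so that
    its noise-free share of the total is exactly the construct's
    target_fraction.  Dropout zeros hit background cells independently at
    the ``dropout`` rate (the dominant target is never dropped).  The
    control condition is named "Vector"; the target row is 0 there.

    Returns (matrix, truth) with truth recording f and the background scale.
    """
    construct = scenario.construct(construct_name)
    if construct_name == "Vector":
        raise ValidationError("construct must differ from the control 'Vector'")
    rng = _rng(scenario, _KEY_PROTEOME, [c.name for c in scenario.constructs].index(construct_name))

    n = scenario.n_proteins
    base = np.exp(rng.normal(scenario.log_mu, scenario.log_sigma, n))
    total_base = float(base.sum())
    f = construct.target_fraction
    bg_scale = construct.background_scale

    cols = {}
    sample_meta = {}
    n_rep = scenario.replicates
    target_base_burden = (
        bg_scale * total_base * f / (1.0 - f) if f > 0 else 0.0
    )
    for rep in range(n_rep):
        noise = _lognoise(rng, scenario.cv_intensity, n)
        cols[f"Vector_r{rep + 1}"] = np.concatenate([base * noise, [0.0]])
        sample_meta[f"Vector_r{rep + 1}"] = ("Vector", rep + 1)
    for rep in range(n_rep):
        noise = _lognoise(rng, scenario.cv_intensity, n)
        t_noise = _lognoise(rng, scenario.cv_intensity, 1)[0]
        cols[f"{construct_name}_r{rep + 1}"] = np.concatenate(
            [base * bg_scale * noise, [target_base_burden * t_noise]]
        )
        sample_meta[f"{construct_name}_r{rep + 1}"] = (construct_name, rep + 1)

    protein_ids = [f"P{i:05d}" for i in range(n)] + [f"TARGET_{construct_name}"]
    df = pd.DataFrame(cols, index=pd.Index(protein_ids, name="protein_id"))

    if scenario.dropout > 0:
        drop = rng.random((n, len(df.columns))) < scenario.dropout
        values = df.to_numpy()
        values[:-1][drop] = 0.0  # target row exempt
        df = pd.DataFrame(values, index=df.index, columns=df.columns)

    matrix = ProteomeMatrix(
        intensities=df,
        samples=sample_meta,
        target_protein_id=f"TARGET_{construct_name}",
    )
    truth = {
        "f": f,
        "background_scale": bg_scale,
        "dropout": scenario.dropout,
        "n_background_proteins": n,
    }
    return matrix, truth
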