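# Methods

This note documents the statistical procedures burdenkit implements, the
parameters that matter, the synthetic-data model behind the test suite, and
the design choices made where the methodology was genuinely open.

## Maximum growth rate (MGR)

A batch growth curve (OD₆₆₀ vs time, typically every 10 min) is summarised
by the steepest sustained slope of its log-OD trace. The estimator slides
every contiguous window of fixed duration `window_min` (default 120 min,
which spans 13 samples at 10-min sampling) along the series, fits ordinary
least squares to ln(OD − blank) within the window, and reports the maximum
slope — converted from per-minute to per-hour — among windows whose mean OD
is at least `od_floor` (default 0.05). The floor keeps pre-growth baseline
noise from winning the maximisation; both knobs are exposed because the
appropriate window length depends on sampling rate and the floor on the
instrument's blank level. Values at or below the blank are clipped to a
small epsilon, excluded from the log fit, and flagged with a warning; at
least 8 points above the floor and 5 points per window are required,
otherwise an explicit "insufficient growth" error is raised.

Reported alongside: the maximising window, the window fit's R², the final
(maximum) OD, and a **lag time** defined as the time where the maximising
window's exponential, extrapolated backwards, crosses the first observed
OD. This lag definition is a convention — simple, deterministic, and
adequate for ranking constructs — not an inference about physiology.

Two numerical properties worth knowing:

- On noise-free exponential data the estimator is exact to machine
  precision for any window length that fits the series (tested).
- On *logistic* data the windowed log-slope underestimates the intrinsic
  rate by roughly the mean of N/K over the maximising window (≈3.5% for
  the defaults N₀ = 0.05, K = 2.0). Because every strain in an experiment
  shares this geometry, the bias cancels almost exactly in the %MGR ratio
  (<1% residual in tests), which is the quantity the neutrality index
  consumes. Absolute per-hour rates from saturating curves should be read
  with this bias in mind.

Generic kinetic series (reporter fluorescence, oxygen-probe fluorescence)
are summarised by their maximum value and by the OLS slope of signal vs
time respectively.

## Densitometry

Lane tables list band intensities (arbitrary units) per gel lane, with one
band optionally marked as the overexpressed target. The target's *percent
of total* is 100 · target / (sum of all listed bands); all listed bands are
summed, since instrument software differs in how it reports faint
background bands and the caller controls the band list. Relative total
protein across strains divides each lane's total by the OD units of cells
loaded, pairs replicates by index, and reports the mean ± SD of the
per-replicate ratios (×100); with `exclude_target` the target band is
removed from the sample totals first, giving the "other proteins" quantity
that reveals synthesis competition. No gel-image processing is attempted —
image densitometry is instrument-specific and belongs upstream.

## Neutrality index

NI = %MGR × %protein, computed per replicate (replicate i of %MGR pairs
with replicate i of %protein — same culture) and then averaged, with the SD
taken over the per-replicate products. The alternative aggregation
(product of the two replicate means) is exposed but not the default: the
mean-of-products matches per-replicate bar-plot presentation and keeps the
SD meaningful. Because both inputs are percentages, NI is invariant to the
arbitrary units of densitometry and to the time units of growth-rate
estimation. Constant-NI curves in the (%protein, %MGR) plane are the
hyperbolas x·y = NI; `ni_isocline` evaluates them exactly.

Group comparisons use Welch's unequal-variance t-test (Welch–Satterthwaite
degrees of freedom, two-sided) with Bonferroni correction; the family size
defaults to the number of non-reference groups in the comparison. Groups
with fewer than two replicates get descriptive statistics and a warning
instead of a test.

## Category rank-shift enrichment

For each category with **at least 11** members present in the fold-change
table ("more than 10"), the members' log2FC values are compared with a
background by a two-sided Mann–Whitney U test. Choices:

- **Background**: by default all genes assigned to ≥1 category, minus the
  focal category's members. Category systems typically cover only part of
  a genome, and unassigned genes are often systematically unusual
  (dubious ORFs, unannotated genes); a flag switches to the full table.
- **Multi-membership**: a gene in several categories is "in" for its focal
  test and part of the background for all others; no exclusivity is
  enforced.
- **Exactness**: for pooled sizes ≤ 12 the two-sided p is computed by
  enumerating all C(n, n_in) labelings (correct under ties, since it works
  on midranks); larger problems use the tie-corrected normal approximation
  on midranks without continuity correction. A degenerate sample in which
  every pooled value is identical returns p = 1.
- **FDR**: Benjamini–Hochberg step-up across the tested categories
  (Benjamini–Yekutieli available via flag). The direction of each
  category's shift is the sign of median(in) − median(out).

The between-condition variant compares the *same* category members' log2FC
under two conditions (unpaired Mann–Whitney, BH across categories) —
flagging categories whose response differs between two overexpression
conditions. The partitioned variant re-runs the in-vs-out test separately
inside a gene stratum (e.g. a drug-responsive population) and its
complement, reporting each category's stratum split ("12/32"-style counts).

Per-gene response classification between two conditions uses fdr < 0.05
(configurable) for significance and assigns `common_up`, `common_down`,
`opposite`, `a_specific`, `b_specific`, or `ns`. Condition–condition
similarity is the Pearson correlation of the two log2FC vectors.

## Proteome composition

The zero filter drops every protein with a zero intensity in *any* sample —
the most conservative treatment of missingness, trading coverage for the
guarantee that all downstream log operations are defined without
imputation or pseudocounts (log operations on unfiltered matrices are
rejected by contract). Per-protein log2FC is the difference of mean log2
intensities between conditions (unpaired, robust to replicate ordering; a
paired mode averages per-pair ratios), with Welch's t on log2 intensities
and BH across proteins; the test choice is a standard reconstruction for
three-replicate intensity data.

Total correction rescales each non-reference sample by (mean total of
reference samples) / (own total), leaving reference samples untouched.
It conserves within-sample proportions exactly and is idempotent; it
converts compositional statements into approximate per-cell statements
under the assumption — supported by densitometry — that total protein per
cell is constant. The overexpression fraction is the target's percent of
total signal per sample, averaged within a condition; an absent target
returns 0 with a warning rather than an error, because absence from a
search output is itself informative. Congruence with a response set is the
percentage of changed proteins (fdr < 0.05) found in the set, optionally
requiring matching direction signs.

## Synthetic-data model

A `BurdenScenario` fixes every parameter and one seed; each generator draws
from its own `SeedSequence` substream (fixed spawn keys), so outputs are
bit-reproducible and adding one generator never perturbs another's draws.

- **Growth link**: μ(f) = μ₀ · max(0, 1 − β·(f − f₀)₊), with defaults
  μ₀ = 0.35 h⁻¹ (a typical batch rate for yeast in synthetic medium),
  onset f₀ = 0.15 (the expression fraction where burden effects begin for
  minimally constrained proteins), and slope β = 1.55, placing a construct
  at f = 0.44 near 55% relative growth (analytic NI ≈ 2422). This
  piecewise-linear link is a test harness chosen once for the suite — it
  is *not* a biological model of burden.
- **Curves**: logistic, N₀ = 0.05, K = 2.0 OD, 10-min sampling to 3000
  min, multiplicative lognormal noise CV 2% (plate-reader scale).
- **Lanes**: one target band at fraction f of the lane plus 12 background
  bands splitting the remainder by a fixed Dirichlet partition shared
  across lanes (the same cellular proteome in every lane), lognormal noise
  CV 5%; the background total scales by the construct's `other_scale`
  (default 1 − f: total protein per cell conserved).
- **Fold-change tables**: 6685 genes, 47 disjoint 30-gene categories
  (the rest unassigned), per-gene log2FC = designed shift + Normal(0,
  σ = 0.5) averaged over 3 replicate draws; per-gene p-values from the
  z-test of the replicate mean against the known noise, BH-adjusted, so the
  FDR columns are internally consistent with the fold changes. Shifts can
  be restricted to a random partition (default 30% of genes).
- **Proteomes**: 4000 background proteins with lognormal abundances
  (ln-scale μ = 8, σ = 1.2), replicate noise CV 20% (DIA scale); under
  burden the background scales by `other_scale` and the target is injected
  so its noise-free share is exactly f; dropout zeros hit background cells
  independently at rate 2.7% per cell, so ~85% of proteins survive the
  six-sample zero filter — the survival level of real DIA matrices of this
  kind. The dominant target is never dropped.

What the generator does **not** emulate: count-based sampling noise and
library-size effects of sequencing, correlated gene modules, mean–variance
relationships of intensities, batch effects, or any mechanistic coupling
between the omics layers and the growth link. Passing tests therefore
demonstrate correctness of the estimators and error control under the
stated noise model, not robustness to every artefact of real data.

## Problem sizes used in the checks

The statistical checks run at: 200 random small instances for rank-test
exactness; 100 seeded tables each for enrichment type-I error and power
(δ = 1, σ = 0.5, 30-member categories); 200 simulations for MGR accuracy at
2% OD noise; 50 seeds for end-to-end recovery (f = 0.44) and for the
proteome composition properties (1000-protein matrices, plus one
4241-protein matrix for the zero-filter survivor count). These sizes give
stable rates while keeping the whole suite fast on a single CPU.

## Known limitations

- The MGR window length and OD floor are conventions; rates from curves
  that saturate quickly carry the logistic bias described above.
- The enrichment background choice (assigned-only vs all genes) can change
  borderline categories; both modes are provided, and the default is
  stated above.
- The Bonferroni family size for panel comparisons is caller-controlled;
  cross-panel multiplicity is not managed automatically.
- `congruence_fraction` treats the response set as fixed and error-free;
  uncertainty in the response set itself is not propagated.
- Reported NI error bars are the SD of per-replicate products; no joint
  error propagation from the MGR and densitometry stages is attempted.
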