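# burdenkit

Quantitative analysis of **protein-overexpression burden** experiments in
budding yeast (and similar microbial systems).

When a gratuitous protein — one with no function, toxicity, or interaction
partners — is forced to very high expression, growth eventually slows simply
because the protein-synthesis machinery is overloaded. Separating this pure
*protein burden* from protein-specific cytotoxicity requires scoring each
construct by how much expression it achieves *and* how much growth it keeps.
burdenkit implements that scoring and the downstream omics analytics used to
characterise the burdened cell state.

## What it computes

**Neutrality index.** For a construct expressed to its limit,

```
NI = %MGR × %protein
```

where %MGR is the maximum specific growth rate as a percent of the vector
control and %protein is the construct's expression as a percent of total
cellular protein (from SDS-PAGE lane densitometry). Constructs with equal NI
lie on the hyperbola `x·y = NI` in the (%protein, %MGR) plane; a high NI
means high expression with little growth penalty (low cytotoxicity), a low
NI means the protein is constrained. MGR itself is the maximum
ordinary-least-squares slope of ln OD₆₆₀ over sliding fixed-duration windows
(default 120 min, mean-OD floor 0.05) of a batch growth curve sampled every
10 min.

**Category rank-shift enrichment.** Given a per-gene table of log2 fold
changes, each functional category (e.g. KEGG Orthology level-3 sets, read
from GMT) with more than 10 members is tested for a shift of its members'
fold changes against the background of all assigned genes outside the
category, with a two-sided Mann–Whitney U test (exact by enumeration for
pooled n ≤ 12, tie-corrected normal approximation otherwise) and
Benjamini–Hochberg FDR across categories. Variants: between-condition
category tests, analysis stratified by a gene partition (e.g.
rapamycin-responsive vs non-responsive populations), per-gene response
classification, and condition–condition Pearson correlation.

**Proteome composition.** Protein × sample intensity matrices are
conservatively preprocessed by dropping any protein with a zero in any
sample; per-protein log2 fold changes use Welch's t-test on log intensities
plus BH FDR; matrices can be analysed as raw composition or rescaled so each
sample's total signal matches the control ("total correction"); the target's
share of total signal and the overlap of changed proteins with a response
gene set (e.g. TORC1-regulated proteins) are reported.

**Synthetic data.** A seeded `BurdenScenario` generates every input with
known ground truth: logistic growth curves whose rate declines linearly with
the target protein fraction above a burden onset, noisy lane tables, fold-
change tables with designed category shifts, and proteome matrices with a
dominant target protein, compensatory reduction of the rest, and dropout
zeros. See `docs/methods.md` for the model and defaults.

## Worked example

Generate a synthetic experiment and score it:

```
burdenkit simulate --seed 7 --out sim/
burdenkit ni --curves sim/curves.csv --lanes sim/lanes.tsv --out-dir out/
```

`out/ni.tsv` then contains (seed 7, default scenario):

```
construct  pct_mgr_mean  pct_mgr_sd   pct_protein_mean  pct_protein_sd  ni_mean  ni_sd    n  p_adj_vs_reference
Vector     100           1.42109e-14  0                 0               0        0        3
moxYG      58.0337       0.293851     43.8743           0.872838        2546.29  59.5619  3  1.70913e-06
```

The burden construct is expressed at ~44% of total protein while keeping
~58% of the control growth rate, giving NI ≈ 2550 — the signature of a
nearly unconstrained protein (the scenario's analytic NI is 2422). The
Bonferroni-corrected Welch p-value compares its raw growth-rate replicates
with the vector control's. Library equivalents: `estimate_mgr`,
`percent_of_total`, `neutrality_index`. The omics side works the same way
(`burdenkit enrich`, `burdenkit proteome`, or `category_shift_test` /
`per_protein_fc` in Python).

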