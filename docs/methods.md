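# Methods

## Model and procedure

`gesrev` treats a gene-expression signature as an unranked pair of disjoint
gene-symbol sets (up- and down-regulated).  All similarity is set-based: the
signed Jaccard index (SJI) combines the four directional Jaccard
coefficients,

    SJI = ( J(up1,up2) + J(down1,down2) − J(up1,down2) − J(down1,up2) ) / 2 ,

and is computed exactly in double precision (the implementation groups the
terms as `(J_uu − J_ud) + (J_dd − J_du)` so that swapping one signature's
directions negates the value bit-exactly).  No rank- or weight-based variant
is offered: the score's point is direction-aware membership overlap.

The analysis unit is the *unique pair*: the unweighted mean SJI over all
signature-level combinations of one drug name and one disease name.
Indicated pairs are those listed in the user-supplied indication table
(curated from FDA "indications and usage" label sections); every other
unique pair is a control — the full non-indicated cross, never a sample.
Signature-count per pair is retained in the output so a weighted
re-aggregation remains possible downstream.

### Inclusion protocol

Filters apply in a fixed order, each signature excluded at most once:
organism allow-list (case-insensitive, with a small synonym table so
"Homo sapiens" matches "human"), drug-approval snapshot (an explicit name
list — never an API call, for reproducibility), explicit exclusion ids
(signatures known to be mis-specified at the source), and dual-label
resolution: a GEO series contributing both drug and disease signatures had
one assay labelled twice, so one side is dropped (default: keep the disease
side).  A final pruning pass removes signatures that cannot participate in
any indicated pair, iterated to a fixed point because removals cascade.
The filter report conserves counts (input = retained + Σ excluded) and is
asserted on every run.

Gene symbols are uppercased and stripped, nothing more: alias mapping would
silently change intersection/union counts in ways that cannot be verified
against the source collections.  A gene listed in both directions of one
signature is contradictory and is removed from both sets with a warning.
Two empty sets get Jaccard 0 by convention (the formula is 0/0; signatures
are non-empty by construction, but robustness requires a defined value).

### Subgroup statistics

Within each of the five classification categories the unique-pair SJIs are
modelled as a cell-means linear model with one cell per
(subgroup, indication) combination.  The indicated-vs-control comparison
inside subgroup *s* is the LS-means slice (partition) F test

    F_s = (m_I − m_C)² / ( MSE · (1/n_I + 1/n_C) ),  df = (1, N − #cells)

with MSE the pooled within-cell residual mean square of the whole category
model.  This is the standard slice semantics of LS-means machinery in
major statistical packages; the cell-means parameterisation makes the
contrast variance exactly `MSE·(1/n_I + 1/n_C)`, which the test suite
verifies against a brute-force least-squares contrast oracle on random
unbalanced designs.  Pooling the residual variance lets a subgroup with a
single indicated pair be tested (its own SD is undefined and rendered
"----------" in the formatted table).  Subgroups observed at only one
indication level are reported untested.  One model per category is fitted —
five models, no cross-category interactions.

Multiple testing: all tested subgroups from all categories form one
Benjamini–Hochberg step-up family by default (a per-category family is
available by option).  The overall indicated-vs-control comparison is a
two-sided two-sample t-test, pooled-variance by default for consistency
with the equal-variance GLM; Welch is available by flag.  Degenerate
inputs are handled explicitly: identical constant groups give p = 1,
constant groups with different means raise rather than fabricate a
statistic.

### Gene-level reversal

For a chosen subgroup (by default the lowest-q tested subgroup), assay
pairs are re-enumerated at signature level: indicated pairs inside the
subgroup versus all non-indicated pairs involving the subgroup's drugs.
Per gene and group, NS counts same-direction occurrences (up/up or
down/down), NR reverse ones, and

    D% = (NS − NR) / total pairs × 100 ,   G^I-R% = D^I% − D^R% .

The denominator is the group's total pair count, absent pairs included —
the formula as stated names total assay pairs with no presence qualifier; a
presence-restricted denominator is available by flag for sensitivity
analysis.  Note the range: each D% lies in [−100, 100], so their
difference is bounded by ±200, although descriptions of the score sometimes
state ±100; the formulas are implemented as written and the wider bound
documented rather than rescaled.  Ranking is ascending in G^I-R% (most
reversed first) with lexicographic tie-breaking for determinism, and the
selection accepts either a fraction (floor(n·fraction)) or an explicit
count, since published top-k lists do not always match an exact fraction.

## Synthetic studies

The generator emulates the structure the analysis assumes, not expression
data: it is set-based because the analysis is set-based.

Defaults (chosen once as a realistic small screening study): 500-gene
effective universe — of the order of the distinct symbols a curated
signature collection of this size actually exercises; 20 drugs × 25
diseases; 1–2 signatures per entity; 20–40 genes per direction, matching
typical curated differential-expression list lengths; indication density
0.08, giving each drug roughly two indicated diseases (each drug is forced
to keep at least one so a default study always has an indicated group);
planted reversal strength ρ = 0.8 in the drugs carrying the sensitive
target label (one of six target labels, so 3–4 of 20 drugs); background
overlap 0.1.

Mechanics: disease signatures are uniform random draws.  A sensitive drug's
signature copies a fraction ρ of its genes, direction-flipped, from the
pooled (gene, direction) entries of its indicated diseases' signatures —
treatment literally reverses disease expression — and fills the remainder
with genes absent from those diseases.  Every other drug signature draws
its overlap from a global pool of all disease-signature entries with
*random* directions, so at ρ = 0 indicated and control pairs are
statistically identical: an exact null for calibrating the subgroup FDR.
Ground truth records sensitive drugs and subgroup labels, planted genes per
drug, and the indicated-pair list.  A single integer seed drives separate
child streams per stage (diseases, indications, annotations, drugs), so
extending one stage never perturbs another, and same-seed runs are
byte-identical.

What the generator does **not** emulate: correlated co-expression modules,
tissue-of-assay mismatch, noisy or partially overlapping replicate
signatures of one entity, non-uniform gene usage, or realistic annotation
hierarchies.  Passing tests therefore demonstrate that the pipeline's
statistics are calibrated and its planted effects recoverable under the
stated generative assumptions — not that any particular real drug-disease
collection will show an effect.

The packaged fixture is the same generator at a fixed seed with ρ = 0 plus
five hand-planted special cases (mouse-organism assay, unapproved drug,
dual-labelled series, explicitly excluded id, drug whose only indication
has no disease signature), with a deterministic full-coverage indication
table so its filter and pair bookkeeping is exact by construction.

## Problem sizes in tests

Calibration and recovery tests run the full pipeline on the default study
size: 200 independent seeds at ρ = 0 for the null FDR calibration, 50 seeds
at ρ = 0.8 for subgroup detection, and 20 seeds at ρ = 1 for planted-gene
recall — sizes at which the binomial Monte-Carlo error of the checked
fractions is a few percent.  The SJI implementation is checked exactly
against a per-gene membership-enumeration oracle on 1000 random signature
pairs over a 50-gene universe.

## Known limitations

- Entity identity is by normalised name; no cross-vocabulary resolution of
  drug or disease synonyms.
- Gene symbols are matched verbatim (case/whitespace-normalised); alias or
  ortholog mapping is out of scope.
- The slice test assumes a common residual variance across a category's
  cells; strongly heteroscedastic subgroups inherit that approximation.
- Chemotherapy pair-level resolution for drugs carrying both labels relies
  on an optional per-pair context table; absent one, such pairs count in
  both chemotherapy subgroups.
- Pathway enrichment on the exported gene list is intentionally out of
  scope; the artifact stops at the ranked list (plain text and GMT).
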