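# Methods

This note documents the models implemented by the package, the defaults
and why, the synthetic data-generating assumptions, and the numerical and
design choices a maintainer would want to know.  Nothing here states an
empirical result the test suite or `scripts/acceptance.py` does not itself
compute.

## Functional profiles

Shotgun gene counts annotated by KEGG Orthology (KO) are *regrouped* to
Enzyme Commission (EC) reactions by summation: a KO mapping to k ECs
contributes its **full count to each** (the "summed and regrouped"
convention).  A fractional 1/k split is available via
`regroup_ko_to_ec(..., split="fractional")` for sensitivity analyses; the
full-count default is what the rest of the pipeline assumes.  KOs missing
from the map accumulate into a per-sample unmapped-mass report rather than
disappearing silently.

Each sample row is then divided by that sample's total regrouped count
over a reference EC set — by default 19 core glycolysis/TCA-cycle enzymes
(`profiles.GLYCOLYSIS_TCA_ECS`).  This internal normalization makes
profiles invariant to sequencing depth (property-tested over random
scalings).  The reference module membership is a configuration list, not a
hard-coded truth: any near-universal energy-metabolism set with nonzero
counts in every sample will do, and users can substitute their own.
Samples with a zero reference total fail fast; an optional pseudocount on
the denominator is available for robustness experiments but is off by
default because it silently changes scale.

Pathway annotation keeps at most the first 5 KEGG pathways per EC, in the
order given.  Duplicate (EC, rank) annotation rows: the last wins, with a
logged warning.

## The index (MPMI)

For each sample, with catalog roles N (favorable assimilation, 12
reactions) and D (putrefaction, 10 reactions):

    MPMI = 100 · a · ( Σᵢ wᵢ Cᵢ(N) ) / ( Σᵢ wᵢ Cᵢ(D) )

* `wᵢ` — per-reaction stoichiometric weights.  No per-reaction
  stoichiometry is tabulated anywhere we know of, so every `wᵢ` defaults
  to 1; the field exists so users can impose one.
* `a` — a single global constant with the convention that equal weighted
  sums give MPMI = 100 ("balance").  Default a = 1; it is a plain scalar
  argument for sensitivity analysis.
* Catalog reactions absent from a matrix contribute 0 and are listed in a
  coverage report.  A zero denominator sum yields NaN with a flag — the
  sample is never silently dropped.

The index is scale-invariant per sample (any common factor cancels) and
strictly monotone: up in any N-reaction abundance, down in any D-reaction
abundance.  Both are property-tested.

**Outlier exclusion** uses quartile-anchored (Tukey-style) fences at
k = 2: values outside [Q1 − 2·IQR, Q3 + 2·IQR] are excluded, quartiles by
linear interpolation.  The phrase "outside the interquartile range (2×)"
admits a second reading — outside median ± 2·IQR — available as
`mode="median"`.  Fewer than 4 values: nothing is excluded.  Exclusion is
applied within comparison groups by default (whether the original analysis
pooled first is not stated; per-group is the conservative choice).

**Group comparisons** are rank-based and two-sided: Mann-Whitney U for two
groups (exact null when both n ≤ 8 and no ties, normal approximation with
tie correction otherwise), Kruskal-Wallis for more.  **Cohort splits** by
body weight: `mean-split` (below/above the group mean; a bird exactly at
the mean goes to Low by default, switchable) and `10pct` (≤ 0.9× mean Low,
≥ 1.1× mean High, middle unlabeled) for the ex vivo design.

## Functional discriminant analysis

*Mean decrease in accuracy* is realized as per-tree out-of-bag (OOB)
permutation importance on a scikit-learn random forest: for each tree,
score its OOB samples, rescore with one feature's OOB values permuted
(one fresh permutation per tree × feature), and average the accuracy drop
over trees.  This is the classic Breiman/Cutler definition used by R's
randomForest.  OOB membership is recovered by replaying the forest's
per-tree bootstrap draw from the tree's recorded seed; a unit test
verifies the recovered OOB sets reproduce scikit-learn's own
`oob_score_` exactly.  Ranking ties break lexicographically by EC id, so
rankings are a deterministic function of (data, labels, config).

Defaults follow the published analysis: `mtry` = 2 candidate features per
split (kept verbatim although unusually small for a 30-feature panel —
override if you want √p behavior), 10,000 trees, truncation to the 30
top-ranked ECs, retraining with identical parameters, ensemble validation
on stratified 60% subsets scored on the 40% complement.  Null calibration
is asserted: on permuted labels, ensemble held-out accuracy concentrates
near 0.5 (within ±0.2 at n = 40, 10 models).

**LFDA** (local Fisher discriminant analysis, Sugiyama 2007) is
implemented directly: within- and between-class scatter matrices weighted
by a local-scaling affinity (σᵢ = distance to the 7th within-class
neighbor; Aᵢⱼ = exp(−‖xᵢ−xⱼ‖²/σᵢσⱼ)), generalized symmetric eigenproblem
S_b v = λ S_w v solved with `scipy.linalg.eigh` after a small ridge on
S_w, eigenvectors weighted by √λ, signs fixed by making each axis's
largest-magnitude loading positive.  The embedding is fit on the truncated
30-feature panel (consistent with the overfitting-minimization intent;
fitting on all ECs is possible by passing `retained_features=None`), and
"coordinates" are the top-2 discriminant components.  The scatter
construction is cross-checked in tests against a brute-force pairwise
double loop.

**Pathway importance** mirrors the profiling regrouping policy: each
retained EC contributes its full importance to each of its ≤ 5 annotated
pathways, signed by the direction of the class-conditional mean difference
relative to the control class (control baseline at 0).

## qPCR mathematics (qMPMI)

Calibration fits `Ct ~ log10(dilution) + C(source)` by ordinary least
squares (statsmodels): one slope per primer *set* (the four pairs of a
marker are blended into one set), additive per-source intercept offsets
with the first source as reference, R² as the quality metric.  At least 3
distinct dilution levels are required; the synthetic series spans 4 orders
of magnitude in duplicate, as the assay design specifies.

Relative abundance uses the printed assay formula

    Aᵢ = 10^(Ctᵢ/mᵢ − Ct₁₆ₛ/m₁₆ₛ)

Note an algebraic subtlety: substituting Ct = m·log10(R) + b gives
Aᵢ = (Rᵢ/R₁₆ₛ)·10^(bᵢ/mᵢ − b₁₆ₛ/m₁₆ₛ) — *proportional* to the true
template ratio with a primer-specific constant.  Every group-ratio
quantity (treatment/control contrasts, the acceptance recovery checks) is
unaffected because the constant cancels.  `intercept_correction=True`
subtracts the intercept terms and recovers the ratio exactly; the printed
formula remains the default because it is the assay's definition.

Replicates are averaged arithmetically **on the A scale** (not the Ct
scale).  Non-detects (no amplification within 40 cycles) default to a
floor abundance equal to the A implied by Ct = 40 for that replicate —
this keeps the index finite and preserves ordering when a marker is
detected in one arm only; `censor` (drop the replicate) and `zero` are
selectable.  qMPMI = (A over numerator qPCR markers) / (A over denominator
qPCR markers) per the catalog roles: (A₂.₃.₁.₁₀₉ + A₂.₆.₁.₁₉) /
(A₃.₅.₃.₁₂ + A₂.₈.₃.₁₈).  Dilution invariance (uniform template scaling
cancels) and strict monotonicity in each marker's template are
property-tested; invariance holds within the quantifiable range — once a
well crosses the Ct-40 censoring limit it no longer can.

## Performance indices

BWG = BW42 − BW0 per bird; ADG = BWG/42.  FCR = total feed intake /
mortality-corrected total gain, with dead birds' gain credited from
recorded removal weights when available and otherwise by linear
interpolation (death assumed midway, i.e. half the pen gain).
cFCR = FCR + c·(target BW − actual BW): the linear correction coefficient
c toward the strain's 42-d target weight is integrator-specific and not
published, so c defaults to 0 (no adjustment) with the hook exposed — the
percent-improvement surfaces use reported group means directly, so nothing
is guessed.  EPEF = ADG/(FCR·10)·livability%, reading "(100% of
mortality)" in the usual EPEF sense of livability = 100 − mortality%.
ANOVA uses pen as the experimental unit, optionally with a block term;
SEM is √(MSE/n) with harmonic-mean n when unbalanced.

## Synthetic data

The generators define the study conditions the tests assume; they are
stand-ins for real cecal data, not models of it.

* **Counts** (`gen_counts`): EC universe = 22 catalog reactions + 19
  normalization enzymes + filler to 100 ECs.  Per-EC baseline abundance
  is log-normal (σ = 1) with the housekeeping normalization enzymes
  boosted 50×; per-sample, per-KO multiplicative log-normal noise with
  σ = 0.3 — functional profiles are empirically far more stable across
  hosts than taxonomic ones, and ~30% CV encodes that stability; counts
  are Poisson at a uniform random depth of 50k–200k.  The treatment
  multiplies numerator-marker KO abundances by `marker_effect_fold`
  (default 3) *before* regrouping, so KO→EC logic is exercised and the
  expected MPMI treatment/control ratio equals the fold (internal
  normalization cancels).  21 samples/arm by default, matching one
  bird per pen per sampling day.
* **qPCR** (`gen_qpcr`): true slopes near −3.32 cycles/decade per marker,
  intercepts ~U(19, 23), 3 template sources with Normal(0, 1) offsets,
  5 dilution levels over 4 orders of magnitude in duplicate, Ct noise
  sd 0.2, censoring at 40 cycles emitted as non-detect wells.  Plate
  templates: 16S load log-normal around 1, marker/16S base ratios
  log-normal around 10⁻³.
* **Pens** (`gen_pens`): control means 2,463 g BWG and 1.855 FCR;
  treatment shifts +75 g and −0.069; between-pen SDs derived from the
  reported SEMs at 21 pens (SD = SEM·√21: 80.6 g, 0.046); mortality
  Binomial(40, 0.03); feed intake back-computed from the pen's FCR and
  its mortality-adjusted gain so the analysis recovers the generating
  FCR exactly.  Under these conditions the analytic per-endpoint powers
  at α = 0.05 are ~0.85 (BWG) and >0.99 (cFCR); the power criterion is
  therefore evaluated at the experiment level (either primary endpoint
  significant) as well as for cFCR alone — the per-endpoint rates are
  printed by `analysis/06_performance.py`.
* **SCFA** (`gen_scfa`): log-normal concentrations with a 10-fold
  treatment effect and a 0.3 mM detection limit placing control
  propionate/butyrate below detection — exercising the non-detect
  reporting path only.

Every generator is a pure function of its config (seed-determinism is
contractual and tested).  What passing tests on these data do **not**
show: real cecal metagenomes are compositional, phylogenetically
correlated, zero-inflated and batch-structured; none of that is modeled.

## Problem sizes and numerical choices

The default test/analysis scale is 40–42 samples × 100 ECs, 10,000 trees
for the acceptance-facing defaults and 100–2,000 trees elsewhere in tests
and drivers — rankings at these data sizes stabilize well below 10,000
trees, and the smaller forests keep the suite quick.  Ridge on the LFDA
within-class scatter: 10⁻⁹·(tr S_w/p + 1).  Quartiles: linear
interpolation (numpy default).  Rank-test exactness switches to the
normal approximation above n = 8 or under ties.  Seeds: every stochastic
operation takes an explicit seed; derived seeds are simple offsets of it.

## Known limitations

* The published study's raw sequencing and qPCR data are not deposited;
  nothing here claims to reproduce its actual EC rankings or group
  medians — only its formulas, procedures and printed summary statistics.
* The real EC universe (~2,083 reactions from a curated gene catalog) is
  catalog-dependent; the synthetic universe is 100 ECs.
* The marker catalog stores the literally printed KO id "K0194"
  (malformed: five digits expected) flagged `suspect=True` rather than
  guessing a correction.
* Primer validation is alphabet/length only — no melting temperature,
  dimer or in-silico PCR checks.
* cFCR's target-weight correction coefficient and the removal-weight
  records it ideally uses are rarely available; defaults degrade
  gracefully (c = 0, interpolated dead-bird gain) and are documented
  above.
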