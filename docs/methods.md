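# Methods

This note documents the models, conventions and numerical choices behind
`fatiguenet`, and what the synthetic-data-based tests do and do not show
about real clinical data.

## Study design being modelled

The analysis flow targets physical-examination cohorts stratified into
three groups by the H20 health-status questionnaire (score 0–100), the
fatigue chief complaint, and clinical diagnosis:

* **healthy** — no positive Western-medicine indexes, no fatigue, H20 in
  [80, 100];
* **sub-health fatigue** — no positive indexes, fatigue present, H20 in
  [60, 79];
* **disease fatigue** — a diagnosed disease (operationalized here as at
  least one positive binarized index) together with fatigue, with no H20
  bound;
* anything else is **unclassified** and excluded.

"No obvious positive indexes" is operationalized as *all* binarized
Western-medicine indexes equal to 0; the source protocol does not define
"obvious", and this is the strictest reading. Missing feature values are
treated as absent/negative (0) with a logged count.

## Binarization

TCM symptoms scored none/mild/severe (0/1/2) binarize with threshold ≥ 1:
mild counts as positive, since the protocol binarizes "positive syndromes"
without distinguishing grades. Qualitative indexes: any `+` grade
(including weak positive) is 1. Quantitative indexes are 1 outside their
normal range, in either direction. Binarization is idempotent on already
binary data.

## Co-occurrence network

Edge weight W_ij counts subjects with both features positive (computed as
XᵀX on the 0/1 matrix). Pairs never co-occurring get no edge; features
never positive remain isolated nodes so Pajek exports match the catalog.
Normalized association weights divide by the single global maximum over
the network (per-block normalization exists but is not the default), so
the top pair is exactly 1.0. Ties in association tables are broken by raw
weight descending, then lexicographic pair codes — printed tables need a
deterministic order even though the statistic itself defines none.
Association filtering keeps normalized weights *strictly* above the
threshold (default 0.5); published tables occasionally include a
just-below-threshold pair, which this implementation does not reproduce.

## Cohesion and node-contraction importance

Cohesion is ∂(WG) = 1/(s·l). Two readings of *s* circulate: the prose
definition (sum over non-isolated nodes of strength/degree) and a typeset
variant (sum of degree × strength). They disagree on any graph with
degree > 1; the prose reading is the default because it is unambiguous and
the scientific output is the *ranking*, which both readings drive through
the same contraction mechanism. The typeset variant remains selectable
(`CohesionParams(strength_aggregation="typeset")`) for sensitivity checks.

*l* is the mean shortest **hop** distance on the unweighted graph obtained
by keeping edges with weight strictly above `edge_threshold` (default 0:
any positive co-occurrence is an edge). For disconnected graphs the
default averages over reachable ordered pairs (`finite_pairs_only`); a
`component_restricted` policy evaluates the whole statistic on the largest
component instead. Internally ∂ is evaluated as
`pairs / (s · Σ distances)` — mathematically identical to 1/(s·l) but with
the integer division done last, so hand-derivable values (1/4, 1/3) are
exact in floating point.

Contracting node v merges {v} ∪ N(v) into one super-node; edges from the
merged set to an outside node are replaced by a single edge carrying their
summed weight, which conserves total co-occurrence mass (tested).
IMC(v) = 1 − ∂(WG)/∂(WG∗v). Conventions at the boundary: if contraction
leaves a single node, or only isolated nodes (no edges), ∂(WG∗v) = +∞ and
IMC = 1, the limit of total collapse. IMC ≤ 1 always; it can be negative
when contraction loosens the network.

IMC is evaluated one node at a time on the full network, not by
sequential removal — "shrinking nodes one by one" means independent
evaluation per node. On dense co-occurrence networks (prevalent features,
large n) most nodes' neighbourhoods span the graph, so many IMC values
saturate at 1.000 — the same pattern seen in published core-symptom tables
of large cohorts; the ranking then falls to the documented tie-break
(strength descending, then code), which preserves a meaningful order.

Ranking correctness is guarded by an independent brute-force oracle
(Floyd–Warshall distances, direct summation, explicit merge dicts):
agreement to 1e-12 over every labeled connected graph on 2–5 nodes with
random integer weights, plus 500 random weighted connected graphs on 6–8
nodes. Exhaustive enumeration beyond 5 nodes is combinatorially
infeasible; the random layer covers the larger topologies.

## Canonical correlation analysis

Both blocks are z-scored (so coefficients are comparable across units),
then the canonical correlations are the singular values of UₓᵀU_y from the
thin SVDs of the centred blocks — numerically equivalent to the
generalized eigenvalue formulation Σxx⁻¹ΣxyΣyy⁻¹Σyx (tested against it to
1e-10 and against scikit-learn's iterative CCA). Variates are scaled to
unit sample variance. Rank-deficient or constant blocks raise errors
naming the offending columns rather than silently regularizing; classical
CCA is undefined there. The sign of each dimension is fixed by making the
largest-magnitude loading of the X (tongue) block positive; published
loading tables report signs without stating a convention, and some fixed
rule is needed for reproducibility.

Significance: Bartlett's chi-square approximation on Wilks' Λ, sequential
over dimensions, χ² = −(n − 1 − (p+q+1)/2)·ln Λ_k with (p−k)(q−k) degrees
of freedom; calibration is verified by simulation (type-I error within 3
binomial SE of 0.05 at 1000 null replicates, n = 500, p = q = 3). A
permutation test over subject order in Y provides a distribution-free
alternative; the two agree in rejection decisions on ≥ 90% of null
replicates in the test suite.

Structure loadings are correlations between each original variable and its
own block's first variate; the derived pulse ratios enter as ordinary
columns alongside the base parameters, as published loading lists mix
both.

## Outlier screening

Subjects with any tongue/pulse value beyond quartile ± 1.5·IQR are dropped
before CCA (values beyond 3·IQR are additionally tagged "extreme" in the
exclusion log). Quartiles default to Tukey hinges, the convention of the
major commercial statistics package used in this literature; a linear
interpolation variant is selectable. Zero-IQR variables are skipped and
logged. Dropping at the inner fence matches exclusion of "outliers or
extreme values"; screening only at the outer fence is available via
`fence_inner=3.0`.

## Synthetic cohort generator

The generator is first-class, tested code defining the study conditions:

* **Group sizes** default to 742 / 361 / 1529 (healthy / sub-health /
  disease), the sizes of the motivating cohort; CCA tables default to the
  post-screening sizes 551 / 252 / 1160.
* **Binary features** follow a noisy-OR latent-factor model: subject s in
  group g activates factor f with probability a_fg; feature j is then
  positive with probability 1 − (1 − base_j)·Π_active(1 − λ_fj). The
  noisy-OR form guarantees valid probabilities and co-occurrence that is
  monotone in the loadings. Four default factors (fatigue syndrome,
  damp-phlegm pattern, metabolic disease, hematologic abnormality) produce
  group-structured symptom/index co-occurrence; baseline prevalences
  (symptoms 0.05–0.30, indexes 0.01) and loadings (0.22–0.90) are chosen
  as clinically plausible magnitudes — the literature reports no
  generative parameters, and these values are configuration, not contract.
* **H20 scores** are truncated normals confined to each group's defining
  interval (healthy 88 ± 6 on [80, 100], sub-health 70 ± 5.5 on [60, 79],
  disease 68 ± 12 on [0, 100]) so the grouping rules are exercised
  honestly: generated "disease" subjects without positive indexes can and
  do land in other groups or in `unclassified`.
* **Tongue/pulse blocks** share a latent bivariate-normal pair (u, v) with
  correlation ρ; each column is loading·latent + N(0, noise_sd²) in
  standardized units, shifted onto physiologic-looking positive scales
  (pulse locations sit ≥ 6 SD above zero so derived ratios are finite).
  The population first canonical correlation is ρ/(1 + noise_sd²); the
  default noise_sd = 0.1 keeps attenuation below 0.005. Planted defaults:
  ρ = 0.475 (healthy), 0 (sub-health, no real association), 0.42
  (disease) — the pattern reported for real cohorts. The four pulse ratios
  are computed from the generated base columns, not planted separately.

What passing tests show — and do not. The generator produces exchangeable
subjects, Gaussian continuous blocks and factor-driven co-occurrence; real
clinical data have measurement error structure, missingness, skewed
marginals and confounding that are not emulated. Parameter-recovery
results (ρ̂ within 0.05 of 0.42 at n = 1160) certify the estimator on
well-specified inputs, not the clinical effect size. Note also that
Tukey-fence trimming of multivariate-normal data truncates the latent
tails and therefore *attenuates* the canonical correlation below the
planted value (visible in the worked example: 0.354 after trimming
vs 0.42 planted); the recovery simulation runs on untrimmed tables, where
the estimator is unbiased up to O(1/n) optimism.

## Pipeline determinism and problem sizes

All randomness flows from one integer seed through
`numpy.random.default_rng`; per-group tongue/pulse seeds are derived
arithmetically and kept below 2³¹. Manifests record config, classified
group sizes and sha256 hashes of every artifact, and deliberately contain
no timestamps so equal seeds yield byte-identical manifests; wall-clock
information goes to the log stream only. The default full run (2632
subjects, three networks, three CCAs) completes in well under a minute;
the test suite's heavier simulations (100 CCA replicates at n = 1160,
1000 null calibration replicates, ~1300 oracle graph comparisons) are
sized to finish in a few minutes on one CPU while keeping each check's
statistical power.

## Known limitations

* The importance statistic is evaluated on the full network only; no
  iterative re-ranking after core removal.
* No regularized/sparse CCA: blocks must be full rank with n > p + q.
* Pajek export covers the undirected `*Vertices`/`*Edges` dialect only (no
  `*Arcs`, no layout coordinates); drawing/layout is out of scope.
* The baseline descriptive statistics of a cohort (mean ± SD tables,
  ANOVA/Kruskal–Wallis) are routine and deliberately outside the tested
  surface.
* Disease subgroup labels (hypertension, diabetes, hyperlipemia, fatty
  liver) are generated for realism but no subgroup-specific analysis is
  defined.
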