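# Methods

This note documents the models, conventions and numerical choices
behind `herbnet`, in the spirit of a statistical software appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential-expression screen

Each gene is tested between the two sample groups with a two-sided
Wilcoxon rank-sum test. Two modes are exposed:

- **exact** — full enumeration of all C(n₁+n₂, n₁) assignments of the
  pooled midranks, with the two-sided p defined as the probability of a
  rank-sum deviation |W − E[W]| at least as large as observed. Midranks
  make the enumeration valid under ties. Enumeration is limited to
  n₁+n₂ ≤ 16 (12,870 assignments at 8+8).
- **normal** — the tie-corrected normal approximation with continuity
  correction (delegated to `scipy.stats.mannwhitneyu`). On continuous
  data at n = 8+8 it tracks exact enumeration to within ~0.01; at very
  small n (2–4 per group) or under heavy ties the approximation is
  coarser, which is inherent to the method and why the exact mode
  exists.

Fold change is `log2((mean(x)+c) / (mean(y)+c))` on CPM-normalised
counts with pseudocount c = 1 by default; CPM normalisation removes
library-size differences and the pseudocount keeps zero-count genes
finite. A gene is flagged when p < 0.05 **and** |log2FC| > 2, both
strict inequalities, with no multiple-testing correction by default —
this mirrors the screening convention of the study design being
reproduced; a Benjamini–Hochberg switch (`correct="bh"`) is provided
for reuse. The joint filter is far stricter than either criterion
alone: on 10,000 null genes it flags essentially none, because a null
gene almost never reaches |log2FC| > 2 at n = 20+20.

## Component–target network and contribution index

Components pass the ADME filter when OB ≥ 30% and DL ≥ 0.18, both
inclusive. The C-T network is a simple bipartite graph; duplicate
edges (the same pair predicted by several sources) collapse to one,
and components left without edges are dropped, since every downstream
quantity is undefined at degree 0.

The contribution index of component i is

- ω_i = C_i / T_edge — the component's share of all edges;
- A_i = ω_i + |(CA_i + CB_i)/(CA_i − CB_i)| — an affinity weight
  contrasting the herb-A and herb-B attributed degrees;
- NE_i = C_i · A_i · Σ_{j∼i} P_j — degree times affinity times the
  summed degrees of i's own targets, so hitting promiscuous targets
  raises NE;
- CI_i = 100 · (NE_i/ΣNE + C_i/ΣC)/2.

Three conventions here were genuinely open and are declared package
choices:

1. **Normalisation.** A linear reading of the CI formula
   ("NE share + degree share × 100") cannot yield percentages that sum
   to 100 (it sums to 101 or 200 depending on where the ×100 binds).
   Since cumulative CI of a top-k subset is reported as a percentage of
   the whole network, the default averages the two shares:
   CI_i = 100·(NE_i/ΣNE + C_i/ΣC)/2, which sums to exactly 100 by
   construction. The unnormalised linear reading remains available as
   `mode="literal"` for comparison.
2. **Herb attribution.** A compound claimed by both herbs carries
   herbs = {A, B} and its edges count toward both CA_i and CB_i, so
   CA_i = CB_i = C_i. The affinity ratio is then degenerate
   (division by zero); it is replaced by CA_i + CB_i — finite and
   monotone in the shared degree — and each occurrence is logged.
   Single-herb components always have ratio exactly 1.
3. **Summation range.** The NE sum runs over the targets adjacent to
   component i (not all targets): NE is the component's own network
   effect and must depend on its own neighbourhood.

Ranking is by descending CI with deterministic lexicographic
tie-breaks on component id; cumulative CI accumulates in rank order.

## PLS-DA, VIP, Q², permutation validation

PLS-DA is fitted by NIPALS on mean-centred (and by default unit-
variance-scaled, SD with ddof = 1) X against the dummy-coded group
response. With a univariate response the NIPALS iteration has a closed
deterministic form per component (w ∝ E'f), so there is no random
initialisation and no convergence tolerance to tune. Score vectors are
mutually orthogonal and weight vectors unit-norm by construction;
R²X/R²Y are cumulative explained sums of squares on the training data.
A constant variable under unit-variance scaling raises an error naming
the variable. The implementation is cross-checked in the test suite
against scikit-learn's NIPALS PLS regression (scores and weights agree
up to sign), which is never used as the implementation itself.

**VIP** follows the Wold formulation,
vip_j = √(p · Σ_a SSY_a w²_aj / Σ_a SSY_a) with SSY_a = q²_a·t'_a t_a
the Y sum of squares explained by component a. Σ vip² = p exactly, so
VIP > 1 flags variables above average importance.

**Q²** uses deterministic venetian-blind cross-validation: samples are
ordered by group then sample id and dealt into 7 folds (the common
software default) by stride; each fold's held-out group codes are
predicted by a model refit on the remainder, and
Q² = 1 − PRESS/SS with SS accumulated against the training-fold mean.
Folds are never random, so Q² is reproducible to the bit. A fold that
empties a group (possible only with a near-singleton group) is an
error rather than a silent skip.

**Permutation validation** refits the model under n ≥ 20 label
permutations and declares the model valid when the original Q² exceeds
the 95th percentile of the permuted Q² distribution. The underlying
validity notion ("the real labels predict better than relabelled
ones") admits several formalisations; the 95th-percentile rule is the
package's declared one, chosen because it is a calibrated one-sided
5% test under exchangeability — on null data it declares validity
~5% of the time by construction.

**OPLS-DA** removes one Y-orthogonal component (w_o ∝ p − (w'p)w)
before fitting a single predictive component, and reports S-plot
coordinates (cov(x_j, t_pred), corr(x_j, t_pred)) per variable. When
the data carry no Y-orthogonal structure the orthogonal weight
vanishes; the model falls back to plain PLS-DA with a warning.

## Metabolite screen

Per metabolite: Welch (unequal-variance) two-sided t-test and fold
change as the ratio of arithmetic group means (treated/control),
trend = up iff FC > 1. The joint screen passes a metabolite when
VIP > 1, p < 0.05 and the fold change departs from 1. The fold-change
criterion is **two-sided** by default (FC > θ or FC < 1/θ, θ = 1):
a literal one-sided "FC > 1" rule would discard every down-regulated
metabolite, contradicting how published screens of this design retain
FC < 1 entries (the bundled 47-row reference table includes 16 such
metabolites). The literal rule is available via `fc_mode="greater"`.
Whether the upstream software computed FC from means or medians, and
whether intensities were log-transformed before modelling, is not
documented for the reference screen; the package defaults (arithmetic
means, no log transform) are stated here so results are interpretable.
No multiple-testing correction is applied by default.

Heatmap ordering z-scores each metabolite row (mean 0, SD 1, ddof = 1,
zero-variance rows excluded with a warning) and derives row and column
leaf orders from average-linkage Euclidean dendrograms — fully
deterministic. Pathway over-representation is the one-sided
hypergeometric tail P(X ≥ k) per pathway, with an optional BH column.

## Synthetic-data generators

The generators emulate the statistical structure each stage assumes,
with explicit seeds and truth sets:

- **Counts**: gamma-Poisson (negative binomial) with variance
  μ + φμ², default dispersion φ = 0.1 (typical bulk RNA-seq
  overdispersion) and per-gene base means log-uniform on [10, 1000].
  Planted genes multiply the tumor-group mean by 2^log2FC (default
  log2FC = 3). Default design 20+20 samples, 20 planted of 500 genes.
- **C-T network**: background component degrees Poisson(3) truncated
  at ≥ 1 (no isolated components), one designated core component with
  exactly 15 distinct targets, 18+18 components over 60 targets, and
  OB/DL drawn so that 80% of components pass the ADME filter (the
  core always passes).
- **Metabolites**: multiplicative log-normal noise with CV = 0.1
  around per-metabolite base levels log-uniform on [10⁴, 10⁷]; the
  log-normal is drawn with mean correction −σ²/2 so arithmetic group
  means hit their targets exactly, making the planted treated/control
  mean ratio equal to the nominal FC (default 4) in expectation.
  Default design 10+10 samples, 10 planted of 200 metabolites.

Defaults were chosen once as realistic desk-scale study conditions and
are the conditions under which the acceptance checks run. What passing
tests on these data do **not** show: real LC-MS intensities are
correlated across metabolites (shared pathways, co-eluting features),
batch-structured, and missing-not-at-random; real RNA-seq has
library-composition effects beyond CPM's reach; real C-T edge lists
carry database-specific ascertainment bias. Recovery and calibration
results here are therefore statements about the method's mechanics,
not field performance.

A known calibration fact worth stating: under the default metabolite
conditions the three screen criteria are not independent — a null
metabolite whose chance group difference reaches p < 0.05 almost
always also exceeds VIP 1, because both statistics are monotone in the
same group-mean contrast. The screen's expected false-positive rate is
therefore ≈ the t-test's α (about 5% of null metabolites), not the
product of the marginal rates; specificity hovers around 0.95 rather
than comfortably above it.

## Pipeline

Stages (`simulate → deg → network → ci → metabo`) each read and write
plain TSV/JSON under one output directory, so any stage can be re-run
standalone. Configuration is YAML merged over documented defaults;
validation rejects unknown keys and reports **all** violations at
once. All randomness flows from the config seed (stage generators use
fixed small offsets from it); identical config + seed gives
byte-identical outputs. Problem sizes throughout the test suite and
acceptance script are desk-scale by design — hundreds of features,
tens of samples, 200-network oracle sweeps — chosen so the full check
suite runs in minutes while still exercising every code path at the
study's stated effect sizes.

## Known limitations

- The contribution index's affinity term is sensitive to the herb
  attribution convention for shared compounds; alternative readings
  (e.g. herb-specific subnetwork degrees) would change A_i for those
  compounds only.
- The exact Wilcoxon mode is O(C(n,k)) and capped at n₁+n₂ = 16.
- OPLS-DA extracts a single predictive component (the two-group
  case); multi-class OPLS is out of scope.
- Pathway ORA ignores pathway topology and inter-metabolite
  correlation; p-values are enrichment screens, not effect sizes.
- No batch-effect modelling, missing-value imputation, or
  normalisation beyond CPM/unit-variance scaling.
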