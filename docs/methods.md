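# Methods

## Profiles and panels

A profile is one subject at one visit: a vector over a fixed panel of K
immune-marker combinations, carried as absolute counts (cells/µL, derived as
percent of gated lymphocytes × absolute lymphocyte count) and as
*panel-relative proportions* (counts renormalised to sum to 1 over the K
analysed populations). The renormalisation is deliberate: the overlap index
needs probability distributions on a common support, and marker panels are
neither exhaustive nor disjoint partitions of the lymphocyte pool.
Overlapping gates (e.g. `CD3+/HLA-DR+` contains
`CD3+/HLA-DR+/CD69+/CD134-`) are analysed as separate features, not
deduplicated. Zero counts are retained; smoothing is the overlap layer's
concern. Controls carry no visit day and enter every per-visit analysis as
the full control set. Whether a downstream computation runs on counts or on
proportions is always an explicit `measure` argument — both scales are
carried because published analyses used absolute numbers for some steps and
proportions for others, and after per-profile renormalisation the two differ
only through the pseudocount scale.

## The overlap index

The I-index between n profiles is pinned to the normalized generalized
Jensen–Shannon overlap

    I = 1 − [H(mean of Pᵢ) − mean of H(Pᵢ)] / log n,

with uniform mixture weights. Properties relied on by the rest of the
pipeline, all covered by tests: I ∈ [0, 1]; 1 iff the distributions are
identical; 0 for pairwise disjoint supports; symmetric in profiles and in
populations; base-invariant (JSD and log n rescale together); restriction
to a feature subset followed by renormalisation is self-consistent. The
functional sits behind one interface (`i_index_matrix`), so an alternative
overlap (e.g. Morisita–Horn) can be swapped without touching FIS or
clustering. A pseudocount (default 0.5 on the counts scale) is added to
every category after subset restriction and before normalisation, keeping
disjoint-support profiles at finite divergence; pseudocount 0 is used in
analytic tests. On the proportion scale a proportion-scale pseudocount
(~1e-4) is the sensible choice.

The case-versus-control-set distance is reported as the overlap *lost*:
`d = I(controls) − I(controls ∪ {case})`, so larger d means a more
divergent case, and a feature with positive contribution to d reads as
"contributes to the difference". (The alternative printed form
`I(case + controls) − I(controls)` is its negation and is non-positive
whenever the case is more divergent than a typical control.)

## Feature importance scores

`FIS(j; J) = d(case; controls | J) − d(case; controls | J∖{j})` depends on
the context subset J, so J is resampled: uniform i.i.d. draws of m distinct
features (repeats across draws allowed; with C(100,10) ≈ 1.7e13 possible
subsets, collisions are negligible at any realistic M). The per-(case,
feature) summary is the median FIS over all sampled subsets containing the
feature. Production design: M = 500,000 with m = 10 of K = 100 or m = 7 of
K = 18; the desk-scale default is M = 20,000, which the exhaustive-oracle
tests show is already well converged for K = 18 (each feature is evaluated
≈ M·m/K ≈ 7,800 times).

Significance is called *across cases*: a one-sample, one-sided Wilcoxon
signed-rank test of the per-case medians against zero (alternative
"greater" — importance positive in almost all cases), then
Benjamini–Hochberg FDR across features at α = 0.05. The across-cases
reading (rather than across-subsets within a case) is a design choice the
config can switch to two-sided; all-zero medians are degenerate for the
signed-rank statistic and get p = 1.

The inner loop is vectorised by reducing restricted-renormalised entropies
to subset sums: with s = Σ_{k∈J} c_k and t = Σ_{k∈J} c_k log c_k,
H = log s − t/s, so leave-one-out values are single-term subtractions, and
the (n+1)-profile mixture reuses the controls-only mixture. The vectorised
engine is tested for exact (1e-12) agreement against the scalar two-distance
composition and against an independent brute-force entropy oracle.

## Rank-sum battery and heatmaps

Each (population, timepoint, cohort pair) cell gets a two-sided Wilcoxon
rank-sum test: exact p-values for tie-free samples with both sides ≤ 25,
otherwise the normal approximation with continuity correction and mid-ranks.
The significance rule is the printed reciprocal cutoff
`round(1/n_comparisons, decimals)` with the rounding precision an explicit
argument (3 decimals reproduces 0.006 from 162 comparisons; 4 decimals give
0.0033 from 300 and 0.0185 from 54). This fixed per-comparison rule budgets
~1 expected false-positive cell per full battery by construction; the
pipeline's false-discovery control lives in the FIS pre-filter, which is why
the fold-ratio heatmap is conventionally displayed over the FIS-selected
populations (`fold_heatmap(..., populations=...)`), with non-significant
cells masked blank. Fold ratios are always median(first cohort)/median
(second cohort), so depressed populations show values < 1; a zero
denominator median flags the ratio as undefined (NaN).

## PCA convergence

One PCA per visit, fitted on the pooled matrix of cases-at-visit plus all
controls. Columns are z-scored by default (counts span orders of magnitude);
for proportion input an optional centered log-ratio transform is available.
Constant columns are dropped with a warning when scaling. Cohort separation
is summarised by Euclidean distances between cohort centroids in the
n_components-dimensional score space — invariant to component sign flips and
orthogonal rotations. Convergence = the case-versus-control centroid
distance shrinking across days 56 → 180 → 365.

## Clustering

Agglomerative clustering on `1 − I-index` (average linkage by default; the
linkage is genuinely open, so it is an argument). Input rows are pre-sorted
by label, making the merge order deterministic and relabeling-invariant.
Newick export uses the ultrametric half-height convention (a two-leaf tree
merging at height h is `(A:h/2,B:h/2);`), so leaf-to-leaf path lengths equal
cophenetic distances. Cohort separation is read off the 2-clade flat cut as
the fraction of controls in the control-majority clade.

## Synthetic cohorts

The generator emulates the emulated study's design: 37 HIV(+) and 30 HIV(-)
transplant recipients sampled at days 56/180/365 and 71 once-sampled healthy
controls. Per subject-visit: absolute lymphocyte total ~ log-normal (median
1500 cells/µL, σ = 0.3, case totals scaled by 0.7/0.85/1.0 across visits to
mimic incomplete early numeric recovery); composition ~ Dirichlet around the
cohort-visit mean (concentration 300) followed by a multinomial split of the
total — Dirichlet-multinomial rather than independent log-normals so that
populations compete compositionally, as percent-of-lymphocyte measurements
do. Cohort-visit means apply multiplicative effects (log₂ fold changes
versus the control baseline, decayed per visit by a non-increasing schedule
in [0,1]) and renormalise; a strong single-feature effect therefore slightly
perturbs all other features, matching the compositional closure of real
data.

The default HIV(+) template encodes the reconstitution phenotype of chronic
HIV infection — activated T cells (`CD3+/HLA-DR+`,
`CD3+/HLA-DR+/CD69+/CD134-`) and memory/effector CD8 subsets elevated;
naive/memory CD4 helpers, activated B cells and NK subsets depressed — with
decay (1.0, 0.6, 0.35), i.e. persistent at one year. The HIV(-) template is
transient (late-activated CD134+ T cells and NK activation high early,
decay (1.0, 0.5, 0.0), fully resolved by day 365). Baseline proportions are
an order-of-magnitude-plausible fixture and are **not** calibrated to any
real cohort's medians: passing tests validate the inferential machinery on
known ground truth, not the absolute realism of any simulated value. Real
cytometry features the generator does not emulate: between-subject
covariance structure beyond compositional closure, within-subject visit
autocorrelation, batch/instrument effects, and nested gate constraints.

## Validation experiments and problem sizes

The acceptance suite runs, at desk scale on one CPU:

* cutoff arithmetic and overlap identities (120 random instances against a
  direct `scipy.stats.entropy` oracle, agreement to 1e-12);
* FIS exhaustive-oracle equivalence (K = 6, m = 3 enumerated exactly;
  K = 8, m = 4 sampled at M = 5,000 within 3 bootstrap SEs);
* null calibration — cases drawn from the control distribution, 18-panel,
  m = 7, M = 20,000, 30 cases, 20 seeds; flagged-feature fraction ≤ 5%;
* recovery — 5 injected features of 18 at |log₂FC| ∈ [1, 1.5] (stronger
  values on the smallest-baseline features, where overlap-based importance
  has the least power), 10 seeds: FIS must return exactly the injected set,
  and the FIS-selected fold heatmap must be fully unmasked with
  template-matching signs;
* convergence — decaying defaults, 10 seeds: per-subject 1 − I trajectory
  lower at day 365 than at day 56 ("decreases over visits" is read as net
  decrease: per-visit strict monotonicity of a per-subject noisy statistic
  is not what a convergence claim asserts) in ≥ 90% of cases, and the
  case-control PCA centroid distance strictly decreasing in 10/10 seeds;
* separation — strong-effect cases versus 71 controls, ≥ 95% of controls in
  the control-majority clade at the 2-clade cut.

## Numerical conventions and edge cases

0·log 0 is 0 throughout (`xlogy`). I-index values are clipped to [0, 1]
against eps-scale float excursions. Single-feature restricted distributions
are degenerate (entropy 0) and handled exactly, so m = 2 subsets are valid
FIS contexts. Feature subsets never sampled at tiny M are excluded from the
median table with a warning. Tie-breaks in clustering resolve by
lexicographic label order via input pre-sorting. All stages consume
explicit seeds; the CLI derives per-stage substreams from one global seed by
hashing, so adding a stage never shifts another stage's stream.

## Known limitations

The I-index estimator here is the pinned Jensen–Shannon form, not a
bias-corrected estimator for undersampled categories — appropriate for
dense cytometry summaries, not sparse repertoires. The reciprocal-cutoff
battery is a fixed-level rule, not an FDR procedure; interpret full-panel
heatmaps accordingly (see above). FIS importance is overlap-based and
therefore composition-relative: a large injected effect on one feature
induces genuine (small) compensatory differences in all others, which at
extreme effect sizes become detectable in their own right.
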