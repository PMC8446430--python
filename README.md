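# immunofis

Information-theoretic comparison of lymphocyte-subset composition profiles
across cohorts and post-transplant visits.

## The problem

After autologous hematopoietic cell transplantation (AHCT), the immune system
rebuilds itself over months. Flow-cytometry immunophenotyping summarises each
patient visit as a vector of lymphocyte-subset quantities — absolute cells/µL
and percent of gated lymphocytes per immune-marker combination (e.g.
`CD3+/HLA-DR+` = activated T cells). Comparing such *composition profiles*
between cohorts (here: HIV(+) transplant recipients, HIV(-) transplant
recipients, healthy controls) and across visits (days 56, 180, 365) raises
three coupled questions this package answers quantitatively:

1. **How far is a patient's immune composition from the healthy-control
   population, and is it converging?**
2. **Which specific populations drive that difference?**
3. **Which individual subset comparisons survive a massively multiplied
   testing burden?**

## The methods

* **I-index** — an overlap measure between n composition profiles, pinned to
  the normalized generalized Jensen–Shannon overlap
  `I = 1 − JSD(P₁…Pₙ)/log n` with `JSD = H(mean Pᵢ) − mean H(Pᵢ)`;
  1 for identical distributions, 0 for disjoint supports, base-invariant.
* **Case-versus-control-set distance** — the overlap *lost* by adding a case
  to the control set: `d(case; controls) = I(controls) − I(controls ∪ case)`;
  the per-subject trajectory statistic is `1 − I({case} ∪ controls)`.
* **Feature Importance Score (FIS)** — for a feature j in a random feature
  subset J, `FIS(j;J) = d(…|J) − d(…|J∖{j})`; medians over many uniform
  random subsets (production design: 500,000 subsets of 10-of-100 or
  7-of-18) summarise each (case, feature), and a one-sided Wilcoxon
  signed-rank test across cases with Benjamini–Hochberg FDR flags the
  populations with positive importance in almost all cases.
* **Similarity clustering** — average-linkage agglomeration on
  `1 − I-index`, Newick export, clade-purity summaries.
* **Rank-sum battery** — two-sided Wilcoxon rank-sum per (population,
  timepoint, cohort pair) with the reciprocal-of-comparisons cutoff:
  `round(1/162, 3) = 0.006`, `round(1/300, 4) = 0.0033`,
  `round(1/54, 4) = 0.0185`; fold-ratio heatmaps mask non-significant cells.
* **Per-visit PCA** — standardized PCA of cases-at-visit pooled with
  controls; cohort-centroid distances in PC space quantify convergence.
* **Synthetic cohort generator** — seeded Dirichlet-multinomial compositions
  around cohort-visit means built from decaying multiplicative effect
  templates, so every stage is testable against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic cohorts (37 HIV(+), 30 HIV(-), 71 controls, 18-population panel):

```bash
python analysis/01_simulate_cohorts.py --seed 1 --out results
python analysis/02_overlap_clustering.py --seed 1 --out results
python analysis/03_fis.py --seed 1 --out results
python analysis/04_battery.py --seed 1 --out results
python analysis/05_pca_convergence.py --seed 1 --out results
```

which prints, among other lines:

```
2-clade cut: 100.0% of the 71 controls sit in the control-majority clade
18-panel pooled: significant FIS features: ['CD3+/HLA-DR+', 'CD4+/CD45RA+',
  'CD4+/CD45RO+', 'CD8+/CD45RA-', 'CD19+/CD80+']
18-panel day365: significant FIS features: none
162 comparisons at cutoff 0.006: 65 significant
HIV_POS vs CONTROL centroid distance by visit: day 56: 4.318,
  day 180: 3.033, day 365: 2.202 (monotone decrease)
```

Reading: the dendrogram cleanly separates cases from controls; FIS pinpoints
exactly the populations the generator perturbed (activated T cells and
memory cytotoxic T cells up, naive/memory helper T cells and activated B
cells down); by day 365 the decaying effects are no longer separable; and
the PCA centroids of the case cohorts move monotonically toward the healthy
controls over the post-transplant year.

The same stages are available as a CLI (`immunofis simulate|iindex|cluster|
fis|battery|pca|all --config cfg.yaml --out dir --seed N`) driven by a YAML
config; reruns with the same config and seed are byte-identical.

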