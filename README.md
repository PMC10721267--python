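# iartcr

Baseline-biomarker analysis of islet antigen-reactive (IAR) CD4+ T cells in
new-onset type 1 diabetes: TCR clonal expansion and sharing from single-cell
junction sequences, flow-style phenotype gating, cluster-level expression
profiling with differential expression, and correlation of per-participant
immune features with the rate of C-peptide decline, stratified by treatment
arm.

The package is for immunologists and biostatisticians who want to run this
kind of pretreatment-biomarker screen on their own single-cell TCR/transcript
and flow data — or to study its statistical behavior. A synthetic-data
generator that plants the cohort structure the analysis assumes (two arms,
five expression clusters, clonally structured paired-chain TCRs, exponential
C-peptide decay coupled to one cluster's fraction in the treated arm only)
makes every stage testable without any data download.

## The core computations

* **Clonal expansion and sharing.** Chains match on exact CDR3 junction
  nucleotide identity within a locus (the C104...F/W118 segment); a chain is
  *expanded* when detected in ≥2 cells, *public* when shared across
  participants. Summaries mirror the standard bookkeeping: unique expanded
  chains, expanded cells, per-cell shared-chain bins (1 / 2 / >2), private
  vs public tallies, per-cluster expansion fractions, and a permutation
  Kolmogorov-Smirnov test of expanded-vs-total cluster distributions.
* **Gating.** Deterministic threshold rules for maturation
  (naive/TSCM/TCM/TEM from CD45RA/CCR7/CD95), T helper polarization
  (Th1/Th2/Th17/Th1-17 from CXCR3/CCR4/CCR6 on memory cells), the
  cluster-3-like gate (CD4+CD45RA−CD45RO+FOXP3−CD2hi CD25+CD127−CD137+),
  25th/75th-percentile gating against a reference population, and cytokine
  positivity cut on a no-stimulation control. The antigen-reactive frequency
  is `n_enriched × 10⁶ / (n_pre_cd4 × dilution_factor)` per million CD4+
  cells.
* **Expression.** Size-factor normalization, Leiden clustering on a kNN
  graph of principal components, Jensen-Shannon marker specificity, marker
  rule-based cluster annotation, and per-gene negative-binomial GLM
  differential expression (cluster vs rest, detection-rate covariate, log
  size-factor offset, BH-FDR).
* **Outcome.** Per-participant exponential decay rate of the C-peptide
  2-hour AUC (OLS slope of log AUC on months, optional empirical-Bayes
  shrinkage), Spearman correlation of each immune feature with the rate by
  exhaustive/Monte Carlo permutation within each arm, BH adjustment within
  arm and feature family, and an *arm-specific* flag (significant in the
  treated arm, not in placebo).

See `docs/methods.md` for the models, assumptions, defaults and known
limitations.

## Worked example

```python
from iartcr import simulate, repertoire, outcome

ds = simulate.simulate_dataset(simulate.SimConfig(seed=1))

groups = repertoire.find_shared_chains(ds.chains)
_, sharing = repertoire.detect_expanded(groups)
print(sharing.n_expanded_cells, sharing.n_expanded_chains, sharing.shared_chain_bins)
# 160 144 {'1': 25, '2': 131, '>2': 4}

arms = ds.cohort.set_index("participant_id")["arm"]
screen = outcome.biomarker_screen(ds.truth.cells, ds.cpeptide, arms, seed=1)
print(screen.flags[["feature", "rho_treated", "q_treated", "rho_placebo", "arm_specific"]]
      .head(3).to_string(index=False))
#   feature  rho_treated  q_treated  rho_placebo  arm_specific
# cluster_3    -0.844072   0.005000     0.821429          True
# cluster_1     0.565555   0.182732    -0.218218         False
# cluster_2     0.229984   0.838083    -0.280680         False
```

Of 1,008 simulated cells, 160 belong to expanded clones sharing 144 unique
chains, most cells sharing exactly two chains (a TRA-TRB pair). The screen
recovers the planted biology: the fraction of a participant's cells in
cluster 3 correlates negatively with their C-peptide decay rate in the
treated arm (rho = −0.84, q < 0.01) but not in placebo, so cluster 3 is
flagged as an arm-specific baseline biomarker.

The same pipeline runs from the shell:

```sh
iartcr run --seed 1 --out run1          # simulate + all analysis stages
iartcr repertoire --airr run1/airr.tsv  # sharing analysis on any AIRR TSV
iartcr validate --cells cells.csv --arms arms.csv --cpeptide cpeptide.csv
```

External data enter as plain text: AIRR-style rearrangement TSV, dense CSV
or MatrixMarket counts, flow-event CSV (one column per marker), and a
long-format C-peptide CSV (participant, month, auc).

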