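# Methods

## Scope and model

`vagidyn` implements a longitudinal analysis of vaginal bacterial
communities sampled at six menstrual-cycle-anchored time points — V1, D7,
D14, D21, V2, V3 at study days 0, 7, 14, 21, 28 and 42, with V1 and V2
falling just after menstruation — in a two-arm (placebo / treatment) design.
Its components are:

1. **Community typing.** Each sample's relative abundance profile,
   aggregated to *Lactobacillus* sub-genus groups and genera otherwise, is
   assigned one of five dominance groups. A taxon dominates when it is the
   most abundant taxon and its relative abundance exceeds 40%. Because the
   *L. crispatus* and *L. iners* groups frequently co-occur at high levels,
   a codominance rule takes precedence: when both exceed 10% and jointly
   exceed 50%, the sample is codominant regardless of single dominance.
   The *L. gasseri*, *L. jensenii* and *L. pasteurii* groups are merged
   into one "other *Lactobacillus*" class; everything else — including
   profiles where no taxon passes 40% — is non-*Lactobacillus*.
2. **Shift statistics.** Per woman, the chronological label sequence is
   summarized two ways, because "a shift" is ambiguous: the number of
   adjacent transitions, and the number of samples deviating from the modal
   label (ties broken toward the earliest-occurring modal label). Both are
   reported; transitions are the headline count. Stability is equivalent
   under either definition (zero transitions iff zero deviations).
3. **Diversity.** Inverse Simpson (1/Σp²) and richness (taxa with count
   > 0) per sample at ASV level; Bray-Curtis dissimilarity
   (½Σ|xᵢ−yᵢ| for normalized vectors, via `scipy.spatial.distance`);
   Bray-Curtis distance of every sample to the same woman's V1 baseline;
   and a one-dimensional sample ordering minimizing the summed Bray-Curtis
   distance between neighbours.
4. **RAD statistics.** For a taxon and an ordered time-point pair
   (t₁ before t₂), a woman's relative abundance difference (RAD) is her
   abundance at t₂ minus at t₁, in [−1, 1]; positive means the taxon rose.
   Per pair the median RAD across pairwise-complete women is reported with
   a two-sided Wilcoxon signed-rank test; the 15 p values are corrected by
   the Benjamini–Yekutieli (BY) step-up procedure, which controls the FDR
   under arbitrary dependence at the cost of the harmonic-number factor
   c(m) = Σ 1/k. Between-arm contrasts use the Hodges–Lehmann estimator
   (median of all treatment-vs-placebo pairwise RAD differences) with a
   two-sided Wilcoxon rank-sum test, BY-corrected the same way.
   Cross-sectional arm comparisons at a single time point use
   Kruskal–Wallis. The same machinery accepts any per-sample scalar (e.g.
   log10 qPCR concentrations) via the `values=` argument.
5. **qPCR concordance.** The qPCR panel quantifies L. crispatus, L. iners,
   L. gasseri and L. jensenii (CFU/mL). The predicted dominance group is
   the most concentrated species, except that crispatus/iners codominance
   is called when those two are the top pair within a two-fold ratio.
   Agreement with 16S typing is scored over *Lactobacillus*-typed samples;
   non-*Lactobacillus* 16S samples are tallied separately because the
   panel cannot express that class (a flag counts them as disagreements
   instead).

## Numerical and procedural choices

* **Thresholds are strict inequalities** (40%, 10%, 50%, two-fold): an
  abundance of exactly 0.40 does not dominate, a ratio of exactly 2 is not
  codominant. `inclusive_thresholds=True` switches every comparison to ≥
  for users who prefer the inclusive reading.
* **Ties at the top abundance** are broken alphabetically by taxon label
  so classification is deterministic and order-invariant.
* **Zero paired differences** are dropped from the signed-rank statistic
  (Wilcoxon's original convention); `zero_method="pratt"` is available.
  Exact null distributions are used for n ≤ 25 without ties or zeros
  (signed-rank) and min arm size ≤ 10 without ties (rank-sum); otherwise
  normal approximations with continuity and tie corrections.
* **BY families** span exactly the tested cells of one matrix (one taxon,
  one analysis); cells with fewer than 2 pairwise-complete women (or an
  empty arm) are marked untested and excluded from the family.
* **Differential sign convention** defaults to treatment − placebo;
  `placebo_minus_treatment` negates the estimate and leaves p values
  unchanged. Both are exposed because the two natural phrasings of
  "difference between arms" have opposite signs.
* **Sample ordering** is solved exactly by Held–Karp dynamic programming up
  to 10 samples and by greedy nearest-neighbour from every start plus
  2-opt refinement beyond; of the two traversal directions the one starting
  at the lexicographically smaller sample id is returned.
* **Missing samples are never imputed**: every paired statistic uses
  pairwise-complete women; baseline distances are NaN when V1 is missing.
* **Reported percentages** are rounded half away from zero to integers
  (so 65/200 prints as 33%); raw fractions are always retained alongside.

## The synthetic cohort generator

Because the analyses require longitudinal, compositional, two-arm data
with known ground truth, the package ships a generator rather than bundled
data. Defaults mirror the emulated study design: 18 placebo and 34
treatment women, six time points, ~3.5% independent sample missingness
(never deleting a woman's whole series, so 52 women yield ≈ 301 of 312
samples), and multinomial read sampling at depth 10,000.

Each woman draws one of five archetypes — crispatus-dominated,
iners-dominated, crispatus+iners codominant, other-*Lactobacillus*
dominated, non-*Lactobacillus* diverse — with probabilities 15/52, 15/52,
12/52, 3/52, 7/52, a disjoint decomposition of the emulated baseline
cohort. Her baseline composition is a Dirichlet draw around the archetype
mean (concentration 150 for dominated, 120 codominant, 60 diverse —
tighter for dominated profiles, looser for diverse ones); each time point
re-draws from a Dirichlet centred on her baseline, giving exchangeable
within-woman noise.

Perturbations act on the **logit scale** — a taxon set with mass p moves
to logistic(logit(p) + δ) and the rest rescales proportionally — which
keeps compositions on the simplex and makes effects invertible:

* menses effect: δ = −0.6 on the crispatus group and +0.5 on Gardnerella
  and Streptococcus at V1 and V2 only. δ = −0.6 yields roughly a 7-point
  mean latent crispatus drop across the cohort, matching the magnitude of
  the post-menstrual reduction the analysis is designed to detect
  (recovery tests use δ = −0.9 ≈ 10 points);
* treatment effects (default off): δ on the combined *Lactobacillus* mass
  and/or on *Prevotella*, in the treatment arm at post-baseline time
  points (supplementation starts at V1).

qPCR concentrations are total load × latent species abundance × lognormal
noise, with total load ~ 10^N(9.8, 0.4) CFU/mL (high, lactobacillus-
dominated vaginal loads) and measurement noise 10^N(0, 0.2). Each woman
owns an RNG stream seeded by (seed, participant index), so resizing the
cohort or removing a woman never perturbs the others' draws; the same
config and seed are bit-reproducible.

### What the generator does and does not emulate

It reproduces the design's sampling structure, compositional noise,
post-menstrual crispatus depression with iners stability, arm imbalance on
demand (`arm_archetype_bias`), missingness, and qPCR proportionality —
enough to verify that every downstream statistic recovers injected effects
and stays calibrated under the null. It does **not** emulate: the high
between-visit community-type turnover of real cohorts (the default
archetypes sit away from the classification boundaries, so synthetic women
are far more stable than real ones — passing shift tests says the counting
is right, not that real dynamics are reproduced); sequencing artifacts
(chimeras, contamination, depth variation); hormonal covariates; or any
taxon beyond the ten modelled groups.

## Problem sizes

Recovery checks use 50 replicates of the full 52-woman design; null
calibration uses 200 replicates; classification fuzzing uses 10⁵ random
simplex points. These sizes give binomial standard errors comfortably
below the asserted margins while keeping the whole suite around a minute
and a half.

## Known limitations

* Classification operates on relative abundances only; total bacterial
  load enters solely through the qPCR panel.
* The BY correction is conservative by construction; with 15 dependent
  cells the null fraction of significant cells runs well below the nominal
  5%.
* The qPCR predictor cannot emit the non-*Lactobacillus* class; agreement
  statistics must be read together with the separately reported
  non-*Lactobacillus* tally.
* The neighbour-ordering heuristic beyond 10 samples is 2-opt-optimal,
  not provably optimal.
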