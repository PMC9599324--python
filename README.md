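# vagidyn

Longitudinal vaginal-microbiome dynamics: dominance-group community
typing, menstrual-cycle-anchored shift statistics, diversity metrics, the
relative-abundance-difference (RAD) statistical framework, and
qPCR-based dominant-taxon prediction — with a synthetic cohort generator
so every stage is testable without access to clinical sequencing data.

## Who this is for

Microbiome researchers analysing 16S rRNA amplicon (ASV) tables from
longitudinal vaginal studies: repeated swabs per woman across the
menstrual cycle (time points V1, D7, D14, D21, V2, V3 at days 0–42, with
V1 and V2 just after menstruation), optionally split into placebo and
treatment arms and accompanied by a species-specific qPCR panel for
*L. crispatus*, *L. iners*, *L. gasseri* and *L. jensenii*.

## The core statistics

**Community typing.** Each sample is classified from its relative
abundance profile (at *Lactobacillus* sub-genus-group level):
crispatus-dominated, iners-dominated, crispatus+iners codominant
(each > 10% and jointly > 50% — checked before single dominance),
other-*Lactobacillus* dominated, or non-*Lactobacillus*. A taxon
dominates when it is the most abundant and exceeds 40%.

**RAD framework.** For a taxon and time points t₁ < t₂, a woman's RAD is
her relative abundance at t₂ minus at t₁. Per time-point pair the median
RAD across pairwise-complete women is tested with a two-sided Wilcoxon
signed-rank test; the 15 pairwise p values are corrected by
Benjamini–Yekutieli (FDR under arbitrary dependence). Between-arm
contrasts report the Hodges–Lehmann estimator — the median of all
pairwise differences RADᵗʳᵉᵃᵗ − RADᵖˡᵃᶜ — with Wilcoxon rank-sum tests,
BY-corrected; cross-sectional arm comparisons use Kruskal–Wallis.

**Diversity.** Inverse Simpson (1/Σp²), richness, Bray-Curtis
dissimilarity (½Σ|xᵢ−yᵢ|), per-woman distance to the V1 baseline, and a
sample ordering that minimizes summed neighbour Bray-Curtis distance
(exact up to 10 samples, greedy + 2-opt beyond).

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

```python
import vagidyn as v

# a synthetic 52-woman cohort (18 placebo / 34 treatment, 6 time points,
# post-menstrual crispatus depression, ~4% missing samples)
result = v.generate_cohort(v.CohortConfig(seed=1))

sub = v.aggregate_taxa(v.to_relative(result.counts), "subgenus_group")
labels = v.classify_cohort(sub, result.design)
shifts = v.cohort_shift_summaries(labels, result.design)
stable = sum(s.stable for s in shifts)
print(f"samples: {len(labels)}   stable women: {stable}/{len(shifts)} "
      f"({v.percent_rounded(stable, len(shifts))}%)")
for taxon in ("L_crispatus_group", "L_iners_group"):
    cell = v.median_rad_matrix(sub, result.design, taxon).cell("D7", "V2")
    print(f"{taxon}: median RAD D7->V2 = {100*cell['median_rad']:+.2f} "
          f"points (n={cell['n']}, BY-adjusted p={cell['p_adj']:.2g})")
```

prints

```
samples: 303   stable women: 49/52 (94%)
L_crispatus_group: median RAD D7->V2 = -7.21 points (n=49, BY-adjusted p=2.7e-08)
L_iners_group: median RAD D7->V2 = +1.66 points (n=49, BY-adjusted p=0.57)
```

Reading: of 312 scheduled samples, 303 were "collected" (the generator
deletes ~4% at random). The *L. crispatus* group's median relative
abundance drops 7.2 percentage points from mid-cycle (D7) to the first
post-menstrual visit of the second cycle (V2) — the injected menses
effect, highly significant after BY correction — while the *L. iners*
group stays flat (+1.7 points, p = 0.57), reproducing the differential
menstrual sensitivity of the two species that motivates stratifying
cohorts by dominant taxon before randomization.

The same stages are available from the shell:

```bash
vagidyn simulate --seed 1 --out cohort/
vagidyn classify --counts cohort/counts.tsv --taxonomy cohort/taxonomy.tsv \
                 --metadata cohort/metadata.tsv --out labels.tsv
vagidyn rad --counts cohort/counts.tsv --taxonomy cohort/taxonomy.tsv \
            --metadata cohort/metadata.tsv --taxon Lactobacillus --out rad.tsv
vagidyn run --config run.yaml     # full pipeline -> report.json + TSVs
```

Input formats are plain TSV (`counts.tsv` taxon × sample, `taxonomy.tsv`
asv_id/genus/subgenus_group, `metadata.tsv` sample/participant/arm/
timepoint, `qpcr.tsv` sample/taxon/cfu_per_ml).

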