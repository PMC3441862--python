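# cnvintegrate

Integrative copy-number + expression analysis for paired tumor/normal
cohorts profiled by array CGH and expression microarrays, of the kind used
to find dosage-driven candidate genes in gastric cancer.

The package takes a probe-level table of log2(tumor/normal) aCGH ratios, a
gene-level log2 expression matrix with matched tumor ("T") and normal ("N")
columns, gene annotation intervals and clinical metadata, and runs:

1. **Per-sample CNV calling** — mode-based centralization of each sample's
   ratio distribution, robust derivative-based noise estimation
   (`σ̂ = median|r[i+1]−r[i]| / (0.6745·√2)`), and recursive
   maximal-scoring-interval segmentation with interval score
   `S(I) = |mean(r over I)|·√|I| / σ̂` called at `S ≥ 4`, followed by the
   aberration filters: ≥ 2 probes per region, |mean log2| ≥ 0.5 (a 1.4-fold
   floor that suppresses shallow calls), at most 10,000 regions per sample,
   chromosome Y excluded.
2. **Recurrence analysis** — per-probe gain/loss frequency profiles;
   recurrent regions as maximal probe runs carried by
   ≥ ⌈0.25·n⌉ samples; minimal common regions (MCRs) as the peak-count
   sub-runs, reported with sizes in Mb and `count (percent)` frequencies.
3. **Subtype comparison** — Fisher's exact test on the 2 groups × 3 states
   (gain/neutral/loss) table per region, by full enumeration of
   margin-preserving tables, for histology (PD vs MD), tumor stage
   (T1-2 vs T3-4) and nodal stage (N0 vs N1-3) contrasts, with SRCC and
   X/Y exclusions, a 25% classifying-frequency gate, raw p < 0.05 flags and
   Benjamini–Hochberg FDR reported alongside.
4. **Dosage integration** — per-gene mean probe log2 ratio; CNV⁺
   classification at |log2| ≥ 0.585 (1.5-fold); expression fold change
   `FC = median(linear tumor expr | CNV⁺) / median(linear tumor expr | CNV⁻)`
   with selection at 1.3-fold and 2-fold; Pearson correlation between gene
   copy log2 ratio and tumor−normal expression log2 ratio with the exact
   t-transform p-value; per-region tumor-vs-normal t-tests.
5. **Two-way clustering** — average-linkage hierarchical clustering of
   genes × arrays under 1 − Pearson distance, Newick export, and a
   two-cluster tumor/normal separation check.
6. **qPCR validation** — 2^−ΔΔCt relative quantification from triplicate Ct
   values normalized to ACTB, correlated back against gene copy ratios.

A synthetic-cohort generator (`cnvintegrate.simulate`) emulates the study
design — 27 paired samples, evenly tiled probes, injected gain/loss
segments reproducing a realistic recurrence spectrum (26–70% carriers plus
sub-recurrent segments), one histology-linked region, and expression that
tracks gene dosage — so every stage can be tested against known truth.

## Worked example

```bash
cnvintegrate --seed 7 --outdir sim simulate
cnvintegrate --seed 7 --outdir out run-all \
    --probes sim/probes.tsv --expression sim/expression.tsv \
    --annotation sim/annotation.tsv --metadata sim/metadata.tsv
```

The second command logs

```
INFO cnvintegrate: pipeline complete: 201 calls, 20 recurrent regions, 168 genes scored
```

and writes `segments.tsv` (per-sample calls), `recurrent_regions.tsv` /
`mcr.tsv` (Table-style region summaries with `size_mb`, `count`, `percent`
columns), `compare_*.tsv` (Fisher scan per contrast), `dosage.tsv`
(gene-level FC, Pearson r, p, FDR and selection flags) and two Newick
trees. On the seed-7 cohort the most frequent gain is carried by 19/27
samples and reported as `19 (70%)`; the injected MD-linked region on
chromosome 4 tops the PD-vs-MD scan (p ≈ 2×10⁻⁴); the median fold change
of scored genes is ≈ 1.66, close to the 2^0.8 ≈ 1.74 expected for a
0.8-log2 gain under a unit dosage coefficient.

The same analyses are available as library calls:

```python
from cnvintegrate import PipelineConfig, run_pipeline, simulate_cohort
from cnvintegrate.simulate import make_annotation

probes, expression, metadata, truth = simulate_cohort(seed=7)
result = run_pipeline(probes, expression, metadata, make_annotation(),
                      PipelineConfig(seed=7))
result.recurrent_regions[0].percent   # 70
result.clustering.separation_purity   # ~0.9-1.0
```

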