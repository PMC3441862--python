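# Methods

This note documents the models, algorithms, parameters and design choices
behind `cnvintegrate`, and what the synthetic benchmark does and does not
establish about real data.

## Copy-number calling

Each sample's probe-level log2(tumor/normal) ratios are processed
independently.

**Centralization.** Tumor DNA yield, labeling efficiency and aneuploidy
shift the whole ratio distribution, so the dominant copy-neutral population
is re-centred at zero by subtracting the distribution's mode: a fixed-width
histogram (bin 0.01 log2 units) locates the modal bin and a parabola
through the three central bin counts refines the estimate to sub-bin
precision. The mode — unlike the mean or median — is robust to large
aberrant fractions (a 10% contaminating gained population displaces the
estimated offset by < 0.02). Constant input returns itself as the offset.
Fewer than ~100 probes makes the mode estimate noisy; a warning is issued.

**Noise estimation.** The interval score needs a per-sample noise scale
that is not inflated by the copy-number signal itself. The first difference
of the ratio track cancels any piecewise-constant signal, so

    σ̂ = median(|r[i+1] − r[i]|) / (0.6745 · √2),

over adjacent same-chromosome probe pairs, estimates the per-probe s.d.
(the denominator converts a median absolute difference of two independent
Gaussians back to one Gaussian's s.d.; 0.6745 = Φ⁻¹(0.75)). On 10,000
i.i.d. Normal(0, 0.2) probes the estimator is within 5% of 0.2. A floor of
1e-8 guards the degenerate constant-input case.

**Segmentation.** Aberrant intervals are found by recursive
maximal-scoring-interval search per chromosome. The score of interval `I`
with `m` probes is

    S(I) = |mean(r over I)| · √m / σ̂,

the interval's mean deviation in noise-s.d. units scaled by √m — the same
statistic family as the commercial aberration-detection algorithms used
with two-colour CGH arrays, whose exact probe-weighting is proprietary.
The search finds the best-scoring interval (exhaustively over all O(n²)
candidates, computed with prefix sums in O(n) per length), accepts it when
`S ≥ adm_threshold` (default 4), and recurses on both flanks; accepted
intervals never overlap. Ties are broken leftmost-then-shortest for
determinism. Filters applied afterwards, in order: probe count
≥ `min_probes` (2); |mean log2| ≥ `min_abs_mean` (0.5, i.e. a 1.4-fold
floor, standing in for the fuzzy-zero suppression of shallow calls whose
exact correction is unpublished); top-`max_regions` (10,000) by score.
Probe-level quality weights are omitted: the synthetic data are
homoscedastic and no weight source exists for the text formats consumed
here. Chromosome Y is dropped before calling.

Two behaviours worth knowing: (i) the recursion only splits *outside* an
accepted interval, so two strong nearby same-direction segments separated
by a short quiet gap can merge when the combined `S` beats each part — with
default noise this requires the gap to be shorter than roughly a third of
the flanking segments; (ii) on pure-noise cohorts the expected number of
surviving calls per sample at defaults is ≈ 0 (measured ≤ 0.05 over
seeded replicates), because a spurious interval must clear both the score
threshold and the 0.5 amplitude floor.

## Recurrence and minimal common regions

Calls are rasterized to a probe × sample matrix of {gain, neutral, loss}.
Gains and losses are analysed separately throughout. With `n` samples and
recurrence fraction 0.25, the carrier threshold is `k = ⌈0.25·n⌉` (7 of
27). A *recurrent region* is a maximal run of consecutive probes whose
direction-specific carrier count is ≥ k, reported at the run's peak count.
The *minimal common region* is the sub-run (possibly several per run)
where the count attains that peak — the smallest interval shared by the
most samples. Region bounds are the first/last probe's bounds (probe
midpoints would change sizes by less than one probe spacing).

Frequencies are printed as `count (percent)` with percent rounded half-up
to the nearest integer (19/27 → 70, 7/27 → 26). Sizes are reported in Mb
as the difference of the endpoint positions after each is rounded half-up
to 0.01 Mb, so printed bounds and printed sizes are always consistent.

## Subtype comparison

Three clinical contrasts are built: PD vs MD histology (excluding
mixed-histology M-PD samples and the partial signet-ring carcinomas),
T1-2 vs T3-4, and N0 vs N1-3 (both excluding the signet-ring samples).
For each recurrent region a sample is gained/lost when calls of that
direction cover at least half of the region's probes (the overlap rule is
a free choice; 50% reciprocal coverage is standard). Regions on X/Y are
skipped, as are regions where neither group has ≥ 25% of samples with
classifying gains or losses. The 2 × 3 table (groups × gain/neutral/loss)
is tested by the conditional exact test: full enumeration of tables with
the observed margins, summing multivariate-hypergeometric probabilities of
all tables no more probable than the observed one (probability ties count
as extreme, tolerance 1e-9 on the log scale). Significance is flagged at
raw p < 0.05, mirroring how such region scans are usually reported;
Benjamini–Hochberg FDR across tested regions is written alongside so the
multiplicity cost is visible.

Calibration: because the test is exact and the tables discrete, the null
rejection rate at α = 0.05 is slightly conservative; with groups of 13/14
and state frequencies (0.3, 0.5, 0.2) it measures ≈ 0.043 (600
replicates), and 0.03–0.053 across plausible state frequencies.

## Dosage integration

Only genes intersecting recurrent regions are analysed, each inheriting
its region's direction. Per gene and sample, the copy ratio is the
arithmetic mean of overlapping probes' log2 ratios (any-bp overlap,
1-based inclusive); genes covered by no probe are flagged and excluded.
Genes whose mean log2 expression across all arrays is ≤ 3.9 are dropped as
unexpressed. A sample is CNV-positive when its gene-level ratio reaches
the 1.5-fold bound (≥ +0.585 for gains, ≤ −0.585 for losses, inclusive).

Fold change is computed on the linear scale — `FC = median(2^tumor-log2 |
CNV⁺) / median(2^tumor-log2 | CNV⁻)` — because fold change is a
linear-scale concept and published FC ranges are linear-style; selection
is inclusive at 1.3-fold (and 2-fold for target-gene nomination), with
reciprocal bounds (≤ 1/1.3) for loss regions. FC is undefined (flagged,
not failed) when either group is empty. FC is invariant to a global linear
scaling of the signals.

The Pearson correlation is computed between the gene's copy log2 ratio and
its tumor−normal expression log2 ratio across the samples present in both
cohorts (n = 25 by default), with the exact t-transform
`t = r√(n−2)/√(1−r²)` for the two-sided p-value; genes with zero variance
are flagged. Raw p < α defines "significant correlation" (as such studies
report); BH FDR across analysed genes is also written. The per-region
differential screen is an equal-variance two-sample t-test of tumor vs
normal arrays per gene with a default selection threshold of p < 1e-4.

## Clustering

The genes selected at 1.3-fold are clustered two-way (genes × arrays).
Each gene is median-centred across arrays (the display convention of the
classic clustering/heatmap toolchain); distance is 1 − Pearson correlation
(constant rows get distance 1 with a warning); agglomeration is average
linkage. Rows and columns are sorted lexicographically by label before
clustering, making results invariant to input order. Trees are exported as
Newick with branch lengths from merge-height differences (ultrametric).
Cutting the sample tree at the root's two children gives the two-cluster
labelling; separation purity is the best-matching agreement with the
tumor/normal labels, in [0.5, 1].

## qPCR validation

Triplicate Ct values are summarised by their mean; ΔCt subtracts the ACTB
reference mean within the same well set, ΔΔCt subtracts the matched-normal
calibrator's ΔCt, and RQ = 2^−ΔΔCt assumes exact doubling per cycle (no
efficiency correction). Replicate s.d. > 0.5 cycles attaches a quality
warning without dropping the record. log2(RQ) is correlated with the
gene-level copy ratio using the same machinery as the integration stage.

## Synthetic cohort

The generator emulates the statistical structure of a ~27-pair
gastric-cancer cohort at desk scale: 4 chromosomes × 100 Mb with 2,000
evenly spaced probes each (the real array's ~8.9 kb median spacing scales
to 50 kb; uniform spacing preserves per-probe statistics), 500 genes of
150 kb on an 800-kb grid, and 25 of the 27 samples carrying expression
arrays. Injected segments reproduce a realistic recurrence spectrum — 15
gains at 26–70% carriers topped by a dominant 30-Mb gain (the 8q-gain
analogue) and a 15-Mb gain at 63% (20q analogue), 5 losses at 26–33%,
sub-recurrent segments near 11–15%, and one gain confined to 80% of the MD
histology class. Same-direction segments sit ≥ 10 Mb apart so inter-region
gaps stay proportional to the real array's. Carriers receive probe ratios
Normal(±0.8, 0.2) inside their segments; everything else is
Normal(0, 0.2); a +0.1 global offset exercises centralization. Dosage
genes (every gene fully inside an injected segment) get tumor expression
`baseline + 1.0 × true copy log2 + Normal(0, 0.3)` over a Uniform(5, 11)
log2 baseline; normals get `baseline + noise`; 5% of genes are given
baselines below the 3.9 cutoff to exercise the present-call filter.
Clinical labels reproduce the cohort composition (12 PD of which 2 partial
SRCC, 11 MD, 4 M-PD; ~half early/late T and N stages; 6 M1). All
randomness flows from one seed through `numpy.random.SeedSequence`
spawning (separate child streams for carriers, probe noise and
expression), so cohorts are bit-reproducible.

**What the benchmark shows.** At these defaults every injected segment
with carrier fraction ≥ 0.30 is recovered as a recurrent region with
boundary error ≤ 2 probes (11/11 on each of ten seeds), ≥ 99% of dosage
genes pass the 1.3-fold selection while no null gene is scored (null genes
never intersect recurrent regions by construction), the MD-linked region
is flagged by the Fisher scan, and the two-cluster purity averages ≈ 0.97.

**What it does not show.** The expression model is dosage-only: there is
no tumor-intrinsic transcriptional program, no patient effects, no tumor
purity or subclonality, and no probe GC/response bias. One consequence is
visible in the clustering: tumors that happen not to carry the dominant
gain block are expression-indistinguishable from normals apart from their
smaller segments, so on a minority of seeds the root bipartition tracks
carriership of the dominant block rather than tissue and purity drops to
~0.86. Real cohorts separate more strongly because tumor expression
differs globally from normal tissue. Passing the synthetic benchmark
therefore validates the pipeline's arithmetic and recovery behaviour, not
the biological effect sizes of any real cohort.

## Numerical choices and problem sizes

Equal-score ties in segmentation resolve leftmost-then-shortest;
agglomeration ties resolve by scipy's deterministic ordering over
lexicographically pre-sorted labels; percent and Mb rounding are half-up
(never banker's). Degenerate inputs (constant ratio tracks, empty CNV
groups, zero-variance correlation vectors, empty Fisher margins) are
flagged or return the conventional neutral value (p = 1) rather than
raising. The packaged benchmark and calibration sizes — one 27-sample ×
8,000-probe cohort per run, 600 Fisher null tables, 1,000 correlation null
replicates, 30 null cohorts for the false-call rate — were chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo
standard errors below the decision margins of each check.
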