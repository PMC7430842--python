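# Methods

## Scope and model

`gapstock` covers the quantitative-genetics chain used to breed
salt/alkali-tolerant apple rootstocks from a large F1 pseudo-testcross:
injury-index phenotype statistics and broad-sense heritability,
bulked-segregant analysis (BSA) with a smoothed G′ statistic,
candidate-gene filtering within QTL intervals, and an additive
genomics-assisted prediction (GAP) model with cross-validation and
simulative selection. Sequencing-level work (read alignment, variant and
DEG calling) is upstream and out of scope; expression and DEG evidence
enter only as boolean flags on gene records.

## Synthetic populations

The generator emulates the F1 design the analysis assumes, not real
genomes. Each marker is heterozygous in the mother, the father, or both,
and segregates 1:1 or 1:2:1 (no distorted ratios). A QTL is a marker
locus with an additive allele effect on the injury index; the per-hybrid
phenotype in year *y* is

    value = clip(trait_mean + Σ_q effect_q · dosage_q + ε_y, 0, 1),
    ε_y ~ N(0, env_sd) independent per year.

Clipping keeps the index in its physical bounds and slightly biases
extreme effect combinations toward the interior; with the default
parameters the clipped mass is negligible. Tolerant/sensitive bulks are
the strict rank tails of the per-hybrid mean phenotype (ties broken by
hybrid id), and bulk allele depths are Poisson(read_depth_mean) with
Binomial(depth, bulk allele frequency) alternate reads.

There is no recombination map: background markers are independent.
Because the G′ scan relies on *local* correlation of the signal, each QTL
is tagged by a cluster of `n_linked` (default 5) markers that share its
segregation exactly, spread over `linked_span_bp` (default 1 Mb); the
marker nearest the locus carries the causal effect. This reproduces the
tight-linkage neighbourhood a real QTL has while keeping the rest of the
genome exchangeable. Consequences for interpretation: passing tests
demonstrate correctness of the statistics and recovery under idealized
linkage, not performance under realistic linkage-disequilibrium decay,
segregation distortion, genotyping error, or year-by-genotype
interaction, none of which are simulated.

Default design (chosen once to mirror the study conditions): 3258
hybrids, 3 years, bulks of 25, ~60× pooled depth, 2000 markers over 17
chromosomes of 30 Mb, six QTLs of moderate mixed-sign effects. The
baseline `trait_mean = 0.56` and `env_sd = 0.11` were set so the
*population* mean injury lands near 0.48 (the simulated QTLs shift the
mean by about −0.08) and the broad-sense heritability near 0.6,
matching the reported phenotype spectra. All randomness flows through
`rng_seed`; fixed seeds give byte-identical outputs.

## Phenotype statistics

The injury index is the standard weighted ordinal average over damage
classes 0..C_max (five classes by default, configurable): Σ c·n_c /
(C_max Σ n_c). Summaries use the sample SD (n−1); CV% = SD/mean·100.

Broad-sense heritability uses a one-way random-effects ANOVA with
hybrids as groups and year observations as replicates:
σ²_g = (MS_hybrid − MS_residual)/r̄ with r̄ the harmonic mean of
per-hybrid replicate counts (robust to mild unbalance), truncated at
zero, and H² = σ²_g/(σ²_g + σ²_e)·100. This is a deliberate choice — the
clonal replication of each hybrid makes total genetic variance the
relevant numerator; REML mixed models are out of scope. Hybrids with a
single record are excluded. Trait correlations are Pearson correlations
of per-hybrid across-year means (year-specific correlation is available
by subsetting first).

## The G′ scan

At each variant the tolerant/sensitive bulk allele depths form a 2×2
table with the log-likelihood-ratio statistic G = 2 Σ o ln(o/e)
(zero-count cells contribute zero; an all-zero table is missing). G is
smoothed into G′ by a tricube kernel over physical distance with
half-window `window_bp` (default 2 Mb), each variant included in its own
window. The null model for G′ is log-normal, fitted after removing
upper outliers above median + 5·MAD (unscaled MAD); per-variant p-values
are the log-normal upper tail and significance is controlled by
Benjamini–Hochberg FDR at q ≤ 0.05. Variants are scanned separately per
parental origin class — maternal-only heterozygous, paternal-only, and
both — because the three segregation tracks have different depth/signal
structure, and each class receives its own threshold. Degenerate classes
(constant G′ or fewer than 50 informative variants) yield no threshold
and no calls.

Intervals are maximal runs of above-threshold variants whose successive
positions lie within `merge_gap_bp` (default 2 Mb), require
`min_variants` (default 3), and are named
`<trait prefix>-<origin code><chromosome>.<rank>` with origin codes
BC/M/H for maternal/paternal/both. Coordinates are 1-based and closed.

## Candidate filter

The cascade removes, in fixed order: unexpressed genes; genes whose
parental variant origin is inconsistent with the QTL's origin (genes with
variants in both parents always pass this stage); genes whose annotation
matches none of the keywords (case-insensitive substring; the shipped
default list covers salt/alkali/ion transport/kinase/ubiquitin/stress/
ABA/channel terms and is fully configurable, since trait-relatedness is
ultimately a judgment call); and promoter-variant-only genes that are not
differentially expressed. The ledger conserves counts exactly and the
stage order is part of the contract — permuting it changes the ledger.

## GAP model

Genotype effects are class-mean deviations from the population mean;
classes below `min_class_size` (default 2) hybrids get effect 0 with a
warning. The scalar marker effect is E_m = max_g |e_{m,g}| ("absolute
genotype effect deviation"); a max-minus-min range variant is available
via `effect_summary="range"`. The phenotype entering the model is the
per-hybrid mean across years. Missing calls and classes unseen in
training contribute zero to GPV, which keeps predictions defined for
every hybrid; an all-missing hybrid receives the population mean and a
warning.

Cross-validation shuffles hybrids with a seeded generator into k
near-equal folds; the training fold supplies both the population mean
and the effects. The headline CV number is the Pearson r of pooled
held-out predictions (per-fold r values are also reported; the
fixed-point identity "refit on GPVs reproduces the effects" holds exactly
only for balanced orthogonal designs and is tested on one).

Simulative selection at cutoff c selects GPV ≤ c (tolerance is
low-injury); efficiency is the share of selected hybrids with OPV ≤ c.
A per-individual variant (OPV_i ≤ GPV_i) is reported in an extra column.
Allele association uses the pooled-variance two-sided Student's t-test
with the conventional */**/*** stars at 0.05/0.01/0.001.

## Numerical and interface choices

TSV is canonical; genotype tables are wide (hybrid × marker); bulk
counts can be read from a two-sample VCF with `AD` depths (biallelic
records only, multiallelics skipped with a warning). Sorting is stable
(mergesort) everywhere ties can occur, so outputs are order-independent
and byte-reproducible under a fixed seed; report files are written with
a fixed float format and the run log records versions, seeds, and knobs
but no timestamps.

The acceptance script scales the study design down (2000 hybrids for the
heritability and scan stages, a 300-hybrid subpanel for the GAP stage,
5000-variant null scan) — sizes chosen as the smallest that keep the
Monte-Carlo noise on the reported quantities small.

## Known limitations

- No linkage-disequilibrium decay, genotyping error, or allele dropout.
- The log-normal null for G′ is an approximation; heavy-tailed depth
  distributions can inflate thresholds (the MAD trim mitigates this).
- Heritability assumes no genotype-by-year interaction variance
  (confounded with residual in the one-way layout).
- The GAP model is purely additive over markers; fully linked markers in
  a panel double-count their shared signal (as the summary() of a
  redundant panel makes visible), so panels should carry one marker per
  QTL.
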