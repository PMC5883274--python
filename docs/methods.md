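# Methods

`songmark` implements a complete marker-discovery procedure for
nucleus-vs-surround microarray contrasts of the kind used to catalogue
constitutive molecular markers of songbird vocal nuclei (HVC vs shelf,
RA vs ventrolateral arcopallium, nXIIts vs supraspinal nucleus, Area X vs
ventral striato-pallidum), together with a synthetic-data generator that
reproduces the statistical structure of those studies so the whole chain
is testable without the original data.

## Probe curation

EST-derived probe collections carry characteristic defects, each handled
by a dedicated rule:

* **Poly-T priming artifacts.** A run of ≥ 15 consecutive T starting
  within the first 5 bases of the 5′ end marks a second-strand oligo-dT
  priming product; the probe assesses the wrong strand and is removed.
  The 5-base start tolerance absorbs vector-trimming slop.
* **Alignment thresholds.** cDNA/EST probes need a genome alignment with
  ≥ 95% identity, 60-mer oligos an alignment score ≥ 25; probes failing
  both are removed (`unaligned` when no alignment exists at all,
  `low_score` otherwise).
* **Multi-locus probes.** Passing alignments on two or more distinct
  *named* chromosomes make a probe uninformative about a single locus.
  The unplaced-scaffold pseudo-chromosome (chrUn) never counts as a named
  chromosome: a secondary chrUn hit at > 95% identity is the signature of
  an allelic copy and the probe is kept with the flag
  `chrun_allelic_retained`. A probe aligning *only* to chrUn is kept and
  flagged the same way, so the decision is auditable.
* **Annotation.** Gene assignment is same-strand only. Overlap with a
  model → `exonic_or_overlapping`; otherwise the nearest same-strand
  model within 3 kb (cDNA) or 5 kb (oligo), measured closest-edge to
  closest-edge → `proximal`; an overlap that exists only on the opposite
  strand is reported as `antisense_conflict` and never assigned.
  Coordinates are 0-based half-open everywhere, including the exported
  BED9 regulation track (green `0,170,0` up, red `200,0,0` down, black
  `0,0,0` assessed non-differential).

## Expression statistics

Two-channel (common-reference, dye-balanced) arrays are background
corrected by the *half* rule (foreground − background, floored at 0.5),
normalized per print-tip group by a robust loess fit of M on A (span 0.3,
degree 1, 3 robustness iterations; groups under 50 spots fall back to the
global curve, since a local fit on a handful of spots chases signal
rather than dye bias), and oriented to log2(sample/reference) by flipping
the sign on arrays whose sample was in Cy3. Oligo-array values arrive
pre-normalized and instead pass two filters:

* **Low-signal filter.** The per-probe detection statistic is the max of
  its per-region mean intensities. Probes are ranked high→low; the
  inflection onto the near-background shoulder is located automatically:
  the steepest interior descent of the rank-smoothed curve marks the
  cliff, and the first rank where the descent relaxes (below
  max(peak/3, 2 × median interior slope)) marks the top of the shoulder.
  The removal threshold is the mean over the following 2w ranks
  (w = 1% of probes) plus 2.5 × its SD. A curve whose steepest interior
  descent is under 10 × the median descent has no detectable inflection
  (a unimodal, all-expressed array scores ≈ 4 on this ratio) and nothing
  is removed. The chord-distance ("knee") rule was evaluated and
  rejected: on majority-expressed arrays its maximum lands on the upper
  convex arc of the curve, far from the background shoulder.
* **CV filter.** Probes whose stdev/mean across samples (computed on the
  unlogged scale) is strictly greater than 2 × the population-mean CV are
  removed; non-positive means are removed with their own flag.

Differential testing is an empirical-Bayes moderated two-group t. With
per-probe pooled variances s²_g on d_g degrees of freedom, the prior
(d₀, s₀²) is fitted by moments on log s²_g (inverse-trigamma solution;
no positive solution ⇒ d₀ = ∞, complete shrinkage), the posterior
variance is s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and
t = M / (s̃_g √(1/n₁ + 1/n₂)) on d₀ + d_g degrees of freedom. d₀ = 0
reproduces the ordinary pooled t exactly and d₀ → ∞ the fixed-variance
z-form; the implementation matches Bioconductor limma's `eBayes` to
1e-6 on shared input (verified in the test suite through Rscript).
Multiple testing uses Benjamini–Hochberg, or Storey q-values (BH scaled
by the median-λ π₀ estimate, λ ∈ {0.05, …, 0.95}, clipped to (0,1]).

## Cutoff calibration

Instead of a blind FDR threshold, each contrast's significance cutoff is
calibrated against an independent validation panel (in the motivating
studies, in-situ hybridization images scored as differential /
non-differential / excluded). Every retained probe of a labeled gene
contributes its p-value to its class. Candidate cutoffs are the
cumulative histogram bin edges (20 equal-width bins plus refined edges
0.001, 0.005, 0.01, 0.02 in the small-p region); the chosen cutoff
maximizes **TPR − w·FPR** with w = 1.5 by default, ties toward the
smaller cutoff.

The weight is a deliberate design choice. The calibration exists to fix
a *high-confidence* cutoff: a false marker costs downstream riboprobe
design and imaging, a missed marker costs nothing but coverage. The
unweighted Youden objective stops where the class densities cross; under
the moderate effect sizes this pipeline targets that crossing falls in a
flat region of the objective, where the argmax is decided by label
sampling noise rather than by the data's structure. Weighting the FPR at
1.5 moves the stopping condition to the density-ratio-1.5 point, which
is insensitive to that noise. `fpr_weight=1` restores the classical
index. Degenerate cases (identical class distributions, empty classes)
fall back to the conventional p < 0.05 with a warning, as does a
contrast with no labels at all; a manual override reproduces visually
chosen cutoffs.

## Gene scoring

Probes of one gene whose genomic intervals overlap by more than 75% of
the shorter interval (single linkage, so chains merge) are one *unique
probe group*; each group contributes the arithmetic mean of its members'
p-values and log2 fold changes and is counted once. A gene with at least
one group is **differential** when ≥ 50% of its groups fall at or below
the calibrated cutoff (inclusive boundary: 1 of 2 qualifies), otherwise
non-differential; genes with no retained probes are **not assessed**.
Direction is up/down only when all significant groups agree in sign;
disagreements are surfaced as `conflict` and flagged, never
majority-voted away. Averaging happens before thresholding. Where an
independent in-situ call exists it overrides the array call on conflict
(flagged `$discordant`), fills unassessed genes, and an unevaluable
image leaves the array call intact.

## Intersection and over-representation

The common universe is the intersection of the per-contrast assessed
gene sets; markers restricted to it are partitioned into the exclusive
Venn regions (15 for four contrasts), with named aggregates for the
all-shared region, the direct-motor-pathway region (HVC∩RA∩nXIIts), the
telencephalic region (HVC∩RA∩AreaX) and per-nucleus unique sets. ORA
tests each GMT set intersected with the universe by the upper-tail
hypergeometric probability P(X ≥ k); sets need overlap ≥ 2, rows with
p ≤ 0.01 are retained, BH runs over the retained rows (an alternative
flag adjusts over all eligible sets), and q < 0.05 flags the reportable
rows. The hosted tool this mirrors does not expose its exact statistic;
the one-sided hypergeometric tail is our interpretation.

## Synthetic data generator

The generator emulates the structure of paired laser-capture studies:
3–9 nucleus/surround pairs per contrast, a common-reference two-channel
design with alternating dye orientation and a smooth per-print-tip
intensity-dependent bias for the cDNA platform, pre-normalized
single-channel values for the oligo platforms, and probe libraries
containing cloning artifacts and multi-locus probes.

* **Genome and probes.** Four named chromosomes plus chrUn;
  non-overlapping gene models with intergenic gaps larger than any
  annotation window, so each probe's only in-window model is its parent.
  Per gene, 1–6 probes; additional probes of a gene default to probing
  the same transcript segment (> 75% mutual overlap,
  `redundant_probe_fraction = 1`), the documented regime of EST-derived
  oligo designs that the collapsing rule exists for; set the fraction
  lower for independent probes.
* **Intensities.** Log-normal model: log2 baselines from a two-component
  mixture — expressed genes at N(10, 1.5) gene-level with N(0, 0.5)
  probe offsets, a `low_expression_fraction` (default 0.2, matching the
  ~7–22% of probes such screens typically discard as undetected) of
  genes near background at N(4, 0.5). Replicate noise SD 0.4 on log2
  (typical array replicate noise), with mild per-probe heterogeneity
  (lognormal σ = 0.15) so variance moderation has something to do.
  Differential genes (default 10%, 60% up) are shifted by
  ±`effect_size_sd` × noise SD (default 2 SD = 0.8 log2) in nucleus
  samples only; near-background genes receive no shift — an unexpressed
  gene shows nothing in either region.
* **Labels.** The validation panel is stratified by class, emulating
  deliberately constructed differential / non-differential validation
  subsets: up to half the `label_coverage × n_genes` slots (default
  0.32, a 320-gene panel at the default scale) go to differential genes,
  the rest to non-differential ones; `label_error_rate` flips labels and
  `label_excluded_fraction` (default 5%) marks genes unevaluable.
* **Determinism.** One master seed; each stage draws from a named
  substream, so identical configurations give byte-identical tables.

What the generator does **not** model: spatial array layout beyond the
tip-group index, probe-sequence-driven intensity effects, correlated
noise between physically overlapping probes, within-pair (same-bird)
covariance by default (`pair_effect_sd` exists but the real covariance
is unknown, so it defaults to 0), and cross-species orthology. Passing
tests therefore demonstrate the correctness of the *procedure* under a
plausible noise model, not performance on the original arrays.

## Operating characteristics and problem sizes

The reference study configuration (1000 genes, 2 probes/gene, 10%
differential at 2 SD, 6 pairs — sized to run the full chain in seconds)
yields, at the calibrated cutoff of 0.05: gene-level sensitivity ≈ 0.87–0.97
over assessed differential genes, empirical false-discovery proportion
≈ 0.01–0.13 across seeds (expected count of false calls ≈ 5, so the
proportion carries Poisson-scale noise around ≈ 0.06), and essentially
perfect direction assignment. Sensitivity is defined over *assessed*
differential genes: a gene whose probes sit at background in both
regions is correctly reported as not assessed, as in any expression
screen. Null simulations (10,000 probes, 3 per group) give KS < 0.01
against uniform p-values and a 0.05-level type-I error within
[0.048, 0.052].

## Numerical notes

* Inverse trigamma by Newton iteration (50 steps, relative tolerance
  1e-10), with the asymptotic branches 1/√y and 1/y at the extremes.
* Probes with zero residual variance are excluded from the prior fit;
  a group with fewer than 2 samples is rejected.
* Loess fallbacks: groups under 50 spots use the global curve; a group
  with all-identical A subtracts its median M.
* Tie-breaks: calibration ties go to the smaller cutoff; annotation ties
  go to the larger overlap, then lexicographic gene id; best alignment =
  named chromosome first, then primary rank, then score/identity.
* The low-signal filter declines to act (with a warning) on curves with
  fewer than 50 probes, zero range, or no detectable inflection.
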