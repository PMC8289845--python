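# Methods

This note documents the statistical models implemented in `evquant`, the
choices made where a procedure admitted more than one reading, what the
synthetic-data generators do and do not emulate, and the numerical
conventions.

## Label-free quantification (`evquant.lfq`)

**Normalization.** "Median and scale normalization on the total signal" is
implemented on the log2 scale: each biological replicate (one
condition × replicate sample) is affinely transformed so its median equals
the across-sample median of per-sample medians and its median absolute
deviation (MAD) the across-sample median of per-sample MADs.  Targeting the
median of per-sample statistics — rather than pooled statistics over all
observations — makes the transform of every other sample exactly invariant
to a constant rescaling of one sample, so instrument-level intensity drift
cannot leak into fold changes.  The applied shift and scale per sample are
returned in a report from which the transform can be inverted exactly.
Samples with fewer than two observations, or zero MAD, are left unscaled
(logged).

**Differential abundance.** Per protein, on the peptides observed in both
compared conditions, we fit by ordinary least squares

    log2(xic) = β0 + β_cond·1[condition = A] + peptide + replicate + ε

with peptide and replicate as fixed categorical effects (replicate is the
block index shared across conditions).  The protein's log2 fold change is
β_cond (A − B) and its p-value a two-tailed t-test on β_cond with
n − rank(X) residual degrees of freedom.  This is the simplest model
consistent with "adjusted on peptides and biological replicates"; variance
is estimated per protein (no cross-protein moderation), and missing XICs
are omitted rather than imputed, since no missingness model is part of the
procedure.  Proteins detected in only one condition receive a ±∞
fold-change sentinel and no p-value — the downstream "unique" rule consumes
them, so no pseudo-count fold change is ever fabricated.  A noiseless fit
with a zero contrast reports p = 1 (exactly null); a noiseless non-zero
contrast has no valid test (p absent, flagged).

**Multiple testing.** Benjamini–Hochberg step-up over the proteins of one
comparison, NaNs passed through (delegated to
`statsmodels.stats.multitest.multipletests`).

## Filter cascade and categorization (`evquant.categorize`)

Boundary semantics are literal: "more than 200/411" is a strict inequality
(200/411 itself is retained); the enrichment cut "log2FC ≥ 1 or ≤ −1" is
inclusive; "adjusted p < 0.05" is strict; "between −1 and 1" excludes the
endpoints the enrichment rule claims.  A protein passing the evidence and
specificity checks in *at least one* GFP-bait condition is retained (the
disjunctive reading).  Exclusion reasons are assigned in the fixed order
non-specific → contaminant → insufficient evidence, and a protein that is
quantifiable nowhere cannot be judged non-specific.

Proteins with |log2FC| ≥ 1 but adjusted p ≥ 0.05 belong to no stated
category; they are assigned `common` with the audit flag
`not_significant_large_fc` so the output remains an exhaustive partition.
The significance level, fold-change cut and contaminant threshold are all
configuration, defaulting to the printed values (0.05, 1, 200/411).

## Compartment enrichment (`evquant.enrichment`)

The reported p-value is the exact hypergeometric upper tail
P(X ≥ k | N, K, n) (scipy's exact survival function; no normal
approximation), uncorrected, as in the original analysis; a BH-adjusted
column is emitted additionally and explicitly labeled an extension.
Multi-compartment proteins count once per compartment; list proteins absent
from the reference are dropped from n (the reference is the universe) and
reported in coverage attributes.  The universe is an explicit input — no
database is bundled or fetched.

## Immunogold stereology (`evquant.stereology`)

Counts are pooled across fields before computing LD = Ngo/P,
RLI = LD_comp/LD_cell, Nge = ΣNgo·P/ΣP and partial χ² = (Ngo − Nge)²/Nge
(plain Pearson terms, no continuity correction).  Degrees of freedom use
analyzed compartments only: a compartment with zero grid points is excluded
and df reduced.  The 10 %-of-total partial-χ² cutoff flags *preferential*
labeling only when the compartment is over-labeled (Ngo > Nge);
under-labeled compartments meeting the cutoff get a separate `depleted`
flag.  A table with zero observed golds yields an explicitly flagged
all-undefined result rather than an exception.

## Image analysis (`evquant.coloc`)

* Preprocessing is per 2D plane: median filter with a disk footprint
  (default radius 1 px) then rolling-ball background subtraction
  (`skimage.restoration.rolling_ball`, the canonical implementation of the
  named operation; default radius 25 px within the stated 10–50 px range),
  clipped at zero.
* Size thresholds ("less than 15 pixels", Golgi "threshold of 20 pixels")
  are read as connected-component areas in pixels, consistent across both
  rules; the interpretation is a parameter, so a diameter reading can be
  obtained by converting before the call.
* Punctate-compartment counting detects local maxima with a caller-supplied
  prominence (the macro's noise-tolerance equivalent, which has no printed
  value; the synthetic fixtures use a prominence well above the noise
  floor), assigns each to its thresholded component, counts at most one
  maximum per component, and keeps components below the size cutoff.
* Mander's coefficients are the standard thresholded form: M1 sums
  channel-1 intensity over voxels where *both* channels exceed their
  thresholds, divided by channel-1 intensity above its own threshold.  The
  alternative (numerator unrestricted by channel 1's threshold) can exceed
  1 and was rejected to keep M ∈ [0, 1].
* Pearson correlation is computed over a caller-supplied cytoplasm mask;
  3-channel colocalization is mask-volume overlap (|A∧B|/|A| for ordered
  pairs plus the three-way term), matching the volumetric mask procedure.
* Interactive per-cell thresholds are replaced by explicit configuration
  values; interactivity is out of scope.
* Coordinates are 0-based (z, y, x); EV diameters are (height + width)/2 of
  the bounding rectangle, histogrammed with configurable bin width.

## Flow cytometry (`evquant.flowcyto`)

MFI defaults to the *median* (robust, the standard cytometry estimator);
because the source text uses "mean fluorescence intensities" once, the
estimator is a config switch.  Gating is an explicit numeric cascade
(debris box on FSC/SSC, doublet tolerance on FSC-A/FSC-H, GFP cutoff at the
99.9th percentile of a non-transfected control when provided) replacing
gating by inspection.  No spectral compensation is implemented (none was
needed for GFP/AF647 on separate lasers).  Both closed-form statistics are
implemented exactly as printed (see README).

## Synthetic data (`evquant.simulate`)

The generators emulate the *statistical structure* of each assay's data,
not its physics:

* **Proteome** (default 400 proteins, 3 conditions × 4 replicates): XICs
  are log-normal on the log2 scale (all thresholds are log2); planted
  classes are enriched_A/B (|log2FC| = 2 by default), common, unique_A/B
  (absent from the other bait condition), contaminant (repository frequency
  uniformly above 200-of-411), nonspecific (more abundant in the control)
  and low-evidence background (single peptide, single replicate).
  Specifically isolated proteins are absent from the non-transfected
  control pulldown, as in a bait-dependent immuno-isolation.  Per-sample
  intensity drift (SD 0.25 log2 units) exercises normalization; missingness
  is completely at random (the real mechanism is unknown and intensity-
  dependent missingness is deliberately not modeled).  The compartment
  reference annotates CD63-class proteins preferentially as
  lysosomal/late-endosomal and CD9-class as plasma membrane, over a
  1000-protein decoy universe.
* **Immuno-EM** (default 4 named compartments + "rest", 7 fields): gold
  counts are multinomial with probabilities point_fraction × RLI for the
  named compartments, the residual compartment absorbing the remaining
  mass so configured RLIs are realized exactly in expectation; grid-point
  counts are apportioned deterministically (largest remainder), since the
  digital point array samples fixed compartment areas.  Under RLI = 1
  everywhere this makes the χ² test exactly calibrated.
* **Image stacks**: solid spheres of known voxel support in a
  (8, 128, 128) volume; a configured fraction of channel-2 spheres shares
  center, radius and amplitude with channel-1 partners (so overlap 1 with
  zero noise gives voxel-identical channels, and overlap 0 is disjoint by
  rejection-sampled placement).  Ground truth records the voxel-count
  overlap of the exact masks — the oracle for Mander's recovery.  No PSF,
  no photon noise model: any shape with known support suffices for testing
  the measurement code, which is the generator's purpose.
* **Flow events**: log-normal fluorescence clouds (median = configured MFI
  exactly at the population level), a debris population at low scatter and
  a doublet population at FSC-A ≈ 2×FSC-H.

All generators are deterministic given their config; the same seed yields
byte-identical tables.

What passing these tests shows: the estimators recover known truth under
their own model assumptions at realistic sizes.  What they do not show:
robustness to intensity-dependent missingness, peptide interference,
segmentation error, optical aberration or instrument-specific artifacts —
none of which the generators model.

## Orchestration and sizes

`evquant.pipeline.run_pipeline` fans a single master seed out to per-stage
sub-seeds via `numpy.random.SeedSequence.spawn`, writes every stage table
as TSV plus the resolved config, and halts with a stage-named error on
failure.  Default problem sizes (400 proteins; 2000 χ²-calibration tables
of 500 golds; 40 compartments per image channel; 10⁴ flow events per
condition) were chosen as the smallest sizes at which the asymptotic
calibration checks are stable, and are configuration, not constants.

## Known limitations

* The linear model treats replicate as a fixed block effect shared across
  conditions; whether the original processing used fixed or random
  replicate effects, or variance moderation, is not derivable from its
  description — results for low-replicate designs may differ from tools
  that moderate variance.
* "Median and scale normalization … on the total signal" admits a
  total-sum-scaling reading; the median/MAD reading implemented here is
  recorded per sample in the normalization report so either can be audited.
* Manual curation steps (transmembrane-protein annotation, manually chosen
  per-cell thresholds, manually defined kinetic start points) are replaced
  by explicit configuration and are not reproduced.
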