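# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic generators do and do not emulate,
and the numerical decisions a user may want to override.

## Pupariation timing and the screen statistic

**P50.** A vial's cumulative pupariation fraction is treated as a
piecewise-linear function of observation time. P50 is the time at which it
first reaches 0.5: if an observation equals 0.5 exactly, that time is taken
(the earliest, if a plateau sits exactly at 0.5); otherwise the two flanking
observations are linearly interpolated. A curve that plateaus below 0.5 is a
developmental arrest — P50 is undefined (NaN, `reached = False`), which is
deliberately distinct from the "insufficient replicates" error raised when a
genotype × diet cell has no usable vial at all. Vials with fewer than three
pupae never enter P50 averaging, but vials with zero pupae still count
toward the pooled pupariation fraction, i.e. toward arrest evidence. Times
are continuous hours from the midpoint of the egg-laying window.

**Excess delay.** Δ = (P50_g,HSD − P50_g,ND) − (P50_c,HSD − P50_c,ND),
computed on replicate-mean P50s; its standard error adds the four cell SEMs
in quadrature. Adding a constant to all observation times shifts every P50
by that constant and leaves Δ unchanged; Δ is exactly zero whenever the
genotype's curves equal the control's.

**Hit classes.** The classifier crosses the normal-diet phenotype with the
high-sugar severity. Severity per diet: *full arrest* = pooled pupariation
fraction exactly 0; *partial arrest* = fraction in (0, 0.5), consistent with
P50 being undefined below 50%; *delay* = completes (fraction ≥ 0.5) with the
delay statistic at or above the threshold; otherwise *none*. Defaults:

* `delay_h = 12` hours. No numeric cut-off is published for what counts as a
  delay; half a day cleanly separates biological delay from scoring
  granularity at the screen's daily cadence, and all planted effect sizes in
  the generator are set at 2× this threshold.
* `alpha = 0.05` for the replicate-level genotype × diet interaction test
  (two-way ANOVA with replication, via statsmodels OLS/anova_lm). The
  significance gate applies only when at least two qualifying replicate P50s
  exist in all four cells; arrest classes are decided by fractions alone.
* Combinations outside the six-class taxonomy — delay on both diets, or full
  arrest already on normal diet — classify as `none`: the first is not a
  stronger-on-sugar phenotype in the taxonomy, the second is a
  diet-independent (essential-gene) phenotype.
* No multiple-testing correction across the screen by default (per-gene
  calls are reported raw); a Benjamini–Hochberg flag would be a caller-side
  addition since the classifier exposes the raw interaction p.

**Crowding check.** One-way ANOVA of replicate P50s across larval-density
groups, per diet — the design assumption that 5–150 larvae per vial do not
shift timing.

## Image quantification

* **Sum projection** sums a (z, y, x) stack over z; 2-D input passes
  through. Background subtraction happens after projection, not per slice.
* **ROI quantification** follows the moved-ROI convention: the background
  region is the same ROI displaced to an unstained area, so areas must match
  and any constant offset cancels exactly. Unequal areas are an error unless
  area-normalization is requested. Negative corrected values are reported
  (with a warning), never clipped — they are informative about background
  placement.
* **Line profiles** sample the segment at ≤ 1-px spacing and average 15
  perpendicular bilinear samples (1-px spacing, symmetric about the
  segment) per position; 15 px is the conventional width for noise
  suppression, and bilinear interpolation is our choice — nothing in the
  measurement definition prescribes the interpolator.
* **tGPH center:surround ratio**: center = mean over 0.45 ≤ x ≤ 0.55,
  surround = mean over [0.35, 0.45) ∪ (0.55, 0.65], with the closed/open
  endpoints applied exactly (a 1e-9 tolerance guards float representation of
  the normalized positions); samples outside [0.35, 0.65] are ignored. The
  ratio is scale-invariant, so illumination differences between specimens
  cancel.
* **Droplet area fraction** thresholds the droplet channel within the cell
  mask with Otsu's method by default; the threshold is an explicit parameter
  because no published segmentation rule exists for this readout. A
  contrast-free mask returns 0. The fraction is per supplied mask — per-cell
  versus per-field is the caller's choice of mask.
* **GCaMP series**: per frame, mean GCaMP over mean tdTomato within each
  soma ROI, then an unweighted mean across neurons. Rescaling both channels
  by a common per-frame factor (illumination drift) leaves the series
  unchanged.

## Phosphoproteomic insulin response

Channel totals are equalized to their grand mean before any ratio is formed,
mirroring total-signal normalization of isobaric-label reporter intensities;
the operation preserves within-channel fold changes and is idempotent.

The response call is fold-change-only: insulin/mock ratio of replicate means
per site, *up* if ≥ 1 + θ and *down* if ≤ 1/(1 + θ), with θ = 0.30. The
reciprocal down-rule (≤ 0.769) is the default because it is symmetric on the
log scale; the plain-ratio reading (≤ 0.70) is available as
`down_rule="linear"` since "a > 30% difference in either direction" admits
both. Counts are at the phosphosite level by default — the published totals
are described as phosphorylation changes — with protein-level counting
available through `dedupe_proteins`. Per-site p-values (one-way ANOVA on
log2 abundances across condition groups, or the two-sample t-test inside
`insulin_response`) feed volcano-style outputs only; they do not gate the
counts.

The dependence set contains control-regulated sites whose direction is
*none* in **every** supplied knockdown (`mode="all"`); requiring only one
knockdown (`mode="any"`) is provided because the published definition does
not say which was used. The dependent fraction is reported as an integer
percent of the control total.

Pathway overrepresentation is the two-sided Fisher exact test on
(hits ∩ pathway, hits ∖ pathway, background non-hits ∩ pathway, rest), with
pathway sets intersected with the background first and raw p < 0.05 as the
significance rule (no multiplicity correction, matching per-pathway
reporting; a BH option belongs upstream of the significance column if
wanted).

## Calibration

Metabolite assays default to a linear (Beer–Lambert) standard curve; ELISAs
default to the four-parameter logistic y = d + (a − d)/(1 + (x/c)^b), whose
inverse is closed-form. Mean blank absorbance is subtracted before fitting
when blanks are supplied. r² < 0.98 triggers a warning; inversion outside
the calibrated absorbance range warns of extrapolation; the 4PL asymptote is
non-invertible and raises. `normalize_sample` applies
normalized = raw × dilution / protein (hemolymph is conventionally assayed
at a 10-fold dilution). Units are labels only; the single conversion helper
maps millimolar to µg/mL given a molar mass.

## Synthetic data: what it emulates, and what it does not

All generators derive every random draw from the integer seed in their
parameter object, so identical parameters reproduce outputs bit-for-bit.

* **Pupariation**: per-larva event times are normal, truncated at zero, with
  the high-sugar mean shifted by a control diet effect (default 40 h) plus
  any planted excess delay; arrest is per-larva Bernoulli censoring. The
  normal-truncated form is a modelling choice — the cumulative curves it
  produces are sigmoid, which is all the P50 statistic sees — not an
  inferred mechanism. Defaults: 5 vials × 30 larvae, base P50 110 h,
  SD 6 h, observations every 8 h (follow-up cadence) or 24 h (screen
  cadence). Planted class effects sit at 2× the classification thresholds
  (24 h delays, arrest probability 0.7 for partial arrest).
* **Fat-body images** are single-plane tilings of rectangular cells with a
  nucleus disk at each center and membrane bands at tile boundaries; the
  reporter channel is cytoplasm = 100 and membrane = enrichment × 100
  before noise. The membrane half-width is 5% of the cell pitch and bands
  are centered on the boundary pixel, so a nucleus-to-nucleus line has its
  middle tenth entirely on membrane and the flanking tenths on cytoplasm —
  the geometry the center:surround score assumes. Droplets are random disks
  accumulated until the planted area fraction is met (within one droplet's
  area). Real tissue has curved membranes, inhomogeneous cytoplasm and
  out-of-focus light; passing tests show the operators are correct on their
  own geometric conventions, not that segmentation of real images is solved.
* **Calcium frames** plant a constant per-soma GCaMP/tdTomato ratio with
  optional transient frames and a sustained KCl response; tdTomato is
  constant per neuron up to noise. No photobleaching, motion, or focal
  drift.
* **Phospho tables** plant a responsive fraction of sites (default 20%,
  effect ±1 log2 unit, random sign) in the control genotype, scale the
  effect by the blunting factor (default 0.2) in both knockdowns, and add
  log2-normal noise (default 0.05). Site→protein mapping is many-to-one by
  construction. No peptide-level structure, missing values, or
  interference/ratio compression is simulated.
* **Plates** are exactly linear with Gaussian absorbance noise; standards
  span the sample range.

## Problem sizes in tests and the acceptance script

The oracle comparisons run at 1,000 random curves (P50), 1,000 null
simulations (interaction type-I), 20 replicate screens (excess-delay
recovery), ≥ 10 cell pairs (tGPH), and the Fisher oracle enumerates all 2×2
tables with row margins ≤ 14 exhaustively plus a 3,000-table seeded sample
with margins ≤ 30. These sizes give comfortable statistical resolution for
the tolerances asserted (e.g. ±0.02 on a 0.05 rejection rate needs ≈1,000
draws) while keeping a full run in tens of seconds.

## Known limitations

* The hit-class thresholds (12 h, fraction 0.5) are package defaults, not
  reconstructions of the original screen's unpublished rule; borderline
  genes can change class under other thresholds.
* The tGPH score assumes the membrane crosses the line near its midpoint;
  badly placed endpoints shift membrane signal into the surround and bias
  the ratio down. The operator does not detect this.
* Droplet quantification with Otsu assumes a bimodal within-mask intensity
  distribution; weakly stained tissue violates this.
* The 4PL fit uses a heuristic initialisation (asymptotes from the extreme
  standards, |b| = 1); pathological standard sets may need explicit starting
  values.
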