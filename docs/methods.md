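# Methods

## The identification-independent signature model

Small-window DIA fragments every precursor in a fixed, prescheduled
sequence of isolation windows, once per cycle.  Two consequences make
identification-free quantification possible:

1. **The window index of an MS/MS scan is determined by the instrument
   method, not the sample.**  The scheme used here tiles the densely
   populated 400–800 m/z precursor range with 6-Th windows overlapping by
   1 Th (5-Th step), giving exactly 80 windows per cycle.  Coverage is
   gapless; interior m/z values at window junctions are intentionally
   co-isolated by two windows.
2. **The acquisition-cycle number of a scan is comparable across runs
   after RT alignment.**  With an 8-s cycle time matched to the ~8-s
   chromatographic peak FWHM, each eluting peptide is fragmented in its
   window in at least two cycles (guaranteed within ±FWHM of the apex for
   every apex phase; the ±2σ support of a Gaussian with FWHM = cycle time
   is shorter than two cycles and admits a worst-case single sample, so
   the two-cycle guarantee is stated on the ±FWHM support).

Every admitted MS/MS scan is assigned a dual index
`dID = (rt_bin, window_index)`; the complete grid of TMT reporter-ion
intensities over all dIDs, one matrix per channel, is the run's proteome
signature.  Unobserved grid cells hold 0, never NA: the signature is a
complete quantitative object and downstream aggregation of any number of
runs is missing-data-free by construction.

The central assumption is that co-isolation — several precursors plus
background sharing one window and cycle — is *reproducible* across runs,
because the sampling scheme is static.  Interference therefore cancels in
comparisons instead of behaving like stochastic noise; the cost is ratio
compression, which blunts effect sizes but not classification.

## Pipeline stages and parameters

**Reporter extraction** (`reporter_quant`).  For each channel the most
intense peak within ±10 ppm (default, `tol_ppm`) of the theoretical
reporter m/z is taken; unmatched channels record 0.  Reporter m/z values
are monoisotopic cation masses derived from the reagents' elemental
compositions (C8H16N+ plus 13C/15N substitutions); the unit tests verify
them against an independent isotope-mass computation.  The TMT N/C
isotopologue pairs are ~6.3 mDa apart — about five 10-ppm half-windows at
m/z 127 — so channels cannot cross-assign.  No isotopic-impurity
correction is applied.

**RT alignment** (`alignment`).  Seven doubly charged anchor precursors
(466.7743, 660.3674, 464.779, 437.2732, 587.3539, 587.864, 706.4723 m/z)
that appear in essentially every run are traced within their isolation
windows (summed intensity within ±10 ppm of the anchor m/z per scan).
The trace is smoothed with a 3-point moving average and the apex located
by 3-point parabolic interpolation, giving sub-cycle accuracy from a
once-per-cycle trace; an apex must rise 5-fold (`min_snr`) above the
trace median to count as detected.  Any ≥2 detected anchors define a
strictly monotone piecewise-linear map from run RT to the reference
(first) run's RT, extrapolated linearly beyond the terminal anchors.
Runs whose anchors elute out of order are rejected.

**Dual indexing** (`alignment.build_signature`).  The RT bin is
`floor(mapped_rt / rt_bin_width) + 1` with `rt_bin_width` defaulting to
the cycle time, so one bin is one acquisition cycle.  One subtlety: the
scans of a cycle carry staggered timestamps (each window is acquired at
its own dwell offset), so binning raw timestamps would place late-cycle
windows exactly on bin boundaries, where sub-second alignment residuals
flip a whole window by one bin between runs.  `build_signature` therefore
reduces each scan to its cycle midpoint — subtracting the per-window
timestamp phase, a constant within a run — before mapping and binning
(`phase_correct=True`).  Bins then cut *between* cycles for every window
alike, and the assignment tolerates residuals up to half a cycle.

If two scans collide on one dID (possible when inter-run drift compresses
cycles), the scan with the larger summed reporter intensity wins
(`collision="keep_max"`); summing is available but double-counts
re-sampled peaks unevenly across runs.  The grid extent is fixed by the
reference run's aligned gradient span; scans mapping outside it are
dropped and counted.

**Aggregation** (`alignment.aggregate_runs`).  Samples are (run, channel)
pairs.  By default the feature set is the intersection of dIDs that
received a scan in every run: prescheduled acquisition makes this overlap
near-complete, and the few cells displaced by residual drift in some run
are excluded rather than zero-filled, so no sample carries placeholder
values for events another run measured.  `features="all"` keeps the full
scheduled grid instead.  Aggregation is invariant to run input order.

**Normalization and batch correction** (`normalize`).  The signature arm
scales every sample row to the mean pre-normalization total (equal signal
per channel; conserves total matrix signal), then works in
log10(x + 1) — the pseudocount handles structural zeros.  Batch effects
(one TMT run = one batch) are removed with the parametric empirical-Bayes
location/scale model (ComBat, via scanpy's implementation behind this
module's interface), with no biological covariates.  Because every
multiplexed run contains all populations, removing per-batch feature
means strips the run axis while leaving the biological contrast intact;
this scale → log → batch-correct → PCA order is packaged as
`pipeline.signature_pca`.  The peptide-based arm instead uses global
median normalization in log space (per-sample median to the global median
of medians) and, where required, down-shifted noise imputation: missing
entries are drawn per sample from Normal(μ − 1.8σ, (0.3σ)²) in log10
space, with μ, σ the sample's observed mean and SD (`mode="absolute"`
shifts by 1.8 log10 units instead; the σ-scaled convention is the
default).  Imputation never alters observed entries and is deterministic
under a fixed seed.

**Clustering and drivers** (`analysis`).  PCA is an exact full-SVD
decomposition of the log10(x+1), mean-centered matrix; unit-variance
scaling is off by default because features share units and variance
carries signal.  Cluster drivers are the top-|loading| features of a
component, joined to whatever peptide identifications map to those dIDs —
unidentified features are retained with empty annotation, which is the
point of the method: they quantify regardless.  Peptide-level utilities
(best-q-value unique-peptide collapse, exact subset intersection counts
for replicate Venn analyses, Pearson correlation with 95% CI between
protein and transcript log2 fold changes) support the comparison arm.

**Library augmentation** (`library_tools`).  Library-search engines only
export quantification for fragments present in the spectral library;
adding the fixed reporter masses as fragment rows (annotation
`reporter_<channel>`, default relative intensity 1.0) to every entry
makes the reporter region visible to such searches.  The operation is
idempotent and never touches non-reporter rows.

## What the simulator emulates — and what it does not

`synthetic` generates ground-truthed cohorts mirroring the benchmark
designs: three TMT10 label-swap mixes of two human-like populations
(5 + 5 channels), a TMT11 yeast standard with wild-type plus three
single-knockout strains (his4 126–127C, met6 128N–129N, ura2 129C–130C,
WT 131N/131C — the conventional layout of the commercial standard), and
dilution series at 0.5/1/5/10 ng.

Per run, every cycle emits one MS/MS scan per window; a scan's reporter
intensities sum the contributions of all co-isolated peptides (channel
abundance × Gaussian elution factor, FWHM 8 s) — co-isolation is emergent
from shared windows and elution times, not scripted — plus a log-normal
multiplicative noise term (CV 15% default) and a sample-derived
background reporter floor.  The floor and background clutter scale with
the loaded amount, as co-isolated labelled material does; this matters,
because a load-independent floor would make the dilution series dominate
the aggregate's variance.  Contributing peptides also leave a residual
precursor peak (30% of their reporter sum) that anchor tracing uses.
Anchors are always included with population-independent abundance.

Scale-down choices (defaults, all configurable): 320-s gradient → 40
cycles × 80 windows = 3200 MS/MS scans per run; 1500 peptides over 300
proteins for the human cohort (≈0.6 peptides per grid cell, matching the
density of real runs where most scans carry peptide signal), two-thirds
of that for yeast; per-protein population log2 fold changes ~ N(0, 1);
base abundances log-normal (log10 mean 4.5, SD 0.5) at the nominal 10-ng
input.  Inter-run RT warps are monotone (offset ± slope ± sinusoid) with
magnitudes chosen so drift *in cycle units* matches a well-behaved
replicate series: sub-percent slope deviation, ±2 s offset, sub-second
nonlinear residual.  On a 12×-shortened gradient, percent-level slope
error would skip whole RT bins — an artifact of the scale-down, not a
property of the method.

Not modelled: fragment-spectrum content (only residual precursors and
random clutter), isotope envelopes and isotopic impurity, ion statistics
/ shot noise, FAIMS or ion mobility, peak tailing, and real proteome
fold-change structure.  Passing tests therefore demonstrate that the
pipeline's bookkeeping, alignment, aggregation and statistics behave as
designed under realistic geometry and noise — not that real biological
samples will separate with any particular explained variance.

## Numerical choices and degenerate inputs

* Window lookup accepts an isolation center within half a window step of
  the nearest scheme center (ties at the midpoint resolve by rounding);
  anything farther is unassignable and excluded with a count.
* The last window may extend past the precursor range's upper bound so
  all windows keep equal width.
* Anchor detection requires ≥2 detected anchors, else alignment aborts;
  apex parabolic interpolation is clamped to ±half a cycle.
* RT maps require strictly increasing anchor sequences on both sides;
  missing anchors are dropped pairwise before fitting.
* A run with zero admitted scans still yields an all-zero grid of the
  scheduled shape (channel count must then be supplied explicitly).
* Equal-signal scaling refuses all-zero samples by name; median
  normalization and imputation refuse samples with no (or <2) observed
  values; batch correction refuses singleton batches (variance
  inestimable), passes constant features through untouched, and is a
  no-op for a single batch.
* PCA refuses constant matrices; with all components retained,
  scores × loadingsᵀ reconstructs the centered matrix to float tolerance.

## Known limitations

* The RT-bin grid is only as good as the anchor set; gradients whose
  drift between anchors exceeds half a cycle will misassign cycles, and
  the piecewise-linear map cannot capture nonlinearity between anchors.
* Ratio compression from co-isolation is inherent; fold changes read off
  signatures are attenuated relative to peptide-level quantification.
* Reporter extraction takes the most intense in-window peak; in very
  dense reporter regions a co-eluting interference closer in intensity
  than the tolerance window would be indistinguishable from signal.
* The intersection feature rule discards dIDs missed by any single run;
  with many poorly aligned runs the feature set shrinks accordingly
  (`features="all"` trades this for zero-filled cells).
* ComBat assumes roughly Gaussian feature distributions in log space and
  batches that share the biological design; correcting batches that are
  confounded with biology (e.g. one species per run) removes the
  biological signal along with the batch axis.
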