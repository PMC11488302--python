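# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `qppdyn` pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The pattern model

A quasi-periodic pattern (QPP) is a voxel × window template `T` of BOLD
activity that recurs throughout a resting-state series. Its *sliding
template correlation* (STC) is the Pearson correlation between the
flattened template and every same-length series segment, stepped by one
frame. Occurrences are strict local maxima of the STC above a threshold
(0.2); the template is refined by averaging the series over occurrence
windows until consecutive templates correlate above 0.99, and the whole
procedure is repeated from many random starting frames (200 in the full
protocol). Windows that would straddle two subjects in the concatenated
group series are excluded throughout (their STC entries are 0), so no
pattern instance ever crosses a subject boundary.

**Threshold ramp.** The first three refinement iterations accept maxima at
0.1 before tightening to 0.2 (final occurrences are always at 0.2). With a
single fixed 0.2, only starting frames essentially inside a true
occurrence ever converge onto the pattern, so the fraction of productive
starts equals the pattern's scan occupancy; at realistic occurrence rates
that sits at or below the 5 %-of-candidates robustness bound and makes
recovery a per-seed coin flip. The ramp — standard in released
implementations of the algorithm — lets partially overlapping starts
collect instances first, roughly doubling the productive-start fraction
without changing what counts as an occurrence.

**Convergence bookkeeping.** A start whose final template has fewer than
two occurrences is flagged non-converged: a "pattern" occurring once (its
own seed window, a fixed point of the iteration) is not recurring. The
iteration is capped at 20 rounds (the cap is a termination guarantee; the
converged flag records whether the 0.99 criterion was met). Zero-variance
windows correlate as 0 and can never be occurrences. Template-convergence
correlation is computed on the flattened V·W vectors.

## Clustering and robustness

Candidates are compared by a combined spatiotemporal distance: spatial =
1 − (max over circular window shifts in ±2 of the flattened-template
correlation), temporal = 1 − (max over the same ±2 frame shifts of the
STC-trace correlation), combined = their 2-norm. The temporal alignment
matters: candidates that found the same pattern at a 1-frame phase offset
have sharply peaked STC traces that decorrelate at lag 0 and would
otherwise split one pattern into two clusters. Agglomerative clustering
uses average linkage; the dendrogram is cut at a fixed combined distance
of 0.3, placed in the measured structural gap: same-pattern candidates
cohere below ~0.1 in both domains, *hybrid* templates (stable mixtures of
two motifs whose occurrences collide in time) sit around 0.2–0.4 from the
clean clusters, and unrelated templates sit near √2 and beyond.
(Silhouette-based selection of k was tried and fails structurally here:
scattered non-pattern candidates are mutually farther apart than two
distinct patterns' tight clusters, so average linkage merges the pattern
clusters before the scatter at any capped k.) The mean silhouette of the
chosen partition is reported for diagnostics. Hybrids that slip inside the
cut can win representative selection — their union occurrence set
maximises the total summed STC — which is the main residual failure mode
observed on two-pattern phantoms (about one seed in ten).

A cluster is robust iff (i) it holds ≥ 5 % of all candidates (including
non-converged ones in the denominator), (ii) its members account for ≥ 5 %
of all occurrences of clustered candidates, and (iii) more than half of
its members each occur in ≥ 80 % (6-frame window) or ≥ 50 % (20-frame
window) of subjects. The representative QPP is the member with the highest
sum of STC values over its occurrences. An empty robust set is a valid,
reported outcome (it is the expected result for a group in which the
pattern has disintegrated); when fewer than two candidates converge at
all, an empty report is returned rather than an error.

## Projection, rates, and QPP regression

Projection correlates one group's representative template with another
group's series and takes supra-0.2 STC maxima as projected occurrences;
the projected pattern is the voxel-wise mean over those windows.
Occurrence rates are counts per minute, per subject (half-open segment
membership) and pooled.

QPP regression builds, per subject segment, the regressor
`r_v(t) = Σ_τ STC(τ)·T_v(t−τ)` (linear convolution of the STC onset train
with the template row, truncated to the segment) and replaces each voxel by
the residual of a least-squares fit on [intercept, r_v]. The fit is over
the whole concatenated series, matching group-level regression; the
convolution never crosses subject boundaries. Zero-variance regressors
pass the voxel through unchanged, flagged.

## Null-model voxel significance and peak timing

For a long (20-frame) pattern, 50 null templates are built; each averages
randomly placed, mutually non-overlapping segments that avoid all real
occurrence windows, with per-subject segment counts matched to per-subject
occurrence counts (rejection sampling, 10 000-attempt cap with diagnostics).
The root sum square (RSS) of each voxel's template time course is
thresholded at the 95th percentile (linear interpolation) of the pooled
null RSS values (a per-voxel variant is available); strict exceedance is
required. Significant voxels are assigned to six named regions; voxels
outside them are dropped.

Peak timings: per occurrence window and voxel, peak 1 = argmax of |BOLD|
over the first half of the window, peak 2 over the second half, ties to
the earliest frame; per-voxel timings are means over occurrences, in
frames (seconds = frames × TR). Three comparison tiers, each with
Benjamini–Hochberg FDR over (2 peaks × regions) or (2 peaks × pairs):

1. per-region voxel-timing means between groups (two-sample pooled t);
2. region-pair timing differences within each group;
3. region-pair timing *intervals* between groups, where each voxel of the
   smaller region is differenced against the mean timing of the bigger
   region (compensating unequal voxel counts).

**Caveats measured on the phantom.** The tier-3 construction shares the
bigger region's mean-timing error across all interval values, inflating
the two-sample t by √(1 + n_small/n_big) — worst (√2) for equal-size
regions. Next to a strong true effect the raised FDR threshold therefore
admits occasional stray null pairs; under the full group null the
false-flag rate stays within its nominal band (tested). The per-occurrence
argmax estimator is also biased toward the half-window centre at finite
SNR, shrinking recovered inter-regional lags (a 2-frame embedded lag is
recovered as ≈ 1.6 frames at the default amplitude/noise of 1); group
*differences* in lag remain detectable because the shrinkage is shared.

**GSR and timing.** The preprocessing chain follows filter → quadratic
detrend → GSR → unit variance, per subject. For timing analyses on the
phantom the chain is run *without* GSR: the phantom has no global nuisance
signal, so the mask mean is dominated by the motifs' lag-imbalance
residual, and regressing it mixes a lag-shifted copy of the waveform into
every voxel, compressing inter-regional lags two- to four-fold (measured).
On real data, with genuine global nuisance, GSR serves its usual purpose;
this is precisely the known signal-distortion caveat of GSR.

## Group statistics

Voxel t-maps: one-sample across occurrence windows (frame-resolved by
default; window-collapsed on request) or two-sample pooled-variance
between stacks; BH-FDR at q = 0.05 over all voxels × frames of one map,
then a spatial cluster-extent filter keeping 6-connected components of
≥ 10 voxels at each frame. Zero-variance voxels give t = ±∞, p = 0,
flagged. Static FC: ROI time series are means over region voxels per
subject; Fisher z = atanh(r) per pair. Occurrence-rate comparisons:
two-sample pooled t with BH-FDR across the family of patterns tested;
degenerate (zero-variance, identical) rate vectors report p = 1.

## The synthetic world

The generator emulates a fast rodent acquisition: TR 0.5 s, 1200 frames
(10 min) per subject, 10 subjects by default, on a 20×20×4 grid (1600 mask
voxels) holding six rectangular regions in two anticorrelated networks.
Motifs are half-sine lobes per region (for 20-frame motifs, a first-half
lobe and a sign-flipped second-half lobe, encoding the flux from one
network's activation to its reversal), with per-region signed amplitudes
and real-valued lags (waveform shifted and truncated at window edges;
|lag| < W/2). Occurrences follow a jittered-periodic process: inter-onset
interval 60/(rate·TR) frames ± 25 % uniform jitter, rejected within one
window of the previous onset or segment edges — honouring
quasi-periodicity and yielding well-separated STC maxima. I.i.d. Gaussian
noise (sd 1.0) and optional per-voxel random quadratic drift (coefficient
sds given on a [−1, 1] time axis) are added. One master seed spawns
per-subject streams, so adding subjects never perturbs existing ones.

Default amplitude/noise = 1 makes extraction succeed but not trivially
(the raw per-window template-segment correlation is ≈ 0.1; the band-pass
raises it above threshold). Occurrence rates: 1/min for the flagship
single-motif fixture; 2/min per motif for two-motif clustering fixtures,
a realistic short-pattern recurrence chosen because the 5 %-size
robustness bound requires each pattern's scan occupancy to sit comfortably
above 5 %. Two-group fixtures default to 8–10 subjects per group, matching
typical cohort sizes.

What the generator does **not** emulate: haemodynamic response shapes,
physiological/global noise spectra, spatial autocorrelation of noise,
motion artefacts, or registration errors. A green test therefore
establishes algorithmic correctness and statistical calibration in an
idealised world, not robustness to real-data confounds.

## Numerical conventions

- Voxels are flattened in C-order over mask-true grid positions; frames
  are 0-based; subject segments are half-open; occurrence frames are
  window starts.
- STC via cumulative window sums and a template–series cross-correlation
  matrix product; results clipped to [−1, 1]; equivalence with the
  brute-force per-window Pearson is tested to 1e-12.
- Variance uses the unbiased (n−1) estimator throughout; t-tests are
  pooled-variance two-tailed by default.
- Band-pass: 4th-order Butterworth, zero-phase (forward–backward), per
  subject segment — timing analysis cannot tolerate phase distortion.
- Storage: float32 in NIfTI templates, float64 in CSV/JSON; serialization
  round-trips are tested.
- All randomness flows from explicit integer seeds (PCG64); identical
  seeds give bit-identical outputs, including serialized CSV/JSON.
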