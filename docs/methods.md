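# Methods

## The quantity

The fractional amplitude of low-frequency fluctuations (fALFF) of a BOLD
time series is the share of its spectral power inside the low-frequency
band,

    fALFF = sum_{0.01 <= f <= 0.1 Hz} |X(f)|^2  /  sum_{f > 0} |X(f)|^2 ,

with the DC coefficient excluded from both sums and the Nyquist bin
included when the series length is even.  "Power" here means squared DFT
amplitudes — equivalently, by Parseval, the sum of squared deviations of
the series from its mean.  (The older vertex-wise literature sums
*amplitudes* rather than squared amplitudes; that convention is available
as `mode="amplitude"` in `network_falff` for cross-checking, but the power
ratio is the package's definition.)

At the network level the signal of interest is not a single vertex but an
intrinsic connectivity network (ICN).  Its representative time series is
obtained by spatial regression (the first stage of dual regression): at
each time point the vertex pattern is regressed on
[intercept | variance-normalized template maps], and the slope series of
template k is that network's time course.  Network fALFF is the power of
the representative series computed from band-pass-filtered data divided by
its power in the unfiltered data.  Because the band-pass is an ideal
rectangular DFT mask and both series come from the same linear operator,
the ratio lies in [0, 1] exactly — no filter roll-off can push band power
above total power.

## Temporal preprocessing

Default chain, applied per subject on T x V vertex-sampled data
(TR = 2 s, 243 acquired volumes by default):

1. discard the first 5 volumes (signal equilibration);
2. scale the 4-D grand mean to 10,000 (one global factor; fALFF-invariant);
3. regress [intercept | Friston-24 motion expansion | WM/CSF channels]
   per vertex (least squares; rank-deficient designs fall back to the
   pseudo-inverse solution rather than failing);
4. remove linear and quadratic trends;
5. ideal FFT band-pass at 0.01-0.1 Hz (bins with f_lo <= f <= f_hi kept,
   DC zeroed).

Stage order is configurable but the band-pass must come last: the stage
before it defines the "original" series used as the fALFF denominator.
Each stage appends to the series' stage tag and refuses to re-apply
itself silently.  Despiking, slice timing and motion *correction* are
deliberately absent: synthetic data are generated in template space, and
on such data those stages are identities.

Motion QC follows the displacement conventions of resting-state practice:
FD(t) = sum |Delta translations| + 50 mm * sum |Delta rotations|, with
mean and RMS taken over frames t >= 1; maxTran is the Euclidean
translation distance from the first frame and maxRot the maximum absolute
axis rotation in degrees.  Default pass thresholds are 3 mm, 3 degrees
and 0.5 mm mean FD.  The reported rmsFD is the RMS of the FD series (an
alternative reading — RMS of the realignment parameters themselves — is
not implemented; the choice is documented here because the field uses
both).

## Cross-subject alignment

Group ICN templates are derived in the ranking-and-averaging group-ICA
style:

- **Per-subject spatial ICA.**  X ~ A S^T via FastICA with the V x K maps
  as sources; maps are z-scored and flipped to non-negative skewness
  (resolving sign indeterminacy before any similarity computation).
  K is a config constant (default 6 for synthetic runs); an "auto" option
  picks the smallest K reaching 90% PCA variance.  A full
  Laplace-approximation model-order estimator is out of scope.
- **Similarity.**  Normalized mutual information between every pair of
  pooled ICs: 64 equal-width bins per map's own range, MI normalized by
  sqrt(H_x H_y).  NMI is invariant to monotone transforms of either map,
  which is why it tolerates ICA's scale and sign ambiguities.
- **Matching.**  Greedy seed-and-grow: seed each aligned component (AC)
  with the globally largest unassigned cross-subject similarity, then grow
  best-first — at every step the unassigned (subject, IC) with the highest
  mean similarity to the current members joins.  Best-first growth makes
  the output invariant to subject input order; exact ties break by
  (subject index, component index).  Each AC holds exactly one IC per
  subject; ICs are consumed; matching stops when any subject runs out.
  On 3-subject instances the greedy total within-AC similarity stays
  within 5% of the exhaustive optimum (verified against an
  enumeration + Hungarian oracle).
- **Consistency.**  A member's centrality is the sum of its similarities
  to the other members.  Its permutation null replaces every *other*
  subject's member with a uniformly random IC of that subject and
  recomputes the centrality; p = (1 + #{null >= obs}) / (n_perm + 1).
  Centrality-weighted averages of the member maps (z-scored) give the
  group map.  ACs whose fraction of significant members (alpha = 0.05)
  strictly exceeds 60% are retained and labeled ICN01, ICN02, ...

## Group inference

Per network, two statistics are reported side by side: a plain pooled
two-sample t (which also accepts printed mean/sd/n summaries and then
matches the raw-data route exactly) and the F of the group term in
fALFF ~ group + age + sex + education, F = ((RSS_red − RSS_full)/1)/(RSS_full/(n−p)).
A true multivariate test across all networks (Pillai's trace via
statsmodels MANOVA) is available as an optional mode; the per-response F
is the primary analysis.  No multiple-testing correction is applied across
networks by default (Bonferroni / Benjamini-Hochberg are opt-in).

Partial correlations use the residual method: both variables are
residualized on [intercept | covariates], r is the Pearson correlation of
the residuals, and p comes from t = r sqrt(df/(1−r^2)), df = n − 2 − k.
Sex is coded 0/1; all results are invariant to affine recoding.  Practice
intensity passes through a Shapiro-Wilk gate (alpha = 0.1): non-normal
samples are natural-log transformed (the base cannot matter for
correlations).  Tukey's far-out rule (3 x IQR beyond the quartiles) flags
outliers, which are excluded from correlation analyses only and retained
in group tests.

## The synthetic cohort

The generator is the package's ground-truth engine, emulating a
cross-sectional two-group design: 22 experienced Tai Chi Chuan
practitioners vs 18 matched controls, TR = 2 s, 243 volumes (5 discarded).

- **Space.**  A flat vertex grid (default V = 4000, standing in for a
  down-sampled cortical surface).  No mesh topology is modeled — the
  analysis only consumes vertex vectors.  Template maps are smooth
  windowed bumps on disjoint supports (mean-centered per support, so
  disjoint maps are exactly uncorrelated); an overlap parameter widens
  supports into neighboring blocks.
- **Spectra.**  Network time courses are built in the Fourier domain:
  random phases and bin amplitudes, with the in-band and out-of-band
  amplitude groups rescaled so the in-band power fraction equals the
  planted fALFF *exactly*.  This turns noise-free end-to-end recovery
  into an identity at machine precision and makes every tolerance in the
  tests attributable to noise or preprocessing, not to the generator.
- **Levels.**  Per-network fALFF levels are drawn from group-specific
  truncated Gaussians whose means/SDs default to the emulated study's
  per-ICN table (deficits in the default-mode, bilateral frontoparietal
  and dorsal prefrontal-angular networks); `null_profile()` equalizes the
  groups for calibration studies.
- **Effects.**  Planted covariate-adjusted correlations are realized in
  residual space: the target variable's covariate-orthogonal part is a
  mix r·zx + sqrt(1−r²)·e with e orthogonalized against both the
  covariates and zx in-sample, so the planted value is the partial
  correlation by construction (up to rare clipping at the [0.02, 0.98]
  fALFF bounds).  Defaults plant intensity↔DMN (r = 0.473),
  log-RT↔left-FPN (r = 0.851) and years↔RT (r = −0.659) inside the
  practitioner group.
- **Nuisance.**  Head motion is a random walk (increments 0.05 mm and
  0.001 rad per unit severity; severity 0.5 yields mean FD near 0.1 mm,
  matching the emulated cohort's motion summaries); WM/CSF surrogates are
  smooth unit-variance noise channels.  Scans carry a positive baseline
  (default 1000) so grand-mean normalization is well posed; the discarded
  equilibration volumes carry an elevated, decaying baseline.
- **Demographics.**  Truncated Gaussians matching the emulated group
  summaries (ages 52.4±6.8 / 54.8±6.8, education 12.2±2.9 / 11.8±2.9,
  practice 14.6±8.6 years).  Weekly practice intensity draws the
  non-outlier practitioners from ≈11.0±3.0 h clipped to [4, 18] and plants
  one subject at 30 h: the sample then reproduces the reported 11.9±5.1
  summary while the 30 h subject stays beyond the 3·IQR far-out fence.  Behavioral scores (ANT conflict RT ≈ 100/115 ± 30 ms,
  accuracy 0.95 ± 0.04) are the generator's own realistic choices; the
  emulated study prints no trial-level summaries.  An optional flag keeps
  behavior for only 10 subjects per group.

What the generator does **not** emulate: hemodynamics (no balloon model),
physiological cardiac/respiratory noise, spatial autocorrelation of the
noise, surface geometry, scanner drift beyond a polynomial, or
motion-coupled signal artifacts' spatial structure.  Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated linear-mixing model, not robustness to every physical
confound of real fMRI.

## Numerical choices

- Band masks use inclusive bounds with a 1e-12 frequency tolerance; DC is
  never in the band.
- rfft bin powers carry conjugate-pair weights (2 for interior bins, 1
  for DC/Nyquist) so frequency-domain power matches time-domain power to
  machine precision.
- Spatial regression caches the pseudo-inverse of the template design for
  cohort-scale reuse; an ill-conditioned design (cond > 1e8) warns and
  falls back to the pseudo-inverse rather than failing.
- Zero-variance vertices yield missing vertex fALFF; a network with zero
  unfiltered power yields missing network fALFF with a warning.
- FastICA non-convergence raises a retriable error carrying the seed and
  iteration count; the pipeline retries a few derived seeds.
- All randomness flows from one top-level seed through numpy
  `SeedSequence` spawning; reruns with the same config and seed are
  byte-identical (fixed float formatting in every writer).

## Problem sizes in the property studies

The end-to-end studies run at sizes chosen to make Monte-Carlo bounds
tight while staying desk-scale: alignment recovery at 8 subjects,
V = 4000, T = 238, K = 6; permutation calibration over 500 simulated
components (10 subjects x 4 ICs, V = 1000, n_perm = 199); group-test
type-I error over 500 null cohorts at V = 500 with 128 analyzed frames;
power for the planted left-FPN deficit over 200 cohorts at the native 238
analyzed frames (the detectability of a planted gap depends on the real
temporal degrees of freedom, so the power question keeps the native scan
length while the null calibration uses the shorter series); partial-r
recovery over 200 cohorts of n = 200 practitioners.

## Known limitations

- The greedy matcher is one member of the "search the similarity matrix"
  family; it is deterministic and near-optimal on small instances but is
  not claimed to replicate any external alignment tool's exact output.
- Aligned components require full membership (one IC from every subject);
  cohorts where a subject genuinely lacks a network will dilute that
  network's consistency rather than drop the subject.
- The global fALFF summary is the vertex mean; fALFF of the spatial-mean
  series is available but not the default (the two differ on real data).
- Friston-24 regression on short series (T ~ 128) measurably attenuates
  in-band power (bias ≈ −0.08 in recovered fALFF at 26 regressors);
  this is a property of nuisance regression itself, shared by any
  implementation, and is why short-series results should be compared
  within, not across, preprocessing configurations.
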