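# Methods

`lewyeeg` re-implements, end to end, a resting-state EEG (rsEEG) source
analysis of cognitive reserve in Lewy-body dementias: individualized
frequency bands anchored on per-subject spectral landmarks, a linear
inverse solution (eLORETA) on a spherical head model, grand-mean
normalization and ROI-by-band aggregation, and an education-stratified
statistical design. Because no public recordings exist for this design,
the package is driven by a synthetic cohort generator whose defaults encode
the study conditions; every pipeline stage is tested against that ground
truth.

## Signal standardization and spectral analysis

Recordings are resampled to 256 Hz (polyphase), band-passed 0.1–45 Hz and
re-referenced to the common average. The band-pass is applied as the
forward–backward (zero-phase) Butterworth power response — high-pass order
2 at 0.1 Hz, low-pass order 10 at 45 Hz — evaluated in the frequency
domain. A 0.1 Hz corner has an impulse response of tens of seconds, so a
time-domain `filtfilt` on a few minutes of data is dominated by edge
transients; the frequency-domain realization has the identical magnitude
response and no transients.

Data are cut into non-overlapping 2-s epochs (a 5-min recording gives 150
epochs). Epoch screening is a programmatic proxy for expert artifact
scoring with three criteria: peak-to-peak amplitude above 100 µV on any
channel; broadband epoch variance more than 3 SD from the recording's
distribution; and a 30–45 Hz / 1–30 Hz power ratio above twice the
recording's median (an EMG proxy; the upper edge is 45 Hz because
standardized data are low-passed there). All thresholds are configurable.
A kept fraction below 75% raises a warning, the value the source study
reports as its minimum retained share. The ratio criterion uses the
recording median rather than a cohort median so the operation is
self-contained per subject.

Power spectra use the Welch approach with each full 2-s epoch as one
Hann-windowed segment, which at 256 Hz gives exactly the 0.5 Hz resolution
of the analysis grid (0.5–45 Hz). Whether segments should subdivide epochs
is unspecified in the source description; one-segment-per-epoch is the only
choice that reproduces the stated resolution without zero-padding.

Landmarks are read off the channel-mean spectrum: the transition frequency
TF is the power minimum in 3–8 Hz, the individual alpha frequency IAF the
maximum power peak in 6–14 Hz (interior local peak preferred; flags record
boundary hits and peakless spectra). Landmarks live on the 0.5 Hz grid, no
sub-bin interpolation. The individualized bands are delta = [TF−4, TF−2),
theta = [TF−2, TF), alpha1 = [TF, (TF+IAF)/2), alpha2 = [(TF+IAF)/2, IAF),
alpha3 = [IAF, IAF+2), plus fixed beta1 = [14, 20), beta2 = [20, 30),
gamma = [30, 40). The delta low edge is clipped at 0.5 Hz (flagged) when
TF < 4.5. A bin belongs to a band when its center satisfies
low ≤ f < high. Subjects whose detected landmarks admit no valid partition
(TF ≥ IAF, or a TF–IAF gap under 1 Hz, which leaves an alpha sub-band with
no grid bin) are excluded from band-wise analysis with a warning, the
analogue of per-subject screening in the original workflow.

## Forward model and inverse solution

The head is three concentric spheres (brain 80 mm, skull 85 mm, scalp
92 mm; conductivities 0.33, 0.0042, 0.33 S/m). Electrode directions come
from the standard 10-05 template montage shipped with MNE, radially
projected onto the scalp sphere; the default montage is the 30-channel
10-10 set, with a 19-channel 10-20 variant for cross-validation-style
data. The dipole potential is computed per spherical-harmonic order by
solving the radial boundary-value problem across the shells exactly
(continuity of potential and radial current, insulating scalp surface);
the series is truncated at 80 terms with a guard that the geometric tail
at the largest source radius stays below 0.1%. For equal conductivities
the series collapses to a closed form derivable with Legendre generating
functions, which the test suite uses as an independent oracle (agreement
to machine precision). Leadfield columns are average-referenced.

The source space is a uniform grid restricted to a spherical cortical
shell (0.74–0.94 of the brain radius; default spacing 5 mm, around 7000
voxels). Since no redistributable realistic template accompanies the
source description, the six macro-ROIs (frontal, central, parietal,
occipital, temporal, limbic) are assigned by angular sectors — occipital
posterior-inferior, temporal lateral-inferior, limbic a medial ring, and
the remainder split anterior/mid/posterior. This cannot reproduce
Brodmann-area boundaries (documented approximation); a loader accepts
externally supplied leadfield + parcellation CSV files when users have a
realistic model.

eLORETA weights are the fixed point of
W_v ← [K_vᵀ (K W⁻¹ Kᵀ + αH)⁺ K_v]^½ with H the average-reference
centering matrix and a pseudo-inverse throughout (the sensor matrix has
rank channels − 1), iterated to a relative change below 1e-6. Orientations
are free (3-D); per voxel and frequency bin the power is
tr(T_v C(f) T_vᵀ), with C(f) the Hermitian sensor cross-spectral matrix
from Hann-windowed epoch FFTs (its diagonal equals the Welch PSD by
construction). The full cross-spectrum, not just the PSD diagonal, is
required because source power of a linear filter depends on inter-channel
phase. Default Tikhonov weight is 1e-4 of the mean eigenvalue of K Kᵀ;
α = 0 gives the exact-localization operator used as the module's primary
correctness oracle (zero localization error for noiseless point sources).

Solutions are normalized per subject by the grand mean over all voxels and
all bins in 0.5–45 Hz, then collapsed to a 6 ROI × 8 band table of log10
mean normalized power — the unit of all statistical analysis.

## Statistics

The central design is a split-plot ANCOVA per clinical group: Education
(Edu−/Edu+) between subjects, Band (8) and ROI (6) within subjects, with
sex, MMSE and clinical unit as covariates (LED replacing MMSE for the DLB
group, whose education subgroups differ in LED). It is computed stratum by
stratum with orthonormal within-subject contrasts; the covariates enter
every stratum, so each consumes error df within strata as in the
commercial package the original analysis used — with three 1-df covariates
and N = 54 that reproduces error df of the form (B−1)(N−5). When the unit
covariate is categorical with more than two levels its dummies consume
correspondingly more df. Type III sums of squares are used with effect
coding and centered covariates; partial η² = SS_effect/(SS_effect +
SS_error); Greenhouse-Geisser ε is estimated per stratum and a corrected
p reported alongside the uncorrected headline F. With no within factors
and no covariates the procedure reduces exactly to the two-sample pooled
t test (F = t²), which is tested.

The Duncan post hoc compares Edu− vs Edu+ per band on subject band scores
(ROI-averaged activity) through the studentized-range distribution; at
range 2 this equals the pooled t test exactly, including unequal group
sizes. Band-wise significance is judged against 0.05/8 = 0.00625. A
general multiple-range implementation (protection levels 1−(1−α)^(r−1),
harmonic-mean group size) is provided for more than two means. Grubbs
screening is two-sided and detect-only at α = 0.001, with the t-based
critical value.

Demographic comparisons dispatch Student t (continuous), Fisher exact
(two-sided, by summing hypergeometric probabilities no larger than the
observed table's) and Mann-Whitney U (normal approximation with tie
correction, no continuity correction, so identical samples give p = 1).
Composite cognitive scores are z-scores against the Healthy reference per
domain, with the global score the mean of available domains. Group
comparisons use tie-corrected Kruskal-Wallis with pairwise Dunn-type z
post hocs (Bonferroni over pairs); at k = 2 the H statistic equals the
squared tie-corrected Mann-Whitney z, which is tested.

The interaction regressions are OLS with Education × activity and
covariates, reporting R², adjusted R², residual SE, model F, residual
diagnostics (Breusch-Pagan, omnibus normality, Cook's-distance counts) and
simple slopes per education level with confidence limits and
Benjamini-Hochberg FDR-adjusted p values. Education-year trends are
per-group OLS slopes on continuous years.

## The synthetic cohort

The generator's defaults are the study conditions: subgroup sizes 27/27
(Healthy), 30/45 (PDD), 21/29 (DLB); subgroup TF/IAF means of 5.6/5.8 ×
8.9/9.0 Hz (Healthy), 4.5/4.7 × 7.2/6.7 (PDD), 4.7/4.8 × 7.6/7.0 (DLB),
with SDs reconstructed from the published standard errors (SD = SE·√N);
ages, education years, MMSE (raw and corrected), LED, UPDRS III, disease
duration, visual-hallucination and RBD rates drawn to the published
subgroup means and dispersions. TF is truncated to [3.5, 7.2] and IAF to
[6.6, 12.5] Hz with IAF ≥ TF + 1.5 so that every subject's landmarks are
identifiable by the published detection rules (a TF above 7.2 pushes the
delta band past the 3 Hz search edge; an IAF at the 6 Hz boundary can
never be an interior peak).

Each voxel carries a radial dipole. Source signals are white noise shaped
by zero-phase band-limited amplitude responses (band-pass filters realized
in the frequency domain): a 1/f pink background (exponent 1.0), both
diffuse (incoherent carriers sampled across the grid) and ROI-coherent;
flat-topped delta and theta bands tied to TF; an alpha component that
rises from TF as a low-alpha shoulder to a peak exactly at IAF; and a beta
bump at 13–30 Hz. Three features of the alpha/theta shapes are load-bearing
for landmark recovery and worth stating plainly: the theta band ends one
grid bin plus Hann-leakage width below TF, so the 3–8 Hz minimum falls in
the bin containing TF; the upper alpha flank of slow peaks (IAF < 7.75 Hz)
keeps a gently rising shelf through 8 Hz, because with a 1/f background
any spectrum whose oscillations die before 8 Hz has its 3–8 Hz minimum at
8 Hz rather than at the theta/alpha transition — the published patient
landmark statistics imply exactly such sustained upper-theta/alpha power;
and slow activity keeps a reduced-amplitude floor below the delta band so
the region near 3 Hz does not undercut the TF valley. With the default
5-min epoch plan, the full spectral chain recovers TF and IAF within one
0.5 Hz bin for ≈95% of subjects each.

Patient groups have elevated delta/theta and reduced, posterior-dominant
alpha amplitudes. Education modulates alpha amplitude through a single
mechanism — a per-year slope on log amplitude (+0.043 Healthy, −0.043
PDD, 0 DLB) — which together with the subgroup education-year
distributions yields both the binary Edu+/Edu− contrast (amplitude ratio
≈1.35 over the ≈7-year gap) and continuous education trends. The
magnitude was fixed a priori such that the subgroup contrast is reliably
detectable at the published sample sizes and thresholds, as the published
outcome implies; the resulting simulated interaction η²p (≈0.08–0.17)
brackets the published 0.09. Note that the grand-mean normalization
partially absorbs alpha-level differences (alpha is a large share of total
power, especially in Healthy spectra), so effects on normalized activity
are smaller than on raw amplitude — and a genuine alpha increase slightly
depresses the normalized fixed high bands, so mirror-image beta/gamma
contrasts can accompany a strong alpha effect. Between-subject amplitude variability
is lognormal (σ = 0.2 per rhythm). The attention/executive raw score is
coupled to log alpha amplitude only in PDD-Edu− (slope 10 per log10 unit),
mirroring the published simple-slope asymmetry; domain raw scores put
patients two Healthy SDs below the reference.

Sensor data are the projection of the source signals through the
leadfield (ROI-coherent rhythms via the mean voxel gain of their ROI, the
diffuse background via carrier gains scaled to be grid-size invariant),
multiplied by a fixed calibration constant of 0.12 µV per unit source
amplitude — chosen once so that standardized channel RMS falls in the
4–20 µV range typical of average-referenced eyes-closed EEG and clean
recordings pass the 100 µV screening with the >75% retention the study
reports — plus white sensor noise of 1.5 µV RMS. Optional artifact
injection adds blink-like frontal transients and 30–70 Hz EMG bursts to a
marked subset of 2-s windows, with the contamination mask kept as ground
truth for testing the screening proxy.

What the generator does not emulate: realistic cortical folding and
conductivity inhomogeneity (spherical model only), non-stationarity within
a recording, reactivity differences between eyes conditions, channel-level
artifacts requiring interpolation, and site effects beyond a categorical
unit label. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's operations under the stated generative
model, not clinical validity on real recordings.

## Problem sizes and numerical choices

Replicate studies (pattern-recovery suites) run on a 22 mm source grid
(≈90 voxels), 16 epochs per subject and the full published sample sizes;
single-cohort landmark studies use an 18 mm grid and the full 150-epoch
plan (or 60 epochs in the acceptance script). These sizes were chosen so
the stochastic suites complete in minutes while leaving the tested
contrasts far from their decision boundaries; the forward/inverse
machinery itself is exercised at ≈1500 voxels in the localization oracle
and supports the 5 mm default. Fixed seeds derive from one master seed via
`numpy` SeedSequence spawning. eLORETA convergence tolerance is 1e-6
(relative change of the weight blocks, typically ~20 iterations);
pseudo-inverse cutoff 1e-10 of the largest eigenvalue; leadfield series
order 80 with a 1e-3 tail guard.

## Known limitations

- The sector parcellation only approximates the Brodmann-area ROI
  definitions; voxel counts and ROI shares differ from a realistic
  template (the loader accepts external models).
- STATISTICA's exact covariate handling in repeated-measures designs is
  not documented; the stratum-wise ANCOVA here reproduces its error-df
  arithmetic for 1-df covariates but treats a multi-level categorical unit
  as dummies, which costs additional df.
- The Duncan post hoc is computed per band from subject band scores with
  the pooled two-group error; software that pools error across strata can
  be slightly more liberal.
- MMSE corrected for age/education is accepted as a supplied column,
  never computed (no normative tables are bundled).
- Landmark detection at 0.5 Hz resolution quantizes TF/IAF; subjects with
  a TF–IAF gap under 1 Hz cannot receive a valid band partition and are
  excluded rather than imputed.
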