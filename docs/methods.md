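# Methods

`mersuite` implements a complete offline analysis chain for single-channel
human microelectrode recordings (MER) of the kind acquired during deep-brain
stimulation surgery: a band-pass-filtered spiking signal (multi-unit
activity, MUA) and, on the same electrode, a low-frequency local field
potential (LFP). The chain covers spike detection and sorting, per-unit
quality control, discharge-pattern statistics, oscillation and spike–field
coupling analysis, and population-level statistics. Because patient
recordings cannot be redistributed, the package ships a seeded
synthetic-recording generator that reproduces the statistical structure these
analyses assume, so every stage is validated against known ground truth.

## Spike detection and sorting

Spikes are detected by a negative voltage threshold at `mean − 3·SD` of the
band-passed signal (the default), or, in `peak-hist` mode, at 3 SD below the
mean of the local-minimum amplitude histogram — the literal reading of a
peak-height-histogram trigger. The two modes agree closely on
symmetric-noise signals; both are exposed because the original acquisition
software's exact rule is proprietary. Each crossing is aligned on its trough
with a 1 ms refractory lockout, and a 0.4 ms pre / 0.8 ms post window is cut
(values match the ~1.2 ms extracellular spike width; both configurable).
Detection is invariant to amplitude scaling and DC offset by construction.

Waveforms are reduced to their first two principal-component scores and
clustered with a k-means scan over k = 1..5. Initial centers are placed
evenly on a circle of radius one feature-SD around the cloud centroid (a
"circular seed" pattern). Each partition is scored with the pseudo-F
(Calinski–Harabasz) statistic

    F(k) = [B/(k−1)] / [W/(n−k)],

the ratio of between- to within-cluster variance scaled by degrees of
freedom; the k maximizing F is chosen, ties breaking toward fewer clusters.
F is undefined at k = 1, so k = 1 is selected when the best silhouette over
k ≥ 2 stays below 0.4. That gate was placed empirically: an arbitrary
k-means bisection of a single isotropic Gaussian cloud — no real structure —
has a silhouette near 0.35, while genuinely distinct waveform clusters score
0.7 and above on every fixture; 0.4 separates the regimes with margin on
both sides. A zero within-variance partition (noiseless renderings) returns
an infinite F sentinel; the smallest k attaining it wins.

Overlapping-spike resolution is out of scope: superimposed spikes from
near-coincident discharges form their own waveform class, which is the
correct behavior for a sorter of this design but means clean-recovery
fixtures must avoid collisions (the generator's gamma renewal option with
shape ≥ 4 emulates refractoriness for this purpose).

## Unit quality control

**Isolation score.** With f(x, y) = exp(−d(x, y)·λ/d̄), where d̄ is the mean
pairwise Euclidean distance among the unit's spike events in PC space and
λ = 10, the score is the mean over spike events x of

    Σ_{y ∈ spikes, y≠x} f(x, y) / Σ_{y ∈ all events, y≠x} f(x, y),

the average fraction of each spike's similarity mass remaining inside its
own cluster. It is bounded in [0, 1], equals ≈ 0.5 when spikes and noise are
drawn from the same distribution in equal numbers, and is invariant to rigid
motion and uniform scaling of the feature space (the d̄ normalization). Units
with a score ≥ 0.6 are "well isolated" by default.

**Stationarity.** The span between a unit's first and last spike is cut into
10 equal bins; the per-bin firing rate and mean spike amplitude are z-scored
across bins (sample SD, ddof = 1 — pinned by the closed form below) and
regressed on the bin index. The slopes (z-score/bin) measure linear drift:
a unit whose per-bin rates are proportional to the bin index has exactly
m = 1/SD(1..10) ≈ 0.3303. Empty bins contribute rate 0 and are excluded from
the amplitude regression; zero-variance bins get z = 0 so the slope is 0
rather than 0/0. Cohort-wise, units whose rate or amplitude slope reaches
the 70th percentile (linear interpolation between order statistics) are
flagged non-stationary; with independent slopes this flags ≈ 1 − 0.7² = 51%
of a driftless cohort, which is the intended operating point of a
percentile-based screen, not a defect. Cutoffs are computed per cohort
(configurable). If every unit has the identical slope on an axis, that axis
flags nobody.

## Discharge-pattern statistics

ISI mean and CV (sample SD/mean; CV > 1 suggests burstiness), time-interval
histograms, and ±500 ms autocorrelograms with 10 ms bins, min–max normalized
to [0, 1] with zero-lag self-pairs excluded (exactly symmetric by pair
counting; a flat histogram returns a flagged 0.5 curve).

**Poisson surprise.** The burst evidence for n spikes in a window of length
T against a homogeneous Poisson baseline at rate r is

    S = −ln P(X ≥ n),  X ~ Poisson(rT),  in nats.

The tail is summed in the log domain (log-pmf terms combined with
logsumexp). This matters: library survival functions underflow once
P < ~1e−308, while real episodes easily reach S of several hundred nats
(10 spikes in 100 ms on a 1.1 Hz baseline already give S ≈ 37).

**Surprise-maximization search.** Defaults: minimal burst length 3 spikes,
threshold S = 10, burst ISI limit = mean(ISI)/2, add limit = 1.5 × ISI
limit, inclusion bound 5. Candidate episodes are maximal runs of ≥ 2
consecutive ISIs below the ISI limit; each is extended forward over spikes
whose ISI is below the add limit, examining at most 5 spikes past the
current end and keeping an extension only if S increases; overlapping
candidates are merged; each is then trimmed (up to 5 spikes from either end)
to the sub-episode maximizing S. Episodes are kept iff S ≥ 10 with ≥ 3
spikes. The baseline r is the global mean rate of the train. The original
tool's "inclusion criteria = 5" semantics are undocumented; the
look-ahead/trim bound here is our concretization and is configurable.
**Burst prevalence** = burst frequency × mean burst duration = fraction of
time spent bursting, in [0, 1].

## Spectra and spike–field coupling

All spectra are Welch estimates with a 1 s Hamming window, 50% overlap and
transform length equal to one window, giving an exact 1 Hz grid; signals are
z-scored first (power in z-score²/Hz), with no further detrending. The MUA
is rectified (absolute value) after z-scoring, so its spectrum follows the
spiking envelope and exposes rhythmic modulation far below the recording's
band-pass; the LFP is not rectified. β-band power (13–30 Hz) is compared to
a baseline obtained by linear interpolation between the flanking 12 and
31 Hz bins, averaged over the in-band bins; on a flat spectrum observed and
baseline coincide exactly, and on white-noise nulls the excess estimator is
unbiased.

The spike-triggered average (STA) of the LFP averages ±500 ms snippets of
the z-scored, band-limited LFP around each spike. Band-limiting uses a
4-pole Butterworth (4–12 or 13–30 Hz) applied forward–backward for zero
phase. The shift predictor repeats the STA after adding an independent
uniform(0, 1) s offset to every spike time, wrapped at the record end so the
spike count is preserved; it destroys any spike–field locking above 1 Hz
while keeping the LFP's own statistics. Under genuine locking the STA peaks
at lag 0 and its β power dwarfs the predictor's; under independence the two
are statistically indistinguishable and both shrink as 1/√n_spikes. The STA
window must span at least 1 s of samples so its own Welch PSD (one window)
is well defined.

## Population statistics

Cohort summaries report median and unscaled MAD alongside mean and SEM, plus
the biased moment skewness m₃/m₂^{3/2}. Firing-rate-vs-isolation curves take
the cumulative cohort (isolation ≥ threshold) at 10 thresholds in [0, 0.9]
and correlate threshold with the per-threshold median and mean rates.
Outliers are values at or beyond mean ± 2 SD (population SD; ≈ 4.55% of a
Gaussian). Two-group comparisons use the Mann-Whitney U (unpaired), Wilcoxon
signed-rank (paired; all-zero differences return p = 1 with no evidence
either way) and the chi-square test on proportions without continuity
correction, all two-sided at α = 0.05.

k = 2 k-means clustering of (firing rate, CV) — optionally adding the MUA
and STA-LFP β powers — runs on raw feature scales (no standardization, to
match how such cohorts are plotted; a flag enables it), with 20 seeded
restarts, and is assessed with per-point silhouettes. A genuine
two-subpopulation cohort yields mean silhouette > 0.8 with no negative
values; a single continuous population with right-skewed rates yields the
"not well separated" signature: negative silhouettes and/or a second cluster
far too small to be a balanced subpopulation. Note that this signature is a
property of realistically skewed data — an isotropic Gaussian cloud bisects
cleanly (all silhouettes positive) and only shows boundary ambiguity.

## Synthetic recordings

The generator produces what the analyses assume: renewal spike trains
(Poisson, or gamma with shape κ; κ → ∞ is the periodic limit) at
SPN-like low rates (~1–5 Hz) or fast (~30 Hz) discharge; injected burst
episodes (by default 10 spikes at 10 ms ISI, placed without overlap);
linear rate and amplitude drift emulating injury potentials, realized by
time-dependent thinning and amplitude scaling (|fractional slope| < 2);
1/f^a LFPs with discrete 8–30 Hz components; spiking phase-locked to an LFP
oscillation through an inhomogeneous Poisson intensity
λ(t) = r·exp(κ·cos(φ(t) − φ₀))/I₀(κ), which preserves the mean rate and
reduces to a plain Poisson train at κ = 0; and extracellular rendering that
embeds one of four biphasic 1.2 ms templates at each spike time in white
Gaussian noise, with optional sub-threshold "hash" spikes stressing the
false-positive failure mode. Defaults: fs_mua = 20 kHz (configurable up to
44/48 kHz — all spectral code takes fs as a parameter), fs_lfp = 1375 Hz.
Everything is seeded and bit-reproducible.

What the generator does **not** emulate: electrode drift in space,
multi-channel geometry, biophysical waveform changes during injury (drift
is a stylized linear stand-in), non-Gaussian noise, or line artifacts.
Passing tests therefore demonstrate correctness of the estimators under
their stated assumptions, not robustness to every pathology of real MER.

## Numerical choices and limitations

- Percentiles use linear interpolation between order statistics; the ≥
  comparison at the cutoff makes the rule reproducible.
- Pseudo-F ties choose the smaller k; an all-identical point set is an
  error, zero within-variance with distinct centers is +inf.
- The surprise search merges overlapping candidates before trimming, and
  trimming only shrinks episodes, so episodes never overlap.
- Jitter in the shift predictor wraps at the record edge rather than
  deleting spikes, preserving n.
- Statistical calibration tests (null flag rates, type-I error, unbiasedness
  bands) are inherently stochastic; they run on fixed seeds at the sample
  sizes stated in the tests, chosen so the checks sit several SEs inside
  their bands under the verified behavior.
- Problem sizes in tests and the calibration script (up to 60–100 s
  segments, 20 kHz, cohorts of a few hundred units) are desk-scale choices;
  every estimator takes duration and sampling rate as parameters.
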