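# Methods

This note records the models, conventions and free choices behind `pupcalls`,
in the order data flows through the pipeline.

## Signal analysis conventions

Audio is mono PCM, nominally 250 kHz / 16 bit, 3.5 min per recording. The
band-pass (25–110 kHz) is a linear-phase FIR (Hamming-windowed sinc, 401
taps) applied by overlap-add convolution with its constant group delay
removed, so onsets are unbiased; stopband attenuation exceeds 50 dB. The
sonogram uses 512-sample Hann-windowed blocks with half overlap, giving a
1.02 ms frame step; the frequency resolution is *reported* under the
fs/(block/2) convention as 0.98 kHz while the internal bin spacing is
fs/block (488 Hz). Processing is float32 end to end (ample for 16-bit input)
and chunked so memory stays flat on 52.5 M-sample files.

Per frame we compute **spectral purity** (max-bin power / total power; 0 for
an all-zero frame), **mean frequency** (power-weighted), and **spectral
discontinuity** between adjacent frames, defined here as 1 − cosine
similarity of the normalized power vectors. Discontinuity is exposed as a
secondary splitting criterion (split a voiced run where discontinuity is
high *and* purity falls below the voicing threshold) and is off by default:
on tonal pup calls the purity/mean-frequency pair alone recovers synthetic
ground truth essentially perfectly, and the precedence among the three
criteria is an open design choice of this implementation.

**Call detection.** A frame is voiced when purity ≥ 0.25 (configurable; the
noise floor of a 257-bin frame sits near 1/257·ln 257 ≈ 0.02) and mean
frequency lies in band. Voiced runs separated by ≤ 10 ms merge; runs shorter
than 5 ms are dropped. Segment boundaries are the outer edges of the first
and last voiced frame (± half a frame step). Recordings with fewer than 10
calls are excluded from all cohort analyses.

**Clicks.** A frequency cell is *empty* when its power is below 2× the
median cell power of the recording; a frame is a click frame when fewer than
200·(n_cells/512) cells are empty. Consecutive click frames (gaps ≤ 2
frames) form one event, since a single millisecond transient straddles
half-overlapped windows. Calls and clicks are mutually exclusive: click
frames cannot be voiced, and click candidates inside detected call segments
are discarded — an abrupt within-call pitch jump places one broadband
transition frame mid-window that would otherwise masquerade as a click.

**Pitch.** The track is the argmax-power frequency per frame; frames with
purity < 0.10 are dropouts. The dropout threshold sits well above the noise
floor (~0.02) but below the purity of fast FM chirps (~0.15+), so pitch is
kept wherever tonality survives. Jumps are |Δf| > threshold between
neighbouring tracked frames, bridging dropouts up to 10 ms (jumps often
straddle brief energy dips); they are never measured across call boundaries.
The per-call max jump uses the same adjacency rule with no threshold.

## Bouts

All inter-call gaps of a day's cohort (genotypes pooled) are histogrammed at
bin sizes 50–300 ms in 10 ms steps, bins anchored at 0 s. Per bin size the
minimum-count bin with center in the absolute window 0.15–0.32 s is taken
(ties → smallest center; empty bins are eligible, so a cohort with no gaps
near the window yields a degenerate low-window estimate rather than an
error); centers are averaged over bin sizes. Calls are split at gaps ≥ the
cutoff (the boundary case counts as inter-bout). An isolated call is a bout
of size one, with recording edges counting as bout boundaries.

## Syllable classification and entropies

Nine types: flat, up-FM, down-FM, chevron, one-jump-up, one-jump-down,
multi-jump, harmonic, other. Jump pattern takes precedence (≥ 2 jumps →
multi-jump; 1 → one-jump-up/down by sign, at a 5 kHz criterion). Jump-free
contours: total excursion < 2.8 kHz → flat; a single prominent rise-fall
reversal (hysteresis 0.8 kHz) with ≥ 2.4 kHz prominence on both sides →
chevron; net slope ≥ 3 kHz → up-/down-FM; anything else (dips, multi-
extremum curves, too-short tracks) → other. `harmonic` is reserved for an
externally supplied overtone flag — a dominant-frequency track cannot reveal
one — so the default rules never emit it. The thresholds are configurable;
the entropy analyses depend only on labels, so any deterministic scheme
preserves their structure.

Usage entropy is the plug-in Shannon entropy (bits) of the label
proportions. The sequence entropy models the label sequence as a first-order
Markov chain: H₂ = −Σ_y p(y) Σ_x p(x|y) log₂ p(x|y) with p(y) the empirical
predecessor marginal and p(x|y) the empirical transition rows. Transitions
are counted within recordings only; bout boundaries do not break pairs. No
bias correction is applied. We read the leading weight of the published formula's
H₂ as the predecessor marginal, i.e. standard conditional entropy; the
plug-in estimate then satisfies H₂ ≤ H(successor marginal) exactly.

## Cohort statistics

Every call or pause contributes to its animal's mean; animals are the units
of the two-sample comparison. The default test is the pooled-variance
Student t (df = n₁+n₂−2), two-tailed, matching the era's common default;
Welch is available by flag. A call-level variant (each call a data point,
t-based 95% CIs) provides the high-n sensitivity analysis. No
multiple-testing correction is applied across metrics by default
(Benjamini–Hochberg available). Power spectra pool all call frames per
subject; group bands are subject-level bootstrap percentile intervals (1000
resamples), a bin is significant when the two groups' 95% intervals are
disjoint, and reported significant only when adjacent to another significant
bin. Weight correlations are Pearson r with two-tailed p, computed per
genotype subset and day.

## Genotype classifier

Five features per included recording — intra-bout pause, mean per-call max
jump, bouts per recording, calls per bout, percent isolated — are z-scored
(sample SD) once over the full included set; per-subsample renormalization
is available by flag. Recordings lacking a defined feature (e.g. no
intra-bout pause because every call was isolated) are excluded. Each of
10,000 repeats draws a WT subset matching the KO count without replacement
and scores leave-one-out k-NN (k = 3 default; 1 and 5 supported) with
Euclidean distance; distance ties resolve toward the smallest row index, and
odd k on two classes precludes vote ties otherwise. The reported interval is
the 2.5–97.5 percentile range of the repeat accuracies. Note the chance
level of leave-one-out on a balanced 15 + 15 table is 0.473, not 0.500: the
left-out recording's own class is down one member (hypergeometric majority
probability), a bias the balanced design inherits.

## Synthetic cohorts

The generator is the package's test bed: it emulates the study conditions
(group sizes 40/13 at P5 and 41/15 at P8, 210 s recordings) with known
ground truth. It is a two-level hierarchy. Group-level presets hold the
per-animal means of call duration, intra-/inter-bout pause, calls per bout,
percent isolated, per-call max jump and body weight, plus between-animal SDs
reconstructed as SEM·√n from the study's reported group summaries. Each animal draws
its means from these; each recording then alternates bouts and inter-bout
gaps: bout size is 1 with the singleton probability q = (isolated fraction ×
mean bout size) and 2 + Poisson(λ) otherwise, with λ solved so the mean bout
size hits its target; intra-bout gaps are truncated normals (within-animal
SD 30 ms on [0.02, 0.23] s), inter-bout gaps shifted exponentials with a
0.35 s floor — the gap distribution is bimodal with its trough inside the
0.15–0.32 s search window by construction. Call durations are truncated
normals (within-animal SD 13 ms on [0.015, 0.15] s). The reported group
summaries include no within-animal SDs, so those two values are free
parameters of this artifact, chosen once for realism.

Contours are piecewise-linear (or U-shaped) frequency tracks at the frame
step, with smooth steps capped at 440 Hz/frame — below the smallest jump
criterion — and planted jumps drawn ≥ 6 kHz, so planted jump counts are
recoverable exactly at any grid threshold. Syllable types drive contour
shape; sequences repeat the previous type with probability 0.35, making
Markov entropy genuinely lower than usage entropy. The per-jump size mean is
calibrated analytically from the per-animal max-jump target (E[max jump] ≈
p_jump·E[size]·1.05 + (1−p_jump)·0.6 kHz); because sizes are truncated at
6 kHz, animals with very low targets are floored, biasing cohort mean max
jump up by a few hundred Hz — well inside 2 reported SEMs. Audio rendering
adds Gaussian background noise at 20 dB SNR (configurable), 2 ms
raised-cosine call ramps to avoid spectral splatter, 2 ms broadband click
bursts at 0.05 events/s placed clear of calls, and a configurable power
attenuation above 65 kHz (0.6 for the KO preset) emulating the
high-frequency deficit. Timing, contours, clicks and the animal draw use
independent child RNG streams of one seed, so annotation-only and rendered
paths share identical event streams.

The P5 KO mean call duration is not available from the reported group summaries;
the preset uses 0.041 s (shorter than the WT 0.044 s, consistent with the
reported call-level difference). HET presets equal WT. What the generator
does *not* emulate: harmonics/overtones, amplitude modulation within calls,
nonstationary noise, overlapping callers, drifting call rates. Passing tests
therefore certify the measurement chain against this event model, not
detector robustness to every nuisance in real recordings.

## Problem sizes in the validation suite

Detector fidelity is scored on five full-length (210 s) rendered recordings;
group-difference recovery uses 41/15-animal annotation cohorts (100
stochastic replicates in the acceptance script, 30 in the test suite);
classifier behaviour uses four null cohorts, one 3×-effect cohort and one
study-scale cohort with 10,000 matched resamples. These sizes give
Monte-Carlo error comfortably below the tolerances asserted while keeping a
full run in a few minutes on one CPU.

## Numerical details and edge cases

Zero-total frames have purity 0, undefined mean frequency and maximal
discontinuity. All-dropout tracks are excluded from jump statistics (NaN).
Recordings with < 2 calls have no pauses; with all calls isolated, the
intra-bout pause is undefined and the recording drops out of that metric and
of the classifier. Two identical constant groups give t = 0, p = 1. The
bootstrap uses the percentile method; reproducibility is per-seed, with CI
endpoints stable to < 1% between seeds at 1000 resamples and 20 subjects.
Histogram bins are anchored at 0 s so cutoff estimates are reproducible
across runs. Half-open [onset, offset) intervals, seconds from recording
start, 0-based indices in all files.
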