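# Methods

`cryseg` segments infant cry recordings into audible expiratory phases
(EXP), audible inspiratory phases (INS) and everything else (OTHER).
The pipeline is the classic generative-classification layout: a signal
decomposition front-end, a 13-dimensional cepstral feature extractor,
and one maximum-likelihood generative model per class, evaluated by
k-fold cross-validated classification error rate (CER).  This note
records the model assumptions, the numerical choices, and what the
synthetic corpus does and does not establish.

## Framing

All front-ends share one frame geometry: windows of 30 ms (default) or
50 ms with 30 % overlap.  At the 44.1 kHz reference rate that is 1323
samples per frame with a 926-sample hop (hop = round(0.7 × N); the
overlap is specified as a percentage, so the rounding convention is
ours).  Trailing samples shorter than one window are dropped rather
than zero-padded — padding would fabricate silent frames that bias the
OTHER class.  Frame labels come from the manual transcription by
majority time overlap, with uncovered time counting as OTHER (OTHER is
explicitly the catch-all class) and ties going to the earlier segment.

## Empirical mode decomposition

EMD extracts intrinsic mode functions (IMFs) by sifting: natural cubic
splines through the local maxima and minima form upper and lower
envelopes, their mean is subtracted, and the step repeats until the
candidate satisfies the IMF criteria — extrema and zero-crossing counts
equal or differing by one, and a (near-)zero mean envelope.

Numerical decisions, in decreasing order of consequence:

* **Criterion 2 tolerance.** A finite sift cannot make the mean envelope
  exactly zero.  It is enforced as
  `max|mean envelope| <= 10^(-resolution_db/20) * RMS(input)`, with
  `resolution_db = 50` by default, combined with a hard cap of 100 sift
  iterations per mode.  When the cap is reached the current candidate is
  accepted: on broadband material the 50 dB threshold is unreachable and
  over-sifting past that point only bleeds amplitude between modes.
  Narrowband signals (tones, chirps) converge in a handful of
  iterations and their accepted IMFs satisfy both criteria.
* **Mode-extraction stop.** Extraction ends at `max_imfs` (default 5 —
  the deeper modes of cry signals carry little further information), or
  when the residue has fewer than `min_extrema = 2` extrema, or when the
  residue energy sits `residual_energy_db = 40` dB below the input
  energy (`10·log10(E_in/E_res) >= 40`).
* **Envelope boundaries.** The two extrema nearest each end are mirrored
  about the boundary sample before spline fitting.  Clamping instead
  produces the well-known end swings that corrupt the first and last
  fraction of every envelope.
* Sifting is fully deterministic; the reconstruction identity
  `x = ΣIMF + residue` holds to float rounding by construction
  (telescoping subtraction), and is asserted at 1e-8 relative error.

EMD is applied to whole recordings, not frames: per-frame EMD would
destroy every mode slower than the frame length.  The EMD front-end
("EMD-MFCC") sums a named subset of IMFs — IMF34, IMF45, IMF234 or
IMF345 (the strongest combination in practice) — and runs the summed
signal through the MFCC extractor.

## Wavelet packet features

The level-5 wavelet packet transform over db1/db10/db20 splits
[0, fs/2] into 32 equal bands (689.0625 Hz each at 44.1 kHz).  The
transform is PyWavelets' filter bank with *periodization* extension, so
it is orthonormal: perfect reconstruction and Parseval energy
conservation are exact (to 1e-8) for frame lengths divisible by 32, and
reconstruction remains exact after truncation otherwise.  Terminal
nodes are returned in natural frequency (Gray-code) order so band k is
a frequency interval.

Per frame, the band energies `E_j = mean(coeff_j²)` are aggregated by a
bank of 32 Mel-spaced triangles — each triangle's *average over* each
uniform band, not its value at band centers, so narrow low-frequency
triangles never vanish between bands — giving Mel-weighted energies
S_p.  The cepstra are the unnormalized DCT-II of `log10(S_p + 1)` (the
+1 keeps all terms nonnegative for nonnegative energies); coefficients
1–12 plus the log total sub-band energy form the 13-vector ("WE_DCT").
Frames are *not* Hamming-windowed before the WPT by default: windowing
before an orthogonal transform would double-taper the analysis, and the
transform needs no periodicity assumption.  A flag exists in the MFCC
path only.

## MFCC

Standard front-end: Hamming window
(`w(n) = 0.54 − 0.46·cos(2πn/(N−1))`, computed half-and-mirror so the
symmetry `w(n) = w(N−1−n)` is exact in floating point), power spectrum
at the next power-of-two FFT size, 24 triangular filters with peaks
equally spaced on the Mel scale (`Mel(f) = 2595·log10(1 + f/700)`)
between 0 and fs/2, log with a 1e-10 floor (silence frames must never
produce NaN/Inf), orthonormal DCT-II, keep c₁..c₁₂.  The 13th component
is the log frame energy; c₀ is dropped because it duplicates the level
information.  The filter count and FFT size are conventional choices —
any cepstral-literature default works, and they are exposed as
parameters.  One widely circulated form of the cepstrum formula garbles
the cosine index (a filter count appears where the running index
belongs); the standard DCT-II kernel over the filter index is used.

## Classifiers

**GMM.** One diagonal-covariance Gaussian mixture per class, default 40
components (16–64 supported; 40 is the strongest setting for the MFCC
systems), fitted by EM from a k-means start.  The variance floor is
1e-4 of the global per-dimension variance, applied every M-step; EM
stops at 1e-4 relative log-likelihood gain or 200 iterations, and the
per-iteration mean log-likelihood history is kept (it is nondecreasing,
which the tests assert).  A component whose responsibility mass
vanishes is re-seeded at the worst-explained data point.  GMMs classify
*frames*; per-segment decisions are majority votes over the segment's
frames.

**HMM.** One strict left-to-right HMM per class — self-loop or advance,
no skips, π = (1,0,…,0) — with 4 or 5 states and a diagonal Gaussian
mixture per state (default 16, clipped so each component can expect at
least ~4 frames of training data).  Initialization is segmental:
uniform-duration state assignment, per-state GMM fits, then Viterbi
realignment iterated to convergence of the alignment likelihood.
Re-estimation is Baum–Welch via hmmlearn's `GMMHMM`; the scaled
forward pass provides exact sequence marginals (cross-checked against
brute-force path enumeration in the tests).  Two numerical notes:
`covars_prior = −1.5` makes hmmlearn's diagonal M-step the plain
maximum-likelihood update, preserving EM monotonicity, and
`covars_weight = 1e-9` keeps a starved component's variance positive
(with pure ML updates an empty component's variance reaches zero and
the next E-step produces NaNs).  Structural zeros of the transition
matrix cannot be resurrected by EM and are asserted after training.
HMMs classify *segments*: the frame sequence of one labeled segment is
one observation sequence.  Sequences shorter than the state count are
skipped in training with a warning.

Classification is pure maximum likelihood with uniform class priors;
ties break in the fixed order EXP < INS < OTHER.  An optional
prior-weighted mode exists but is off by default.

## Evaluation

Recordings — never frames — are partitioned into k folds (default 10)
so adjacent frames cannot straddle the train/test split.  Each fold
report carries both a per-frame and a per-segment 3×3 confusion matrix;
the headline CER (`100 − 100·trace/total`) uses the classifier's native
unit (frames for GMM, segments for HMM) and the reported figure is the
mean over folds.  Per-class precision and recall are derivable from the
confusion matrices.  A training split that lacks a class yields a
partial model set that classifies among the classes it has; a fold
whose training fails outright is skipped and reported.

## Synthetic corpus

Clinical cry corpora are not redistributable, so testing runs on a
generated stand-in that reproduces the acoustic *contrasts* the task
depends on:

* EXP: harmonic source, f0 ~ U(350, 600) Hz with 4–7 Hz vibrato, 8
  harmonics with a low-pass tilt (h^−1.2), attack/decay envelope,
  25–35 dB SNR additive noise; 0.3–2.0 s.
* INS: high-passed noise (centroid > 2 kHz) plus a weak harmonic at
  HNR −8…−2 dB; 0.1–0.6 s, usually directly after an EXP, as in the
  natural alternating cry pattern.
* OTHER: silence, pink noise, an AM "speech-like" buzz (f0 100–200 Hz,
  below any EXP fundamental), or a pure-tone beep (0.8–3 kHz).

Default mix: 45 % EXP / 10 % INS / 45 % OTHER of recording time —
expiration dominates audible cry time and inspirations are brief, as in
real cry corpora.  The `realistic` difficulty adds band-passed,
amplitude-modulated babble-like noise at 10 dB SNR.  All parameter
ranges are design constants of the generator, not measurements of any
corpus.  One seeded generator drives everything, so corpora are
bit-reproducible.

**What this does not show.** The generator's classes are far better
separated than real cry recordings: real expirations share spectral
material with speech, real inspirations are faint and often clipped by
the annotator, and real "other" includes crying *other infants*.  CER
on the synthetic corpus (typically ≤ 1 % for FFT+MFCC+GMM on the
`separable` preset) therefore validates the machinery — framing,
features, training, folding, scoring — and the *ordering* of systems,
not clinical-grade error rates.

## Problem sizes

The packaged reference corpus is 20 recordings × 10 s (seed 1,
`separable`) for the cross-validated GMM runs, and a 5-recording × 6 s
smoke corpus exercises all nine decomposition/feature/classifier
combinations end to end, with EMD decompositions cached per recording
and shared across the three EMD systems.  These sizes were chosen so a
full verification pass of the package completes in minutes on a laptop
while still giving every class hundreds of training frames per fold.

## Known limitations

* EMD has no uniqueness guarantee; mode mixing appears when component
  frequencies are closer than about a factor of 2, which also limits
  how cleanly "IMF3+4+5" isolates the cry fundamental region.
* The WE_DCT Mel aggregation over 32 uniform wavelet bands is one
  defensible mapping among several; nothing pins down a canonical one.
* Per-frame GMM decisions ignore temporal continuity entirely; the CLI
  `segment` command applies only median smoothing, not a transition
  model.
* The generator does not attempt physiologically faithful cry
  synthesis, pathology effects, reverberation, or channel variation.
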