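# Methods

`bistream` implements the statistical pipeline used to localize percept-related
neural activity during auditory bistable streaming: a listener hears a long
sequence of `ABA_` tone triplets and reports spontaneous alternations between
an integrated 1-stream percept and a segregated 2-stream percept, while
multi-site intracranial voltages are recorded. The package answers, per
recording site and at the group level, whether the neural response to the
*same* stimulus differs with the *reported percept*.

## Stimulus and behavior model

The stimulus unit is the 600 ms triplet: three 100 ms tones (A, B, A) with
50 ms gaps and a 200 ms silence before the next triplet, hence a 300 ms onset
asynchrony between successive A tones and 600 ms between B tones. Tone A sits
`df` semitones above the base tone B: `f_A = f_B * 2^(df/12)`, reported to the
nearest Hz (with `f_B` = 1000 Hz, df = 2/6/8/12 gives 1122/1414/1587/2000 Hz).
A standard block is 500 triplets (5 min).

Percept reports form a piecewise-constant timeline: a button press at time
`t` switches the label from that instant on (boundary inclusive at the
press). Dominance durations — intervals between consecutive reports — are
treated as gamma distributed; after normalization to unit mean per block and
percept, a maximum-likelihood gamma fit (location fixed at 0) summarizes
their shape, which for bistable alternation sits near 2. The first percept of
a block and the final block-truncated interval are excluded from duration
statistics (the final interval's length is censored by the block end, so
keeping it would bias the fit; this is the one place where a reasonable
alternative — keeping it as a censored observation — was declined for
simplicity).

## Synthetic data generator

No public recordings exist for this task, so the generator is the test bed
for every downstream stage. It emulates:

- **Evoked responses**: each tone onset adds a Gabor-like damped oscillation
  whose latency, width, amplitude and frequency depend on the site's
  anatomical class — short-latency (~30 ms), sharp, large responses in core
  auditory cortex (HGPM), progressively later (~80-90 ms), broader and
  smaller ones in lateral temporal and non-auditory sites. The classes
  reproduce the qualitative core vs non-core contrast, not biophysics.
- **The percept effect**: at configurable effect sites the tone-B response
  differs between percepts by `effect_amp` (default 8 uV, inside the 4-18 uV
  range such AEP differences span) within a window 60-130 ms after tone-B
  onset. The difference is injected symmetrically (-amp/2 on 1-stream
  triplets, +amp/2 on 2-stream ones): the AEP difference equals `effect_amp`
  exactly, while neither percept class carries one-sided extreme samples that
  would interact with the amplitude-rejection rule. Ground truth (effect
  sites, window, per-triplet true percept) is returned with the data and can
  never disagree with it.
- **Background**: equal-power 1/f ("pink", exponent configurable) plus white
  noise, default SD 30 uV per site. The noise floor intentionally dwarfs the
  evoked mean — as in real single-trial LFP, where evoked components emerge
  only after averaging; a smaller floor makes the 4-SD artifact rule fire on
  evoked peaks, which real recordings do not do.
- **Interference and artifacts**: a ~2.5 Hz sinusoid shared across sites
  (exercising the spatial filter) and Poisson-placed 50 ms bipolar transients
  at 8-12 x the noise SD, which trip the 4-SD rejection rule by construction.
- **Behavior**: alternating gamma(shape 2) dominance durations with
  per-percept means (defaults 22.9/32.6 s, typical of the long durations seen
  in clinical recordings) and button presses delayed by a truncated-normal
  reaction time (default mean 0.6 s).

All randomness flows through one seeded generator: identical seeds give
bit-identical blocks.

What the generator does *not* emulate — volume conduction, electrode
geometry, spatially correlated noise beyond the single shared interference
component, non-stationary vigilance effects, epileptiform activity — bounds
what green tests mean: they validate the statistics and their calibration on
data with the assumed structure, not performance on any particular patient's
recording.

## Preprocessing

Continuous voltages are polyphase-resampled to 1 kHz, band-passed 1.5-70 Hz
(4th-order Butterworth, applied forward-backward for zero phase), and cleaned
of the 2.2-2.7 Hz interference band in two steps: the band-limited component
is decomposed via the eigenvectors of its unit-diagonal spatial correlation
matrix and the projection onto the leading `min(n_discard, n_sites-1)`
components (default 30) is subtracted from the broadband signal; a per-site
temporal notch then subtracts what remains of the band. One numerical choice
matters here: a Butterworth notch this narrow at a 1 kHz rate has poles so
close to the unit circle that `sosfiltfilt` leaves ~0.2-0.9% broadband error,
so the narrow band is isolated with an exact zero-phase FFT mask instead
(out-of-band signal is untouched to machine precision; the block length makes
spectral resolution a non-issue).

Trials are 600 ms triplet-locked epochs (t = 0 at triplet onset); the
embedding analysis uses (700, 600, 700) ms windows instead, dropping the two
triplets at each block edge that lack context. The rejection rule masks a
site-trial whenever any sample deviates more than 4 SD from the site's
within-block mean; mean and SD are always computed over the whole block so
the rule is idempotent and order-independent. Rejection is per site-trial,
not per trial: a transient on one channel does not discard the triplet
elsewhere.

Labeling assigns each trial the percept reported at its onset. Excluded:
trials before the first report, and the `k = max(2, ceil(rt / 0.6 s))`
epochs preceding each press — during the reaction-time lag the new percept
has begun but is not yet reported, so those epochs are mislabeled by
construction. The formula reproduces the discard counts that pair with
reaction times of ~0.6, 1.34, 2 and 3.22 s (2, 3, 4 and 6 epochs). In
control blocks, where the stimulus itself switches, trials between a
stimulus change and the behavioral response to it are excluded the same way.
For switch-locked analyses, each press contributes exactly one trial: the
last triplet whose full 600 ms lies at or before the press, labeled by the
percept being switched *into*.

## Cluster-level-mass permutation test

Per site, the two percepts' trial sets are compared with a pointwise
two-sample t test (pooled variance; the choice between pooled and Welch is
exposed but pooled is the default). Points with two-tailed p < 0.05 whose t
values share a sign are grouped into temporally adjacent clusters; clusters
shorter than 20 samples (20 ms at 1 kHz) are discarded; a cluster's mass is
the sum of its t values. The null distribution of the most extreme cluster
mass (maximum absolute value, 0 when no cluster survives) is built by
randomly reassigning percept labels within the site's retained trials —
10,000 permutations by default, with the full t/threshold/cluster/mass
pipeline recomputed each time. A cluster's Monte-Carlo p is `(r+1)/(n+1)`,
`r` counting null statistics at least as extreme; it can never be 0. The
cluster's p is assigned to each member time point, 1 elsewhere; the site's p
is the minimum over the trial window; Benjamini-Hochberg FDR at q = 0.01
across sites yields the spatial map. Same-sign clustering and the treatment
of zero-variance points (never significant) are the two conventions the
procedure needs that are not forced by the definition; both follow standard
cluster-statistic practice.

The permutation inner loop is vectorized (group sums via an indicator-matrix
product, run detection on a flattened sign matrix with row separators) and is
verified in the tests against a scalar reference implementation and, on an
8-trial instance, against exhaustive enumeration of all 70 label
assignments.

## Percept classification

Features are the mean LFP in twelve 50 ms bins per site over the 600 ms
trial; trials missing any site (rejection masks) are dropped to keep the
matrix complete. Each of 100 repetitions: a random 4/5-1/5 train/test split;
per-feature z-scaling computed on the training and test sets separately (the
per-set convention is unusual but deliberate here; with ~100-500 trials per
set the difference from train-derived scaling is negligible and the pipeline
stays invariant to per-feature affine transforms); majority-class
undersampling to a balanced training set; features ranked by the F score
(between-class squared mean deviations over summed within-class variances,
infinite for zero-variance separation); the top `D = ceil(0.10 x training
size)` retained; then backward elimination k = D..1 dropping the lowest-F
feature each step, scoring each k with 5 subtraining/validation splits
(80/20, redrawn if single-class) under a linear SVM (C = 1); the optimal
dimension `D*` is the smallest k attaining the minimum mean validation
error. The refit model's held-out performance is the balanced accuracy
(mean of per-class recalls). Across repetitions the per-feature selection
probability is accumulated; features above 0.3 define the classifier-driven
site map. The same inner splits score every k so the validation curve over k
is not confounded by split noise.

## High-gamma band power

The 70-150 Hz band is extracted (zero-phase Butterworth), the power envelope
is the squared magnitude of the analytic (Hilbert) signal, log-transformed
(natural log), normalized by subtracting the site's mean log-power over the
block (subtraction in the log domain, making the pipeline exactly invariant
to global gain), and smoothed by a 1.5-40 Hz zero-phase band-pass. The
envelope is epoched, screened (4-SD rule on the envelope itself) and labeled
exactly like the LFP, and fed to the identical cluster permutation test.

## Diffusion-map embedding and group statistics

Each 2-s trial is z-scored per site over its own time axis (excluding
zero-variance traces), and pairwise cosine similarities are computed on the
concatenated site traces within each auditory area group — core (HGPM), the
non-core superior temporal plane (HGAL, PT, PP), and lateral STG. The cosine
is taken in absolute value, folding angles into [0, 90] degrees; the affinity
is `a = exp(-lambda tan(theta))` — 1 for collinear trials, 0 (the limit
value) for orthogonal ones. Group kernels are averaged (missing groups are
skipped with a warning), the mean kernel is row-normalized to a Markov
operator, and each trial's coordinate is its entry in the right eigenvector
of the second-largest eigenvalue — the first nontrivial one; the leading
eigenvector of the normalized operator is constant, which is precisely why
the normalized operator is decomposed rather than the raw kernel. The sign
is fixed so the largest-magnitude entry is positive, making repeated runs
and cross-subject pooling deterministic. A disconnected kernel has no
meaningful diffusion coordinate and raises an error naming the components.
`lambda` defaults to 0.2 (0.1 is the other value in routine use; smaller
lambda flattens the kernel).

Maintenance statistics are two-sided Wilcoxon rank-sum tests between
1-stream and 2-stream coordinates, per subject/condition and pooled, with
BH-FDR at 1% over the family. The switch test pools, across subjects, the
coordinates of pre-switch trials labeled by the incoming percept. Rank-sum
tests use the Mann-Whitney implementation: exact for small untied samples,
tie-corrected normal approximation otherwise.

## Problem sizes and calibration checks

The acceptance-level tests run the pipeline at the scale it is meant for:
5-min blocks of 500 triplets with ~200 trials per percept class. Type-I
calibration uses 20 effect-free 50-site blocks at 1000 permutations (the
per-site false-positive rate must sit in the 95% binomial band around 0.05,
with at most 2 BH discoveries at q = 0.01 across all 1000 site-tests); power
uses a 2x-noise-SD effect at 10 of 50 sites (>= 90% detected pre-FDR with
the best cluster overlapping the injected 60-130 ms window). The classifier
checks use 12-site blocks (reduced from the full site count to keep the
feature space proportionate to the deliberately strong 4x-noise-SD effect)
with 100 repetitions; the embedding checks use 400 2-s trials from two trial
templates. `scripts/acceptance.py` recomputes the same quantities at
moderately reduced sizes (5 calibration seeds, 30 sites, 500-1000
permutations, 50 classifier repetitions) and writes them as JSON.

## Known limitations

- The generator's evoked templates are stylized; latency/width classes are
  coarse and noise is spatially independent, so cross-site statistics are
  easier than in real data.
- The demodulated-band-transform denoising used in some ECoG workflows is
  not reproduced; standard zero-phase filtering stands in for it, since the
  downstream statistics are the package's contribution.
- Electrode localization and surface projection are out of scope; spatial
  maps are emitted as ranked site tables, not renderings.
- The eigen-decomposition convention (normalized operator vs raw kernel) and
  the per-set z-scaling convention are documented choices where the
  procedure admits variants; both are flagged in the code where they apply.
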