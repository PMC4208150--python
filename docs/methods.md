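# Methods

## The prompted-labeling model

The pipeline models a phone-side annotation loop with five stages.

1. **Sensing.** A participant follows a script of activity bouts; the phone
   records tri-axial acceleration at 50 Hz and a GPS-derived speed at 1 Hz.
2. **Recognition.** Every contiguous, non-overlapping 3-s window (150
   samples) is classified into one of four activities.
3. **Smoothing.** A window label only changes the machine's *stable state*
   after three consecutive identical detections (9 s). Shorter runs are
   absorbed: a lone mislabeled window inside a walking episode never splits
   it. Windows before the first stable state belong to no state.
4. **Prompting.** Each adjacency (stable moving state → stable standing
   state) fires one prompt asking the user to label the activity they just
   finished. A prompt unanswered after 20 s is recorded as missed (the
   boundary is inclusive: a response at exactly 20 s counts). Prompts never
   overlap; a transition arriving while one is open is queued until it
   resolves. The previous stable state's full sample span is saved as a
   labeled segment whether or not the prompt was answered.
5. **Evaluation.** Saved segments carry up to three labels — the
   recognizer's, the user's (absent on missed prompts) and the observer's
   (the scripted bout covering the segment midpoint) — compared as raw
   percent agreement.

## Synthetic signal model

Each activity class is a mean gravity vector (1 g on z), a vertical
sinusoid and white noise:

| class          | freq (Hz) | amplitude (g) | noise sd (g) | speed (m/s) |
|----------------|-----------|---------------|--------------|-------------|
| standing_still | –         | 0             | 0.01         | 0.0         |
| walking        | 2.0       | 0.4           | 0.05         | 1.4         |
| jogging        | 3.0       | 0.9           | 0.08         | 2.8         |
| bus            | 0.5       | 0.1           | 0.05         | 8.0         |

Oscillation frequency and amplitude sit in the range of human gait
(~2 steps/s walking, ~3 running) and low-frequency vehicle sway; amplitudes
are ordered standing < bus < walking < jogging so that per-window magnitude
variance alone separates standing from movement. The oscillation phase is
randomized per bout, a per-stream gravity jitter (sd 0.02 g) emulates small
orientation differences, the speed trace is piecewise-constant per bout with
0.05 m/s noise, and bout durations are rounded to whole samples. The
`noiseless()` variant zeroes every stochastic term and is used wherever a
deterministic fixture is needed.

What this generator deliberately does **not** emulate: realistic
biomechanics (impact transients, harmonics, asymmetric gait), phone
orientation changes mid-bout, GPS dropout or multipath, and audio/Wi-Fi
context. Consequently, passing tests show that the state machine,
bookkeeping and statistics behave as specified on signals with the assumed
statistical structure — not that the classifier would reach the same
accuracy on real free-living data (on the contrary, the free-living
agreement gap is exactly what prompted-label collection is meant to
measure).

## Classifier

Twelve features per window: per-axis mean and sd, mean and sd of the
magnitude |a|, signal magnitude area, and — from a 150-point periodogram of
the mean-removed magnitude — dominant frequency, total spectral energy and
spectral entropy. A constant window is defined to have zero energy, zero
dominant frequency and zero entropy. Features are z-scored with statistics
pooled over the training windows; one full-covariance Gaussian mixture
(default k = 2, `reg_covar` 1e-4, fixed seed) is fitted per class, and
classification is argmax of the mixture log-likelihood with ties broken by
the fixed class order (standing < walking < jogging < bus). Speed
validation overrides gross inconsistencies using thresholds at 0.3, 2.2 and
5 m/s (typical boundaries between standing, walking and vehicular speeds);
these are parameters, not claims.

The default training corpus is generated in-process: two seeded replicates
each of the two scripted protocols, boundary-straddling windows excluded.
A variance/frequency threshold baseline (standing below 0.05 g magnitude-sd;
jogging above 0.45 g; walking above 0.2 g; bus otherwise) serves as an
independent cross-check: on noiseless streams a noiseless-trained mixture
must agree with it on every non-boundary window. The noiseless check trains
on noiseless streams because spectral features of literally zero-noise
standing windows (zero energy/entropy) are degenerate relative to any
noisy-trained mixture.

## Respondent and observer

Respondent misses a prompt with probability `miss_probability`, otherwise
answers after a log-normal latency (median per context — 4.2 s structured,
6.11 s semi-structured, 7.77 s free-living are realistic anchors; sigma
0.4) and gives the true label except with probability
`label_error_probability` (then uniform over the other classes). The
default free-living miss rate of 0.14 corresponds to roughly 34 misses per
237 prompts. A fixed number of random variates is drawn per prompt so that,
under one seed, lowering the miss probability only converts misses into
answers (monotonicity). The observer log is the script itself as
(label, start, end) intervals; a saved segment's observer label is the bout
covering its midpoint, which tolerates segments that leak a little across a
boundary.

## Statistics

Percent agreement is `round_half_up(100 * n_same / n, 2)`; pairs with a
missing label (missed prompts) are excluded before comparison, while
recognizer-vs-observer comparisons keep every saved segment. Prompt
summaries count delivered and missed per group, and mean latency is taken
over answered prompts only (undefined when none were answered). CSUQ
summaries reduce each participant's 1–7 Likert answers to subscale means
(OVERALL items 1–18, SYSUSE 1–8, INFOQUAL 9–15, INTERQUAL 16–18) and report
mean, median and sample sd (n−1) across participants.

## CUSUM segmentation

Two-sided tabular CUSUM with drift allowance k and threshold h, both in
series units; after each detection both statistics reset and the in-control
mean μ₀ is re-estimated from the next five windows (also how it is
initialized). Defaults k = 0.25, h = 1.0 are exposed, not claimed optimal.
The detector watches the per-window *activity level* — the mean rectified
magnitude, mean(| |a| − mean|a| |) — rather than the raw per-window mean
|a|: a zero-mean oscillation averages out within a window, so activity
changes barely move the raw mean, whereas the rectified series shifts by
roughly 2/π times the oscillation amplitude. Both series constructors are
provided.

## Orchestration and numerical choices

The runner derives one sub-seed per stage as
`sha256(f"{master_seed}|{stage}")[:4] mod 2^31`, so runs are byte-identical
under a fixed config (log and JSON report included; log floats are written
with `repr` for exact round-trip, stream CSVs with 6 decimals so a
write→read→write cycle is byte-stable). Log timestamps are ISO-8601 at
millisecond precision, which is exact for a 50 Hz grid. The free-living
stand-in script draws bout labels from a Markov chain (moving→standing with
probability 0.6, no self-transitions) and durations log-uniform on
10–300 s; it is a plumbing device, not a model of anyone's day. Injected
prompt-vibration bursts default to 20 Hz — high-frequency but below the
25 Hz Nyquist limit, where a sinusoid would alias to zero.

## Known limitations

- The four-class set has no audio- or Wi-Fi-based disambiguation, so
  bus-vs-standing separation rests entirely on the (optimistic) synthetic
  accelerometer contrast and the speed trace.
- Stable states absorb short label runs, so activities shorter than ~9 s are
  invisible to the prompt trigger by construction.
- Human-subject outcomes (latencies, usability scores) are simulation
  inputs, not reproducible measurements; only their bookkeeping is.
- Test and default problem sizes (270–600 s scripts, a few seeded
  replicates) are chosen to keep the full pipeline comfortably
  deterministic and fast on one core.
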