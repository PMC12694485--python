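# Methods

This note documents the models, parameter choices and numerical conventions
behind `emgspeller`, and what its synthetic experiments do and do not show.

## Signal model and synthetic generator

The generator emulates the statistical structure a threshold decoder relies
on, not muscle physiology. Each channel carries i.i.d. Gaussian baseline
noise (default SD 15 µV — a realistic resting surface-EMG floor) sampled at
200 Hz. A scripted gesture adds, on the channels mapped to its command, a
*burst*: white noise band-limited to 20–90 Hz by a 4th-order Butterworth
filter, scaled to a target RMS (default 1500 µV, comfortably inside the
50 µV–20 mV physiological envelope and ≈100× the noise floor, emulating a
strong voluntary contraction), with a 50 ms raised-cosine onset/offset ramp
so no step discontinuity excites the analysis filters. Event onsets get
Gaussian jitter (SD 20 ms) and amplitudes a 10 % multiplicative jitter,
shared across the channels of one event so SELECT co-contractions stay
simultaneous. Optional mains contamination injects identical 50 Hz + 60 Hz
sinusoids on every channel; it is off in most unit tests and used
specifically to exercise the notch stage.

Not modeled: motor-unit firing statistics, fatigue-induced spectral shifts,
electrode-skin impedance, inter-channel crosstalk, or the asymmetric
activation timing real users show when co-contracting two muscles. Passing
tests therefore demonstrate that the decoder is correct *given its signal
assumptions*, not that those assumptions hold on any particular user.

Scripted protocols: the command-recognition schedule performs each of the
five commands twice per trial (10 key operations), 2 s rest between
commands, 2.5 s quiet lead-in for calibration; directional contractions
last 0.8 s and SELECT holds 0.5 s. Three subjects × ten trials give the
300-event session used by the acceptance script. Text-entry scripts are
produced by planning shortest cursor paths (breadth-first search under the
cursor-motion rules) to each key of the task text and laying the commands
out at the same cadence.

## Preprocessing

Causal (forward-only) IIR filtering throughout, mirroring a real-time
system; zero-phase filtering is rejected as non-causal. Order: notch 50 Hz →
notch 60 Hz (both 2nd-order, Q = 30) → Butterworth bandpass 20–90 Hz
(4th order, bilinear design, −3 dB exactly at the edges) → full-wave
rectification. Initial filter state is zero; frequency-response tests
discard a settling transient before measuring steady-state amplitude.
Filter state persists across streamed chunks, so chunked processing equals
whole-recording processing bit for bit.

Windows are 1.0 s long, stepped every 5 ms (one sample at 200 Hz),
half-open sample ranges `[k·step, k·step + N)`, 0-based; window positions
are identical across channels so the SELECT simultaneity test is well
defined. Features are computed on the rectified envelope, i.e. SSC counts
slope reversals of the envelope; rectification-first matches the stated
real-time processing order and makes zero-crossing features meaningless
(one reason they are excluded, along with waveform length, as
noise-sensitive).

## Features and thresholds

RMS and peak are scale-equivariant; the SSC difference product is on an
amplitude-squared scale, so its threshold is too. The SSC threshold
defaults to the squared mean baseline RMS of the filtered, rectified
lead-in (auto-calibrated per recording, overridable): reversals whose
adjacent-difference product does not exceed the noise floor's scale are
ignored. SSC uses the strict inequality `> threshold`, so a constant window
scores 0.

Activation gating is the conjunction of three per-channel tests against the
2 s baseline profile: RMS > 2.0 × baseline RMS, SSC ≥ 10, peak > 3.0 ×
baseline peak. The multiplicative gains make the gate scale-free across
subjects/amplitudes; the defaults sit far below a strong contraction
(≈100× noise) yet far above noise fluctuation, and the monotone-degradation
tests probe exactly the regime where they begin to fail (bursts ≤ ~2–3×
noise SD). An all-zero baseline is rejected as degenerate rather than
silently yielding zero thresholds.

## Segmentation

Frames are timestamped at the window *end* — the first moment a causal
system can know the feature — so decoded onsets track contraction onsets
instead of leading them by one window length. Per maximal run of frames
with any activation, at most one event is emitted:

- a co-activation of ≥2 channels sustained > 0.3 s → SELECT (the hold
  rejects transient overlaps);
- a run in which exactly one channel is ever active, lasting ≥ 0.1 s
  (debounce against window-edge flicker) → that channel's command;
- a short co-activation whose tail leaves one channel active alone is
  re-timed from the moment it became solo and judged as a single-channel
  run; any other sub-hold co-activation emits nothing — deliberately
  indeterminate rather than guessed, which removes SELECT→direction
  confusions from the decoder by construction.

A 0.5 s refractory period after each event suppresses runs that start too
soon, preventing double-fires from one contraction (the protocols rest 2 s
between commands, so this is conservative). Because a 1 s window overlaps a
burst before and after it, activation runs are longer than the underlying
contraction by up to ~0.9 s; with ≥2 s rests runs never merge, but this
generator/decoder pair should not be used with inter-command gaps below
about 1.2 s.

## Cheonjiin keyboard

Default layout (4×4, 14 active keys, 10 jamo-producing): top row ㅣ ㆍ ㅡ
del; then ㄱㅋ ㄴㄹ ㄷㅌ space; ㅂㅍ ㅅㅎ ㅈㅊ enter; ㅇㅁ '.' with two empty
cells. The top-row placement of the vowel keys and del is a structural
invariant; function-key positions are configurable via the layout file.
Cursor starts at (0,0); moves skip empty cells and clamp at edges.

Consonant keys cycle on consecutive presses (ㄱ→ㅋ→ㄲ→ㄱ…, two-character
groups with period 2); the seven cycles cover all 19 initial consonants.
The vowel automaton is a prefix automaton over {ㅣ, ㆍ, ㅡ} with exactly 21
accepting states, one per standard medial vowel. Three historically
inconsistent tail entries use the standard Cheonjiin decompositions
ㅘ = ㆍㅡㅣㆍ (ㅗ+ㅏ), ㅝ = ㅡㆍㆍㅣ (ㅜ+ㅓ), ㅙ = ㅘ+ㅣ, ㅞ = ㅝ+ㅣ; ㅟ is
ㅡㆍㅣ. A vowel keypress that extends no valid sequence finalizes the
current vowel and is dropped.

Syllables are committed by enter as precomposed Unicode
(0xAC00 + (cho·21 + jung)·28 + jong), validated by the exhaustive
19×21×28 round trip. Compound finals (ㄳ ㄵ … ㅄ) are supported; enter
commits per syllable and no cross-syllable re-syllabification is performed.
del removes the most recent uncommitted jamo first (last final component,
then last vowel key, then the initial), then committed characters. A vowel
without an initial is held as pending but cannot be committed; a second
consonant with no vowel flushes the first as a bare compatibility jamo.
Multi-tap state survives cursor motion (key identity decides), and commits
on any different keypress, vowel, or enter — there is no timing-based
multi-tap timeout because input pacing is command-driven.

## Evaluation

True and decoded event streams are matched greedily in time order: each
true event takes the nearest unmatched prediction within a 2.0 s window
(the protocol's inter-command rest). Missed and spurious events occupy an
extra "(none)" row/column of the confusion matrix. Metrics follow the
one-vs-rest definitions; both trace/total multiclass accuracy and the mean
one-vs-rest accuracy are reported because the two conventions genuinely
differ. F1 is defined as 0 when precision + recall = 0. Display rounds to
one decimal; full precision is kept internally.

ITR uses the standard symmetric-channel formula with N = 5; the P log₂ P
and (1−P) terms take their limits at P = 1, the value is exactly 0 at
chance P = 1/N, and P below chance raises an error rather than returning a
negative rate. Selection time T is active session time (excluding scripted
inter-trial rests) divided by emitted events.

## Problem sizes and determinism

The test suite and acceptance script run entirely on generated data:
single trials (≈30 s of signal) for unit tests, the full 300-event schedule
(30 sessions, ≈28 s each) plus the two text-entry tasks for acceptance —
a few seconds of compute in total, thanks to vectorized sliding-window
features. Every stochastic component is driven by an explicit seed;
property tests use seeded generators or derandomized hypothesis profiles.

## Known limitations

- The synthetic generator's stationary bursts make threshold decoding
  easier than real EMG with ramped effort, fatigue and crosstalk; the 100 %
  high-SNR recovery result is a correctness check of the pipeline, not a
  performance claim about human users.
- The matching-window evaluation cannot distinguish a substitution from a
  near-coincident deletion + insertion closer than the window.
- Latency is one window (1 s) by construction; the decoder is not suitable
  for sub-second command cadences without shortening the window, which
  would change every threshold's statistics.
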