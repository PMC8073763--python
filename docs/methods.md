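# Methods

## Model and pipeline

The detector treats each EEG channel independently. The working assumption
is that ictal (and often pre-ictal) activity expresses itself as transient
phase locking between the channel's upper and lower envelopes in the β band,
and that this locking peaks at about the same record time on many channels
at once. The pipeline per channel is:

β band-pass → half-wave extrema → spline envelopes → analytic-signal phase
of each envelope → unwrap → windowed PLV. Per record: per-channel max-PLV
positions `V_p` → median boundaries → σ threshold → zone verification.

The upper and lower envelopes are deliberately *not* the analytic envelope:
the analytic magnitude is a single curve shared by both extremes and carries
no upper-vs-lower phase information. Peak-interpolated envelopes differ
whenever the signal's positive and negative excursions are modulated
differently.

## Filtering

Equiripple FIR band-pass, 12–30 Hz passband at 256 Hz, applied
forward–backward (`filtfilt`, even-reflection padding of three filter
lengths), so the net phase response is zero and envelope timing is
undistorted. The band follows the experimental setup of the source study
(its introduction quotes β as 14–30 Hz; the experiments use 12–30 Hz, and we
follow the experiments). Design targets, verified at design time and grown
to meet: single-pass magnitude within ±1 dB over
[low+transition, high−transition] and ≤ −40 dB in both stopbands, with a
2 Hz transition width. The exact order/ripple used in the original
experiments is unreported, so acceptance is against these response targets,
not coefficient values. At 256 Hz the design settles at 333 taps.

## Envelope extraction

Half-wave rule: a maximum candidate is the largest sample of a maximal run
of positive samples; minima mirror this on negative runs. The running
extremum of a half-wave is committed when the run ends (zero crossing); a
run cut off by the record edge still commits unless its extremum sits on the
literal edge sample, which is not a turning point. The 20-sample constraint
is applied greedily left to right between *retained* extrema of the same
kind: a candidate closer than `min_separation` (default 20) samples to the
previously retained one is dropped. Ties inside a half-wave take the
earliest sample. These choices resolve two ambiguities in the original
description (commit-at-detection vs commit-at-half-wave-end; separation
against candidates vs retained extrema) in favour of the deterministic
reading that yields one extremum per half-wave.

Knots are joined by a natural cubic spline (second derivative zero at the
outer knots — avoids oscillatory end behaviour) evaluated at every sample
index; outside the outer knots the envelope holds the nearest knot value.
Envelopes are built over the whole record; the "collect 2·N extrema"
phrasing of the source is read as "collect until the record is exhausted",
since full-record PLV series are needed.

## Phase and PLV

The analytic signal uses the four-step FFT construction with spectral
weights h = [1, 2, …, 2, 1, 0, …, 0] (ones at DC and Nyquist). Odd-length
records are reflect-padded by one sample and trimmed after, since h is
defined for even lengths. The phase is the four-quadrant `atan2` (the
source prints a two-quadrant arctan; four-quadrant is required for phases
covering (−π, π]). Unwrapping shifts by multiples of 2π wherever a
consecutive jump reaches π. Samples with real = imag = 0 carry the previous
phase forward and are counted. No edge trimming is applied to the series
itself; tests exclude the outer 5% where edge effects concentrate.

PLV windows are rectangular, N = 10 s × fs samples, hop N/2 (50% overlap);
a final partial window is dropped rather than padded, because the PLV
normalisation assumes a full window. Window positions are reported as
window start times (configurable downstream consumers may recentre).
Because PLV depends on Δφ only through cos/sin, wrapped and unwrapped
phases give identical values; unwrapped is kept for fidelity to the
pipeline description. The windowed implementation uses cumulative sums of
cos Δφ and sin Δφ; its rounding error (~1e−10 relative on hour records) is
negligible against the 1e−12 single-window tolerance verified directly on
`compute_plv`.

## Classifier

σ is interpreted as an absolute count threshold with inclusive comparison:
abnormal ⇔ (#{V_p inside [μ−μρ/100, μ+μρ/100]} ≥ σ), boundaries closed.
This reproduces both worked examples of the source (18-of-23 abnormal for
any σ < 19; 9-of-23 quiet at σ = 10); the source's formula prints a strict
">" which contradicts its own example arithmetic and is not followed. A
`sigma_mode="percent"` switch converts a percentage of the channel count to
a count (rounded half up), reconciling the percent-valued sweep grid with
the count-valued fixed settings quoted elsewhere in the source; the ρ=20
variant of its first example (14 in-boundary yet "σ < 19") is inconsistent
under any single reading and is not reproduced.

FN is defined as "seizure annotated but no abnormal activity declared" —
the source leaves it implicit, but sensitivity is otherwise incomputable.
Each record-epoch contributes exactly one of TP/FP/TN/FN. FP covers two
sub-cases, counted together and reported separately: abnormal with no
annotation at all, and abnormal with no in-boundary position in any zone.
Zone 1 is closed–closed; zones 2–7 are closed at the earlier edge, open at
the later, tiling the 1300 s before the clinical start with no gaps. The
sweep accumulates confusion counts over records per (σ, ρ) grid point,
ρ-major.

## Synthetic data

The generator emulates the one property the method feeds on: β-band
activity whose upper/lower envelope phases are coupled inside labeled
seizure windows and drift independently outside. Each channel is

x(t) = A(t)·cos(2π f_c t) + B(t)·cos(4π f_c t) + noise,
A = (u + l)/2, B = (u − l)/2,

with target envelopes u = 1 + d·cos θ_u and l = 1 + d·cos θ_l. The second
harmonic is essential: both components sit inside the β band
(f_c = 14 Hz, 2f_c = 28 Hz), so the upper/lower asymmetry survives the
band-pass — a plain AM tone would have mirror-identical envelopes
everywhere and nothing to detect. Envelope phases advance at base rates
1.0 and 1.3 Hz plus independent Gaussian random walks (0.8 rad/√s), so the
uncoupled background PLV sits near 0.9 with the peak elsewhere each
realisation; inside seizure windows the lower modulator is pulled onto the
upper with weight 0.9 (default `coupling_in`), driving PLV to ≈ 0.996.
Defaults mirror the recording conditions the method targets: 3600 s,
256 Hz, 23 channels, 16-bit EDF quantisation, modulation depth 0.6, white
noise of 0.1 carrier units (an optional 1/f mode exists), amplitude scale
50 µV. The default benchmark is 10 records, the first 6 with one 90-s
seizure placed in the middle half of the record by the seed.

What the generator does *not* emulate: 1/f background spectra by default,
artefacts, inter-channel correlation, montage effects, or any
physiologically realistic seizure morphology. Passing tests therefore show
that the pipeline recovers envelope-phase coupling where it exists, not
that real seizures produce such coupling — validating the latter requires
recorded data via `envsync eval`.

## Problem sizes and tolerances in the test suite

The benchmark tests run the full default benchmark (10 hour-long, 23-channel
records, ≈ 2 minutes total). The seizure-localisation check across ten
generator seeds uses 1800-s, 4-channel records — the statistic there is
per-record, so channel count only adds redundancy. Analytic PLV limits are
asserted to 1e−12; Hilbert-vs-DFT oracle agreement to 1e−8 on n ≤ 64;
envelope recovery to 5% of the modulator amplitude excluding 2 s at each
edge; tone phase slope to 1e−4 rad/sample excluding the outer 5%. EDF
round-trips are asserted to one quantisation step of the file's physical
range.

## Known limitations

- Spline envelopes can cross between sparse knots; only knot interpolation
  is guaranteed.
- The median boundary μ ± μ·ρ/100 scales with μ, so records whose seizures
  occur early (small μ) get narrower absolute bands — inherited from the
  method's definition.
- The EDF writer covers the plain-EDF subset this package produces
  (uniform rate, 1-s records, µV); it is not a general EDF+ writer.
- Hour-long records are processed whole through FFTs (~1 M samples); memory
  is O(record), not streaming.
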