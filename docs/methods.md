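# Methods

`hfoscale` models how the surface area of an intracranial EEG electrode
shapes the measurement of high-frequency oscillations (HFOs), and provides
the detection and statistics pipeline needed to quantify that effect on
synthetic (or real, EDF-format) multichannel recordings.

## The measurement model

A recorded channel is composed in three stages.

**1. Source activity.** HFO-generating tissue under the contact emits a
train of oscillatory bursts.  Bursts are generated by a renewal process:
an inter-pulse gap `s`, then a pulse of duration `d`, amplitude `K` and
intra-burst frequency `f0`, repeated until the record ends (a pulse that
would overrun the end is dropped).  Each pulse is rendered as
`K · w(t) · sin(2π f0 t + φ)` with phase `φ ~ U(0, 2π)`.  The envelope `w`
is a flat-top Tukey window with fixed 5 ms raised-cosine ramps: a
plateaued burst keeps its duration well defined under threshold detection
(the recovered duration of a fully tapered, e.g. Hann, burst depends
strongly on its amplitude margin over the detection threshold, which would
leak an artificial duration-vs-size effect into the experiment).  A Hann
envelope remains available via `SimulationConfig.envelope`.

**2. Tissue mixing.** The proportion of the contact covered by
HFO-generating tissue is `ρ_HFOG`, drawn once per record (it models a
fixed tissue geometry under one electrode).  Coverage saturates at the
full contact: `p = min(ρ, 1)`, so `ρ = 1` and `ρ = 3` measure identically.
Two independent, equal-variance 1/f^α background processes represent the
covered and uncovered tissue:

    v_tissue = p · (hfo + bg_covered) + (1 − p) · bg_rest

When the same source is re-measured at a larger contact area `A` (the
cohort simulator), the covered fraction becomes `p = min(ρ · A0 / A, 1)`
with `A0` the reference (smallest) area: a fixed patch of generating
tissue covers less of a bigger contact.  This is the mechanism by which
detected rate and amplitude fall with electrode size while the underlying
activity is unchanged.

**3. Electrode and amplifier.** The tissue potential passes through the
voltage divider `H(f) = Z_in / (Z_in + Z_e)` where the electrode-tissue
interface impedance is

    Z_e(f) = R_s(A) + ( r_ct/A ∥ 1/(j 2π f c_dl A) ),
    R_s = ρ_t / (4 √(A/π))   (disc spreading resistance)

and `Z_in` is the amplifier input impedance (R ∥ C).  Johnson noise of the
interface, one-sided PSD `4 k_B T Re(Z_e)`, is added at the amplifier
input after the divider.  With the default platinum-scale constants
(`c_dl = 0.2 µF/mm²`, `r_ct = 1 MΩ·mm²`, `ρ_t = 3 Ω·m`,
`Z_in = 100 MΩ ∥ 10 pF`, `T = 310 K`) the interface impedance is a few
kΩ in-band, so `|H|` is close to (and provably never above) 1 and the
thermal noise is ~0.1 µV RMS: under realistic constants the size effect is
dominated by tissue-coverage dilution, not by the divider.  Every constant
is a field of `ElectrodeModel`.

## Default generator parameters

The defaults define the study conditions for all tests and the acceptance
script.  Shapes follow what is typical for fast ripples in human iEEG;
each is overridable in `SimulationConfig`.

| parameter | default | why |
|---|---|---|
| fs | 1000 Hz | clinical iEEG sampling rate |
| duration | 1200 s (tests use 120 s) | 20-minute clinical recordings |
| s (gap) | Exponential, mean 5 s | ~11 events/min injected, an active epileptic channel |
| d (duration) | Gamma(k=4), mean 50 ms | typical FR durations, 20–110 ms central mass |
| K (amplitude) | TruncNormal(20, 10) µV on [1, 60] | symmetric, Gaussian-like amplitude distribution |
| ρ_HFOG | Uniform(0.05, 3] | generator size from "almost nothing" to 3× the contact |
| f0 | U(260, 400) Hz (FR), U(90, 240) Hz (R) | see sampling-limit note below |
| bg_sigma | 15 µV broadband | in-band (250–500 Hz) background ≈ 4.1 µV RMS |
| bg_exponent | 1.0 | 1/f EEG background |
| contact areas | 1.08 / 2.16 / 4.32 mm² | high-density grid contact and its 2×/4× shorted ensembles |

**Sampling-limit note.** The FR `f0` support stops at 400 Hz.  At
fs = 1 kHz the rectified waveform of a tone at `f0` shows supra-threshold
humps at the alias rate `|fs − 2 f0|`; above ~405 Hz that rate falls below
what the six-peak validation stage can count within a typical 50 ms event,
so such events are unmeasurable by this detector/sampling-rate combination
at any amplitude.  Injecting them would only dilute recall statistics with
events the measurement system cannot represent.

## The detector

Per channel and per 60 s segment (thresholds are recomputed each segment):

1. Zero-phase band-pass (Butterworth order 6, applied forward-backward)
   in the ripple (80–250 Hz) or fast-ripple (250–500 Hz) band, plus
   zero-phase IIR notches at the odd 60 Hz harmonics inside the band.
   When the upper band edge sits at Nyquist (FR at fs = 1 kHz) the
   band-pass degenerates to the equivalent high-pass.
2. **Stage 1:** the RMS envelope (centered 3 ms sliding window) must
   exceed `T1 = mean + 3 SD` of the envelope for at least 6 ms.  Runs
   separated by less than `merge_gap = 20 ms` merge before the duration
   test; the 20 ms default bridges the sub-threshold dips that the aliased
   second harmonic carves into the 3-sample envelope of near-Nyquist
   events (measured recall at SNR 5: 0.975 vs 0.909 at 10 ms).
3. **Stage 2:** the rectified band-passed signal must cross
   `T2 = mean + 3 SD` of itself upward at least 6 times inside the
   candidate.  Crossing counting is used instead of strict sample-level
   local maxima because sampled maxima undercount below ~3 samples per
   cycle; `peak_mode="maxima"` preserves the literal local-maxima rule.
   A `threshold_reference` switch likewise allows `T1` to be taken from
   the rectified signal instead of the envelope.
4. **Artifact rejection:** (a) the full detector runs on the
   common-average-reference signal and any event overlapping a CAR
   detection is removed; (b) an event is removed if the wide-band signal
   within ±100 ms contains a jump between adjacent 10 ms block means
   exceeding 5× the segment's wide-band SD (DC shift), or if a single
   sample-to-sample jump carries more than 20% of the event's
   first-difference energy (fast transient).  All four constants are
   fields of `DetectorParams` and are approximations of published
   artifact-screening practice.

Both thresholds are linear in the data, so detections are invariant under
uniform positive scaling of a segment.  Zero-variance segments are
skipped and logged.  Sample coordinates are 0-based half-open intervals.

## Features and statistics

* **Amplitude** — mean of the upper Hilbert envelope over the event,
  computed with ≥ 50 ms padding and cropped back (edge events are
  reflection-padded and flagged).
* **Peak frequency** — in-band argmax of the FFT magnitude after
  first-difference whitening, Hann windowing and zero-padding to ≥ 1 Hz
  resolution; undefined (NaN) for events shorter than two cycles of the
  band's lower edge.
* **Spread S** — events are grouped into connected components of the
  temporal-overlap graph (strictly positive intersection, transitive
  chaining); S is the number of distinct channels in a group.
* **Rates** — per-channel events/min; the global rate counts each group
  once; the global rate per area divides by the summed physical contact
  area (64 × 1.08 = 69.12 mm², identical for the small/pair/quad
  schemes).  For single-electrode simulations the rate per area reduces
  to rate / A.
* **Rank-sum test** — two-sided Wilcoxon rank-sum.  For combined n ≤ 20
  the p-value is an exact enumeration over all C(n, n₁) assignments of
  the pooled mid-ranks (ties handled; two fully tied samples give p = 1);
  larger samples use the tie-corrected normal approximation.

**Unit of analysis.** In the size experiment, rate per area is a
per-record quantity; amplitude, duration and peak frequency are properties
of individual detected events and are compared at the event level (with
per-record medians retained as `record_*` fields).  Comparing per-record
median durations instead would superimpose a detection-selection artifact:
records that still yield events at large contact areas carry fewer,
lower-margin events whose threshold-crossing durations are biased short.

## Virtual shorting

Electrically shorting adjacent contacts averages their signals; the
package mirrors this with an unweighted mean over 1×2 (pair) or 2×2
(quad) tiles, deterministic from the top-left corner (pair orientation
horizontal by default, configurable).  CAR is computed over the channels
of the active configuration (64, 32 or 16).

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure relevant to the size
question: renewal-process event trains, partial tissue coverage with
saturation, 1/f background from covered and uncovered tissue, the lumped
measurement chain, and line-noise-free conditions.  It does not emulate
interictal spikes, state changes (sleep stages, seizures), spatially
correlated background across grid channels, electrode impedance drift, or
any spatial structure of HFO generators beyond the scalar coverage
fraction — so channels are statistically independent and spread `S` on
fully simulated grids is nearly always 1.  Passing tests therefore
demonstrate internal consistency of the measurement model and detector,
not clinical performance on patient iEEG.

## Numerical choices and problem sizes

Test- and acceptance-scale experiments use 50 records × 2 min per area
(the same distributions as a full-scale 5000 × 20 min campaign, which
remains available through `SimulationConfig`).  Background draws
are renormalized to their target RMS exactly; the power-law spectrum is
flattened below 1 Hz.  Filters are SOS-form for numerical stability.
The noise-floor regression value of the detector on signal-free records
(dist_K ≡ 0) is 0.0 events/min/channel, measured over 11 seeds × 128
channel-minutes and asserted at the 0.02 events/min resolution of a
64-channel × 2-minute run.

## Known limitations

* The lumped circuit constants are literature-scale defaults, not fitted
  to any specific electrode; with realistic values the divider is nearly
  transparent, so experiments probe coverage dilution rather than
  interface filtering.  Exotic parameter choices (tiny `Z_in`) make the
  divider matter and remain fully supported.
* Fast ripples with `f0` ≳ 405 Hz are unmeasurable at fs = 1 kHz (see
  sampling-limit note) — a property of the detector-plus-sampling-rate
  combination, not of this implementation.
* EDF export quantizes to 16 bits and zero-pads the final 1 s record.
* Events spanning a 60 s segment boundary are truncated at the boundary.
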