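# hfoscale

Electrode-size-aware simulation, detection and statistics of
high-frequency oscillations (HFOs) in intracranial EEG.

HFOs — transient bursts with peak frequencies above 80 Hz, split into
ripples (R, 80–250 Hz) and fast ripples (FR, 250–500 Hz) — are a
candidate biomarker of epileptogenic tissue, but they are recorded with
electrodes whose contact areas span three orders of magnitude.  `hfoscale`
is built for researchers who need to ask: *are HFO rates and morphologies
measured with differently sized electrodes comparable at all?*  It
provides:

* a **synthetic iEEG generator**: renewal-process HFO pulse trains
  (inter-pulse gap `s`, duration `d`, amplitude `K`, intra-burst
  frequency `f0`) embedded in 1/f^α background and measured through a
  lumped platinum-electrode model — the divider
  `H(f) = Z_in/(Z_in + Z_e)` with
  `Z_e = R_s(A) + (r_ct/A ∥ 1/(j2πf·c_dl·A))` — parameterized by contact
  area `A`.  The fraction of the contact covered by HFO-generating tissue,
  `ρ_HFOG ∈ (0, 3]`, saturates at 1 and shrinks as `A` grows, which is the
  physical mechanism linking electrode size to detectability;
* a **two-threshold RMS detector** (3 ms sliding RMS above mean + 3 SD
  for ≥ 6 ms, then ≥ 6 rectified peaks above a second mean + 3 SD
  threshold, per channel per one-minute segment) with common-average-
  reference and transient/DC-shift artifact rejection;
* **virtual electrode shorting** on an 8×8 high-density grid
  (1.08 mm² contacts, 3 mm pitch): averaging 1×2 or 2×2 groups mimics
  2.16 mm² and 4.32 mm² contacts;
* the **feature/statistics layer**: per-channel rate `r_min`, global rate
  per unit area (unique events/min divided by the 69.12 mm² summed grid
  area), Hilbert-envelope amplitude, duration, whitened-FFT peak
  frequency, spatial spread `S`, and exact/asymptotic Wilcoxon rank-sum
  comparisons.

## Worked example

Simulate one 2-minute fast-ripple channel, detect, and summarize:

```python
import numpy as np
import hfoscale as h

cfg = h.default_config("fast_ripple", duration=120.0, seed=1)
rec = h.simulate_recording(cfg)
events = h.detect_hfos(rec, "fast_ripple")

print(f"injected: {len(rec.ground_truth[0].trains[0])}  "
      f"detected: {len(events)}  rho={rec.meta['rho_hfog']:.2f}")
for e in events[:3]:
    print(f"  t={e.start_s:7.3f}s  dur={e.duration_s*1e3:4.0f} ms  "
          f"amp={e.amplitude:5.1f} uV  f={e.peak_frequency:5.1f} Hz")
```

```
injected: 28  detected: 17  rho=1.54
  t=  5.367s  dur=  65 ms  amp= 34.4 uV  f= 319.0 Hz
  t= 18.006s  dur=  33 ms  amp= 17.2 uV  f= 354.0 Hz
  t= 29.899s  dur= 110 ms  amp= 28.1 uV  f= 377.0 Hz
```

With `ρ ≈ 1.5` the generating tissue saturates the 1.08 mm² contact; the
17/28 yield reflects the amplitude distribution straddling the detection
threshold at this background level.  Re-measuring the *same* sources at
three contact areas and comparing distributions:

```python
res = h.run_size_experiment(h.default_config(duration=120.0),
                            n_per_area=50, seed=7)
print([round(m, 2) for m in res.medians("rate_per_area")])   # events/min/mm^2
print([round(m, 1) for m in res.medians("amplitude")])       # uV
print([round(m, 1) for m in res.medians("duration_ms")])     # ms
```

```
[6.48, 3.01, 0.98]
[19.8, 16.6, 12.2]
[45.0, 44.0, 45.0]
```

Rate per unit area and amplitude fall steeply as the contact grows
(adjacent-pair rank-sum p < 10⁻⁴ in `res.pairwise_p`), while duration —
and likewise peak frequency — stay flat: larger contacts dilute small HFO
generators below the detection threshold but do not distort the surviving
events.

The same pipeline is scriptable from the shell:

```bash
hfoscale simulate --areas 1.08,2.16,4.32 --n 10 --seed 7 --out sim/
hfoscale detect --in sim/rec0000_area1.08.h5 --band fast_ripple --out events.csv
hfoscale experiment --config cfg.yaml --n 50 --seed 7 --out results/
```

## Layout

```
src/hfoscale/
  core.py       bands, pulse trains, Recording container
  dists.py      serializable distribution specs
  electrode.py  lumped electrode-tissue model + Johnson noise
  simulate.py   single-channel / cohort / grid generators
  grid.py       8x8 layout, virtual shorting, CAR
  detect.py     filters, RMS envelope, two-threshold detector, artifacts
  features.py   amplitude, peak frequency, grouping, rates, spread
  analysis.py   rank-sum test, size experiment, band comparison
  io.py         EDF+ write/read, HDF5 container, event tables, manifests
  cli.py        `hfoscale` command group
docs/methods.md   model, parameter and algorithm documentation
```
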