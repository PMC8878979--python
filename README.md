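# rssistep

Human **step-length estimation from on-ankle RSSI recordings**, for
researchers in wearable sensing, gait analysis and digital health. A pair of
2.4 GHz transceivers worn on the inner ankles exchanges packets continuously
while the subject walks or jogs; the received signal strength indicator
(RSSI) of each packet is logged. This package turns such a log into an
estimate of the average step length — the mean maximum distance between the
two ankles — without cameras, lasers, instrumented mats or inertial
dead-reckoning drift.

## Method

Each logged RSSI converts to an **on-ankle path loss** `PL = Pt + RSSI`
(transmit power `Pt`, default 0 dBm). Path loss maps to inter-ankle distance
through a corrected free-space model,

    PL_OA(d) = 20 log10(4 π d / λ) + ΔPL,        d(PL) = (λ / 4π) · 10^((PL − ΔPL)/20),

with carrier wavelength λ (2.4 GHz by default) and an empirical hardware
correction ΔPL = 10 dB. Rows flagged with the 120 dB sentinel (lost packets)
and the initial 0.64 s synchronization window are discarded.

During steady gait the path-loss histogram is bimodal: a small hump where
the feet pass each other and a dominant hump where they are most apart. The
histogram is fitted with a **two-term Gaussian**

    f(x) = a1·exp(−((x−b1)/c1)²) + a2·exp(−((x−b2)/c2)²),

whose second term gives μ = b2 and σ = c2/√2. Samples outside a threshold
window are outliers:

* **upper threshold** = μ + k·σ, with k = 1 indoors and k = 0.5 outdoors;
* **lower threshold** = the observed path-loss value where the empirical
  survival function S(x) = P(PL ≥ x) is closest to 0.68.

The step length estimate d̄ is the arithmetic mean of the distances of all
retained samples, scored against ground truth `d0` by the absolute error
|d̄ − d0| (mm) and relative error |d̄ − d0|/d0 × 100 %. When `d0` is known,
the threshold pair can instead be found by exhaustive grid search minimizing
the relative error.

Because real ankle-worn recordings are rarely shareable, the package also
ships a **gait-trace simulator** (`rssistep.simulate`) producing RSSI logs
with the same statistical structure — periodic inter-ankle separation with
stance/double-support dwell, dB-domain channel noise and excess-loss spikes,
integer-dB quantization, sentinel packet errors — and a known true step
length, so the whole pipeline is testable end to end.

## Worked example

Simulate five minutes of indoor walking with a true step length of 0.714 m,
then estimate it back:

```sh
rssistep simulate --preset indoor-walking --duration-s 320 --seed 7 --out walk.csv
rssistep estimate --input walk.csv --env indoor --mode rule --true-length 0.714
```

Output (abridged):

```json
{
  "d_bar_m": 0.7054770286654896,
  "n_retained": 8536,
  "pair": {
    "lower_db": 43.0,
    "upper_db": 50.85808021173628,
    "method": "rule",
    "k_used": 1.0,
    "survival_at_lower": 0.6866852297177573
  },
  "metrics": {
    "abs_error_mm": 8.522971334510409,
    "rel_error_pct": 1.1936934642171442
  }
}
```

Of 16,000 simulated packets, 8,536 fall inside the threshold window
(43 dB, 50.86 dB); their mean distance 0.7055 m misses the true 0.714 m
step length by 8.5 mm (1.2 %). `rssistep fit` prints the underlying
two-term Gaussian coefficients (here μ = 47.28 dB, σ = 3.58 dB), and
`rssistep gridsearch --true-length 0.714` sweeps threshold pairs
exhaustively and emits the error matrix as CSV — for this trace the best
grid cell, (41 dB, 51 dB), errs by 4.2 mm.

The same works from Python:

```python
import rssistep as rs

trace = rs.simulate_trace(rs.preset_config("indoor-walking"), seed=7)
est = rs.run_pipeline(trace, "indoor", d0=0.714)
print(est.d_bar_m, est.metrics.abs_error_mm)
```

## Layout

| module | contents |
| --- | --- |
| `rssistep.channel` | path-loss ↔ distance conversions, error metrics |
| `rssistep.io` | RSSI log CSV reader/writer, sentinel and sync cleaning |
| `rssistep.histogram` | probability histogram, two-term Gaussian fit, survival curve |
| `rssistep.thresholds` | μ+kσ / survival-0.68 rules, filtering, grid search |
| `rssistep.pipeline` | end-to-end `run_pipeline`, `StepLengthEstimate` |
| `rssistep.simulate` | gait-trace generator and scenario presets |
| `rssistep.cli` | `rssistep estimate / fit / gridsearch / simulate` |

See `docs/methods.md` for the model assumptions, simulator design and
numerical choices.
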