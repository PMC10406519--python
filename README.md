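# defibopt

Low-energy defibrillation asks whether a train of weak, well-timed
electrical pulses can terminate fibrillation where a single massive
shock — with its tissue damage and traumatic pain — is the clinical
default. `defibopt` is a simulation and optimisation toolkit for that
question in 2D phenomenological cardiac tissue: it

* simulates fibrillation-like spiral-wave chaos in the Fenton–Karma
  (three-variable, parameter sets FK1–FK3) and Bueno-Orovio–Cherry–
  Fenton (four-variable) models of human ventricular tissue, using an
  explicit FTCS scheme with an isotropic 9-point Laplacian and no-flux
  ghost-point boundaries (`Δt = 0.1 ms`, `h = 1 mm`, 256²/512² grids);
* models low-energy pacing as current injection through ~2000 randomly
  placed, non-overlapping 3×3-pixel sites (~28% coverage), each with a
  uniform(0,1) efficacy standing in for virtual-electrode recruitment;
* scores an N-pulse protocol (N amplitudes, N−1 intervals, 2 ms pulses)
  by pacing cost `PC = Σ a_k²·pulse_len` and termination ratio `TR` =
  fraction of (episode × site-distribution) attempts with
  `max u < 0.05 a.u.` after a 5×T_dom observation horizon;
* derives spectrum-guided adaptive-deceleration (ADP) reference
  protocols by equal-partitioning the cumulative mean power spectrum of
  the fibrillating voltage below a cutoff frequency; and
* optimises 5-pulse protocols with a genetic algorithm using
  dual-percentile acceptance (a candidate must rank high in both PC and
  TR) and alternating lexicographic replacement.

The science and all tunable parameters are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Estimate the dominant period of the FK1 model from a seeded
fibrillation episode, then derive its deceleration protocol:

```python
from defibopt import load_parameter_set
from defibopt.episodes import (make_fibrillation_ic, record_episode,
                               estimate_dominant_period_from_record)
from defibopt.adp import mean_power_spectrum, adp_intervals

params = load_parameter_set("FK1")
ic = make_fibrillation_ic(params, seed=11, burn_in=2000.0)   # S1-S2 cross-field
records, _ = record_episode(params, ic, record_s=10.0, rates_hz=(120.0, 100.0))

dom = estimate_dominant_period_from_record(records[120.0], fs_hz=120.0)
print(f"T_dom = {dom.t_dom:.1f} ms")

spectrum = mean_power_spectrum(records[100.0], sampling_ms=10.0)
print([round(iv, 1) for iv in adp_intervals(spectrum, cutoff_hz=15.0, n_pulses=5)])
```

```
T_dom = 124.2 ms
[103.0, 119.5, 144.2, 211.2]
```

`T_dom` is the reciprocal of the grid-averaged per-pixel peak FFT
frequency — the mean oscillation period of the chaotic wave activity
(reference value for FK1: 130 ms). The four ascending intervals are the
inter-pulse periods of the 5-pulse decelerating protocol obtained by
splitting the sub-15 Hz spectral mass into five equal parts (reference:
104, 123, 150, 220 ms); its uniform amplitude is then fixed by a
dose-response curve (`defibopt.adp.dose_response`) at the desired
termination ratio.

The same pipelines are scriptable from the shell:

```sh
defibopt episodes tdom --model FK1 --seed 11 --out runs/tdom-fk1
defibopt adp derive --model FK1 --seed 11 --out runs/adp-fk1
defibopt ga run --config ga.yaml
```

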