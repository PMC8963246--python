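# rtdcca — real-time detrended cross-correlation analysis

`rtdcca` estimates power-law (scale-free) cross-correlation between
nonstationary time series **in real time**, one datapoint at a time.  It is
aimed at applications that cannot wait for a full recording before
analyzing it: EEG-based mental-state monitoring and brain–computer
interfaces, physiological monitoring (heart rate, hemodynamics), and
streaming financial data.

## The statistics it computes

Detrended fluctuation analysis (DFA) integrates a series
`X(t) = Σ_{i≤t} x(i)`, splits the profile into windows of size `s`, removes
a least-squares linear trend from each window, and averages the residual
variance to get a fluctuation function `F_DFA(s)`.  Long-range
autocorrelation shows up as a power law `F_DFA(s) ∝ s^α`.  Detrended
cross-correlation analysis (DCCA) is the bivariate generalization: the
residual *covariance* of two profiles gives `F²_DCCA(s)`, and the
detrended cross-correlation coefficient

```
ρ_DCCA(s) = F²_DCCA,xy(s) / (F_DFA,x(s) · F_DFA,y(s))   ∈ [−1, 1]
```

is the nonstationary analogue of Pearson's r, resolved per time scale.

Classically these are two-pass, whole-signal computations.  `rtdcca`
instead maintains, per scale, a handful of running sums over the current
window of the integrated profiles — `Σ X`, `Σ iX`, `Σ XY`, `Σ X²`, … —
which are sufficient statistics for the window's detrended covariance: when
a window fills, its OLS trend coefficients and residual covariance come out
in closed form from those sums alone, and the sums reset.  Memory is
`O(n_scales)`, independent of stream length, and cost per sample is
constant.  A moving analysis window of `W` samples (advanced circularly in
steps of the largest scale `s_max`) turns this into a stream of
`ρ_DCCA(s)` estimates: the first after `W` samples, then one every `s_max`.

The same update written with channel vectors and one accumulated
outer-product matrix per scale handles `K` channels simultaneously: each
filled window yields a symmetric `K×K` detrended-covariance matrix whose
diagonal is the per-channel DFA value — so all pairwise `ρ_DCCA(i,j,s)`
and all DFA exponents `α(i)` fall out of a single pass.  (The bivariate
exponent λ cannot be tracked online because `F²_DCCA` may be negative; the
offline helper `cross_scaling_exponent` fits `|F²|^(1/2)` instead.)

A mixed-correlated ARFIMA (mc-ARFIMA) simulator generates test signals with
known exponents (`α = 0.5 + d`, `λ = (d2 + d3 + 1)/2`), plus white-noise and
Hanning-spike contamination for robustness studies.

## Worked example

```python
import numpy as np
import rtdcca as rt

x, y = rt.simulate_mc_arfima(rt.DEFAULT_MC_ARFIMA, N=4096, seed=7)
scales = rt.preset_for_length(4096)          # dyadic scales 8..1024, W = N
eng = rt.init_pair(scales)
est = eng.push_many(x, y)[-1]                # single estimate at t = N

print("scale   rho_DCCA   F2_cross")
for s, r, f2 in zip(est.scales, est.rho, est.f2_cross):
    print(f"{s:5d}   {r:8.4f}   {f2:10.3f}")

alpha_x = rt.fit_exponent(scales, np.sqrt(est.f2_x))
lam = rt.cross_scaling_exponent(x, y, scales)
print(f"alpha_x = {alpha_x:.3f}   lambda = {lam:.3f}  (theory: 0.8)")
```

prints

```
scale   rho_DCCA   F2_cross
    8     0.8526        0.441
   16     0.8351        1.270
   32     0.8423        4.682
   64     0.8365       13.607
  128     0.8467       45.205
  256     0.8623      167.904
  512     0.8588      476.309
 1024     0.8560     1160.921
alpha_x = 0.829   lambda = 0.830  (theory: 0.8)
```

The simulated pair carries strong long-range cross-persistence (innovation
correlation 0.9 between the heavily weighted components), so `ρ_DCCA ≈ 0.85`
across all scales, and the fitted exponents sit near the theoretical
`(d2 + d3 + 1)/2 = 0.8`.  Feeding the same samples through
`eng.push(x_t, y_t)` one at a time gives bit-identical results — that is
the point of the engine.

The command line mirrors the library:

```
rtdcca simulate -n 4096 --seed 7 -o pair.csv
rtdcca analyze pair.csv --engine pairwise --s-min 8 --s-max 1024 --whole-signal -o est.csv
rtdcca stream --s-min 8 --s-max 128 --window 512 < stream.csv   # EEG-style JSONL
rtdcca evaluate --experiment spikeA -o grid.csv
```

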