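# despotsim

Simulation and fitting-bias analysis for multi-component DESPOT myelin water
fraction (MWF) estimation.

## The problem

Multi-component DESPOT estimates the myelin water fraction by fitting rapid
steady-state SPGR and phase-cycled bSSFP signals to a two-pool tissue model:
a fast-relaxing myelin-water pool and a slow-relaxing intra/extra-cellular
pool (relaxation times T1F, T1S, T2F, T2S; equilibrium fractions
M0F = MWF and M0S = 1 − MWF; exchange rates k_FS, k_SF tied by detailed
balance k_FS·M0F = k_SF·M0S).  The model is usually fitted with Stochastic
Region Contraction (SRC): repeatedly sample candidate parameter sets
uniformly inside a search box, keep the 50 lowest-residual candidates,
contract the box around them, and stop when the box is within 1% or after
30 iterations.

When intercompartmental exchange is included, the inverse problem is highly
degenerate: widely different parameter combinations produce signal curves
that differ by less than the measurement noise.  SRC then converges — with
deceptively small variance — onto whichever part of the degenerate solution
manifold its initial search bounds steer it to, so the reported MWF depends
on the acquisition scheme and on the fitting constraints rather than on the
tissue alone.  This package provides the forward models, the SRC fitter, a
search-space degeneracy toolkit (normalized RMS residual
η(θ, θ̂) = RMS(S(θ) − S(θ̂))/σ, large-scale sampling with top-k retention,
kernel-PCA manifold embedding, 2-D minimum projections and planar cuts) and
Monte Carlo drivers to quantify these biases.  It is aimed at quantitative
MRI researchers who want to reproduce, probe or extend the bias analysis.

## Worked example

```python
import despotsim as ds

hb = ds.builtin_tissue("HB")          # T1F=0.45 s, T1S=1.4 s, T2F=15 ms,
                                      # T2S=90 ms, MWF=0.15, k_FS=8 /s
s1 = ds.builtin_scheme("S1")          # 10 SPGR + 10 bSSFP180 + 10 bSSFP0
b1 = ds.builtin_bound_set("B1")

# noiseless signals, normalized per sequence group
data = ds.normalize(ds.forward_signals(hb, s1))

fit = ds.src_fit(data, s1, b1, ds.SRCConfig(n_candidates=40_000, seed=3))
print({n: round(getattr(fit.estimate, n), 4) for n in ds.PARAM_NAMES})
print(round(fit.residual, 6), fit.iterations_used, fit.converged)
```

prints

```
{'t1f': 0.5543, 't1s': 1.4808, 't2f': 0.0202, 't2s': 0.1024, 'mwf': 0.2317, 'kfs': 8.0474}
0.00023 30 False
```

Even with *noiseless* data the fitter lands on a degenerate solution: the
residual corresponds to signals ~0.3 noise SD from the truth at SNR 100
(far below what noise could distinguish), yet the estimated MWF is 0.23
instead of the true 0.15.  Repeating with the exchange-free variant
(`ds.builtin_tissue("HB", exchange=False)` and
`SRCConfig(n_candidates=40_000, fit_exchange=False, fixed_kfs=0.0, seed=3)`)
converges in ~17 iterations to the true values within rounding — the
degeneracy, not the optimiser, is the culprit.

The Monte Carlo drivers quantify this over noise realizations:

```python
summaries = ds.run_bound_sensitivity(
    {"HB": hb}, {"S1": s1},
    {b: ds.builtin_bound_set(b) for b in ("B1", "B2", "B3", "B4")},
    snr=100, n_realizations=100,
    src_config=ds.SRCConfig(n_candidates=5000), seed=42,
)
for s in summaries:
    print(s.labels["bounds"], round(s.median()["mwf"], 3))
```

```
B1 0.292
B2 0.25
B3 0.227
B4 0.193
```

Four different search-bound sets, four different — individually precise
(SD ≈ 0.015–0.02) — MWF values, all well above the true 0.15.

A command-line interface mirrors the library
(`despotsim fit|explore|embed|project|cut|run ...`; see `despotsim --help`).

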