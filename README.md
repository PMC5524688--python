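# geminate

Excited-state proton-transfer (ESPT) kinetics for photoacid probes:
a spherically-symmetric Debye–Smoluchowski solver with a reversible
back-reaction boundary condition, TCSPC reconvolution fitting, and
steady-state band-ratio analysis.

## The problem

2-naphthol-based photoacids (2N, 2N6S, 2N8S, 2N6,8S) release a proton upon
photoexcitation.  The decay of the protonated ROH* emission encodes the
whole photoprotolytic cycle:

    ROH*  ⇌(k_PT, k_a)  [RO⁻*⋯H⁺]  →  RO⁻* + H⁺

The geminate proton diffuses in the Coulomb field of its parent anion,
V(r) = −R_D/r in k_BT units, where R_D = |Z₁Z₂|e²/(4πε₀ε_r k_BT) is the
Debye radius.  When such a probe binds to a surface — here, insulin amyloid
fibrils — the fitted parameters report on the binding site: the
proton-transfer rate k_PT on local hydrophobicity, the effective
dimensionality d of the proton's diffusion space (3 in bulk water, ~2 on a
surface, ~1 along a channel) on the binding geometry, and the diffusion
coefficient D on surface water mobility.  The long-time ROH* survival falls
as t^(−d/2), so the tail slope of a single fluorescence decay measures d
directly.

This package is aimed at time-resolved fluorescence practitioners: it
solves the forward model, fits measured (or synthetic) TCSPC histograms by
IRF reconvolution, and generates all inputs synthetically from the
published parameter registry of the four photoacids, free in pH 7 buffer
and fibril-bound.

## What's inside

| Module | Contents |
| --- | --- |
| `geminate.dse_core` | Debye–Smoluchowski solver (back-reaction BC, fractional d), Debye radius, closed-form and Brownian-dynamics validation oracles |
| `geminate.signal_model` | Lifetime weighting, Gaussian IRF, causal convolution, two-band spectra and RO⁻*/ROH* ratio unmixing |
| `geminate.fitting` | Diffusion-model and 3-exponential IRF-reconvolution fits (Poisson-weighted, seeded multi-start) |
| `geminate.synthetic_data` | Photoacid registry, TCSPC histogram generator with Poisson noise, amyloidogenesis trace generator/fitter |
| `geminate.io`, `geminate.pipeline`, `geminate.cli` | Delimited-text I/O, config-driven parameter report, `geminate` command line |

## Worked example

```python
import numpy as np
from geminate import (SolverConfig, GridSpec, solve_dse, debye_radius,
                      MediumContext, BandModel, synth_spectrum, measure_ratio)

medium = MediumContext()  # water at 20 degC
print("R_D (Z1=1):", round(debye_radius(1, 1, medium), 2), "Å")

# 2N bound to insulin fibrils: nearly 1D proton diffusion
cfg = SolverConfig(contact_radius_a=4.0, debye_radius_RD=10.0,
                   D_cm2_per_s=5e-5, dimensionality_d=1.2,
                   k_PT=0.4, k_a=1.5)
grid = GridSpec.auto(cfg, t_max=400.0, output_times=np.geomspace(0.01, 400, 300))
trace = solve_dse(cfg, grid)
tail = trace.times >= 40.0
slope = np.polyfit(np.log(trace.times[tail]), np.log(trace.p_bound[tail]), 1)[0]
print(f"ROH* survival at 10 ns: {np.interp(10, trace.times, trace.p_bound):.3f}")
print(f"log-log tail slope: {slope:.3f}  (-d/2 = {-cfg.dimensionality_d/2})")

bands = BandModel(roh_center=370.0, ro_center=420.0)
wl = np.arange(300.0, 560.0, 0.5)
spectrum = synth_spectrum(48.5, bands, wl)
print(f"measured RO-*/ROH* ratio: {measure_ratio(spectrum, bands):.1f}")
```

prints

```
R_D (Z1=1): 7.12 Å
ROH* survival at 10 ns: 0.198
log-log tail slope: -0.581  (-d/2 = -0.6)
measured RO-*/ROH* ratio: 48.5
```

The Debye radius for a singly-charged anion in water rounds to 7 Å (14 and
21 Å for the di- and tri-sulfonated acids).  After 10 ns about 20% of the
bound 2N population still holds its proton, and the fitted tail slope of
−0.58 reads back the nearly one-dimensional diffusion (d = 1.2) the
configuration was built with — the crossover into the asymptotic regime
accounts for the few-percent offset from −0.6.  The steady-state round
trip returns the band-area ratio exactly.

From the shell:

```sh
geminate debye --z1 2                        # 14.233 (Å)
geminate synth --photoacid 2N6S --condition fibrils --seed 1 \
               --peak 10000 --out decay.txt  # + decay_irf.txt
geminate fit --decay decay.txt --irf decay_irf.txt --scheme fibrils --seed 1
geminate report --seed 1 --out report/      # full 8-row parameter table
```

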