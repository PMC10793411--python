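# colonystats

Stochastic cell-size regulation and clonal-proliferation statistics for
rod-shaped bacteria.

When single bacterial cells found colonies in a microfluidic chamber, the
number of descendants N(t) varies from colony to colony.  How much it
varies depends on *how cells decide to divide*: a **timer** (cycle duration
τd drawn independently of size) keeps population noise CV²_N = σ²_N/⟨N⟩²
high, while an **adder** (a fixed mean size increment Δd per cycle,
independent of birth size) suppresses it, leaving a late-time noise floor
set by the size variability of the colony *progenitors*, CV²_sb.  Because a
rod-shaped cell's size can be measured as length L, surface area A = πLw,
or volume V = πLw²/4 − πw³/12 (a sphero-cylinder of width w), and because
width noise enters these proxies with different weights,

    CV²_A ≈ CV²_w + CV²_L,      CV²_V ≈ 4·CV²_w + CV²_L,
    hence CV²_L < CV²_A < CV²_V,

each proxy predicts *different* CV²_N(t) dynamics.  Matching predicted
against observed population noise therefore identifies which size proxy
governs division — for *Corynebacterium glutamicum*, surface area.

This package implements the complete workflow:

* **`colonystats.simulate`** — exact event-driven branching simulation of
  colony expansion (timer with gamma τd; adder with gamma Δd; a rate-based
  adder whose division propensity is μ·s/Δ̄d), with closed-form division
  times, per-colony RNG substreams, an Euler–Lotka timer calibration, and
  a generation-vectorised fast path for 10⁴-colony ensembles.
* **`colonystats.population`** — synchronized ensemble moments ⟨N⟩(t) and
  CV²_N(t) with colony-level percentile-bootstrap CIs, plus the Yule-process
  oracles of the exponential timer (geometric N, CV²_N = 1 − e^{−μt}) and
  the biomass decomposition CV²_N ≈ CV²_B + CV²_s/⟨N⟩.
* **`colonystats.geometry`** — capsule morphometrics: invert the projected
  area A_p = w(L−w) + π(w/2)² for the width, surface area/volume closed
  forms, delta-method CV propagation, power-law scaling fits.
* **`colonystats.SizeRegulationModel`** — a statsmodels-style model over a
  segmentation lineage table (one row per cell per frame).  `fit()` returns
  a results object with per-proxy newborn and added-size statistics
  (Table-style summary with bootstrap CIs), the adder test R(Δd, s_b), and
  `compare_proxies()` for the simulation-vs-observation proxy ranking.
* **`colonystats.synthetic`** — a generator of segmentation-style lineage
  tables with known ground truth, emulating the microfluidic time-lapse
  conditions (10-min frames, ~6 generations, 154 colonies, 3% measurement
  noise).
* **`colonystats` CLI** — `synth`, `simulate`, `analyze`, `compare`, `all`
  subcommands; every run writes a manifest with config and seeds.

## Worked example

```python
import numpy as np
from colonystats import GeneratorParams, SizeRegulationModel, generate_dataset

table = generate_dataset(GeneratorParams(seed=3))   # area-governed adder
res = SizeRegulationModel(table.frames).fit(n_boot=300, seed=1)
print(res.summary())
comp = res.compare_proxies(seed=5)
print("ranking:", comp.ranking)
```

prints

```
Cell size regulation summary (τ̄d = 74.5 min, boundary=midpoint, corrected moments)
=====================================================================
proxy  mean s_b CV²_sb mean Δd CV²_Δd R(Δd,s_b)     R 95% CI      n
---------------------------------------------------------------------
length    1.584 0.0259   1.600 0.0687    +0.194 [+0.175, +0.214] 9702
  area    4.716 0.0171   4.764 0.0569    -0.006 [-0.026, +0.017] 9702
volume    0.899 0.0298   1.149 0.0663    +0.132 [+0.107, +0.153] 9701
---------------------------------------------------------------------
ranking: ['area', 'length', 'volume']
```

Read: per size proxy, the mean newborn size s_b, its squared CV, the mean
added size Δd per cycle and its squared CV, and the Pearson correlation
between Δd and s_b.  The generating proxy (surface area) shows R ≈ 0 — the
adder signature — and recovers the generator's Δ̄d = 4.75 µm² and
CV²_Δd = 0.058; the ranking stage correctly picks `area` as the proxy whose
fitted noise reproduces the observed CV²_N(t).

The same pipeline runs from a shell:

```bash
colonystats synth --n-colonies 154 --seed 3 --outdir out/synth
colonystats analyze out/synth/lineage.csv --outdir out/analysis
colonystats compare out/synth/lineage.csv --outdir out/comparison
```

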