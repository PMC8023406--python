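# cytomon

Online flow-cytometry monitoring of non-axenic microalgal cultures.

Industrial microalgal cultivation (e.g. *Chlorella vulgaris* feedstock
production) is rarely axenic: prokaryotic contaminants can surge and impair
culture stability and productivity. Automated online flow cytometry — a
sampling/staining robot feeding a cytometer every ~25 minutes for days —
makes it possible to watch both the alga and the prokaryotic community in
situ. `cytomon` implements the analysis side of such a monitoring setup:

- **FCS I/O** — read/write FCS 3.0/3.1 list-mode files with acquisition
  metadata (analyzed volume, dilution, timestamp) and assemble them into
  time-ordered measurement series.
- **Gating** — log10 transform and polygon gating on the green (FL1,
  SYBR Green I nucleic-acid stain) vs red (FL3, chlorophyll
  autofluorescence) fluorescence plane: `microalgal`, `HNA_p`, `LNA_p`
  (split at FL1 = 1.5×10⁴), `HFL3_p`, and background. Counts become
  concentrations via `count × dilution / volume` (cells·µL⁻¹ of undiluted
  culture).
- **Dynamics** — per-population concentration trajectories, lag /
  exponential / stationary / decline phase annotation from the specific
  growth rate µ (h⁻¹), fold-change and percent-change summaries.
- **Fingerprint diversity** — the phenotypic fingerprint: bivariate kernel
  densities over all pairs of FL1-A, FL3-A, FSC-A, SSC-A on a fixed grid,
  concatenated and normalized to a probability vector **p**. The phenotypic
  diversity index is the Hill number of order two,

  D₂ = (Σᵢ pᵢ²)⁻¹,

  the "effective number of phenotypic states", reported with a bootstrap
  error (n = 3 resamples by default).
- **Synthetic cocultures** — a seeded generator of complete monitoring runs
  (log-normal event clusters, lag→logistic growth, Poisson sampling at the
  instrument's volume/dilution, background scattering), with ground truth,
  so the entire pipeline is testable without instrument data. Five bundled
  scenarios emulate monitored *C. vulgaris* cocultures with *Sphingopyxis*,
  *Tistrella* and *Pseudomonas* strains spanning 2.2–1002.4 cells·µL⁻¹.

## Worked example

```python
from cytomon import (coculture_scenarios, simulate_coculture_series,
                     default_gateset, transform_events, count_populations,
                     assemble_timeseries, detect_growth_phases,
                     diversity_with_bootstrap)

gates = default_gateset()
cfg = coculture_scenarios(seed=1)["sphingopyxis"]       # 72.5-h lag scenario
series, truth = simulate_coculture_series(cfg)
print(f"simulated {len(series)} samples over {cfg.duration_h:.0f} h")

counts = [count_populations(transform_events(s), gates, elapsed_h=float(t))
          for s, t in zip(series, series.elapsed_hours())]
prok = assemble_timeseries(counts, "HNA_p")
print(f"prokaryotes: {prok.concentrations[0]:.1f} -> "
      f"{prok.concentrations[-1]:.1f} cells/uL")

for seg in detect_growth_phases(prok, window_h=10.0).segments:
    print(f"  {seg.label:12s} {seg.t_start:6.1f}-{seg.t_end:6.1f} h"
          f"   mu = {seg.mu:+.4f} 1/h")

d2 = diversity_with_bootstrap(transform_events(series.samples[-1]),
                              gate=gates["HNA_p"], n_boot=3, seed=1)
print(f"D2 = {d2.d2_mean:.0f} +/- {d2.d2_sd:.0f} a.u."
      f"  (n = {d2.n_events} gated events)")
```

Output:

```
simulated 289 samples over 120 h
prokaryotes: 3.3 -> 34.4 cells/uL
  lag             0.0-  78.3 h   mu = +0.0021 1/h
  exponential    78.3- 120.0 h   mu = +0.0686 1/h
D2 = 490 +/- 45 a.u.  (n = 21 gated events)
```

The dilute prokaryotic population (true initial 2.4 cells·µL⁻¹ means only
~1.5 measured events per sample) is recovered from counting noise; the
annotated lag ends within hours of the configured 72.5 h, and the
exponential-phase µ̂ approximates the generating rate (0.058 h⁻¹). D₂ is in
arbitrary units, comparable only across identical grid/bandwidth/gate
settings.

There is also a CLI mirroring the library stages:

```bash
cytomon simulate --scenario assemblage_high --seed 1 --out run/
cytomon monitor --in run/ --out report/ --seed 1
```

`monitor` writes `counts.csv`, `dynamics.csv`, `diversity.csv`, a JSON
manifest (config, seed, version, input checksums) and plots.

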