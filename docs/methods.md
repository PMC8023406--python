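# Methods

## Measurement model

One online measurement is a list-mode FCS file: N events × channels
(FSC-A, SSC-A, FL1-A, FL3-A, optionally pulse-height variants), acquired
after 1:100 dilution of the culture and SYBR Green I staining, with a
nominal analyzed volume of 61 µL per 90-s acquisition. The concentration of
a gated population in the undiluted culture is

    c = count × dilution_factor / acquired_volume_uL   [cells·µL⁻¹].

Volume and dilution are treated as per-sample *data*, read from FCS
keywords ($VOL, nanoliters, per the FCS 3.1 standard; #DILUTION) or a YAML/
JSON sidecar; absent both, the online defaults (61 µL, 1:100) are applied
with a warning so real files remain usable. The package includes its own
compact FCS 3.0/3.1 reader and FCS 3.1 writer (single-precision list mode);
round-trips are lossless at float32. Area (-A) channels are canonical for
all analysis; -H channels are carried through and used only to emulate the
instrument's acquisition trigger.

## Gating

Intensities are mapped x → log10(max(x, 1)) — total on non-negative 24-bit
instrument data — and the transform is recorded on the table so it cannot
be applied twice. Gates are simple polygons in log10(FL1-A) × log10(FL3-A)
with **closed-boundary** membership (edge and vertex points are inside;
deterministic and consistent with common cytometry practice), evaluated
**first-match-wins** in the priority `microalgal > HFL3_p > HNA_p > LNA_p`.
Events matching no gate remain in the totals as `ungated`; events whose
FL1-H falls below the acquisition threshold (default 800 instrument units)
are discarded first, emulating the instrument trigger.

Default gates (rectangles, log10 units): microalgal FL1 ∈ [3.2, 7.0] ×
FL3 ∈ [4.5, 7.2]; HFL3_p [2.7, 6.0] × [3.5, 4.5]; HNA_p [4.176, 6.0] ×
[0, 3.5]; LNA_p [3.3, 4.176] × [0, 3.5]. Only the HNA_p/LNA_p boundary
(FL1-A = 1.5×10⁴, log10 = 4.176) is a calibrated value; the other vertices
are documented working defaults meant to be adapted per experiment via the
YAML gate files — gate placement always requires validation against the
actual instrument and stain. HNA_p and LNA_p deliberately share the FL1
boundary edge; "disjoint" therefore means interiors disjoint (pairwise
polygon-intersection area zero), with shared-edge points resolved by
priority.

## Growth-phase annotation

ln(concentration) is regressed against time; zeros are replaced by half the
smallest positive observed concentration (standard pseudo-count, keeps lag
phases analyzable). The trajectory is divided into windows of `window_h`
(default 10 h, which resolves the ~50–72.5 h lags seen at 25-min cadence
without over-segmenting). Each window is labeled by a slope **pooled over
the window ± one neighbouring window**: exponential if µ̂ > µ_threshold
(default 0.02 h⁻¹), decline if µ̂ < −µ_threshold, otherwise lag (before any
growth) or stationary. Pooling matters at the dilute end of the measured
range: at 2.4 cells·µL⁻¹ the instrument sees ≈1.5 events per sample, and a
raw 10-h window slope has a standard error (~0.05 h⁻¹) larger than the
threshold, whereas the pooled slope's (~0.01 h⁻¹) is comfortably below it.
Single-window blips are absorbed into the longer neighbour, and every
remaining boundary is refined by a continuous two-slope ("hinge")
least-squares fit over the two flanking segments, which localizes a
lag→exponential transition to within a few hours even at that noise level.
Per-segment µ̂ is the ordinary log-linear regression slope over the final
segment. A series that is all zeros raises a degenerate-series error.

Fold change is last/first (or max/first) concentration; percent change is
reported rounded to one decimal. Both require a positive reference value.

## Phenotypic fingerprint and diversity index

Log intensities are rescaled to [0, 1] by the fixed full scale log10(2²⁴)
(per-sample min/max would make grids incomparable across samples). For each
of the six unordered pairs of {FL1-A, FL3-A, FSC-A, SSC-A}, events are
binned on an nbin × nbin grid over the unit square and smoothed with a
Gaussian kernel — a binned KDE: deterministic, fast, and grid-aligned with
the fingerprint definition. σ is the `bandwidth` parameter on the unit
scale (default 0.01, i.e. 1.28 bins at the default nbin = 128; both follow
the documented defaults of the established fingerprinting approach for
aquatic microbial communities and are exposed as parameters). The kernel is
truncated at 4σ with zero-padding at the grid border. The six grids are
flattened, concatenated, and **globally** normalized to sum 1 (per-pair
normalization is available as an option), making

    D₂ = 1 / Σᵢ pᵢ²

a single effective number of phenotypic states over the whole fingerprint.
General orders use D_q = (Σ pᵢ^q)^{1/(1−q)}, with q = 1 computed as
exp(Shannon entropy). D₂ is in arbitrary units: it depends on nbin,
bandwidth, channel set and gate, and is comparable only across identical
settings, which the reports embed as a settings hash.

Diversity is computed on the HNA_p-gated community by default (LNA_p is
often background-dominated and HFL3_p unconfirmed, so both are excluded
from diversity analysis); the gate is a parameter. Error bars come from
`n_boot` (default 3) resamples of the gated events with replacement at full
gated size; the bootstrap SD uses ddof = 1 (defined as 0 for a single
resample). In a diversity time series, samples with fewer than two gated
events are skipped with a warning.

## Synthetic coculture generator

The generator emulates what the analysis consumes, not the instrument
electronics. Each population is a multivariate-normal cluster in log10
(FSC, SSC, FL1, FL3) — matching the log-scaled appearance of cytometric
populations — whose concentration follows

    N(t) = N0                                     for t < lag
    N(t) = K·N0·e^{µ(t−lag)} / (K + N0·(e^{µ(t−lag)} − 1))   afterwards,

optionally followed by exponential decline after a peak time (one
parametric family covers lag, exponential, saturation and peak-then-decline
patterns). The measured event count per sample is Poisson with mean
N(t)·volume/dilution; FL1-H mirrors FL1-A with a small negative log offset;
background scattering is uniform over a low-FL1 box below the LNA_p domain.
All randomness flows from a mandatory seed through `numpy`
SeedSequence/Generator substreams, one per sample, so runs are reproducible
and stages independently re-runnable. Ground truth (true concentration
schedule and per-event labels) is always returned, and synthetic FCS files
carry a `#SYNTHETIC` provenance keyword.

Five bundled scenarios reproduce the monitored coculture conditions at
25-min cadence, 61 µL, 1:100 dilution: *Sphingopyxis* (2.4 → 37.0
cells·µL⁻¹ after a 72.5-h lag; this scenario runs 120 h because the lag
plus a subsequent exponential phase cannot fit in 72 h), *Tistrella*
(2.2 → 28.4, ~50-h lag), a three-strain assemblage inoculated below the
alga (2.6 → 47.6 plus a constant 12.8 cells·µL⁻¹ HFL3 cluster), the same
assemblage inoculated above the alga (126.6 growing immediately to a
1305.7 peak at 37.5 h, declining to 1002.4, HFL3 constant at 47.6), and a
spontaneous contamination (2.2 → 39.9). Growth rates are derived from those
endpoint pairs; cluster centres are placed inside their gates and
within-population covariances (sd ≈ 0.12–0.18 log10 units) are plausible
defaults, **not** fits — real within-population scatter is not recoverable
from published density plots.

What the generator does not emulate: staining kinetics, spectral overlap /
compensation, doublets, instrument drift, and non-Gaussian cluster shapes.
Passing recovery tests therefore demonstrates that the gating, counting,
phase-detection and diversity machinery is correct under the stated
statistical model of the data, not that the default gates fit any
particular instrument.

## Problem sizes and estimators

Test-suite and acceptance runs use the scenarios as configured: 173–289
samples per run at roughly 10³ events per sample, and ~10 replicate
simulations where an average is reported — comfortably converged for every
quantity checked. Because single samples at the dilute end carry Poisson
noise of order the signal (λ ≈ 1.5 events), fold-change endpoints in the
acceptance script are window averages (a 48-h window inside the lag phase;
the final 2 h) across replicates — the initial sample alone can contain
zero events, making a raw ratio undefined. Integer/one-decimal rounding is
applied only where the summary is conventionally quoted that way
(fold-changes, percent changes).

## Known limitations

- Absolute D₂ values are not comparable across nbin/bandwidth/channel/gate
  settings, nor to values produced with other fingerprinting software.
- Default gate vertices beyond the FL1 = 1.5×10⁴ boundary are qualitative
  and must be adapted per instrument; automated gate learning is out of
  scope, as are compensation and doublet discrimination.
- Phase labels come from a piecewise log-linear description, not a
  mechanistic growth model (no Monod/Baranyi fitting).
- The FCS writer emits the single list-mode float32 dialect the reader
  consumes plus standard keywords; exotic FCS 2.0 dialects and analysis
  segments are unsupported.
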