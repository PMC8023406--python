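"""Concentration time series, growth-phase annotation, and change summaries.

Per-population concentrations from consecutive gated samples form a
:class:`CultureTimeSeries`.  Growth phases (lag, exponential, stationary,
decline) are annotated from the specific growth rate µ (h^-1) estimated by
log-linear regression: coarse labels come from locally pooled window
slopes, and each phase boundary is then refined by a continuous two-slope
("hinge") least-squares fit over the flanking segments, which localizes
lag-to-exponential transitions well even at the few-events-per-sample
counting noise typical of dilute online measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_MU_THRESHOLD = 0.02  # h^-1; below this a window counts as non-growing
DEFAULT_WINDOW_H = 10.0

PHASE_LAG = "lag"
PHASE_EXPONENTIAL = "exponential"
PHASE_STATIONARY = "stationary"
PHASE_DECLINE = "decline"


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no usable signal (e.g. all zeros)."""


@dataclass
class CultureTimeSeries:
    """Concentration trajectory of one gated population."""

    population: str
    times_h: np.ndarray
    concentrations: np.ndarray  # cells / µL
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if len(self.times_h) and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass
class PhaseSegment:
    t_start: float
    t_end: float
    label: str
    mu: float  # specific growth rate over the segment, h^-1


@dataclass
class GrowthPhaseAnnotation:
    segments: list[PhaseSegment]

    def label_at(self, t: float) -> str:
        for seg in self.segments:
            if seg.t_start <= t <= seg.t_end:
                return seg.label
        raise ValueError(f"t={t} outside annotated span")

    def boundaries(self) -> list[float]:
        return [seg.t_start for seg in self.segments[1:]]

    def lag_exponential_boundary(self) -> float | None:
        """Start of the last exponential segment, or None if none exists."""
        for seg in reversed(self.segments):
            if seg.label == PHASE_EXPONENTIAL:
                return seg.t_start
        return None


def assemble_timeseries(counts: list, population: str) -> CultureTimeSeries:
    """Build a population trajectory from per-sample :class:`CountResult`.

    A sample that lacks the requested gate is an error (never a silent
    zero), as is a duplicated time point.
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 count results to form a time series")
    times, conc, ids = [], [], []
    for c in counts:
        if population not in c.concentrations:
            raise KeyError(
                f"population {population!r} missing from sample {c.sample_id!r}; "
                f"has {sorted(c.concentrations)}"
            )
        times.append(c.elapsed_h)
        conc.append(c.concentrations[population])
        ids.append(c.sample_id)
    order = np.argsort(times)
    times = np.asarray(times)[order]
    if np.any(np.diff(times) <= 0):
        raise ValueError("duplicate or non-increasing sample times")
    return CultureTimeSeries(
        population=population,
        times_h=times,
        concentrations=np.asarray(conc)[order],
        sample_ids=[ids[i] for i in order],
    )


def _log_with_pseudocount(conc: np.ndarray) -> np.ndarray:
    positive = conc[conc > 0]
    if positive.size == 0:
        raise DegenerateSeriesError("all concentrations are zero")
    pseudo = positive.min() / 2.0
    return np.log(np.where(conc > 0, conc, pseudo))


def _hinge_breakpoint(t: np.ndarray, y: np.ndarray) -> float:
    """Breakpoint of the best continuous two-slope fit y = a + b1*t + (b2-b1)*(t-tau)+."""
    best_tau, best_sse = t[len(t) // 2], np.inf
    for tau in t[2:-2]:
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tau, 0.0)])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = res[0] if res.size else float(np.sum((y - X @ beta) ** 2))
        if sse < best_sse:
            best_sse, best_tau = sse, tau
    return float(best_tau)


def detect_growth_phases(
    series: CultureTimeSeries,
    window_h: float = DEFAULT_WINDOW_H,
    mu_threshold: float = DEFAULT_MU_THRESHOLD,
) -> GrowthPhaseAnnotation:
    """Segment a trajectory into lag/exponential/stationary/decline phases.

    Zeros are replaced by half the smallest positive concentration before
    taking logs.  Window grid points ``window_h`` apart get a slope from a
    regression pooled over the three surrounding windows (counting noise at
    one or two events per sample would otherwise flip individual windows);
    same-label windows merge, short segments are absorbed, and every
    remaining boundary is refined by a hinge least-squares fit over the two
    flanking segments.
    """
    t = series.times_h
    if len(t) < 5:
        raise ValueError("need >= 5 points to annotate growth phases")
    y = _log_with_pseudocount(series.concentrations)
    span = t[-1] - t[0]
    n_windows = max(int(round(span / window_h)), 1)
    edges = np.linspace(t[0], t[-1], n_windows + 1)
    if np.searchsorted(t, edges[1]) < 3 and n_windows > 1:
        raise ValueError("window_h must span >= 3 points")

    # pooled slope per window (window +- one window on each side)
    labels: list[str] = []
    for i in range(n_windows):
        lo = max(edges[i] - window_h, t[0])
        hi = min(edges[i + 1] + window_h, t[-1])
        sel = (t >= lo) & (t <= hi)
        mu = _slope(t[sel], y[sel])
        if mu > mu_threshold:
            labels.append(PHASE_EXPONENTIAL)
        elif mu < -mu_threshold:
            labels.append(PHASE_DECLINE)
        else:
            labels.append(PHASE_STATIONARY)  # lag/stationary resolved later

    # merge adjacent windows with equal labels into segments [i0, i1)
    segments: list[list] = []
    for i, lab in enumerate(labels):
        if segments and segments[-1][2] == lab:
            segments[-1][1] = i + 1
        else:
            segments.append([i, i + 1, lab])

    # absorb single-window blips into the longer neighbour
    def seg_len(s):
        return s[1] - s[0]

    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, s in enumerate(segments):
            if seg_len(s) == 1 and len(segments) > 1:
                nbrs = [segments[j] for j in (i - 1, i + 1) if 0 <= j < len(segments)]
                target = max(nbrs, key=seg_len)
                s[2] = target[2]
                merged = []
                for seg in segments:
                    if merged and merged[-1][2] == seg[2]:
                        merged[-1][1] = seg[1]
                    else:
                        merged.append(seg)
                segments = merged
                changed = True
                break

    # refine boundaries between differently-labelled segments by hinge fit
    bounds = [t[0]]
    for i in range(len(segments) - 1):
        lo, hi = edges[segments[i][0]], edges[segments[i + 1][1]]
        sel = (t >= lo) & (t <= hi)
        if sel.sum() >= 6:
            tau = _hinge_breakpoint(t[sel], y[sel])
            tau = min(max(tau, edges[segments[i][0] + 1]), edges[segments[i + 1][1] - 1])
        else:
            tau = edges[segments[i][1]]
        bounds.append(tau)
    bounds.append(t[-1])

    out: list[PhaseSegment] = []
    seen_growth = False
    for (t0, t1), seg in zip(zip(bounds[:-1], bounds[1:]), segments):
        sel = (t >= t0) & (t <= t1)
        mu = _slope(t[sel], y[sel]) if sel.sum() >= 2 else 0.0
        label = seg[2]
        if label == PHASE_STATIONARY and not seen_growth:
            label = PHASE_LAG
        if label in (PHASE_EXPONENTIAL, PHASE_DECLINE):
            seen_growth = True
        out.append(PhaseSegment(t_start=float(t0), t_end=float(t1), label=label, mu=mu))
    return GrowthPhaseAnnotation(segments=out)


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    if len(t) < 2 or np.ptp(t) == 0:
        return 0.0
    return float(stats.linregress(t, y).slope)


def fold_change(series: CultureTimeSeries, mode: str = "final") -> float:
    """Ratio of final (or maximum) to initial concentration."""
    first = series.concentrations[0]
    if first <= 0:
        raise ZeroDivisionError(
            f"fold change undefined: initial concentration of {series.population!r} is 0"
        )
    if mode == "final":
        return float(series.concentrations[-1] / first)
    if mode == "max":
        return float(series.concentrations.max() / first)
    raise ValueError(f"mode must be 'final' or 'max', got {mode!r}")


def percent_change(reference: float, target: float, direction: str = "increase") -> float:
    """Percent increase or decline of ``target`` relative to ``reference``.

    Reported to one decimal, matching how trajectory summaries are usually
    quoted (e.g. a rise from 1465.5 to 2341.1 a.u. is a 59.7% increase).
    """
    if reference <= 0:
        raise ZeroDivisionError("percent change undefined for reference <= 0")
    if direction == "increase":
        pct = (target - reference) / reference * 100.0
    elif direction == "decline":
        pct = (reference - target) / reference * 100.0
    else:
        raise ValueError(f"direction must be 'increase' or 'decline', got {direction!r}")
    return round(pct, 1)
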