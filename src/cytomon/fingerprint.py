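"""Phenotypic fingerprints and Hill-diversity of gated communities.

A phenotypic fingerprint summarizes the single-cell phenotype distribution
of a (typically HNA_p-gated) prokaryotic community: for every unordered
pair of the selected channels (FL1-A, FL3-A, FSC-A, SSC-A by default) a
bivariate kernel density is estimated on a fixed nbin x nbin grid over the
unit square, and the six grids are flattened, concatenated, and normalized
to a single probability vector.  The phenotypic diversity index is the
Hill number of order two of that vector,

    D2 = 1 / sum_i p_i^2,

the "effective number of phenotypic states" weighting richness and
evenness equally.  Its absolute value depends on nbin, bandwidth, channel
set and gate, so it is an arbitrary-unit index comparable only across
identical settings; a small bootstrap (n = 3 by default) over the gated
events supplies an error bar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

from .fcs_io import EventTable, MeasurementSeries
from .gating import Gate, apply_gate

logger = logging.getLogger(__name__)

#: unit scale: log10 of the 24-bit instrument range
LOG_FULL_SCALE = float(np.log10(2**24))

DEFAULT_CHANNELS = ("FL1-A", "FL3-A", "FSC-A", "SSC-A")
DEFAULT_NBIN = 128
DEFAULT_BANDWIDTH = 0.01  # Gaussian kernel sigma on the unit scale
DEFAULT_N_BOOT = 3


class InsufficientEventsError(ValueError):
    """Raised when fewer than two gated events are available."""


@dataclass
class Fingerprint:
    """Concatenated, globally normalized bivariate-KDE probability vector."""

    values: np.ndarray
    channels: tuple[str, ...]
    nbin: int
    bandwidth: float
    gate_name: str | None
    n_events: int
    subsample_n: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_pairs = len(list(combinations(self.channels, 2)))
        if self.values.size != n_pairs * self.nbin**2:
            raise ValueError(
                f"fingerprint length {self.values.size} != "
                f"{n_pairs} pairs x {self.nbin}^2"
            )
        if np.any(self.values < 0):
            raise ValueError("fingerprint entries must be >= 0")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("fingerprint must sum to 1")

    @property
    def settings(self) -> dict:
        return {
            "channels": list(self.channels),
            "nbin": self.nbin,
            "bandwidth": self.bandwidth,
            "gate": self.gate_name,
        }


@dataclass
class DiversityResult:
    """Bootstrap summary of the order-2 Hill diversity (arbitrary units)."""

    d2_mean: float
    d2_sd: float
    d2_boot: np.ndarray
    n_boot: int
    n_events: int
    elapsed_h: float = float("nan")
    settings: dict = field(default_factory=dict)


def rescale_channels(table: EventTable, channels: list[str] | None = None) -> np.ndarray:
    """Map log10 intensities onto [0, 1] by the fixed 24-bit full scale.

    A fixed denominator (log10(2^24)) — rather than per-sample min/max —
    keeps KDE grids comparable across samples and experiments.
    """
    if not table.log_transformed:
        raise ValueError("rescale_channels expects a log-transformed table")
    if channels is None:
        channels = list(DEFAULT_CHANNELS)
    cols = [table.channel(c) for c in channels]
    mat = np.column_stack(cols) / LOG_FULL_SCALE
    if np.any(mat > 1.0):
        logger.warning("intensities above full scale clipped to 1.0")
        mat = np.minimum(mat, 1.0)
    return mat


def _pair_density(x: np.ndarray, y: np.ndarray, nbin: int, bandwidth: float) -> np.ndarray:
    hist, _, _ = np.histogram2d(x, y, bins=nbin, range=[[0.0, 1.0], [0.0, 1.0]])
    sigma_bins = bandwidth * nbin
    if sigma_bins > 0:
        hist = ndimage.gaussian_filter(hist, sigma=sigma_bins, truncate=4.0, mode="constant")
    return hist


def compute_fingerprint(
    table: EventTable,
    gate: Gate | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    nbin: int = DEFAULT_NBIN,
    bandwidth: float = DEFAULT_BANDWIDTH,
    subsample_n: int | None = None,
    seed: int | np.random.Generator | None = None,
    normalize: str = "global",
) -> Fingerprint:
    """Phenotypic fingerprint of the (optionally gated) events of one sample.

    Each of the ``C(len(channels), 2)`` channel pairs yields a 2-D histogram
    on an ``nbin x nbin`` grid over the unit square, smoothed with a
    Gaussian kernel of sigma ``bandwidth`` (unit scale, truncated at 4
    sigma); the grids are flattened, concatenated and normalized —
    ``normalize="global"`` over the whole vector (so D2 is one effective
    number of states), or ``"per_pair"`` to give each pair grid mass 1/6.
    """
    mat = rescale_channels(table, list(channels))
    if gate is not None:
        mat = mat[apply_gate(table, gate)]
    if mat.shape[0] < 2:
        raise InsufficientEventsError(
            f"need >= 2 events after gating, got {mat.shape[0]}"
        )
    if subsample_n is not None and subsample_n < mat.shape[0]:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        mat = mat[rng.integers(0, mat.shape[0], size=subsample_n)]

    idx = {c: j for j, c in enumerate(channels)}
    grids = [
        _pair_density(mat[:, idx[a]], mat[:, idx[b]], nbin, bandwidth).ravel()
        for a, b in combinations(channels, 2)
    ]
    if normalize == "per_pair":
        grids = [g / (g.sum() * len(grids)) for g in grids]
    elif normalize != "global":
        raise ValueError(f"normalize must be 'global' or 'per_pair', got {normalize!r}")
    vec = np.concatenate(grids)
    vec /= vec.sum()
    return Fingerprint(
        values=vec,
        channels=tuple(channels),
        nbin=nbin,
        bandwidth=bandwidth,
        gate_name=gate.name if gate is not None else None,
        n_events=mat.shape[0],
        subsample_n=subsample_n,
    )


def hill_diversity(fp: Fingerprint | np.ndarray, q: float = 2.0) -> float:
    """Hill number D_q = (sum_i p_i^q)^(1/(1-q)) of a probability vector.

    q = 2 is the inverse Simpson index 1/sum(p^2); q = 1 is the limit
    exp(Shannon entropy); q = 0 counts the support.
    """
    p = fp.values if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be >= 0")
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"input must be normalized to sum 1 (got {total:.6g})")
    p = p[p > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2.0:
        return float(1.0 / np.sum(p * p))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_with_bootstrap(
    table: EventTable,
    gate: Gate | None = None,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    nbin: int = DEFAULT_NBIN,
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator | None = None,
    elapsed_h: float = float("nan"),
) -> DiversityResult:
    """Order-2 Hill diversity of gated events with bootstrap error.

    Resamples the gated events with replacement at full size ``n_boot``
    times; each resample yields a fingerprint and its D2.  The bootstrap SD
    is 0 by definition for ``n_boot = 1``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    mask = apply_gate(table, gate) if gate is not None else np.ones(table.n_events, bool)
    gated = table.with_events(table.events[mask])
    if gated.n_events < 2:
        raise InsufficientEventsError(
            f"need >= 2 gated events, got {gated.n_events} (gate {getattr(gate, 'name', None)!r})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d2 = np.empty(n_boot)
    fp_settings: dict = {}
    for b in range(n_boot):
        resampled = gated.with_events(
            gated.events[rng.integers(0, gated.n_events, size=gated.n_events)]
        )
        fp = compute_fingerprint(
            resampled, gate=None, channels=channels, nbin=nbin, bandwidth=bandwidth
        )
        fp_settings = fp.settings
        d2[b] = hill_diversity(fp, q=2.0)
    fp_settings["gate"] = gate.name if gate is not None else None
    sd = float(np.std(d2, ddof=1)) if n_boot > 1 else 0.0
    return DiversityResult(
        d2_mean=float(d2.mean()),
        d2_sd=sd,
        d2_boot=d2,
        n_boot=n_boot,
        n_events=gated.n_events,
        elapsed_h=elapsed_h,
        settings=fp_settings,
    )


def diversity_timeseries(
    series: MeasurementSeries,
    gate: Gate,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    nbin: int = DEFAULT_NBIN,
    bandwidth: float = DEFAULT_BANDWIDTH,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    transform=None,
) -> list[DiversityResult]:
    """Diversity trajectory over a measurement series (default gate HNA_p).

    Samples with fewer than two gated events are skipped with a warning
    rather than aborting the run.  ``transform`` is applied to each raw
    sample first (pass :func:`cytomon.gating.transform_events` for linear
    FCS input; None if the tables are already log-transformed).
    """
    if len(series) == 0:
        raise ValueError("empty measurement series")
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(len(series))]
    hours = series.elapsed_hours()
    out: list[DiversityResult] = []
    for sample, t_h, rng in zip(series, hours, streams):
        tab = transform(sample) if transform is not None else sample
        try:
            out.append(
                diversity_with_bootstrap(
                    tab,
                    gate=gate,
                    channels=channels,
                    nbin=nbin,
                    bandwidth=bandwidth,
                    n_boot=n_boot,
                    seed=rng,
                    elapsed_h=float(t_h),
                )
            )
        except InsufficientEventsError:
            logger.warning(
                "sample %s at t=%.2f h: <2 gated events, skipped", sample.sample_id, t_h
            )
    return out
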