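"""Seeded synthetic coculture experiments for end-to-end pipeline testing.

Real instrument runs (an online-staining robot feeding a flow cytometer
every 25 min for ~3 days) are emulated as mixtures of log-normal event
clusters: one microalgal cluster with strong chlorophyll autofluorescence,
up to three prokaryotic clusters in the high-nucleic-acid (HNA) region,
an optional red-shifted (HFL3) cluster, and uniform low-intensity
background scattering.  Per-population concentrations follow
lag -> logistic growth (optionally peak-then-exponential-decline), and the
number of events actually measured in a sample is Poisson with mean
``N(t) * volume / dilution``.

The bundled scenarios mirror monitored coculture experiments of
C. vulgaris with Sphingopyxis sp., Tistrella sp. and Pseudomonas sp.
spanning initial/final concentrations from 2.2 to 1002.4 cells/µL; their
parameters are the generator's defaults, and every simulation returns the
ground-truth schedule so recovery can be tested quantitatively.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fcs_io import EventTable, MeasurementSeries

CHANNELS = ["FSC-A", "SSC-A", "FL1-A", "FL3-A", "FL1-H"]
_MEAN_ORDER = ("FSC-A", "SSC-A", "FL1-A", "FL3-A")

BACKGROUND = "background"
#: log10 bounds of the uniform background cloud, per channel in _MEAN_ORDER
BACKGROUND_BOX = ((3.0, 4.5), (2.5, 4.0), (2.6, 3.3), (0.0, 3.3))
#: FL1-H is FL1-A shifted down slightly in log space (pulse height < area)
FL1H_LOG_OFFSET = -0.05
FL1H_LOG_SD = 0.03


@dataclass
class PopulationSpec:
    """One event cluster and its growth trajectory.

    ``mean`` is the cluster centre in log10 instrument units over
    (FSC-A, SSC-A, FL1-A, FL3-A); ``cov`` either a per-channel sd vector
    (diagonal) or a full 4x4 covariance in log10 units squared.
    """

    name: str
    mean: tuple[float, float, float, float]
    cov: np.ndarray | tuple[float, ...] = (0.15, 0.15, 0.15, 0.15)
    n0: float = 1.0  # initial concentration, cells/µL
    lag_h: float = 0.0
    mu: float = 0.0  # specific growth rate, h^-1
    carrying_capacity: float = 1e4  # cells/µL
    peak_time_h: float | None = None
    decline_rate: float = 0.0  # h^-1, applied after peak_time_h

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov**2)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError(f"population {self.name!r}: cov must be symmetric 4x4")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError(f"population {self.name!r}: cov must be positive-definite")
        self.cov = cov
        if self.n0 < 0 or self.mu < 0 or self.lag_h < 0 or self.decline_rate < 0:
            raise ValueError(f"population {self.name!r}: rates/concentrations must be >= 0")
        if self.mu > 0 and self.carrying_capacity < self.n0:
            raise ValueError(
                f"population {self.name!r}: carrying capacity below initial concentration"
            )


@dataclass
class SyntheticCultureConfig:
    """Complete description of one synthetic monitoring experiment."""

    populations: list[PopulationSpec]
    seed: int
    duration_h: float = 72.0
    interval_min: float = 25.0
    volume_uL: float = 61.0
    dilution: float = 100.0
    background_rate: float = 150.0  # expected background events per sample
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2024, 1, 1, 8, 0, 0)
    )

    def __post_init__(self) -> None:
        if self.duration_h <= 0 or self.interval_min <= 0:
            raise ValueError("duration and sampling interval must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulations")

    def sampling_times_h(self) -> np.ndarray:
        n = math.floor(self.duration_h * 60.0 / self.interval_min) + 1
        return np.arange(n) * self.interval_min / 60.0


@dataclass
class GroundTruth:
    """True concentration schedule and per-event labels of a simulation."""

    times_h: np.ndarray
    concentrations: dict[str, np.ndarray]  # population -> cells/µL at each time
    labels: list[np.ndarray]  # per sample: population name per event


def simulate_growth(spec: PopulationSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Concentration (cells/µL) of a population at time ``t`` hours.

    N(t) = N0 during the lag; logistic growth
    N = K N0 e^{mu (t-lag)} / (K + N0 (e^{mu (t-lag)} - 1)) afterwards; if a
    peak time is set, exponential decline at ``decline_rate`` beyond it.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    n0, k, mu = spec.n0, spec.carrying_capacity, spec.mu

    def base(tt: np.ndarray) -> np.ndarray:
        out = np.full_like(tt, n0, dtype=float)
        grow = tt >= spec.lag_h
        if mu > 0 and n0 > 0:
            e = np.exp(mu * (tt[grow] - spec.lag_h))
            out[grow] = k * n0 * e / (k + n0 * (e - 1.0))
        return out

    n = base(t)
    if spec.peak_time_h is not None and spec.decline_rate > 0:
        past = t > spec.peak_time_h
        n_peak = base(np.asarray([spec.peak_time_h]))[0]
        n[past] = n_peak * np.exp(-spec.decline_rate * (t[past] - spec.peak_time_h))
    return float(n) if n.ndim == 0 else n


def _draw_cluster(spec: PopulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    logs = rng.multivariate_normal(spec.mean, spec.cov, size=n)
    return logs


def _assemble_events(log_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Add the FL1-H column and exponentiate log10 draws to linear units."""
    fl1h = log_rows[:, 2] + FL1H_LOG_OFFSET + rng.normal(0.0, FL1H_LOG_SD, len(log_rows))
    full = np.column_stack([log_rows, fl1h])
    return np.power(10.0, full)


def simulate_sample(
    config: SyntheticCultureConfig,
    t_h: float,
    rng: np.random.Generator,
    return_labels: bool = False,
):
    """One measurement point: Poisson event counts, log-normal clusters.

    Expected measured events per population are ``N(t) * volume / dilution``;
    background events are uniform over a low-intensity box in log space.
    """
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for spec in config.populations:
        lam = simulate_growth(spec, t_h) * config.volume_uL / config.dilution
        n = int(rng.poisson(lam))
        if n:
            blocks.append(_draw_cluster(spec, n, rng))
            labels.append(np.full(n, spec.name, dtype=object))
    n_bg = int(rng.poisson(config.background_rate))
    if n_bg:
        lo = np.array([b[0] for b in BACKGROUND_BOX])
        hi = np.array([b[1] for b in BACKGROUND_BOX])
        blocks.append(rng.uniform(lo, hi, size=(n_bg, 4)))
        labels.append(np.full(n_bg, BACKGROUND, dtype=object))

    if blocks:
        log_rows = np.concatenate(blocks)
        lab = np.concatenate(labels)
        order = rng.permutation(len(log_rows))
        events = _assemble_events(log_rows[order], rng)
        lab = lab[order]
    else:
        events = np.empty((0, len(CHANNELS)))
        lab = np.empty(0, dtype=object)

    table = EventTable(
        events=events,
        channel_names=list(CHANNELS),
        acquired_volume_uL=config.volume_uL,
        dilution_factor=config.dilution,
        timestamp=config.start_time + _dt.timedelta(hours=float(t_h)),
        sample_id=f"t{t_h:07.2f}h",
        extra_keywords={"#SYNTHETIC": "cytomon-simulated coculture"},
    )
    return (table, lab) if return_labels else table


def simulate_coculture_series(
    config: SyntheticCultureConfig,
) -> tuple[MeasurementSeries, GroundTruth]:
    """Full monitoring run: one sample per cadence tick plus ground truth."""
    times = config.sampling_times_h()
    streams = np.random.SeedSequence(config.seed).spawn(len(times))
    tables, labels = [], []
    for t_h, ss in zip(times, streams):
        table, lab = simulate_sample(
            config, float(t_h), np.random.default_rng(ss), return_labels=True
        )
        tables.append(table)
        labels.append(lab)
    truth = GroundTruth(
        times_h=times,
        concentrations={
            spec.name: np.asarray(simulate_growth(spec, times))
            for spec in config.populations
        },
        labels=labels,
    )
    series = MeasurementSeries(
        samples=tables, t0=config.start_time, sampling_interval_min=config.interval_min
    )
    return series, truth


# ---------------------------------------------------------------------------
# bundled coculture scenarios
# ---------------------------------------------------------------------------

#: cluster centres, log10 (FSC-A, SSC-A, FL1-A, FL3-A)
CLUSTER_MEANS = {
    "chlorella": (5.5, 5.0, 5.2, 5.8),
    "sphingopyxis": (4.3, 3.9, 4.90, 1.8),
    "tistrella": (4.1, 3.7, 4.75, 2.2),
    "pseudomonas": (4.4, 4.0, 5.05, 1.5),
    "hfl3_cluster": (4.2, 3.8, 4.20, 4.0),
    "contaminant": (4.2, 3.8, 4.85, 1.9),
}
_ALGA_SD = (0.18, 0.18, 0.18, 0.18)
_PROK_SD = (0.15, 0.15, 0.15, 0.15)
_HFL3_SD = (0.12, 0.12, 0.12, 0.12)


def _rate(n_start: float, n_end: float, dt_h: float) -> float:
    return math.log(n_end / n_start) / dt_h


def _alga(n0: float, k: float) -> PopulationSpec:
    return PopulationSpec(
        name="chlorella", mean=CLUSTER_MEANS["chlorella"], cov=_ALGA_SD,
        n0=n0, mu=0.05, carrying_capacity=max(k, n0),
    )


def coculture_scenarios(seed: int = 0) -> dict[str, SyntheticCultureConfig]:
    """The five bundled coculture monitoring scenarios.

    Initial and final concentrations follow the monitored experiments
    (e.g. Sphingopyxis rising from 2.4 to 37.0 cells/µL after a 72.5-h lag;
    the dense multispecies assemblage growing immediately from 126.6 to a
    1305.7 peak before declining to 1002.4).  Growth rates are derived from
    those endpoints; cluster shapes are plausible defaults, not fits.
    """
    sub = np.random.SeedSequence(seed).generate_state(5)

    scenarios: dict[str, SyntheticCultureConfig] = {}
    # 1: C. vulgaris + Sphingopyxis sp. — long lag, then exponential growth
    scenarios["sphingopyxis"] = SyntheticCultureConfig(
        seed=int(sub[0]),
        duration_h=120.0,
        populations=[
            _alga(46.5, 49.0),
            PopulationSpec(
                name="sphingopyxis", mean=CLUSTER_MEANS["sphingopyxis"], cov=_PROK_SD,
                n0=2.4, lag_h=72.5, mu=_rate(2.4, 37.0, 120.0 - 72.5),
            ),
        ],
    )
    # 2: C. vulgaris + Tistrella sp. — ~50-h lag
    scenarios["tistrella"] = SyntheticCultureConfig(
        seed=int(sub[1]),
        populations=[
            _alga(27.2, 48.0),
            PopulationSpec(
                name="tistrella", mean=CLUSTER_MEANS["tistrella"], cov=_PROK_SD,
                n0=2.2, lag_h=50.0, mu=_rate(2.2, 28.4, 22.0),
            ),
        ],
    )
    # 3: multispecies assemblage inoculated below C. vulgaris
    n0_each = 2.6 / 3.0
    mu3 = _rate(2.6, 47.6, 22.0)
    scenarios["assemblage_low"] = SyntheticCultureConfig(
        seed=int(sub[2]),
        populations=[
            PopulationSpec(
                name="chlorella", mean=CLUSTER_MEANS["chlorella"], cov=_ALGA_SD,
                n0=43.6, peak_time_h=0.0, decline_rate=_rate(39.1, 43.6, 72.0),
            ),
            *[
                PopulationSpec(
                    name=strain, mean=CLUSTER_MEANS[strain], cov=_PROK_SD,
                    n0=n0_each, lag_h=50.0, mu=mu3,
                )
                for strain in ("sphingopyxis", "tistrella", "pseudomonas")
            ],
            PopulationSpec(
                name="hfl3_cluster", mean=CLUSTER_MEANS["hfl3_cluster"], cov=_HFL3_SD,
                n0=12.8,
            ),
        ],
    )
    # 4: multispecies assemblage inoculated above C. vulgaris —
    #    immediate exponential growth, peak at 37.5 h, then decline
    mu4 = _rate(126.6, 1305.7, 37.5)
    scenarios["assemblage_high"] = SyntheticCultureConfig(
        seed=int(sub[3]),
        populations=[
            _alga(66.4, 66.7),
            *[
                PopulationSpec(
                    name=strain, mean=CLUSTER_MEANS[strain], cov=_PROK_SD,
                    n0=126.6 / 3.0, mu=mu4, peak_time_h=37.5,
                    decline_rate=_rate(1002.4, 1305.7, 72.0 - 37.5),
                )
                for strain in ("sphingopyxis", "tistrella", "pseudomonas")
            ],
            PopulationSpec(
                name="hfl3_cluster", mean=CLUSTER_MEANS["hfl3_cluster"], cov=_HFL3_SD,
                n0=47.6,
            ),
        ],
    )
    # 5: spontaneous contamination — decelerated start, late exponential rise
    scenarios["undefined"] = SyntheticCultureConfig(
        seed=int(sub[4]),
        populations=[
            _alga(45.6, 49.2),
            PopulationSpec(
                name="contaminant", mean=CLUSTER_MEANS["contaminant"], cov=_PROK_SD,
                n0=2.2, lag_h=40.0, mu=_rate(2.2, 39.9, 32.0),
            ),
        ],
    )
    return scenarios


PROKARYOTE_POPULATIONS = ("sphingopyxis", "tistrella", "pseudomonas", "contaminant")

#: which gate each synthetic population should land in with the default gate set
POPULATION_GATE = {
    "chlorella": "microalgal",
    "sphingopyxis": "HNA_p",
    "tistrella": "HNA_p",
    "pseudomonas": "HNA_p",
    "contaminant": "HNA_p",
    "hfl3_cluster": "HFL3_p",
    BACKGROUND: "ungated",
}


# ---------------------------------------------------------------------------
# YAML scenario config
# ---------------------------------------------------------------------------

def config_to_dict(config: SyntheticCultureConfig) -> dict:
    return {
        "seed": config.seed,
        "duration_h": config.duration_h,
        "interval_min": config.interval_min,
        "volume_uL": config.volume_uL,
        "dilution": config.dilution,
        "background_rate": config.background_rate,
        "start_time": config.start_time.isoformat(),
        "populations": [
            {
                "name": p.name,
                "mean": list(p.mean),
                "cov": np.asarray(p.cov).tolist(),
                "n0": p.n0,
                "lag_h": p.lag_h,
                "mu": p.mu,
                "carrying_capacity": p.carrying_capacity,
                "peak_time_h": p.peak_time_h,
                "decline_rate": p.decline_rate,
            }
            for p in config.populations
        ],
    }


def load_scenario(path: str | Path) -> SyntheticCultureConfig:
    raw = yaml.safe_load(Path(path).read_text())
    pops = [
        PopulationSpec(
            name=p["name"],
            mean=tuple(p["mean"]),
            cov=np.asarray(p["cov"]) if "cov" in p else _PROK_SD,
            n0=float(p.get("n0", 1.0)),
            lag_h=float(p.get("lag_h", 0.0)),
            mu=float(p.get("mu", 0.0)),
            carrying_capacity=float(p.get("carrying_capacity", 1e4)),
            peak_time_h=p.get("peak_time_h"),
            decline_rate=float(p.get("decline_rate", 0.0)),
        )
        for p in raw["populations"]
    ]
    return SyntheticCultureConfig(
        populations=pops,
        seed=int(raw["seed"]),
        duration_h=float(raw.get("duration_h", 72.0)),
        interval_min=float(raw.get("interval_min", 25.0)),
        volume_uL=float(raw.get("volume_uL", 61.0)),
        dilution=float(raw.get("dilution", 100.0)),
        background_rate=float(raw.get("background_rate", 150.0)),
        start_time=_dt.datetime.fromisoformat(
            raw.get("start_time", "2024-01-01T08:00:00")
        ),
    )


def save_scenario(config: SyntheticCultureConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
    return path
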