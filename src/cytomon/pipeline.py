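"""End-to-end orchestration: simulate/load -> gate -> count -> dynamics -> diversity.

`run_monitor` drives a complete monitoring analysis from either a directory
of FCS files or a synthetic scenario config, and writes a reproducible
report bundle: counts.csv, dynamics.csv, diversity.csv, a JSON manifest
(config, seed, software version, input checksums) and advisory plots.
CSV outputs are the deterministic contract; plots are not byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import assemble_timeseries, detect_growth_phases, fold_change
from .fcs_io import MeasurementSeries, load_series
from .fingerprint import (
    DEFAULT_BANDWIDTH,
    DEFAULT_N_BOOT,
    DEFAULT_NBIN,
    diversity_timeseries,
)
from .gating import GateSet, count_populations, default_gateset, load_gateset, transform_events
from .synthetic import load_scenario, simulate_coculture_series

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised for unusable run configurations (e.g. an empty input dir)."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage and sample."""


@dataclass
class RunConfig:
    """Configuration of one monitoring run."""

    input_path: str | Path  # directory of FCS files, or a scenario YAML
    output_dir: str | Path
    seed: int = 0
    gate_file: str | Path | None = None
    diversity_gate: str = "HNA_p"
    nbin: int = DEFAULT_NBIN
    bandwidth: float = DEFAULT_BANDWIDTH
    n_boot: int = DEFAULT_N_BOOT
    diversity_stride: int = 1  # compute diversity every k-th sample
    window_h: float = 10.0
    mu_threshold: float = 0.02
    make_plots: bool = True
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(self.input_path)
        d["output_dir"] = str(self.output_dir)
        d["gate_file"] = str(self.gate_file) if self.gate_file else None
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input(config: RunConfig) -> tuple[MeasurementSeries, dict[str, str]]:
    path = Path(config.input_path)
    if path.is_dir():
        fcs = sorted(path.glob("*.fcs"))
        if not fcs:
            raise PipelineConfigError(f"no .fcs files found in {path}")
        return load_series(fcs), {str(p): _sha256(p) for p in fcs}
    if path.suffix.lower() in (".yaml", ".yml"):
        scenario = load_scenario(path)
        series, _ = simulate_coculture_series(scenario)
        return series, {str(path): _sha256(path)}
    raise PipelineConfigError(
        f"input must be a directory of FCS files or a scenario YAML, got {path}"
    )


def _counts_stage(series: MeasurementSeries, gates: GateSet) -> list:
    hours = series.elapsed_hours()
    results = []
    for sample, t_h in zip(series, hours):
        try:
            table = transform_events(sample)
            results.append(count_populations(table, gates, elapsed_h=float(t_h)))
        except Exception as exc:
            raise StageError(f"stage=counting sample={sample.sample_id!r}: {exc}") from exc
    return results


def run_monitor(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Returns a mapping of artifact name to written path.  Any stage failure
    aborts with the stage name and sample id; whatever was written before
    the failure is flagged as partial in the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    series, checksums = _load_input(config)  # fail before creating outputs
    out.mkdir(parents=True, exist_ok=True)
    gates = load_gateset(config.gate_file) if config.gate_file else default_gateset()

    artifacts: dict[str, Path] = {}
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "software": {"package": "cytomon", "version": __version__},
        "inputs": checksums,
        "n_samples": len(series),
        "complete": False,
    }
    manifest_path = out / "manifest.json"
    try:
        counts = _counts_stage(series, gates)
        rows = []
        for c in counts:
            for name, n in c.counts.items():
                rows.append(
                    {
                        "sample_id": c.sample_id,
                        "time_h": c.elapsed_h,
                        "population": name,
                        "count": n,
                        "concentration_cells_per_uL": c.concentrations.get(name, np.nan),
                        "total_events": c.total_events,
                        "below_threshold": c.n_below_threshold,
                    }
                )
        counts_df = pd.DataFrame(rows)
        artifacts["counts"] = out / "counts.csv"
        counts_df.to_csv(artifacts["counts"], index=False, float_format="%.10g")

        dyn_rows = []
        for name in gates.names:
            try:
                ts = assemble_timeseries(counts, name)
            except (KeyError, ValueError) as exc:
                raise StageError(f"stage=dynamics population={name!r}: {exc}") from exc
            annotation = None
            if len(ts) >= 5 and ts.concentrations.max() > 0:
                annotation = detect_growth_phases(
                    ts, window_h=config.window_h, mu_threshold=config.mu_threshold
                )
            for t_h, conc in zip(ts.times_h, ts.concentrations):
                label, mu = "", np.nan
                if annotation is not None:
                    seg = next(
                        s for s in annotation.segments if s.t_start <= t_h <= s.t_end
                    )
                    label, mu = seg.label, seg.mu
                dyn_rows.append(
                    {
                        "time_h": t_h,
                        "population": name,
                        "concentration_cells_per_uL": conc,
                        "phase_label": label,
                        "mu_per_h": mu,
                    }
                )
        dyn_df = pd.DataFrame(dyn_rows)
        artifacts["dynamics"] = out / "dynamics.csv"
        dyn_df.to_csv(artifacts["dynamics"], index=False, float_format="%.10g")

        sub = MeasurementSeries(
            samples=list(series)[:: config.diversity_stride],
            t0=series.t0,
            sampling_interval_min=series.sampling_interval_min,
        )
        divs = diversity_timeseries(
            sub,
            gate=gates[config.diversity_gate],
            nbin=config.nbin,
            bandwidth=config.bandwidth,
            n_boot=config.n_boot,
            seed=config.seed,
            transform=transform_events,
        )
        settings_hash = ""
        div_rows = []
        for d in divs:
            settings_hash = hashlib.sha256(
                json.dumps(d.settings, sort_keys=True).encode()
            ).hexdigest()[:12]
            div_rows.append(
                {
                    "time_h": d.elapsed_h,
                    "D2_mean": d.d2_mean,
                    "D2_sd": d.d2_sd,
                    "n_events_gated": d.n_events,
                    "settings_hash": settings_hash,
                }
            )
        div_df = pd.DataFrame(div_rows)
        artifacts["diversity"] = out / "diversity.csv"
        div_df.to_csv(artifacts["diversity"], index=False, float_format="%.10g")

        if config.make_plots:
            artifacts.update(_make_plots(out, counts_df, div_df, series, gates))

        manifest["complete"] = True
    finally:
        manifest["artifacts"] = {k: str(v) for k, v in artifacts.items()}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = manifest_path
    return artifacts


def _make_plots(out: Path, counts_df, div_df, series, gates) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made: dict[str, Path] = {}
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, grp in counts_df[counts_df.population != "ungated"].groupby("population"):
        ax.plot(grp.time_h, grp.concentration_cells_per_uL, label=name, lw=1)
    ax.set_xlabel("time since inoculation [h]")
    ax.set_ylabel("concentration [cells/µL]")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    made["plot_concentrations"] = out / "concentrations.png"
    fig.savefig(made["plot_concentrations"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if len(div_df):
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(div_df.time_h, div_df.D2_mean, yerr=div_df.D2_sd, fmt="o-", ms=2, lw=1)
        ax.set_xlabel("time since inoculation [h]")
        ax.set_ylabel("phenotypic diversity index D2 [a.u.]")
        made["plot_diversity"] = out / "diversity.png"
        fig.savefig(made["plot_diversity"], dpi=120, bbox_inches="tight")
        plt.close(fig)

    # FL1/FL3 density panels for the first and last sample, gates overlaid
    picks = [series.samples[0], series.samples[-1]]
    fig, axes = plt.subplots(1, len(picks), figsize=(5 * len(picks), 4), squeeze=False)
    for ax, sample in zip(axes[0], picks):
        table = transform_events(sample)
        if table.n_events:
            ax.hist2d(
                table.channel("FL1-A"), table.channel("FL3-A"),
                bins=128, range=[[0, 7.3], [0, 7.3]], cmin=1, cmap="viridis",
            )
        for gate in gates.gates:
            xs, ys = zip(*(gate.vertices + [gate.vertices[0]]))
            ax.plot(xs, ys, lw=0.8)
            ax.annotate(gate.name, gate.vertices[0], fontsize=7)
        ax.set_xlabel("log10 FL1-A")
        ax.set_ylabel("log10 FL3-A")
        ax.set_title(sample.sample_id, fontsize=8)
    made["plot_density"] = out / "density_panels.png"
    fig.savefig(made["plot_density"], dpi=120, bbox_inches="tight")
    plt.close(fig)
    return made


def fold_change_from_counts(counts: list, population: str, mode: str = "final") -> float:
    """Convenience: fold change of one gated population over a run."""
    return fold_change(assemble_timeseries(counts, population), mode=mode)
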