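"""Parameter sweeps, seizure detection and report export.

A sweep runs the standard seizure experiment (induction current, then one
stimulation protocol) over a grid of protocol settings and a list of
seeds, and reports the efficacy rate (nS/s over the stimulation window)
per cell with across-seed mean and standard deviation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import build_connectivity
from .engine import (SimulationConfig, SimulationResult, efficacy_rate,
                     run_simulation)
from .protocols import PROTOCOL_POLARITIES, ProtocolSpec

__all__ = [
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "percent_change_map",
    "detect_seizures",
    "export_report",
]


@dataclass
class SweepSpec:
    """Grid over FTSTS settings crossed with a seed list.

    Every combination of amplitude x train_offset x width x
    inter_pulse_interval x protocol name is one cell; each cell is run once
    per seed.  ``base`` supplies everything else (network, seizure input,
    stimulation window via base.protocol_onset/duration).
    """

    amplitudes: Sequence[float] = (2.0,)
    train_offsets: Sequence[float] = (0.0,)
    widths: Sequence[float] = (1.0,)
    inter_pulse_intervals: Sequence[float] = (10.0,)
    protocols: Sequence[str] = ("inverted-standard",)
    overlap_fractions: Sequence[float] = (0.0,)
    seeds: Sequence[int] = (0, 1, 2, 3, 4)
    base: SimulationConfig = field(default_factory=SimulationConfig)
    protocol_onset: float = 10000.0
    protocol_duration: float = 5000.0

    def __post_init__(self) -> None:
        for name, grid in (("amplitudes", self.amplitudes),
                           ("train_offsets", self.train_offsets),
                           ("widths", self.widths),
                           ("inter_pulse_intervals",
                            self.inter_pulse_intervals),
                           ("protocols", self.protocols),
                           ("overlap_fractions", self.overlap_fractions),
                           ("seeds", self.seeds)):
            if len(list(grid)) == 0:
                raise ValueError(f"{name} grid must be non-empty")

    def cells(self):
        return itertools.product(self.protocols, self.amplitudes,
                                 self.widths, self.inter_pulse_intervals,
                                 self.train_offsets, self.overlap_fractions)


@dataclass
class SweepResult:
    """Long-format per-run table plus per-cell aggregate."""

    runs: pd.DataFrame      # one row per (cell, seed)
    summary: pd.DataFrame   # one row per cell: mean, sd, n

    @property
    def best_increase(self) -> pd.Series:
        return self.summary.loc[self.summary["rate_mean"].idxmax()]

    @property
    def best_decrease(self) -> pd.Series:
        return self.summary.loc[self.summary["rate_mean"].idxmin()]


_CELL_COLS = ["protocol", "amplitude", "width", "inter_pulse_interval",
              "train_offset", "overlap_fraction"]


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Run every (cell, seed) simulation and aggregate efficacy rates.

    Individual run failures are recorded (rate = NaN, error message kept)
    and the sweep continues.  Connectivity is built once and shared.
    """
    weights = build_connectivity(spec.base.connectivity)
    window = (spec.protocol_onset,
              spec.protocol_onset + spec.protocol_duration)
    rows = []
    for cell in spec.cells():
        proto_name, amp, width, ipi, offset, overlap = cell
        proto = ProtocolSpec(
            name=proto_name, amplitude=amp, width=width,
            inter_pulse_interval=ipi, train_offset=offset,
            onset=spec.protocol_onset, duration=spec.protocol_duration,
            overlap_fraction=overlap)
        for seed in spec.seeds:
            config = replace(spec.base, seed=seed, electrical=[proto],
                             optogenetic=[], record_spikes=False)
            row = dict(zip(_CELL_COLS, cell), seed=seed, error="")
            try:
                result = run_simulation(config, weights=weights)
                row["rate"] = efficacy_rate(result, window)
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                row["rate"] = np.nan
                row["error"] = str(exc)
            rows.append(row)
            if progress:
                print(f"{cell} seed={seed}: rate={row['rate']:.3f}")
    runs = pd.DataFrame(rows)
    grouped = runs.groupby(_CELL_COLS, sort=False)["rate"]
    summary = grouped.agg(rate_mean="mean", rate_sd="std",
                          n="count").reset_index()
    return SweepResult(runs=runs, summary=summary)


def percent_change_map(W_start: np.ndarray, W_end: np.ndarray) -> np.ndarray:
    """Per-synapse percent change 100*(W_end - W_start)/W_start.

    Entries with zero baseline are returned as NaN (undefined).
    """
    if W_start.shape != W_end.shape:
        raise ValueError("weight matrices must share a shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (W_end - W_start) / W_start
    out[W_start == 0] = np.nan
    return out


def detect_seizures(result: SimulationResult, bin_ms: float = 100.0,
                    rate_threshold_hz: float = 10.0,
                    exclude_windows: Sequence[tuple[float, float]] = (),
                    min_duration_ms: float = 300.0) -> list[tuple[float, float]]:
    """Locate network-wide seizure episodes from the excitatory raster.

    A seizure bin is one where the mean per-neuron excitatory firing rate
    exceeds ``rate_threshold_hz`` (baseline spontaneous activity sits well
    below 1 Hz).  Contiguous seizure bins of at least ``min_duration_ms``
    form one episode; bins inside ``exclude_windows`` (e.g. stimulation
    windows, whose forced firing is not ictal activity) are ignored.
    Returns a list of (start_ms, end_ms) episodes.
    """
    n_e = result.config.connectivity.N_E
    duration = result.config.duration
    edges = np.arange(0.0, duration + bin_ms, bin_ms)
    counts, _ = np.histogram(result.spike_times_e, bins=edges)
    rate_hz = counts / n_e / (bin_ms / 1000.0)
    hot = rate_hz > rate_threshold_hz
    centers = 0.5 * (edges[:-1] + edges[1:])
    for lo, hi in exclude_windows:
        hot &= ~((centers >= lo) & (centers <= hi))
    episodes: list[tuple[float, float]] = []
    start = None
    for j, flag in enumerate(hot):
        if flag and start is None:
            start = edges[j]
        elif not flag and start is not None:
            if edges[j] - start >= min_duration_ms:
                episodes.append((float(start), float(edges[j])))
            start = None
    if start is not None and edges[-1] - start >= min_duration_ms:
        episodes.append((float(start), float(edges[-1])))
    return episodes


def _config_hash(spec: SweepSpec) -> str:
    payload = json.dumps(dataclasses.asdict(spec), sort_keys=True,
                         default=lambda o: getattr(o, "tolist", lambda: str(o))())
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def export_report(result: SweepResult, outdir: str | Path,
                  spec: SweepSpec | None = None,
                  make_figures: bool = True) -> dict[str, Path]:
    """Write sweep tables (and optional figures) to ``outdir``.

    Outputs: runs.csv (long format), summary.csv (per-cell mean/sd), and
    best_parameters.csv (strongest increase and decrease rows).  When a
    spec is given, a config hash and the seed list are embedded so that
    re-exports of identical results are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    runs = result.runs.copy()
    summary = result.summary.copy()
    if spec is not None:
        runs["config_hash"] = _config_hash(spec)
        summary["config_hash"] = _config_hash(spec)
        summary["seeds"] = ";".join(str(s) for s in spec.seeds)
    paths["runs"] = outdir / "runs.csv"
    runs.to_csv(paths["runs"], index=False, float_format="%.6g")
    paths["summary"] = outdir / "summary.csv"
    summary.to_csv(paths["summary"], index=False, float_format="%.6g")
    if len(summary):
        best = pd.DataFrame([
            {"direction": "increase", **result.best_increase.to_dict()},
            {"direction": "decrease", **result.best_decrease.to_dict()},
        ])
    else:
        best = pd.DataFrame(
            columns=["direction", *_CELL_COLS, "rate_mean", "rate_sd", "n"])
    paths["best"] = outdir / "best_parameters.csv"
    best.to_csv(paths["best"], index=False, float_format="%.6g")
    if make_figures and len(summary):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for proto, sub in summary.groupby("protocol"):
            fig, ax = plt.subplots(figsize=(5, 3.5))
            for amp, sub2 in sub.groupby("amplitude"):
                ax.plot(sub2["train_offset"], sub2["rate_mean"],
                        marker="o", label=f"{amp} nA")
            ax.set_xlabel("train-offset (ms)")
            ax.set_ylabel("rate of weight change (nS/s)")
            ax.set_title(proto)
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = outdir / f"efficacy_{proto}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            paths[f"figure_{proto}"] = path
    return paths
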