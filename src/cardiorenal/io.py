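"""Structured outputs: trajectory CSVs, summaries, run manifests, plots."""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ModelConfig
from .engine import SimulationResult

__all__ = ["RunManifest", "write_outputs", "write_beat_trace"]

#: significant digits in CSV output, chosen so CSV round-trips are exact
#: at the stored precision
CSV_DIGITS = 10


@dataclass
class RunManifest:
    config_hash: str
    scenario: str
    version: str
    wall_time_s: float
    status: str


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=f"%.{CSV_DIGITS}g")


def write_outputs(
    result: SimulationResult,
    out_dir: str | Path,
    config: ModelConfig | None = None,
    wall_time_s: float = 0.0,
    plots: bool = False,
) -> dict:
    """Write trajectory CSV, summary.json and manifest.json into ``out_dir``.

    Returns the paths written.  An empty trajectory still yields a valid
    headers-only CSV.  With ``plots=True`` a PV-loop-style trajectory
    figure is saved as well (requires matplotlib).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    traj_path = out / "trajectory.csv"
    _write_csv(result.trajectory, traj_path)
    paths["trajectory"] = traj_path

    summary = {
        "scenario": result.scenario,
        "status": result.status,
        "final_beat": result.final_summary.as_dict(),
    }
    if len(result.trajectory):
        last = result.trajectory.iloc[-1]
        for key in ("LV_mass", "V_w", "dD", "dL", "V_b", "GFR", "RBF", "PRA", "h_over_R"):
            if key in result.trajectory.columns:
                summary[key] = float(last[key])
    sum_path = out / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=2, default=float))
    paths["summary"] = sum_path

    manifest = RunManifest(
        config_hash=(config or ModelConfig()).config_hash(),
        scenario=result.scenario,
        version=__version__,
        wall_time_s=wall_time_s,
        status=result.status,
    )
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(asdict(manifest), indent=2))
    paths["manifest"] = man_path

    if plots and len(result.trajectory):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        tr = result.trajectory
        fig, axes = plt.subplots(2, 3, figsize=(12, 6), constrained_layout=True)
        panels = [
            ("MAP", "MAP (mmHg)"), ("sigma_f_peak", "peak fiber stress (kPa)"),
            ("sigma_f_ED", "ED fiber stress (kPa)"), ("V_b", "blood volume (L)"),
            ("LV_mass", "LV mass (g)"), ("EDP", "LV EDP (mmHg)"),
        ]
        for ax, (col, label) in zip(axes.flat, panels):
            if col in tr.columns:
                ax.plot(tr["time_day"], tr[col])
            ax.set_xlabel("time (days)")
            ax.set_ylabel(label)
        fig_path = out / "trajectory.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        paths["plot"] = fig_path
    return paths


def write_beat_trace(trace: pd.DataFrame, path: str | Path) -> Path:
    """Write a single-beat trace CSV (columns per the beat-trace layout)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_csv(trace, path)
    return path
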