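"""Result serialization: CSV tables plus a JSON run summary."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, param_hash, resolved_dict, save_config
from .metrics import ShiftRecord
from .protocols import NetworkResult, SimplifiedResult

__all__ = ["save_results", "records_frame"]


def records_frame(records: list[ShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "neuron": [r.neuron for r in records],
        "odi_before": [r.odi_before for r in records],
        "odi_after": [r.odi_after for r in records],
        "mean_rate_norm": [r.mean_rate for r in records],
        "shift_class": [r.shift_class.value for r in records],
    })


def save_results(result, cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write deterministic output files for one run.

    simplified runs: odi trajectory CSV + weight snapshots CSV.
    network runs: per-neuron shift records CSV.
    Both: summary.json with seed, parameter hash and version, and the
    resolved config YAML for exact re-runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": param_hash(cfg),
        "model": cfg.model,
        "deprivation": cfg.deprivation.value,
        "stage": cfg.stage.value,
        "rule": cfg.rule.value,
    }

    if isinstance(result, SimplifiedResult):
        stride = max(cfg.stride_ms // cfg.params.drive.cycle_ms, 1)
        traj = pd.DataFrame({
            "cycle": np.arange(result.rate_trace.size),
            "rate_e": result.rate_trace,
        }).iloc[::stride]
        files["trajectory"] = out / "trajectory.csv"
        traj.to_csv(files["trajectory"], index=False)
        wdf = pd.DataFrame({
            "afferent_ipsi": result.afferent_ipsi,
            "w_initial": result.w_initial,
            "w_at_reduction": result.w_at_reduction,
            "w_final": result.w_final,
        })
        files["weights"] = out / "weights.csv"
        wdf.to_csv(files["weights"], index=False)
        summary.update(
            odi_initial=result.odi_initial,
            odi_at_reduction=result.odi_at_reduction,
            odi_final=result.odi_final,
            odi_shift=result.odi_shift,
        )
    elif isinstance(result, NetworkResult):
        files["shift_records"] = out / "shift_records.csv"
        records_frame(result.records).to_csv(files["shift_records"], index=False)
        good = ~(np.isnan(result.odi_before) | np.isnan(result.odi_after))
        summary.update(
            odi_initial=float(np.mean(result.odi_before[good])),
            odi_final=float(np.mean(result.odi_after[good])),
            odi_shift=result.population_shift,
            n_toward_closed=sum(r.shift_class.value == "toward-closed"
                                for r in result.records),
            n_toward_open=sum(r.shift_class.value == "toward-open"
                              for r in result.records),
        )
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")

    files["summary"] = out / "summary.json"
    files["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
    files["config"] = out / "config.yaml"
    save_config(cfg, files["config"])
    return files
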