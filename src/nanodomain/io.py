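"""Export of trajectory ensembles to portable text formats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .engine import TrajectoryRecord
from .params import SimParams

__all__ = ["records_to_frame", "save_ensemble"]


def records_to_frame(records: list[TrajectoryRecord]) -> pd.DataFrame:
    """Tidy event-log table: one row per (trajectory, interval).

    Columns: ``traj_id, t_start, t_end, compartment, liganded``. Records
    without an interval log (simulated with ``record_events=False``) raise.
    """
    frames = []
    for tid, rec in enumerate(records):
        if rec.intervals is None:
            raise ValueError(f"record {tid} has no interval log")
        iv = rec.intervals.copy()
        iv.insert(0, "traj_id", tid)
        frames.append(iv)
    return pd.concat(frames, ignore_index=True)


def save_ensemble(
    out_dir, records: list[TrajectoryRecord], params: SimParams, root_seed: int
) -> None:
    """Write ``trajectories.csv`` and a JSON run manifest to ``out_dir``.

    The manifest carries the full parameter set (with derived ``dt``), a
    parameter hash, the root seed, per-trajectory seeds and censoring flags.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(out / "trajectories.csv", index=False)
    pdict = params.to_dict()
    manifest = {
        "params": pdict,
        "params_sha256": hashlib.sha256(
            json.dumps(pdict, sort_keys=True).encode()
        ).hexdigest(),
        "root_seed": root_seed,
        "trajectory_seeds": [int(r.seed) for r in records],
        "censored": [bool(r.censored) for r in records],
        "n_trajectories": len(records),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
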