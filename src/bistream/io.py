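"""HDF5 / TSV / JSON persistence for recordings, epochs and reports.

Conventions: TSV (UTF-8) for tables, 1-based site ids, times in seconds,
window offsets in ms, sample indices 0-based half-open.  Every report embeds
the configuration hash and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import LabeledEpochs, RecordingBlock
from .stimulus import PerceptTimeline, TripletStimulus

__all__ = [
    "write_block",
    "read_block",
    "write_epochs",
    "read_epochs",
    "write_table",
    "read_table",
    "write_report",
]


class SchemaError(ValueError):
    """An HDF5 container is missing a required field."""


def _require(h5: h5py.Group, name: str):
    if name not in h5:
        raise SchemaError(f"missing required field: /{name}")
    return h5[name]


def _site_table_to_h5(grp: h5py.Group, table: pd.DataFrame) -> None:
    grp.create_dataset("site_id", data=table["site_id"].to_numpy(dtype=np.int64))
    grp.create_dataset(
        "area", data=np.array(table["area"].astype(str), dtype=h5py.string_dtype())
    )
    for col in ("x", "y", "z"):
        if col in table:
            grp.create_dataset(col, data=table[col].to_numpy(dtype=float))


def _site_table_from_h5(grp: h5py.Group) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "site_id": _require(grp, "site_id")[()],
            "area": [s.decode() for s in _require(grp, "area")[()]],
        }
    )
    for col in ("x", "y", "z"):
        if col in grp:
            out[col] = grp[col][()]
    return out


def _timeline_to_h5(grp: h5py.Group, tl: PerceptTimeline) -> None:
    grp.create_dataset("press_times", data=tl.press_times)
    grp.create_dataset("percepts", data=tl.percepts)
    grp.create_dataset("stim_changes", data=tl.stim_changes)
    grp.attrs["block_dur"] = tl.block_dur


def _timeline_from_h5(grp: h5py.Group) -> PerceptTimeline:
    return PerceptTimeline(
        press_times=_require(grp, "press_times")[()],
        percepts=_require(grp, "percepts")[()],
        block_dur=float(grp.attrs["block_dur"]),
        stim_changes=grp["stim_changes"][()] if "stim_changes" in grp else np.array([]),
    )


def write_block(path: str | Path, block: RecordingBlock) -> None:
    """Recording container: /data (sites x samples), /fs, /site_table, /events."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=block.data)
        f.create_dataset("fs", data=float(block.fs))
        _site_table_to_h5(f.create_group("site_table"), block.site_table)
        ev = f.create_group("events")
        if block.stim is not None:
            s = ev.create_group("stimulus")
            for name in ("f_b", "df", "tone_dur", "intra_gap", "inter_gap"):
                s.attrs[name] = getattr(block.stim, name)
            s.attrs["n_triplets"] = block.stim.n_triplets
        if block.timeline is not None:
            _timeline_to_h5(ev.create_group("timeline"), block.timeline)


def read_block(path: str | Path) -> RecordingBlock:
    with h5py.File(path, "r") as f:
        data = _require(f, "data")[()]
        fs = float(_require(f, "fs")[()])
        site_table = _site_table_from_h5(_require(f, "site_table"))
        stim = timeline = None
        if "events" in f:
            ev = f["events"]
            if "stimulus" in ev:
                a = ev["stimulus"].attrs
                stim = TripletStimulus(
                    f_b=float(a["f_b"]),
                    df=float(a["df"]),
                    n_triplets=int(a["n_triplets"]),
                    tone_dur=float(a["tone_dur"]),
                    intra_gap=float(a["intra_gap"]),
                    inter_gap=float(a["inter_gap"]),
                )
            if "timeline" in ev:
                timeline = _timeline_from_h5(ev["timeline"])
    return RecordingBlock(data=data, fs=fs, site_table=site_table, stim=stim, timeline=timeline)


def write_epochs(path: str | Path, ep: LabeledEpochs) -> None:
    """Epochs container: /trials (trial x site x time), labels, masks, window."""
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=ep.trials)
        f.create_dataset("labels", data=ep.labels)
        f.create_dataset("kept", data=ep.kept)
        f.create_dataset("trial_onsets", data=ep.trial_onsets)
        f.create_dataset("fs", data=float(ep.fs))
        f.attrs["window_ms"] = list(ep.window)
        _site_table_to_h5(f.create_group("site_table"), ep.site_table)


def read_epochs(path: str | Path) -> LabeledEpochs:
    with h5py.File(path, "r") as f:
        return LabeledEpochs(
            trials=_require(f, "trials")[()],
            labels=_require(f, "labels")[()],
            kept=_require(f, "kept")[()],
            trial_onsets=_require(f, "trial_onsets")[()],
            window=tuple(f.attrs["window_ms"]),
            fs=float(_require(f, "fs")[()]),
            site_table=_site_table_from_h5(_require(f, "site_table")),
        )


def write_table(path: str | Path, table: pd.DataFrame, config: PipelineConfig | None = None) -> None:
    """TSV table; the config hash and seed ride along as a header comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.digest()} seed={config.seed}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: str | Path, report: dict, config: PipelineConfig | None = None) -> None:
    """JSON report with the config hash and seed embedded."""
    out = dict(report)
    if config is not None:
        out["config_hash"] = config.digest()
        out["seed"] = config.seed
    Path(path).write_text(json.dumps(_jsonable(out), indent=2, sort_keys=True))
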