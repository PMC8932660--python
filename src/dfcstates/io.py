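"""Plain-text interchange formats for sessions, connectomes and EEG.

Everything is delimited text so datasets round-trip without binary
containers: ROI time series as TSV (scans x ROIs, header row of labels) plus
a CSV session manifest; the connectome as a square TSV matrix and a
coordinate table; EEG as channels-in-columns TSV with a header line carrying
the sampling rate.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamic_fc import ROITimeSeries
from .synthetic import EEGRecording, StructuralConnectome, SyntheticSession

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_manifest",
    "read_manifest",
    "write_connectome",
    "read_connectome",
    "write_eeg",
    "read_eeg",
]


def write_timeseries(path: str | Path, session: SyntheticSession | ROITimeSeries,
                     labels: list[str] | None = None) -> None:
    data = session.timeseries if isinstance(session, SyntheticSession) else session.data
    if labels is None:
        labels = [f"ROI{i + 1:03d}" for i in range(data.shape[1])]
    pd.DataFrame(data, columns=labels).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, tr: float, condition: str = "",
                    session_id: str = "") -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(
        data=df.to_numpy(float), tr=tr, condition=condition, session_id=session_id
    )


def write_manifest(path: str | Path, rows: list[dict]) -> None:
    """One row per session: path, condition, tr, seed."""
    pd.DataFrame(rows, columns=["path", "condition", "tr", "seed"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_connectome(weights_path: str | Path, coords_path: str | Path,
                     sc: StructuralConnectome) -> None:
    pd.DataFrame(sc.weights, index=sc.labels, columns=sc.labels).to_csv(
        weights_path, sep="\t"
    )
    pd.DataFrame(sc.coords, index=sc.labels, columns=["x", "y", "z"]).to_csv(
        coords_path, sep="\t"
    )


def read_connectome(weights_path: str | Path, coords_path: str | Path) -> StructuralConnectome:
    w = pd.read_csv(weights_path, sep="\t", index_col=0)
    c = pd.read_csv(coords_path, sep="\t", index_col=0)
    return StructuralConnectome(
        weights=w.to_numpy(float), coords=c.to_numpy(float), labels=list(w.index)
    )


def write_eeg(path: str | Path, rec: EEGRecording) -> None:
    """Channels in columns; first line '# fs=<Hz> period=<s|none>'."""
    period = rec.artifact_period if rec.artifact_period is not None else "none"
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs} period={period}\n")
        pd.DataFrame(rec.data.T, columns=list(rec.channel_names)).to_csv(
            fh, sep="\t", index=False
        )


def read_eeg(path: str | Path) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    period = None if meta.get("period", "none") == "none" else float(meta["period"])
    return EEGRecording(
        data=df.to_numpy(float).T,
        fs=float(meta["fs"]),
        channel_names=tuple(df.columns),
        artifact_period=period,
    )
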