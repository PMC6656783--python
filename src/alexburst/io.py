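"""Readers and writers for photon streams and burst tables.

Two on-disk forms are supported for photon data:

* a minimal photon-HDF5-style layout (``/photon_data/timestamps``,
  ``/photon_data/detectors``; alternation metadata as attributes), and
* a plain CSV dialect with columns ``timestamp_us, channel, excitation``
  where channel is ``D``/``A`` and excitation ``Dex``/``Aex``.

Burst tables are plain CSV with one row per burst.
"""
from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .photons import (ACCEPTOR, CHANNEL_LABELS, DONOR, EXCITATION_LABELS,
                      PhotonStream)

BURST_COLUMNS = [
    "burst_id", "start_us", "end_us", "duration_ms",
    "n_DexDem", "n_DexAem", "n_AexDem", "n_AexAem", "E_star", "S",
]


# ---------------------------------------------------------------- photon CSV

def write_stream_csv(stream: PhotonStream, path) -> None:
    exc = stream.excitation
    df = pd.DataFrame(
        {
            "timestamp_us": stream.timestamps_us,
            "channel": np.array(["D", "A"])[stream.channel],
            "excitation": np.array(["Dex", "Aex"])[exc],
        }
    )
    df.to_csv(path, index=False)


def read_stream_csv(path, alternation_period_us: int = 50) -> PhotonStream:
    df = pd.read_csv(path)
    ch = (df["channel"].to_numpy() == "A").astype(np.uint8)
    return PhotonStream(df["timestamp_us"].to_numpy(np.int64), ch,
                        alternation_period_us)


# --------------------------------------------------------------- photon HDF5

def write_stream_hdf5(stream: PhotonStream, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps_us)
        g.create_dataset("detectors", data=stream.channel)
        g.attrs["timestamps_unit_us"] = 1
        g.attrs["alternation_period_us"] = stream.alternation_period_us
        g.attrs["detector_donor"] = DONOR
        g.attrs["detector_acceptor"] = ACCEPTOR


def read_stream_hdf5(path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        g = f["photon_data"]
        ts = g["timestamps"][()]
        det = g["detectors"][()]
        period = int(g.attrs["alternation_period_us"])
    return PhotonStream(ts, det, period)


# --------------------------------------------------------------- burst table

def write_burst_csv(df: pd.DataFrame, path) -> None:
    df.loc[:, BURST_COLUMNS].to_csv(path, index=False)


def read_burst_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BURST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"burst table missing columns: {missing}")
    return df


# ------------------------------------------------------------- ground truth

def write_truth_csv(truth: pd.DataFrame, path) -> None:
    """Sidecar table of simulated ground-truth transit intervals."""
    truth.to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
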