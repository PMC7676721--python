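"""Epoch containers, file I/O and segmentation.

The canonical container is :class:`EpochSet`: a stack of fixed-length
multichannel epochs with sampling-rate metadata, per-epoch emotion labels
from the six-class vocabulary, and a cohort tag (NC or PD).

On disk, epochs travel as long-format CSV — columns ``epoch_id, channel,
sample_index, value`` (0-based sample indices) — with labels in a separate
table ``epoch_id, label[, group]``; EDF recordings are read through mne
and segmented into epochs here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EMOTIONS",
    "EpochSet",
    "read_epochs_csv",
    "write_epochs_csv",
    "read_edf",
    "segment",
]

#: The six-emotion class vocabulary.
EMOTIONS = ("sadness", "happiness", "fear", "disgust", "surprise", "anger")


@dataclass
class EpochSet:
    """Labelled fixed-length multichannel EEG epochs.

    data : array (n_epochs, n_channels, n_samples)
    fs : sampling frequency in Hz
    labels : emotion class per epoch (may be None for unlabelled data)
    group : cohort tag, "NC" or "PD"
    provenance : free-form record of where the epochs came from
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    channel_names: list[str] | None = None
    group: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, n_channels, n_samples), got {self.data.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.data.shape[0]:
                raise ValueError("one label per epoch required")
            unknown = set(map(str, self.labels)) - set(EMOTIONS)
            if unknown:
                raise ValueError(
                    f"unknown class names {sorted(unknown)}; expected one of {EMOTIONS}"
                )
        if self.channel_names is None:
            self.channel_names = [f"ch{c + 1}" for c in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def write_epochs_csv(epochs: EpochSet, data_path, label_path=None) -> None:
    """Write an EpochSet as long-format CSV (+ optional label table)."""
    n_e, n_c, n_s = epochs.data.shape
    eid = np.repeat(np.arange(n_e), n_c * n_s)
    ch = np.tile(np.repeat(np.arange(n_c), n_s), n_e)
    si = np.tile(np.arange(n_s), n_e * n_c)
    pd.DataFrame(
        {
            "epoch_id": eid,
            "channel": ch,
            "sample_index": si,
            "value": epochs.data.ravel(),
        }
    ).to_csv(data_path, index=False, float_format="%.17g")  # lossless doubles
    if label_path is not None and epochs.labels is not None:
        lab = pd.DataFrame({"epoch_id": np.arange(n_e), "label": epochs.labels})
        if epochs.group is not None:
            lab["group"] = epochs.group
        lab.to_csv(label_path, index=False)


def read_epochs_csv(data_path, label_path=None, fs: float = 128.0) -> EpochSet:
    """Read long-format epoch CSV (columns epoch_id, channel, sample_index,
    value) plus an optional label table covering every epoch."""
    df = pd.read_csv(data_path, float_precision="round_trip")
    required = {"epoch_id", "channel", "sample_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{data_path}: missing columns {sorted(missing)}")
    bad = df[~np.isfinite(df["value"])]
    if len(bad):
        # +2: 1-based line numbers plus the header row
        raise ValueError(f"{data_path}: malformed value at line {bad.index[0] + 2}")

    epoch_ids = np.sort(df["epoch_id"].unique())
    channels = np.sort(df["channel"].unique())
    samples = np.sort(df["sample_index"].unique())
    n_e, n_c, n_s = len(epoch_ids), len(channels), len(samples)
    if len(df) != n_e * n_c * n_s:
        raise ValueError(
            f"{data_path}: ragged epochs — expected {n_e * n_c * n_s} rows "
            f"({n_e} epochs x {n_c} channels x {n_s} samples), got {len(df)}"
        )
    df = df.sort_values(["epoch_id", "channel", "sample_index"])
    data = df["value"].to_numpy().reshape(n_e, n_c, n_s)

    labels = group = None
    if label_path is not None:
        lab = pd.read_csv(label_path)
        if "epoch_id" not in lab or "label" not in lab:
            raise ValueError(f"{label_path}: need epoch_id and label columns")
        lab = lab.set_index("epoch_id")
        missing_ids = set(epoch_ids) - set(lab.index)
        if missing_ids:
            raise ValueError(f"{label_path}: missing labels for epochs {sorted(missing_ids)}")
        labels = lab.loc[epoch_ids, "label"].to_numpy()
        if "group" in lab:
            groups = set(lab.loc[epoch_ids, "group"])
            if len(groups) == 1:
                group = groups.pop()
    return EpochSet(
        data=data,
        fs=fs,
        labels=labels,
        group=group,
        provenance={"source": str(data_path)},
    )


def read_edf(path, window_s: float = 6.0, overlap_s: float = 0.0,
             channels: list[str] | None = None) -> EpochSet:
    """Read a continuous EDF recording and segment it into epochs.

    Channels are mapped by name when ``channels`` is given.  Requires mne
    (install the ``edf`` extra).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires mne (pip install tqeeg[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    fs = float(raw.info["sfreq"])
    cont = raw.get_data()
    eps = segment(cont, fs, window_s=window_s, overlap_s=overlap_s)
    return EpochSet(
        data=np.stack(eps),
        fs=fs,
        channel_names=list(raw.ch_names),
        provenance={"source": str(path), "window_s": window_s, "overlap_s": overlap_s},
    )


def segment(continuous, fs: float, window_s: float = 6.0, overlap_s: float = 0.0):
    """Cut a continuous (channels x T) recording into fixed windows.

    Windows are ``window_s * fs`` samples, consecutive and non-overlapping
    by default; a positive ``overlap_s`` shortens the hop.  The trailing
    remainder shorter than a full window is dropped.
    """
    arr = np.atleast_2d(np.asarray(continuous, dtype=float))
    length = int(round(window_s * fs))
    step = length - int(round(overlap_s * fs))
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    if arr.shape[1] < length:
        raise ValueError(
            f"recording of {arr.shape[1]} samples shorter than one "
            f"{length}-sample window"
        )
    n_windows = (arr.shape[1] - length) // step + 1
    return [arr[:, i * step : i * step + length].copy() for i in range(n_windows)]
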