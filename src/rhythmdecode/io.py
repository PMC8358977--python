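"""On-disk formats: the HDF5 session/epoch container and TSV event sidecars.

The canonical container is one HDF5 file per recording (data in microvolts,
float32) or per epoch set, carrying rate, channel metadata, events and, for
epochs, labels and the reject mask. A TSV sidecar (columns ``onset_sample``,
``label``) mirrors the events in plain text. EDF files can be ingested when
mne is installed (reading only).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .containers import EpochSet, Recording


def write_events_tsv(recording: Recording, path) -> None:
    """Plain-text event sidecar: onset_sample (0-based, at `rate`) and label."""
    with open(path, "w") as fh:
        fh.write("onset_sample\tlabel\n")
        for onset, label in zip(recording.event_onsets, recording.event_labels):
            fh.write(f"{int(onset)}\t{label}\n")


def read_events_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    onsets, labels = [], []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["onset_sample", "label"]:
            raise ValueError(f"unexpected event sidecar header: {header}")
        for line in fh:
            if not line.strip():
                continue
            onset, label = line.rstrip("\n").split("\t")[:2]
            onsets.append(int(onset))
            labels.append(label)
    return np.asarray(onsets, dtype=np.int64), np.asarray(labels, dtype=object)


def save_recording(recording: Recording, path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32), compression="gzip")
        f.attrs["rate"] = recording.rate
        f.attrs["site"] = recording.site
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype=h5py.string_dtype()),
        )
        if recording.channel_positions is not None:
            f.create_dataset("channel_positions", data=recording.channel_positions)
        f.create_dataset("event_onsets", data=recording.event_onsets)
        f.create_dataset(
            "event_labels",
            data=np.array([str(l) for l in recording.event_labels], dtype=h5py.string_dtype()),
        )
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][...],
            rate=float(f.attrs["rate"]),
            channel_labels=[s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][...]],
            channel_positions=f["channel_positions"][...] if "channel_positions" in f else None,
            event_onsets=f["event_onsets"][...],
            event_labels=np.array(
                [s.decode() if isinstance(s, bytes) else s for s in f["event_labels"][...]],
                dtype=object,
            ),
            site=str(f.attrs.get("site", "A")),
        )


def save_epochs(epochs: EpochSet, path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32), compression="gzip")
        f.attrs["rate"] = epochs.rate
        f.attrs["epoch_length"] = epochs.epoch_length
        f.create_dataset(
            "labels", data=np.array([str(l) for l in epochs.labels], dtype=h5py.string_dtype())
        )
        if epochs.reject_mask is not None:
            f.create_dataset("reject_mask", data=epochs.reject_mask)
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][...],
            labels=np.array(
                [s.decode() if isinstance(s, bytes) else s for s in f["labels"][...]],
                dtype=object,
            ),
            rate=float(f.attrs["rate"]),
            epoch_length=float(f.attrs["epoch_length"]),
            reject_mask=f["reject_mask"][...] if "reject_mask" in f else None,
        )


def read_recording(path, events_tsv=None) -> Recording:
    """Load a recording from the HDF5 container or an EDF file.

    EDF ingestion uses mne (optional dependency); stimulus events are taken
    from the TSV sidecar when given.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional, EDF reading only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rec = Recording(
            data=raw.get_data() * 1e6,  # volts -> microvolts
            rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )
    else:
        rec = load_recording(path)
    if events_tsv is not None:
        rec.event_onsets, rec.event_labels = read_events_tsv(events_tsv)
    return rec
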