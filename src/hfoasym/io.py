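"""Readers and writers: EDF signals and versioned CSV/TSV tables.

EDF is the clinical interchange format for the recordings; reading goes
through MNE. Writing uses a minimal built-in EDF encoder (16-bit, one
1-second data record per segment second) sufficient for round-tripping
simulated recordings. All tabular artifacts carry a schema tag on their
first line; readers reject unknown schemas so silent format drift cannot
corrupt an analysis.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ChannelInfo, EventRecord, GroundTruthEvent, SeegRecording

__all__ = [
    "write_edf",
    "read_recording",
    "write_table",
    "read_table",
    "channels_to_frame",
    "frame_to_channels",
    "events_to_frame",
    "frame_to_events",
    "ground_truth_to_frame",
]

_SCHEMAS = {
    "channels": "hfoasym-schema channels v1",
    "events": "hfoasym-schema events v1",
    "ground_truth": "hfoasym-schema ground_truth v1",
    "rates": "hfoasym-schema rates v1",
    "cohort": "hfoasym-schema cohort v1",
    "groups": "hfoasym-schema groups v1",
}


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | os.PathLike, signals: np.ndarray, sampling_rate: float,
              channel_ids: list[str], patient_id: str = "X") -> None:
    """Write a multichannel µV signal array as a 16-bit EDF file.

    One data record per second; the segment is zero-padded to a whole
    number of seconds. Physical ranges are per-channel symmetric around
    zero, so amplitude resolution adapts to each channel's dynamics.
    """
    signals = np.asarray(signals, dtype=float)
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = signals.shape
    if n_ch != len(channel_ids):
        raise ValueError("channel_ids length must match signal rows")
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = signals

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6) * 1.0001
    dig_max, dig_min = 32767, -32768
    header = b"".join([
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad("hfoasym simulated SEEG", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        b"".join(_pad(cid, 16) for cid in channel_ids),
        b"".join(_pad("SEEG depth", 80) for _ in channel_ids),
        b"".join(_pad("uV", 8) for _ in channel_ids),
        b"".join(_pad(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_pad(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_pad(str(dig_min), 8) for _ in channel_ids),
        b"".join(_pad(str(dig_max), 8) for _ in channel_ids),
        b"".join(_pad("LP:800Hz", 80) for _ in channel_ids),
        b"".join(_pad(str(fs), 8) for _ in channel_ids),
        b"".join(_pad("", 32) for _ in channel_ids),
    ]
    # quantize: phys -> digital, per channel
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.clip(np.round(padded * scale[:, None]), dig_min, dig_max
                      ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_recording(edf_path: str | os.PathLike,
                   channels_tsv: str | os.PathLike,
                   patient_id: str | None = None) -> SeegRecording:
    """Read an EDF file plus its channel-metadata sidecar.

    Signals are returned in µV; the sampling rate comes from the EDF
    header. Every EDF channel must have a row in the TSV (extra TSV rows,
    e.g. a cohort-wide sheet, are allowed).
    """
    import mne

    raw = mne.io.read_raw_edf(os.fspath(edf_path), preload=True, verbose="error")
    meta = read_table(channels_tsv, "channels")
    meta_by_id = {row.channel_id: row for row in meta.itertuples()}
    channels = []
    for name in raw.ch_names:
        if name not in meta_by_id:
            raise ValueError(
                f"channel {name!r} in EDF has no metadata row in {channels_tsv}"
            )
        row = meta_by_id[name]
        channels.append(ChannelInfo(name, row.lesion, bool(row.soz)))
    signals = raw.get_data() * 1e6  # MNE loads SI volts
    if patient_id is None:
        patient_id = Path(edf_path).stem
    return SeegRecording(patient_id, signals, float(raw.info["sfreq"]), channels)


# ---------------------------------------------------------------------------
# versioned tables


def write_table(df: pd.DataFrame, path: str | os.PathLike, schema: str) -> None:
    """Write a CSV/TSV with the schema tag as its first line."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    sep = "\t" if str(path).endswith(".tsv") else ","
    with open(path, "w") as fh:
        fh.write(f"# {_SCHEMAS[schema]}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | os.PathLike, schema: str) -> pd.DataFrame:
    """Read a schema-tagged table, rejecting unknown or mismatched tags."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    with open(path) as fh:
        first = fh.readline().strip()
        if first.lstrip("# ") != _SCHEMAS[schema]:
            raise ValueError(
                f"{path}: expected schema tag '# {_SCHEMAS[schema]}', "
                f"found {first!r}"
            )
        sep = "\t" if str(path).endswith(".tsv") else ","
        return pd.read_csv(fh, sep=sep)


def channels_to_frame(channels: list[ChannelInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.channel_id, c.lesion, c.soz) for c in channels],
        columns=["channel_id", "lesion", "soz"],
    )


def frame_to_channels(df: pd.DataFrame) -> list[ChannelInfo]:
    return [ChannelInfo(r.channel_id, r.lesion, bool(r.soz))
            for r in df.itertuples()]


def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.channel_id, e.event_type, e.start, e.end, e.peak_envelope,
          e.n_cycles) for e in events],
        columns=["channel_id", "type", "start_s", "end_s",
                 "peak_envelope_uv", "n_cycles"],
    )


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    return [
        EventRecord(r.channel_id, r.type, float(r.start_s), float(r.end_s),
                    float(r.peak_envelope_uv),
                    None if pd.isna(r.n_cycles) else int(r.n_cycles))
        for r in df.itertuples()
    ]


def ground_truth_to_frame(patient_id: str,
                          events: list[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(patient_id, e.channel_id, e.event_type, e.onset, e.duration,
          e.center_frequency, e.amplitude) for e in events],
        columns=["patient_id", "channel_id", "type", "onset_s", "duration_s",
                 "center_freq_hz", "amplitude_uv"],
    )
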