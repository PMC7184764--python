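"""Recording I/O and fixed-length segmentation.

A recording is a channels-by-samples matrix (microvolts) with a sampling
rate, ordered channel labels and a per-channel boolean seizure-onset-zone
(SOZ) mask supplied by the epileptologist.  Recordings are accepted either
as EDF (read through :mod:`mne`, if installed) or as a delimited numeric
text matrix (channels as rows) with a JSON sidecar carrying the metadata.

Segmentation cuts each channel into non-overlapping fixed-duration windows
(20 s by default); every segment of an SOZ channel is labelled focal,
every other segment non-focal.
"""

from __future__ import annotations

import json

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "Segment",
    "read_recording",
    "write_recording",
    "segment_recording",
]


@dataclass
class Recording:
    """Multichannel iEEG recording with SOZ annotations.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, microvolts.
    fs
        Sampling rate in Hz.
    channel_ids
        Ordered channel labels, one per row of ``data``.
    soz_mask
        Boolean array, ``True`` where the channel lies in the clinically
        annotated seizure onset zone.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str]
    soz_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_ids = [str(c) for c in self.channel_ids]
        self.soz_mask = np.asarray(self.soz_mask, dtype=bool)
        n = self.data.shape[0]
        if len(self.channel_ids) != n:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for {n} data rows"
            )
        if self.soz_mask.shape != (n,):
            raise ValueError("soz_mask length must equal the channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One fixed-length window of one channel."""

    x: np.ndarray
    channel_id: str
    channel_index: int
    segment_index: int
    label: bool  # True = focal (SOZ channel)

    def __len__(self) -> int:
        return len(self.x)


def _resolve_soz_mask(channel_ids: list[str], soz: list) -> np.ndarray:
    mask = np.zeros(len(channel_ids), dtype=bool)
    for item in soz:
        name = str(item)
        if name not in channel_ids:
            raise ValueError(
                f"SOZ label {name!r} does not match any channel "
                f"(channels: {channel_ids[:8]}{'...' if len(channel_ids) > 8 else ''})"
            )
        mask[channel_ids.index(name)] = True
    return mask


def _read_sidecar(path: Path) -> dict:
    """Read metadata: JSON object, or a plain text list of SOZ channel ids."""
    text = path.read_text()
    try:
        meta = json.loads(text)
        if not isinstance(meta, dict):
            raise ValueError("sidecar JSON must be an object")
        return meta
    except json.JSONDecodeError:
        soz = [line.strip() for line in text.splitlines() if line.strip()]
        return {"soz": soz}


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> Recording:
    """Read a recording from EDF or a delimited text matrix.

    For text matrices the sidecar is required and must provide ``fs`` and
    the ``soz`` channel list (``channel_ids`` optional, defaults to
    ``ch01..chNN``).  For EDF files the rate and labels come from the
    header and the sidecar supplies only the SOZ list (JSON with a
    ``soz`` key, or one channel id per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as err:  # pragma: no cover
            raise ImportError("reading EDF requires the 'mne' package") from err
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        channel_ids = list(raw.ch_names)
        if sidecar is None:
            raise ValueError("EDF input needs a sidecar listing SOZ channels")
        meta = _read_sidecar(Path(sidecar))
    else:
        if sidecar is None:
            sidecar = path.with_suffix(".json")
        meta = _read_sidecar(Path(sidecar))
        if "fs" not in meta:
            raise ValueError(f"sidecar {sidecar} must declare 'fs'")
        data = np.loadtxt(path, ndmin=2)
        fs = float(meta["fs"])
        channel_ids = meta.get(
            "channel_ids", [f"ch{i + 1:02d}" for i in range(data.shape[0])]
        )
    soz_mask = _resolve_soz_mask([str(c) for c in channel_ids], meta.get("soz", []))
    return Recording(data=data, fs=fs, channel_ids=channel_ids, soz_mask=soz_mask)


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write a recording as a TSV matrix plus JSON sidecar.

    Returns the (data, sidecar) paths.  EDF output is not supported; the
    text format round-trips through :func:`read_recording`.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    np.savetxt(path, rec.data, fmt="%.8g", delimiter="\t")
    meta = {
        "fs": rec.fs,
        "channel_ids": rec.channel_ids,
        "soz": [c for c, m in zip(rec.channel_ids, rec.soz_mask) if m],
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar


def segment_recording(rec: Recording, segment_seconds: float = 20.0) -> list[Segment]:
    """Cut every channel into non-overlapping ``segment_seconds`` windows.

    The trailing remainder shorter than one window is dropped, so each
    channel yields ``floor(duration / segment_seconds)`` segments of
    identical length ``L = round(fs * segment_seconds)``.  A 30-minute
    recording at 2 kHz with 20-s windows gives 90 segments per channel,
    L = 40,000.
    """
    if segment_seconds <= 0:
        raise ValueError("segment_seconds must be positive")
    L = int(round(rec.fs * segment_seconds))
    n_seg = rec.n_samples // L
    if n_seg == 0:
        raise ValueError(
            f"recording shorter than one segment "
            f"({rec.duration:.3f} s < {segment_seconds} s)"
        )
    out: list[Segment] = []
    for ci, (cid, focal) in enumerate(zip(rec.channel_ids, rec.soz_mask)):
        for si in range(n_seg):
            out.append(
                Segment(
                    x=rec.data[ci, si * L : (si + 1) * L],
                    channel_id=cid,
                    channel_index=ci,
                    segment_index=si,
                    label=bool(focal),
                )
            )
    return out
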