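"""Recording containers, file I/O, preprocessing and fixed-length segmentation.

A recording is a channels x samples matrix of microvolt values plus a
sampling rate, ordered channel names and a channel->region map.  Two file
dialects are supported:

* ``edf`` — European Data Format.  Reading goes through :mod:`mne`;
  writing uses a minimal 16-bit EDF writer (one 1-second data record per
  second of signal), sufficient for fixtures and synthetic exports.
* ``matrix`` — a plain-text dialect: one comma-separated row per channel in
  a ``.csv`` file, with a JSON sidecar (same path + ``.json``) holding
  ``{"fs": ..., "channel_names": [...], "region_map": {...}}``.

Preprocessing removes baseline drift with a zero-phase high-pass filter,
optionally notches line noise, and records amplitude-threshold exceedances
so that segmentation can flag artifact windows.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from .montage import DEFAULT_REGION_MAP, ECG_CHANNEL

RESPONSIVE = "responsive"
RESISTANT = "resistant"
LABELS = (RESPONSIVE, RESISTANT)


# ---------------------------------------------------------------------------
# containers


@dataclass
class EEGRecording:
    """Multichannel EEG signal in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Microvolt samples, one row per channel.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels in row order (10-20 names, optional ECG).
    region_map : dict
        Channel name -> region label for every non-ECG channel.
    artifact_mask : ndarray of bool, shape (n_samples,), optional
        Samples where any channel exceeded the artifact amplitude
        threshold; filled in by :func:`preprocess`.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    region_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_MAP))
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        missing = [
            ch for ch in self.channel_names
            if ch != ECG_CHANNEL and ch not in self.region_map
        ]
        if missing:
            raise ValueError(f"channels missing from region_map: {missing}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_names.index(name)]


@dataclass
class EEGSegment:
    """One fixed-length window cut from a recording."""

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    label: str | None = None
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.samples).all():
            raise ValueError("segment contains non-finite samples")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def window_len(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channel_names.index(name)]


class SegmentSet:
    """Ordered collection of equally shaped segments with aligned labels."""

    def __init__(self, segments: Sequence[EEGSegment]):
        segments = list(segments)
        if segments:
            first = segments[0]
            for seg in segments[1:]:
                if seg.fs != first.fs:
                    raise ValueError("segments mix sampling rates")
                if seg.window_len != first.window_len:
                    raise ValueError("segments mix window lengths")
                if seg.channel_names != first.channel_names:
                    raise ValueError("segments mix channel orders")
        self.segments = segments

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[EEGSegment]:
        return iter(self.segments)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return SegmentSet(self.segments[idx])
        return self.segments[idx]

    @property
    def labels(self) -> list[str | None]:
        return [seg.label for seg in self.segments]

    @property
    def fs(self) -> float:
        return self.segments[0].fs

    @property
    def window_len(self) -> int:
        return self.segments[0].window_len

    @property
    def channel_names(self) -> list[str]:
        return self.segments[0].channel_names

    def drop_artifacts(self) -> "SegmentSet":
        return SegmentSet([s for s in self.segments if not s.artifact_flag])

    # -- archive dialect: compressed arrays + JSON manifest -----------------

    def save(self, path: str | Path) -> None:
        """Serialize as an .npz archive with an embedded JSON manifest."""
        if not self.segments:
            raise ValueError("cannot save an empty SegmentSet")
        manifest = {
            "fs": self.fs,
            "channel_names": self.channel_names,
            "labels": self.labels,
            "artifact_flags": [s.artifact_flag for s in self.segments],
        }
        data = np.stack([s.samples for s in self.segments])
        np.savez_compressed(
            path, samples=data, manifest=np.frombuffer(
                json.dumps(manifest).encode(), dtype=np.uint8
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        with np.load(path) as npz:
            manifest = json.loads(bytes(npz["manifest"].tobytes()).decode())
            data = npz["samples"]
        segs = [
            EEGSegment(
                samples=data[i],
                fs=manifest["fs"],
                channel_names=list(manifest["channel_names"]),
                label=manifest["labels"][i],
                artifact_flag=bool(manifest["artifact_flags"][i]),
            )
            for i in range(data.shape[0])
        ]
        return cls(segs)


# ---------------------------------------------------------------------------
# reading / writing


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt"):
        return "matrix"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording from ``edf`` or the plain ``matrix`` dialect.

    Channel order is preserved from the file.  Microvolt units are assumed
    for the matrix dialect; EDF physical units are converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "matrix":
        return _read_matrix(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'matrix'")


def write_recording(rec: EEGRecording, path: str | Path,
                    format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "matrix":
        _write_matrix(rec, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'matrix'")
    return path


def _read_matrix(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"matrix sidecar header not found: {sidecar}")
    header = json.loads(sidecar.read_text())
    for key in ("fs", "channel_names"):
        if key not in header:
            raise ValueError(f"sidecar header missing field {key!r}")
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(np.array([float(v) for v in line.split(",")]))
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        shortest = min(range(len(rows)), key=lambda i: len(rows[i]))
        name = header["channel_names"][shortest] if shortest < len(
            header["channel_names"]) else f"row {shortest}"
        raise ValueError(
            f"inconsistent channel lengths {sorted(lengths)}; "
            f"shortest channel is {name}"
        )
    return EEGRecording(
        signal=np.vstack(rows),
        fs=float(header["fs"]),
        channel_names=list(header["channel_names"]),
        region_map=dict(header.get("region_map", DEFAULT_REGION_MAP)),
    )


def _write_matrix(rec: EEGRecording, path: Path) -> None:
    with open(path, "w") as fh:
        for row in rec.signal:
            fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")
    header = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "region_map": rec.region_map,
    }
    _sidecar_path(path).write_text(json.dumps(header, indent=1))


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if not raw.info["sfreq"] or raw.info["sfreq"] <= 0:
        raise ValueError("EDF file has no valid sampling rate")
    # mne reports EEG in volts; the package convention is microvolts.
    data = raw.get_data() * 1e6
    names = list(raw.ch_names)
    region_map = {ch: DEFAULT_REGION_MAP[ch] for ch in names
                  if ch in DEFAULT_REGION_MAP}
    unmapped = [ch for ch in names
                if ch != ECG_CHANNEL and ch not in DEFAULT_REGION_MAP]
    for ch in unmapped:
        region_map[ch] = "unknown"
    return EEGRecording(signal=data, fs=float(raw.info["sfreq"]),
                        channel_names=names, region_map=region_map)


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit samples, uV units.

    The trailing partial record (< 1 s) is dropped, matching EDF's
    whole-record layout.
    """
    n_ch = rec.n_channels
    spr = int(round(rec.fs))
    if spr != rec.fs:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    sig = rec.signal[:, : n_rec * spr]
    pmin = np.floor(sig.min(axis=1))
    pmax = np.ceil(sig.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    def fixed(value, width: int) -> bytes:
        raw = str(value).encode("ascii")[:width]
        return raw + b" " * (width - len(raw))

    hdr = io.BytesIO()
    hdr.write(fixed("0", 8))                     # version
    hdr.write(fixed("X X X X", 80))              # patient id (anonymous)
    hdr.write(fixed("Startdate X X X X", 80))    # recording id
    hdr.write(fixed("01.01.00", 8))              # start date
    hdr.write(fixed("00.00.00", 8))              # start time
    hdr.write(fixed(256 * (1 + n_ch), 8))        # header bytes
    hdr.write(fixed("", 44))                     # reserved
    hdr.write(fixed(n_rec, 8))
    hdr.write(fixed(1, 8))                       # record duration (s)
    hdr.write(fixed(n_ch, 4))
    for name in rec.channel_names:
        hdr.write(fixed(name, 16))
    for _ in range(n_ch):
        hdr.write(fixed("EEG", 80))
    for _ in range(n_ch):
        hdr.write(fixed("uV", 8))
    for v in pmin:
        hdr.write(fixed("%g" % v, 8))
    for v in pmax:
        hdr.write(fixed("%g" % v, 8))
    for _ in range(n_ch):
        hdr.write(fixed(dmin, 8))
    for _ in range(n_ch):
        hdr.write(fixed(dmax, 8))
    for _ in range(n_ch):
        hdr.write(fixed("", 80))
    for _ in range(n_ch):
        hdr.write(fixed(spr, 8))
    for _ in range(n_ch):
        hdr.write(fixed("", 32))

    gain = (pmax - pmin) / (dmax - dmin)
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            chunk = sig[:, r * spr : (r + 1) * spr]
            dig = np.rint((chunk - pmin[:, None]) / gain[:, None] + dmin)
            fh.write(dig.astype("<i2").tobytes())


# ---------------------------------------------------------------------------
# preprocessing


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering and artifact-marking settings.

    highpass_hz : zero-phase Butterworth high-pass cutoff removing baseline
        drift (0 disables).
    notch_hz : optional mains notch frequency (None disables).
    artifact_threshold_uv : samples with |x| above this are marked so
        segmentation can flag the containing window.
    order : Butterworth order of the high-pass.
    """

    highpass_hz: float = 0.5
    notch_hz: float | None = None
    artifact_threshold_uv: float = 100.0
    order: int = 4
    notch_q: float = 30.0


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """High-pass (and optionally notch) filter a recording, zero-phase.

    Output length equals input length.  Amplitude exceedances of the
    filtered signal are stored in ``artifact_mask``.
    """
    cfg = cfg or PreprocessConfig()
    nyquist = rec.fs / 2.0
    if cfg.highpass_hz >= nyquist:
        raise ValueError(
            f"high-pass cutoff {cfg.highpass_hz} Hz >= Nyquist {nyquist} Hz"
        )
    if cfg.notch_hz is not None and cfg.notch_hz >= nyquist:
        raise ValueError(f"notch {cfg.notch_hz} Hz >= Nyquist {nyquist} Hz")

    out = rec.signal
    if cfg.highpass_hz > 0:
        sos = sps.butter(cfg.order, cfg.highpass_hz, btype="highpass",
                         fs=rec.fs, output="sos")
        out = sps.sosfiltfilt(sos, out, axis=1)
    if cfg.notch_hz is not None:
        b, a = sps.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    mask = np.any(np.abs(out) > cfg.artifact_threshold_uv, axis=0)
    return replace(rec, signal=out, artifact_mask=mask)


# ---------------------------------------------------------------------------
# segmentation


def segment(rec: EEGRecording, window_samples: int,
            label: str | None = None) -> SegmentSet:
    """Cut a recording into consecutive non-overlapping windows.

    The trailing remainder shorter than one window is dropped, so the
    segment count is ``floor(n_samples / window_samples)``.  Windows
    containing artifact-marked samples are kept but flagged.
    """
    if window_samples <= 0:
        raise ValueError(f"window_samples must be positive, got {window_samples}")
    if window_samples > rec.n_samples:
        return SegmentSet([])
    n_windows = rec.n_samples // window_samples
    segs = []
    for w in range(n_windows):
        sl = slice(w * window_samples, (w + 1) * window_samples)
        flag = bool(rec.artifact_mask[sl].any()) if rec.artifact_mask is not None else False
        segs.append(
            EEGSegment(
                samples=rec.signal[:, sl],
                fs=rec.fs,
                channel_names=list(rec.channel_names),
                label=label,
                artifact_flag=flag,
            )
        )
    return SegmentSet(segs)
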