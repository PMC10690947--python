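"""Synthetic two-class EEG emulating antidepressant treatment-response data.

Each simulated window mixes, per channel:

* a 1/f-shaped Gaussian background (power spectral density ~ f^-exponent),
* four narrowband rhythm oscillations (delta, theta, alpha, beta), built
  as unit-RMS band-limited Gaussian noise scaled to a per-band microvolt
  amplitude.  Channels within the same cortical region share a latent
  oscillation per band, mixed with channel-private noise through a
  ``region_coupling`` weight — this induces the within-region Pearson
  correlation block structure the adjacency construction relies on.

Class structure:

* ``resistant`` windows multiply every band amplitude by
  ``resistant_gain`` (> 1): globally elevated spectral power.
* ``responsive`` windows insert transient alpha-suppression events
  (amplitude scaled by ``1 - depth`` for ``duration`` seconds) on a fixed
  subset of channels (default F3, C4, Fz, P3, P4); the event count per
  window is Poisson with mean ``alpha_event_rate``.

Everything is deterministic given the seed; dataset generation derives a
child seed per segment from ``(master_seed, index)`` so results do not
depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import EEGRecording, EEGSegment, RESISTANT, RESPONSIVE, SegmentSet
from .montage import DEFAULT_REGION_MAP, SCALP_CHANNELS


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; amplitudes in microvolts (RMS per component)."""

    channels: tuple[str, ...] = SCALP_CHANNELS
    fs: float = 256.0
    window: int = 1024
    band_amplitudes: dict = field(
        default_factory=lambda: {"delta": 20.0, "theta": 10.0,
                                 "alpha": 15.0, "beta": 5.0}
    )
    resistant_gain: float = 1.6
    alpha_event_rate: float = 1.0
    alpha_event_depth: float = 0.5
    alpha_event_duration: float = 0.5
    alpha_event_channels: tuple[str, ...] = ("F3", "C4", "Fz", "P3", "P4")
    noise_exponent: float = 1.0
    noise_amplitude: float = 5.0
    region_coupling: float = 0.5
    region_map: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MAP))
    include_ecg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resistant_gain < 1:
            raise ValueError("resistant_gain must be >= 1 (1 = null, no elevation)")
        if not 0 < self.alpha_event_depth < 1:
            raise ValueError("alpha_event_depth must lie in (0, 1)")
        if self.alpha_event_rate < 0 or self.alpha_event_duration <= 0:
            raise ValueError("event rate must be >= 0 and duration positive")
        if not 0 <= self.region_coupling <= 1:
            raise ValueError("region_coupling must lie in [0, 1]")
        unmapped = [ch for ch in self.channels if ch not in self.region_map]
        if unmapped:
            raise ValueError(f"channels missing from region map: {unmapped}")


#: band edges used by the generator (Hz)
_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_segment(label: str, cfg: SimConfig | None = None,
                     seed: int | np.random.SeedSequence | tuple = 0) -> EEGSegment:
    """Generate one labeled window; deterministic in (label, cfg, seed)."""
    cfg = cfg or SimConfig()
    if label not in (RESPONSIVE, RESISTANT):
        raise ValueError(f"label must be responsive or resistant, got {label!r}")
    rng = np.random.default_rng(seed)
    n = cfg.window
    channels = list(cfg.channels)
    regions = [cfg.region_map[ch] for ch in channels]
    gain = cfg.resistant_gain if label == RESISTANT else 1.0
    rho = cfg.region_coupling
    mix_latent = rho
    mix_private = np.sqrt(max(0.0, 1.0 - rho**2))

    # shared latent oscillation per (region, band); drawn first so a fixed
    # seed pins the whole latent structure regardless of channel subsets
    latents = {
        (region, band): _bandlimited_noise(rng, n, cfg.fs, *_BAND_EDGES[band])
        for region in dict.fromkeys(regions)
        for band in _BAND_EDGES
    }

    # alpha-suppression envelope for the responsive class
    alpha_env = np.ones(n)
    if label == RESPONSIVE and cfg.alpha_event_rate > 0:
        n_events = rng.poisson(cfg.alpha_event_rate)
        span = min(n, int(round(cfg.alpha_event_duration * cfg.fs)))
        for _ in range(n_events):
            start = int(rng.integers(0, max(1, n - span + 1)))
            alpha_env[start : start + span] = np.minimum(
                alpha_env[start : start + span], 1.0 - cfg.alpha_event_depth
            )

    data = np.empty((len(channels), n))
    for c, (ch, region) in enumerate(zip(channels, regions)):
        x = cfg.noise_amplitude * _pink_noise(rng, n, cfg.fs, cfg.noise_exponent)
        for band, (lo, hi) in _BAND_EDGES.items():
            private = _bandlimited_noise(rng, n, cfg.fs, lo, hi)
            osc = mix_latent * latents[(region, band)] + mix_private * private
            amp = cfg.band_amplitudes[band] * gain
            if band == "alpha" and ch in cfg.alpha_event_channels:
                osc = osc * alpha_env
            x = x + amp * osc
        data[c] = x
    names = channels
    if cfg.include_ecg:
        # crude ECG proxy: periodic sharp pulses at ~70 bpm plus noise
        t = np.arange(n) / cfg.fs
        beat = 70.0 / 60.0
        ecg = 400.0 * np.exp(-((t * beat) % 1.0 - 0.5) ** 2 / 0.002)
        ecg += 10.0 * rng.standard_normal(n)
        data = np.vstack([data, ecg])
        names = channels + ["ECG"]
    return EEGSegment(samples=data, fs=cfg.fs, channel_names=list(names),
                      label=label)


@dataclass
class LabeledDataset:
    """Segments with aligned labels and the generating configuration."""

    segments: SegmentSet
    config: SimConfig
    seed: int

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def __len__(self) -> int:
        return len(self.segments)


def simulate_dataset(n_responsive: int, n_resistant: int,
                     cfg: SimConfig | None = None, seed: int = 0
                     ) -> LabeledDataset:
    """Independent labeled segments; child seed = (master seed, index)."""
    cfg = cfg or SimConfig()
    if n_responsive < 0 or n_resistant < 0:
        raise ValueError("segment counts must be non-negative")
    labels = [RESPONSIVE] * n_responsive + [RESISTANT] * n_resistant
    segs = [
        simulate_segment(lbl, cfg, seed=(seed, i))
        for i, lbl in enumerate(labels)
    ]
    return LabeledDataset(segments=SegmentSet(segs), config=cfg, seed=seed)


def dataset_to_recording(ds: LabeledDataset) -> EEGRecording:
    """Concatenate a dataset's segments into one continuous recording.

    Useful for exercising the preprocessing/segmentation path end to end;
    the label sequence must be tracked separately (segment order is kept).
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    sig = np.concatenate([s.samples for s in ds.segments], axis=1)
    return EEGRecording(signal=sig, fs=ds.segments.fs,
                        channel_names=list(ds.segments.channel_names),
                        region_map=dict(ds.config.region_map))
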