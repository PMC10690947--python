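"""Spectra, band power, and the non-learnable frequency-attention vector.

The attention mechanism weights each EEG channel by its mean spectral
power: each channel's discrete Fourier transform gives a total power
``E = (1/n) * sum_k |X_k|^2`` (by Parseval's theorem this equals the sum of
squared samples), the mean power per sample is ``E_bar = E / n``, and the
per-channel ``E_bar`` values are max-min normalized into ``[0.1, 1]`` to
form the attention vector.  The weights are applied as a Hadamard product
to the node features (rows of X) and/or symmetrically to the adjacency.

Band powers use the canonical EEG rhythm bands: delta 0.5-4 Hz, theta
4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz.  Band powers over a disjoint cover
of [0, fs/2] sum to the total power E.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import EEGSegment

#: lower bound of the attention weights after max-min normalization
ATTENTION_FLOOR = 0.1


@dataclass(frozen=True)
class Spectrum:
    """Discrete Fourier coefficients of a single channel."""

    coefficients: np.ndarray  # complex, length n
    fs: float
    n: int

    @property
    def frequencies(self) -> np.ndarray:
        """Signed bin frequencies in Hz (positive then negative half)."""
        return np.fft.fftfreq(self.n, d=1.0 / self.fs)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.coefficients)


@dataclass(frozen=True)
class ChannelPower:
    """Total spectral power E and mean power E_bar of one channel."""

    E: float
    E_bar: float
    channel: int = 0


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


def spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """n-point DFT of a single-channel sample sequence."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite samples")
    return Spectrum(coefficients=np.fft.fft(x), fs=fs, n=x.size)


def mean_power(x: np.ndarray, channel: int = 0) -> ChannelPower:
    """Total power E and mean power E_bar from spectral magnitudes.

    The continuous power integral is discretized as
    ``E = (1/n) * sum_k |X_k|^2``, which by Parseval equals
    ``sum_n x_n^2``; ``E_bar = E / n`` is the mean power per sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    coeffs = np.fft.fft(x)
    n = x.size
    E = float(np.sum(np.abs(coeffs) ** 2) / n)
    return ChannelPower(E=E, E_bar=E / n, channel=channel)


def band_power(x: np.ndarray, fs: float, band: BandDefinition) -> float:
    """Spectral power of ``x`` within ``[band.lo, band.hi)``.

    Counts bins from both spectral halves (|f| in the band) with the same
    1/n scaling as :func:`mean_power`, so band powers over a disjoint
    cover of [0, fs/2] sum to the total power E.  A band whose upper edge
    reaches Nyquist includes the Nyquist bin.
    """
    x = np.asarray(x, dtype=float)
    nyquist = fs / 2.0
    if band.hi > nyquist + 1e-12:
        raise ValueError(
            f"band {band.name} [{band.lo}, {band.hi}) exceeds Nyquist {nyquist} Hz"
        )
    coeffs = np.fft.fft(x)
    n = x.size
    af = np.abs(np.fft.fftfreq(n, d=1.0 / fs))
    if band.hi >= nyquist - 1e-12:
        mask = (af >= band.lo) & (af <= band.hi + 1e-12)
    else:
        mask = (af >= band.lo) & (af < band.hi)
    return float(np.sum(np.abs(coeffs[mask]) ** 2) / n)


def band_power_table(seg: EEGSegment,
                     bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> pd.DataFrame:
    """Per-channel band powers as a channels x bands table."""
    rows = {
        ch: [band_power(seg.channel(ch), seg.fs, b) for b in bands]
        for ch in seg.channel_names
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[b.name for b in bands]
    )


@dataclass(frozen=True)
class AttentionVector:
    """Per-channel attention weights, channel-ordered."""

    values: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size != len(self.channels):
            raise ValueError("one weight per channel required")

    def __len__(self) -> int:
        return self.values.size


def attention_vector(seg: EEGSegment,
                     channels: Sequence[str] | None = None) -> AttentionVector:
    """Mean-power channel attention, max-min normalized into [0.1, 1].

    ``a_i' = 0.1 + 0.9 * (E_bar_i - min) / (max - min)``.  If every channel
    has identical mean power the rescaling is undefined; all weights are
    then set to 1 (no differential attenuation).
    """
    channels = list(channels) if channels is not None else list(seg.channel_names)
    if not channels:
        raise ValueError("empty channel list")
    powers = np.array([mean_power(seg.channel(ch)).E_bar for ch in channels])
    lo, hi = powers.min(), powers.max()
    if hi - lo <= 0:
        values = np.ones_like(powers)
    else:
        values = ATTENTION_FLOOR + (1 - ATTENTION_FLOOR) * (powers - lo) / (hi - lo)
    return AttentionVector(values=values, channels=tuple(channels))


def apply_attention(X: np.ndarray, a: AttentionVector | np.ndarray,
                    target: str = "features") -> np.ndarray:
    """Apply attention weights to a matrix as a Hadamard product.

    target='features': row i of X is multiplied by a_i.
    target='adjacency': entry (i, j) is multiplied by a_i * a_j, the
    symmetric scaling that preserves adjacency symmetry.
    """
    weights = a.values if isinstance(a, AttentionVector) else np.asarray(a, float)
    X = np.asarray(X, dtype=float)
    if target == "features":
        if weights.size != X.shape[0]:
            raise ValueError(
                f"{weights.size} weights for {X.shape[0]} feature rows"
            )
        return X * weights[:, None]
    if target == "adjacency":
        if X.shape[0] != X.shape[1] or weights.size != X.shape[0]:
            raise ValueError("adjacency target needs a square matrix of matching order")
        return X * np.outer(weights, weights)
    raise ValueError(f"unknown target {target!r}; expected 'features' or 'adjacency'")
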