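"""Per-segment graph construction.

Each EEG window becomes one graph sample: nodes are scalp electrodes, the
adjacency blends two sources of coupling,

    A_ij = R_ij + lam * H_ij

where R is the Pearson correlation of the channel time series and H is a
block-constant brain-region similarity (every channel pair from the same
pair of regions shares the same entry).  The blended adjacency is given
self-loops and symmetrically degree-normalized, A_hat = D~^{-1/2} (A + I)
D~^{-1/2}, the propagation operator of the graph-convolution layers.

The region-similarity measure is pluggable.  The default assigns each
region the average of its channels' signals and sets the similarity of two
regions to the absolute Pearson correlation of their averages; a region's
self-similarity is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_io import EEGSegment
from .montage import SCALP_CHANNELS
from .spectral import AttentionVector, DEFAULT_BANDS, apply_attention, attention_vector, band_power

RegionSimilarityFn = Callable[[Mapping[str, np.ndarray]], "RegionSimilarity"]


@dataclass(frozen=True)
class RegionSimilarity:
    """Pairwise similarity over region labels, entries in [0, 1]."""

    regions: tuple[str, ...]
    matrix: np.ndarray

    def value(self, r1: str, r2: str) -> float:
        return float(self.matrix[self.regions.index(r1), self.regions.index(r2)])


@dataclass(frozen=True)
class AdjacencyComponents:
    """The two adjacency halves and their blend A = R + lam * H."""

    R: np.ndarray
    H: np.ndarray
    lam: float
    A: np.ndarray


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Self-looped, symmetrically degree-normalized adjacency."""

    A_tilde: np.ndarray
    D_tilde: np.ndarray  # diagonal (degree) vector of A_tilde
    A_hat: np.ndarray


@dataclass
class GraphSample:
    """Node features, normalized adjacency, attention and label for one window."""

    X: np.ndarray
    adjacency: NormalizedAdjacency
    attention: AttentionVector
    label: str | None = None

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.adjacency.A_hat.shape[0]:
            raise ValueError("node count of X and adjacency disagree")
        if not np.isfinite(self.X).all():
            raise ValueError("node features contain non-finite values")


@dataclass(frozen=True)
class GraphConfig:
    """Settings for per-segment graph assembly.

    lam : blending constant of the region-similarity half (> 0).
    negative_policy : how negative adjacency entries are handled before
        normalization — 'abs' (default), 'clip' to zero, or 'keep'.
    feature_mode : 'bandpower' (default; X = the four rhythm-band powers
        per channel, as mean power per sample in feature_scale_uv^2 units)
        or 'raw' (X = window samples / feature_scale_uv).
    attention_target : 'features', 'adjacency', or 'both'; 'none' disables
        the attention module (the plain-GCN ablation).
    feature_scale_uv : reference microvolt amplitude scaling the node
        features to O(1); None picks a mode-appropriate default
        (10 uV for bandpower, 50 uV for raw).
    """

    lam: float = 0.5
    negative_policy: str = "abs"
    feature_mode: str = "bandpower"
    attention_target: str = "features"
    channels: tuple[str, ...] = SCALP_CHANNELS
    feature_scale_uv: float | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.negative_policy not in ("abs", "clip", "keep"):
            raise ValueError(f"unknown negative_policy {self.negative_policy!r}")
        if self.feature_mode not in ("raw", "bandpower"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.attention_target not in ("features", "adjacency", "both", "none"):
            raise ValueError(f"unknown attention_target {self.attention_target!r}")
        if self.feature_scale_uv is not None and self.feature_scale_uv <= 0:
            raise ValueError("feature_scale_uv must be positive")

    @property
    def effective_feature_scale(self) -> float:
        if self.feature_scale_uv is not None:
            return self.feature_scale_uv
        return 10.0 if self.feature_mode == "bandpower" else 50.0


def pearson_matrix(seg: EEGSegment | np.ndarray,
                   channels: Sequence[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix R of the channel time series."""
    if isinstance(seg, EEGSegment):
        channels = list(channels) if channels is not None else list(seg.channel_names)
        data = np.stack([seg.channel(ch) for ch in channels])
        names = channels
    else:
        data = np.asarray(seg, dtype=float)
        names = [str(i) for i in range(data.shape[0])]
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples per channel")
    variances = data.var(axis=1)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance channel(s): {[names[i] for i in dead]}"
        )
    R = np.corrcoef(data)
    np.fill_diagonal(R, 1.0)
    return R


def region_average_correlation(
        region_signals: Mapping[str, np.ndarray]) -> RegionSimilarity:
    """Default region similarity: |Pearson r| of region-average signals.

    Self-similarity is 1.  Degenerate (zero-variance) region averages get
    similarity 0 to any other region.
    """
    regions = tuple(region_signals.keys())
    k = len(regions)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = region_signals[regions[i]], region_signals[regions[j]]
            if a.std() == 0 or b.std() == 0:
                r = 0.0
            else:
                r = abs(float(np.corrcoef(a, b)[0, 1]))
            mat[i, j] = mat[j, i] = r
    return RegionSimilarity(regions=regions, matrix=mat)


def region_similarity(seg: EEGSegment, region_map: Mapping[str, str],
                      channels: Sequence[str] | None = None,
                      method: RegionSimilarityFn = region_average_correlation,
                      ) -> np.ndarray:
    """Channel-level similarity matrix H, block-constant over region pairs.

    ``method`` maps {region: average signal} to a :class:`RegionSimilarity`;
    H_ij is the similarity of the regions of channels i and j, so entries
    depend only on the region pair and lie in [0, 1].
    """
    channels = list(channels) if channels is not None else list(seg.channel_names)
    unmapped = [ch for ch in channels if ch not in region_map]
    if unmapped:
        raise ValueError(f"channels missing from region map: {unmapped}")
    regions_of = [region_map[ch] for ch in channels]
    region_signals: dict[str, np.ndarray] = {}
    for region in dict.fromkeys(regions_of):  # preserve first-seen order
        members = [ch for ch, r in zip(channels, regions_of) if r == region]
        region_signals[region] = np.mean(
            [seg.channel(ch) for ch in members], axis=0
        )
    sim = method(region_signals)
    if np.any(sim.matrix < -1e-12) or np.any(sim.matrix > 1 + 1e-12):
        raise ValueError("region similarity method produced values outside [0, 1]")
    n = len(channels)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            H[i, j] = sim.value(regions_of[i], regions_of[j])
    return H


def build_adjacency(R: np.ndarray, H: np.ndarray,
                    lam: float = 0.5) -> AdjacencyComponents:
    """Blend correlation and region similarity: A = R + lam * H."""
    R = np.asarray(R, dtype=float)
    H = np.asarray(H, dtype=float)
    if lam <= 0:
        raise ValueError(f"calibration constant lam must be > 0, got {lam}")
    if R.shape != H.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs H {H.shape}")
    return AdjacencyComponents(R=R, H=H, lam=lam, A=R + lam * H)


def normalize_adjacency(comp: AdjacencyComponents | np.ndarray,
                        negative_policy: str = "abs") -> NormalizedAdjacency:
    """Self-loops plus symmetric degree normalization of the adjacency.

    A_tilde = A + I, D_tilde_ii = sum_j A_tilde_ij,
    A_hat = D~^{-1/2} A_tilde D~^{-1/2}.

    Negative entries would make the degree roots undefined, so a policy is
    applied first: 'abs' |A|, 'clip' max(A, 0), or 'keep' unchanged.
    """
    A = comp.A if isinstance(comp, AdjacencyComponents) else np.asarray(comp, float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if negative_policy == "abs":
        A = np.abs(A)
    elif negative_policy == "clip":
        A = np.clip(A, 0.0, None)
    elif negative_policy != "keep":
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    A_tilde = A + np.eye(A.shape[0])
    degrees = A_tilde.sum(axis=1)
    bad = np.flatnonzero(degrees <= 0)
    if bad.size:
        raise ValueError(f"non-positive degree at node(s) {bad.tolist()}")
    inv_sqrt = 1.0 / np.sqrt(degrees)
    A_hat = A_tilde * np.outer(inv_sqrt, inv_sqrt)
    A_hat = (A_hat + A_hat.T) / 2.0  # enforce exact symmetry
    return NormalizedAdjacency(A_tilde=A_tilde, D_tilde=degrees, A_hat=A_hat)


def node_features(seg: EEGSegment, cfg: GraphConfig) -> np.ndarray:
    """Node-feature matrix X per the configured feature mode."""
    data = np.stack([seg.channel(ch) for ch in cfg.channels])
    scale = cfg.effective_feature_scale
    if cfg.feature_mode == "raw":
        return data / scale
    # bandpower: four rhythm-band powers per channel, reported as mean
    # power per sample in units of scale^2 so typical entries are O(1)
    powers = np.array([
        [band_power(row, seg.fs, b) for b in DEFAULT_BANDS] for row in data
    ])
    return powers / (data.shape[1] * scale**2)


def build_graph_sample(seg: EEGSegment, cfg: GraphConfig | None = None,
                       region_map: Mapping[str, str] | None = None,
                       method: RegionSimilarityFn = region_average_correlation,
                       ) -> GraphSample:
    """Assemble one graph sample from a preprocessed segment.

    Computes R, H, A = R + lam*H, the normalized propagation operator, the
    frequency-attention vector, and applies attention to the configured
    target (features, adjacency, both, or none for the ablation).
    """
    from .montage import DEFAULT_REGION_MAP

    cfg = cfg or GraphConfig()
    region_map = region_map or DEFAULT_REGION_MAP
    missing = [ch for ch in cfg.channels if ch not in seg.channel_names]
    if missing:
        raise ValueError(f"segment lacks configured channels: {missing}")

    R = pearson_matrix(seg, cfg.channels)
    H = region_similarity(seg, region_map, cfg.channels, method)
    comp = build_adjacency(R, H, cfg.lam)
    att = attention_vector(seg, cfg.channels)
    A = comp.A
    if cfg.attention_target in ("adjacency", "both"):
        A = apply_attention(A, att, target="adjacency")
    norm = normalize_adjacency(
        AdjacencyComponents(R=comp.R, H=comp.H, lam=comp.lam, A=A),
        cfg.negative_policy,
    )
    X = node_features(seg, cfg)
    if cfg.attention_target in ("features", "both"):
        X = apply_attention(X, att, target="features")
    return GraphSample(X=X, adjacency=norm, attention=att, label=seg.label)
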