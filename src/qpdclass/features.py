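"""Segment → FFT magnitude → per-channel PCA feature extraction.

Each 120 s acquisition is cut into non-overlapping 500 ms segments; every
segment channel is mapped to the magnitude of its one-sided discrete
Fourier transform with the DC bin removed (the static offset carries no
dynamical information), and an independent 2-component PCA per channel
reduces each spectrum to two scores.  For the default settings the chain is

    (3 channels x 5000 samples) -> (3 x 2500 magnitudes) -> 6 features.

No window is applied before the FFT and no detrending beyond the DC-bin
removal is done.  PCA signs are fixed by requiring the largest-magnitude
loading of each component to be positive, so stored models and features are
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .trap_sim import InvalidParameterError, QPDTrace

__all__ = [
    "Segment",
    "SpectrumSet",
    "ChannelPCA",
    "PCAModel",
    "FeatureVector",
    "segment_trace",
    "spectral_transform",
    "fit_channel_pca",
    "project_features",
    "features_to_frame",
    "SUM_CHANNEL_INDEX",
]

SUM_CHANNEL_INDEX = 2
ChannelMode = Literal["all", "sum_only"]


@dataclass(frozen=True)
class Segment:
    """A fixed-duration slice of a trace (3 channels), with provenance."""

    channels: np.ndarray  # (3, n)
    parent_signal_id: int
    label: str
    index: int

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 2 or ch.shape[0] != 3:
            raise InvalidParameterError("segment channels must have shape (3, n)")
        object.__setattr__(self, "channels", ch)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]


@dataclass(frozen=True)
class SpectrumSet:
    """One-sided FFT magnitudes per channel, DC bin removed; (3, n//2)."""

    magnitudes: np.ndarray
    parent_signal_id: int
    label: str
    index: int

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.ndim != 2 or m.shape[0] != 3:
            raise InvalidParameterError("magnitudes must have shape (3, nbins)")
        object.__setattr__(self, "magnitudes", m)

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


@dataclass(frozen=True)
class ChannelPCA:
    """PCA of one channel: mean spectrum, orthonormal components (rows),
    explained-variance fractions, and absolute explained variances."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_bins)
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray


@dataclass(frozen=True)
class PCAModel:
    """Independent PCA per channel, fitted on training spectra only."""

    channels: tuple[ChannelPCA, ChannelPCA, ChannelPCA]
    fitted_on: int

    @property
    def n_bins(self) -> int:
        return self.channels[0].mean.size

    @property
    def n_components(self) -> int:
        return self.channels[0].components.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """The reduced representation of one segment: 2 scores per used channel
    (6 values in 3-channel mode, 2 in SUM-only mode)."""

    values: np.ndarray
    label: str
    parent_signal_id: int
    index: int


def segment_trace(trace: QPDTrace, segment_duration: float = 0.5) -> list[Segment]:
    """Cut a trace into consecutive non-overlapping segments.

    The trailing partial segment is discarded; each segment inherits the
    trace's label and signal id.
    """
    n_seg = round(segment_duration * trace.sampling_rate)
    if n_seg < 2:
        raise InvalidParameterError("segment must contain at least 2 samples")
    if n_seg > trace.n_samples:
        raise InvalidParameterError(
            f"segment of {n_seg} samples longer than trace of {trace.n_samples}"
        )
    n_full = trace.n_samples // n_seg
    return [
        Segment(
            channels=trace.channels[:, i * n_seg : (i + 1) * n_seg],
            parent_signal_id=trace.signal_id,
            label=trace.label,
            index=i,
        )
        for i in range(n_full)
    ]


def spectral_transform(segment: Segment) -> SpectrumSet:
    """Magnitude of the one-sided DFT of each channel, DC bin dropped.

    For an even segment length N the output has N/2 bins per channel
    (Nyquist retained).  No window, no detrending: removing bin 0 already
    makes the representation invariant to constant channel offsets.
    """
    mags = np.abs(np.fft.rfft(segment.channels, axis=1))[:, 1:]
    return SpectrumSet(
        magnitudes=mags,
        parent_signal_id=segment.parent_signal_id,
        label=segment.label,
        index=segment.index,
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    out = components.copy()
    for i, comp in enumerate(out):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            out[i] = -comp
    return out


def fit_channel_pca(
    training_spectra: Sequence[SpectrumSet], n_components: int = 2
) -> PCAModel:
    """Fit an independent PCA per channel on mean-centred spectra.

    Components are ordered by explained variance (non-increasing) and
    sign-fixed deterministically.  Centring is mean subtraction only — no
    variance scaling.
    """
    n = len(training_spectra)
    if n < n_components + 1:
        raise InvalidParameterError(
            f"need at least {n_components + 1} training spectra, got {n}"
        )
    stacks = np.stack([s.magnitudes for s in training_spectra])  # (n, 3, bins)
    channels = []
    for c in range(3):
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(stacks[:, c, :])
        channels.append(
            ChannelPCA(
                mean=pca.mean_.copy(),
                components=_fix_signs(pca.components_),
                explained_variance_ratio=pca.explained_variance_ratio_.copy(),
                explained_variance=pca.explained_variance_.copy(),
            )
        )
    return PCAModel(channels=tuple(channels), fitted_on=n)


def _used_channels(channel_mode: ChannelMode) -> tuple[int, ...]:
    if channel_mode == "all":
        return (0, 1, 2)
    if channel_mode == "sum_only":
        return (SUM_CHANNEL_INDEX,)
    raise InvalidParameterError(f"unknown channel mode {channel_mode!r}")


def project_features(
    spectrum: SpectrumSet, model: PCAModel, channel_mode: ChannelMode = "all"
) -> FeatureVector:
    """Project one spectrum set onto the fitted components.

    Per used channel, the two scores are the inner products of the centred
    spectrum with the component directions; ordering is (X1, X2, Y1, Y2,
    SUM1, SUM2) in 3-channel mode and (SUM1, SUM2) in SUM-only mode.
    """
    if spectrum.n_bins != model.n_bins:
        raise InvalidParameterError(
            f"spectrum has {spectrum.n_bins} bins but model expects {model.n_bins}"
        )
    values = []
    for c in _used_channels(channel_mode):
        ch = model.channels[c]
        centred = spectrum.magnitudes[c] - ch.mean
        values.extend(ch.components @ centred)
    return FeatureVector(
        values=np.asarray(values),
        label=spectrum.label,
        parent_signal_id=spectrum.parent_signal_id,
        index=spectrum.index,
    )


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors: signal_id, segment_index, label, f1..fk."""
    rows = []
    for fv in features:
        row = {
            "signal_id": fv.parent_signal_id,
            "segment_index": fv.index,
            "label": fv.label,
        }
        row.update({f"f{i + 1}": v for i, v in enumerate(fv.values)})
        rows.append(row)
    return pd.DataFrame(rows)
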