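"""Filtering chain: IIR mains notch followed by a 10–450 Hz Butterworth
band-pass, applied identically to whole recordings and to streamed chunks.

The chain is causal by default because the online stage demands
causality and offline training must see the same signal the decoder
will; a zero-phase (forward-backward) mode is available for offline
exploration.  Filters are realised as second-order sections for
numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import N_CHANNELS, Recording

__all__ = [
    "FilterSpec",
    "notch_filter",
    "bandpass_filter",
    "preprocess",
    "StreamingPreprocessor",
]


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of the notch + band-pass chain.

    ``order`` is the Butterworth design order per band edge (the default
    2 gives the conventional "second-order band-pass").  ``notch_quality``
    is the notch Q factor (centre frequency / −3 dB width).
    """

    mains_hz: float = 50.0
    notch_quality: float = 30.0
    band_low_hz: float = 10.0
    band_high_hz: float = 450.0
    order: int = 2
    causal: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.band_high_hz >= nyq:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} must be below the "
                f"Nyquist frequency {nyq}"
            )
        if self.mains_hz >= nyq:
            raise ValueError("mains frequency must be below Nyquist")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def notch_sos(self, sampling_rate_hz: float) -> np.ndarray:
        b, a = sps.iirnotch(self.mains_hz, self.notch_quality, fs=sampling_rate_hz)
        return sps.tf2sos(b, a)

    def bandpass_sos(self, sampling_rate_hz: float) -> np.ndarray:
        return sps.butter(
            self.order,
            (self.band_low_hz, self.band_high_hz),
            btype="bandpass",
            fs=sampling_rate_hz,
            output="sos",
        )

    def chain_sos(self, sampling_rate_hz: float) -> np.ndarray:
        """Notch and band-pass cascaded into one SOS array."""
        return np.vstack(
            [self.notch_sos(sampling_rate_hz), self.bandpass_sos(sampling_rate_hz)]
        )


def _apply(recording: Recording, sos: np.ndarray, causal: bool) -> Recording:
    if causal:
        out = sps.sosfilt(sos, recording.samples, axis=0)
    else:
        out = sps.sosfiltfilt(sos, recording.samples, axis=0)
    return recording.copy_with(out)


def notch_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Remove mains interference; events and shape are unchanged."""
    spec.validate(recording.sampling_rate_hz)
    return _apply(recording, spec.notch_sos(recording.sampling_rate_hz), spec.causal)


def bandpass_filter(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-limit to the EMG band (10–450 Hz by default)."""
    spec.validate(recording.sampling_rate_hz)
    return _apply(recording, spec.bandpass_sos(recording.sampling_rate_hz), spec.causal)


def preprocess(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Notch then band-pass — the full chain, one call."""
    spec.validate(recording.sampling_rate_hz)
    return _apply(recording, spec.chain_sos(recording.sampling_rate_hz), spec.causal)


class StreamingPreprocessor:
    """The same chain with filter state carried between chunks.

    Feeding a signal chunk by chunk yields exactly the samples that one
    whole-signal :func:`preprocess` call produces (causal mode only —
    zero-phase filtering is acausal and has no streaming equivalent).
    """

    def __init__(self, spec: FilterSpec, sampling_rate_hz: float) -> None:
        if not spec.causal:
            raise ValueError("streaming preprocessing must be causal")
        spec.validate(sampling_rate_hz)
        self.spec = spec
        self.sampling_rate_hz = sampling_rate_hz
        self._sos = spec.chain_sos(sampling_rate_hz)
        n_sections = self._sos.shape[0]
        self._zi = np.zeros((n_sections, 2, N_CHANNELS))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=float)
        if chunk.ndim != 2 or chunk.shape[1] != N_CHANNELS:
            raise ValueError(f"chunk must be (n, {N_CHANNELS})")
        out, self._zi = sps.sosfilt(self._sos, chunk, axis=0, zi=self._zi)
        return out
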