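"""Core containers shared across the pipeline.

The label vocabulary covers the six facial movements used by the
face-computer interface plus REST:

====== ==============================all==========
label  movement
====== ============================================
LEb    lift both eyebrows
LEBO   left eye blink once, slowly
REBO   right eye blink once, slowly
Bk     bick (clench, as if chewing something hard)
TML    tilt mouth to the left
TMR    tilt mouth to the right
REST   relaxed face, no movement
====== ============================================

Each movement has a dedicated surface electrode ("main channel"):
channel 1 forehead (LEb), 2 left eye corner (LEBO), 3 right eye corner
(REBO), 4 masseter (Bk), 5 left mouth corner (TML), 6 right mouth
corner (TMR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the six active movements, in main-channel order (channel 1..6)
MOVEMENTS: tuple[str, ...] = ("LEb", "LEBO", "REBO", "Bk", "TML", "TMR")
REST: str = "REST"
#: full label vocabulary
LABELS: tuple[str, ...] = MOVEMENTS + (REST,)

N_CHANNELS: int = 6

#: main channel index (0-based) per movement
MAIN_CHANNEL: dict[str, int] = {m: i for i, m in enumerate(MOVEMENTS)}

DEFAULT_CHANNEL_LABELS: tuple[str, ...] = (
    "ch1_frontal",
    "ch2_l_orb_oculi",
    "ch3_r_orb_oculi",
    "ch4_masseter",
    "ch5_l_risorius",
    "ch6_r_risorius",
)


@dataclass
class Recording:
    """A multi-channel surface-EMG recording with prompt events.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, 6)
        Signal, one column per channel, arbitrary amplitude units (mV).
    sampling_rate_hz : float
        Sampling rate; the acquisition protocol uses 1,000 Hz.
    channel_labels : tuple of str
        Exactly six labels.
    events : list of (float, str)
        ``(prompt_time_s, movement_label)`` pairs, strictly increasing
        in time and within the signal extent.
    sample_labels : ndarray of str, optional
        Ground-truth label per sample; carried by synthetic online
        streams so decoders can be scored. ``None`` for offline data.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...] = DEFAULT_CHANNEL_LABELS
    events: list[tuple[float, str]] = field(default_factory=list)
    sample_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be (n, {N_CHANNELS}), got {self.samples.shape}"
            )
        if len(self.channel_labels) != N_CHANNELS:
            raise ValueError("exactly 6 channel labels required")
        dur = self.duration_s
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(not 0.0 <= t <= dur for t in times):
            raise ValueError("event time outside the signal extent")
        for _, lab in self.events:
            if lab not in LABELS:
                raise ValueError(f"unknown movement label {lab!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def copy_with(self, samples: np.ndarray) -> "Recording":
        """Same metadata, new signal (filters use this)."""
        return Recording(
            samples=samples,
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=self.channel_labels,
            events=list(self.events),
            sample_labels=None
            if self.sample_labels is None
            else self.sample_labels.copy(),
        )
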