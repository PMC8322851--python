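"""Sliding-window segmentation of event-marked recordings.

Each prompt yields 200 ms windows at a 50 ms step from two spans:

* the *active* span 1,500–2,650 ms after the prompt, labelled with the
  prompted movement — 20 windows;
* the *rest* span covering the 350 ms immediately before the prompt,
  labelled REST — 4 windows.

Window starts are half-open intervals ``[start, start + 200 ms)``, so
the last active window starts at prompt + 2,450 ms and ends exactly at
2,650 ms.  A 20-round acquisition therefore yields
20 × 6 × (20 + 4) = 2,880 labelled windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import REST, Recording

__all__ = ["WindowSpec", "LabeledWindow", "count_windows", "segment_recording"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    window_ms: float = 200.0
    step_ms: float = 50.0
    active_start_ms: float = 1500.0   # offset after the prompt
    active_end_ms: float = 2650.0
    rest_pre_ms: float = 350.0        # span length before the prompt

    def __post_init__(self) -> None:
        if self.step_ms <= 0:
            raise ValueError("step must be positive")
        if self.active_end_ms <= self.active_start_ms:
            raise ValueError("active span must have positive length")
        if self.window_ms > self.active_end_ms - self.active_start_ms:
            raise ValueError("window longer than the active span")
        if self.window_ms > self.rest_pre_ms:
            raise ValueError("window longer than the rest span")


@dataclass
class LabeledWindow:
    """One fixed-length window with its movement label and provenance."""

    samples: np.ndarray            # (window length, 6)
    label: str
    round_index: int
    prompt_index: int
    start_s: float                 # window start, seconds into the recording


def count_windows(span_ms: float, window_ms: float, step_ms: float) -> int:
    """Number of windows a span admits: ``floor((span − window)/step) + 1``."""
    if span_ms < window_ms:
        raise ValueError("span shorter than the window")
    if step_ms <= 0:
        raise ValueError("step must be positive")
    return int(np.floor((span_ms - window_ms) / step_ms + 1e-9)) + 1


def _span_windows(
    recording: Recording,
    spec: WindowSpec,
    span_start_s: float,
    span_end_s: float,
    label: str,
    round_index: int,
    prompt_index: int,
) -> list[LabeledWindow] | None:
    """Windows covering ``[span_start, span_end]``; None if out of bounds."""
    fs = recording.sampling_rate_hz
    win_n = int(round(spec.window_ms * fs / 1000.0))
    step_n = int(round(spec.step_ms * fs / 1000.0))
    first = int(round(span_start_s * fs))
    last_end = int(round(span_end_s * fs))
    if first < 0 or last_end > recording.n_samples:
        return None
    k = count_windows(
        1000.0 * (span_end_s - span_start_s), spec.window_ms, spec.step_ms
    )
    out = []
    for j in range(k):
        s = first + j * step_n
        out.append(
            LabeledWindow(
                samples=recording.samples[s : s + win_n],
                label=label,
                round_index=round_index,
                prompt_index=prompt_index,
                start_s=s / fs,
            )
        )
    return out


def segment_recording(
    recording: Recording,
    spec: WindowSpec = WindowSpec(),
    round_index: int = 0,
) -> list[LabeledWindow]:
    """Cut the active and rest windows around every prompt.

    Windows are ordered by prompt, then by window start (the 4 REST
    windows of a prompt precede its 20 active windows).  Prompts whose
    spans fall outside the recording are skipped with a warning.
    """
    out: list[LabeledWindow] = []
    for p_idx, (t_prompt, movement) in enumerate(recording.events):
        rest = _span_windows(
            recording, spec,
            t_prompt - spec.rest_pre_ms / 1000.0, t_prompt,
            REST, round_index, p_idx,
        )
        active = _span_windows(
            recording, spec,
            t_prompt + spec.active_start_ms / 1000.0,
            t_prompt + spec.active_end_ms / 1000.0,
            movement, round_index, p_idx,
        )
        if rest is None or active is None:
            logger.warning(
                "prompt %d at %.3f s too close to the recording edge; skipped",
                p_idx, t_prompt,
            )
            continue
        out.extend(rest)
        out.extend(active)
    return out
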