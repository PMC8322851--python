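"""Seeded synthetic facial-EMG generator.

Real facial-EMG for this interface is recorded with six monopolar
electrodes at 1,000 Hz while the subject performs six facial movements
in prompted rounds.  This module emulates that acquisition so the whole
pipeline is testable without hardware:

* each movement produces an interference-pattern burst — amplitude
  modulated, band-limited (20–450 Hz) Gaussian noise — on every channel,
  scaled by a movement-by-channel cross-talk gain matrix;
* the gain matrix encodes the observed cross-talk structure: the clench
  (Bk) bleeds into every channel, the eyebrow lift (LEb) into almost
  none, and each movement is strongest on its own electrode, with
  amplitudes ordered Bk > LEb > TML ≈ TMR > LEBO ≈ REBO;
* mains interference (50 Hz by default) and white baseline noise are
  added everywhere.

Everything is driven by integer seeds: identical seeds give bit
identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import (
    LABELS,
    MAIN_CHANNEL,
    MOVEMENTS,
    N_CHANNELS,
    REST,
    Recording,
)

__all__ = [
    "CrosstalkProfile",
    "ProtocolConfig",
    "default_crosstalk_profile",
    "generate_round",
    "generate_dataset",
    "generate_online_stream",
    "StreamingSynth",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CrosstalkProfile:
    """Movement-by-channel burst gains plus noise/interference levels.

    ``gains[label]`` is a length-6 array of non-negative burst RMS
    amplitudes (signal units).  Every movement must be strictly loudest
    on its own main channel, and REST carries no burst at all.
    """

    gains: dict[str, np.ndarray]
    burst_band_hz: tuple[float, float] = (20.0, 450.0)
    mains_hz: float = 50.0
    mains_amplitude: float = 0.01
    baseline_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        self.gains = {k: np.asarray(v, dtype=float) for k, v in self.gains.items()}
        for lab in LABELS:
            if lab not in self.gains:
                raise ValueError(f"profile missing gain row for {lab!r}")
            row = self.gains[lab]
            if row.shape != (N_CHANNELS,):
                raise ValueError(f"gain row for {lab!r} must have 6 entries")
            if not np.all(np.isfinite(row)) or np.any(row < 0):
                raise ValueError(f"gains for {lab!r} must be finite and >= 0")
        if np.any(self.gains[REST] != 0):
            raise ValueError("REST gain row must be all zeros")
        for mov in MOVEMENTS:
            row = self.gains[mov]
            main = MAIN_CHANNEL[mov]
            others = np.delete(row, main)
            if not row[main] > others.max():
                raise ValueError(
                    f"{mov}: main channel {main + 1} must be the strict "
                    "maximum of its gain row"
                )
        lo, hi = self.burst_band_hz
        if not 0 < lo < hi:
            raise ValueError("burst band must satisfy 0 < low < high")

    def gain(self, label: str, channel: int) -> float:
        """Burst gain for ``label`` on 1-based ``channel``."""
        return float(self.gains[label][channel - 1])


@dataclass
class ProtocolConfig:
    """Timing of the prompted acquisition protocol.

    One round presents the six movements once each, in seeded random
    order, with a rest period between actions.  The prompt precedes the
    action onset by ``onset_latency_s`` (subject reaction time), so the
    analysis epoch 1.5–2.65 s after the prompt lies inside the burst.
    """

    n_rounds: int = 20
    action_duration_s: float = 3.0
    rest_between_s: float = 5.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0
    onset_latency_s: float = 0.5
    ramp_s: float = 0.1  # raised-cosine on/off ramp of the burst envelope

    def __post_init__(self) -> None:
        if self.action_duration_s <= 0 or self.rest_between_s <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate_hz < 900:
            raise ValueError(
                "sampling rate must be >= 900 Hz to carry the 450 Hz band edge"
            )
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


def default_crosstalk_profile() -> CrosstalkProfile:
    """Default cross-talk gain matrix.

    Quantitative gains are package defaults chosen to reproduce the
    qualitative structure of the real recordings: per-movement rows
    (channels 1..6) with the main channel largest, Bk bleeding into all
    channels, LEb into none, and the eye blinks weakest overall.
    """
    g = {m: np.zeros(N_CHANNELS) for m in LABELS}
    g["LEb"][0] = 0.60                       # forehead only
    g["LEBO"][1] = 0.15
    g["REBO"][2] = 0.15
    g["REBO"][0] = 0.04                      # right blink reaches the forehead
    g["Bk"][:] = (0.25, 0.25, 0.25, 1.00, 0.12, 0.12)  # clench hits everything
    g["TML"][4] = 0.40
    g["TML"][1] = 0.08                       # left mouth tilt -> left eye corner
    g["TML"][3] = 0.10                       # ... and masseter
    g["TMR"][5] = 0.40
    g["TMR"][2] = 0.08                       # right mouth tilt -> right eye corner
    return CrosstalkProfile(gains=g)


# ---------------------------------------------------------------------------
# signal construction
# ---------------------------------------------------------------------------

def _burst_sos(profile: CrosstalkProfile, fs: float):
    lo, hi = profile.burst_band_hz
    hi = min(hi, 0.99 * fs / 2)
    return sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _burst_norm(profile: CrosstalkProfile, fs: float) -> float:
    # unit-variance white noise through the band-pass keeps roughly the
    # in-band fraction of its power; rescale so gains read as burst RMS
    lo, hi = profile.burst_band_hz
    hi = min(hi, 0.99 * fs / 2)
    return 1.0 / np.sqrt((hi - lo) / (fs / 2))


def _carrier(profile: CrosstalkProfile, n: int, fs: float, rng) -> np.ndarray:
    """Unit-RMS band-limited noise, one independent column per channel."""
    white = rng.standard_normal((n, N_CHANNELS))
    sos = _burst_sos(profile, fs)
    return sps.sosfilt(sos, white, axis=0) * _burst_norm(profile, fs)


def _raised_cosine_envelope(
    n: int, fs: float, onset_s: float, duration_s: float, ramp_s: float
) -> np.ndarray:
    """0→1→0 envelope with raised-cosine ramps, sampled at ``fs``."""
    t = np.arange(n) / fs
    env = np.zeros(n)
    t0, t1 = onset_s, onset_s + duration_s
    ramp = max(ramp_s, 1.0 / fs)
    rise = (t >= t0) & (t < t0 + ramp)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - t0) / ramp))
    env[(t >= t0 + ramp) & (t <= t1 - ramp)] = 1.0
    fall = (t > t1 - ramp) & (t <= t1)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - t[fall]) / ramp))
    return env


def _background(
    profile: CrosstalkProfile, n: int, fs: float, rng
) -> np.ndarray:
    """Mains sinusoid (random phase, common to all channels) + white noise."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    mains = profile.mains_amplitude * np.sin(2 * np.pi * profile.mains_hz * t + phase)
    noise = profile.baseline_noise_sd * rng.standard_normal((n, N_CHANNELS))
    return noise + mains[:, None]


def generate_round(
    profile: CrosstalkProfile,
    config: ProtocolConfig,
    round_seed: int,
) -> Recording:
    """One acquisition round: the six movements once each, random order.

    The prompt schedule is rest, prompt, (latency, action, rest), ...;
    one event is recorded per prompt.  Identical ``round_seed`` gives a
    bit-identical recording.
    """
    fs = config.sampling_rate_hz
    rng = np.random.default_rng(round_seed)
    order = [str(m) for m in rng.permutation(MOVEMENTS)]

    slot = config.onset_latency_s + config.action_duration_s + config.rest_between_s
    prompts = [config.rest_between_s + k * slot for k in range(len(order))]
    total_s = prompts[-1] + config.onset_latency_s + config.action_duration_s + 1.0
    n = int(round(total_s * fs))

    carrier = _carrier(profile, n, fs, rng)
    amp = np.zeros((n, N_CHANNELS))
    for t_prompt, mov in zip(prompts, order):
        env = _raised_cosine_envelope(
            n, fs, t_prompt + config.onset_latency_s,
            config.action_duration_s, config.ramp_s,
        )
        amp += env[:, None] * profile.gains[mov][None, :]

    samples = carrier * amp + _background(profile, n, fs, rng)
    events = [(t, mov) for t, mov in zip(prompts, order)]
    return Recording(samples=samples, sampling_rate_hz=fs, events=events)


def generate_dataset(
    profile: CrosstalkProfile, config: ProtocolConfig
) -> list[Recording]:
    """``config.n_rounds`` independent rounds with distinct derived seeds."""
    seeder = np.random.default_rng(config.seed)
    round_seeds = seeder.integers(0, 2**31 - 1, size=config.n_rounds)
    return [generate_round(profile, config, int(s)) for s in round_seeds]


def generate_online_stream(
    profile: CrosstalkProfile,
    intended_sequence: list[tuple[str, float]],
    sampling_rate_hz: float = 1000.0,
    seed: int = 0,
    ramp_s: float = 0.05,
) -> Recording:
    """Continuous stream realizing a scripted label sequence.

    ``intended_sequence`` is a list of ``(label, duration_s)`` segments
    (REST allowed).  The returned recording keeps the ground-truth label
    per sample in ``sample_labels`` so decoder output can be scored.
    """
    if not intended_sequence:
        raise ValueError("intended_sequence must not be empty")
    for lab, dur in intended_sequence:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        if dur <= 0:
            raise ValueError("segment durations must be positive")

    fs = sampling_rate_hz
    rng = np.random.default_rng(seed)
    seg_n = [int(round(d * fs)) for _, d in intended_sequence]
    n = sum(seg_n)

    labels = np.empty(n, dtype=object)
    amp = np.zeros((n, N_CHANNELS))
    pos = 0
    for (lab, dur), m in zip(intended_sequence, seg_n):
        labels[pos : pos + m] = lab
        if lab != REST:
            env = _raised_cosine_envelope(m, fs, 0.0, dur, ramp_s)
            amp[pos : pos + m] = env[:, None] * profile.gains[lab][None, :]
        pos += m

    samples = _carrier(profile, n, fs, rng) * amp + _background(profile, n, fs, rng)
    return Recording(
        samples=samples,
        sampling_rate_hz=fs,
        events=[],
        sample_labels=labels.astype(str),
    )


class StreamingSynth:
    """Tick-by-tick fEMG synthesis for closed-loop simulation.

    Produces the same class of signal as :func:`generate_online_stream`
    but one chunk at a time, with filter state carried across chunks so
    the band-limited carrier is continuous.  The burst gain ramps
    linearly across each chunk when the intended label changes.
    """

    def __init__(
        self,
        profile: CrosstalkProfile,
        sampling_rate_hz: float = 1000.0,
        seed: int = 0,
    ) -> None:
        self.profile = profile
        self.fs = sampling_rate_hz
        self.rng = np.random.default_rng(seed)
        self._sos = _burst_sos(profile, sampling_rate_hz)
        self._norm = _burst_norm(profile, sampling_rate_hz)
        zi1 = sps.sosfilt_zi(self._sos)
        self._zi = np.repeat(zi1[:, :, None], N_CHANNELS, axis=2) * 0.0
        self._gain = np.zeros(N_CHANNELS)
        self._t = 0  # samples emitted so far
        self._mains_phase = self.rng.uniform(0, 2 * np.pi)

    def tick(self, label: str, n_samples: int) -> np.ndarray:
        """Generate the next ``n_samples`` of signal under ``label``."""
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        white = self.rng.standard_normal((n_samples, N_CHANNELS))
        carrier, self._zi = sps.sosfilt(self._sos, white, axis=0, zi=self._zi)
        carrier *= self._norm

        target = self.profile.gains[label]
        ramp = np.linspace(0.0, 1.0, n_samples, endpoint=False)[:, None]
        amp = self._gain[None, :] * (1 - ramp) + target[None, :] * ramp
        self._gain = target.copy()

        t = (self._t + np.arange(n_samples)) / self.fs
        mains = self.profile.mains_amplitude * np.sin(
            2 * np.pi * self.profile.mains_hz * t + self._mains_phase
        )
        noise = self.profile.baseline_noise_sd * self.rng.standard_normal(
            (n_samples, N_CHANNELS)
        )
        self._t += n_samples
        return carrier * amp + noise + mains[:, None]
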