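"""File formats and run configuration.

Recordings travel as delimited text: a samples CSV whose header row
carries the six channel labels, with a ``<name>.events.csv`` sidecar
(``prompt_time_s,label``) and, for synthetic online streams, an
optional ``<name>.labels.csv`` sidecar holding the ground-truth label
per sample.  EDF is supported as an exchange format: reading goes
through MNE; writing uses a minimal EDF+C encoder (16-bit, one
annotation channel carrying the prompt events) defined here, since no
installed library writes EDF.

Every artifact written by the package carries the seed and a config
digest in a leading ``#`` comment line so runs can be reproduced
exactly.  Errors carry distinct exit codes for the command line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .decoder import DecoderConfig
from .preprocess import FilterSpec
from .segmentation import WindowSpec
from .synth import CrosstalkProfile, ProtocolConfig, default_crosstalk_profile
from .types import LABELS, N_CHANNELS, Recording

__all__ = [
    "RecordingIOError",
    "ChannelCountError",
    "MissingEventsError",
    "read_recording",
    "write_recording",
    "write_edf",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
    "RunConfig",
    "config_digest",
]

MODEL_FORMAT_VERSION = 1


class RecordingIOError(Exception):
    """Unreadable or malformed recording file."""

    exit_code = 6


class ChannelCountError(RecordingIOError):
    exit_code = 4


class MissingEventsError(RecordingIOError):
    exit_code = 5


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _sidecar(path: Path, kind: str) -> Path:
    return path.with_name(path.stem + f".{kind}.csv")


def write_recording(
    recording: Recording,
    path: str | Path,
    sampling_comment: str | None = None,
) -> None:
    """Samples CSV (+ events sidecar, + labels sidecar if present)."""
    path = Path(path)
    header = f"# myoface fs_hz={recording.sampling_rate_hz}"
    if sampling_comment:
        header += f" {sampling_comment}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        pd.DataFrame(
            recording.samples, columns=list(recording.channel_labels)
        ).to_csv(fh, index=False, float_format="%.9g")
    pd.DataFrame(recording.events, columns=["prompt_time_s", "label"]).to_csv(
        _sidecar(path, "events"), index=False
    )
    if recording.sample_labels is not None:
        pd.DataFrame({"label": recording.sample_labels}).to_csv(
            _sidecar(path, "labels"), index=False
        )


def _read_csv_recording(path: Path, require_events: bool) -> Recording:
    fs = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("fs_hz="):
                fs = float(tok.split("=", 1)[1])
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise RecordingIOError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] != N_CHANNELS:
        raise ChannelCountError(
            f"{path}: expected {N_CHANNELS} channels, found {df.shape[1]}"
        )
    if fs is None:
        fs = 1000.0

    ev_path = _sidecar(path, "events")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        events = [
            (float(t), str(lab))
            for t, lab in zip(ev["prompt_time_s"], ev["label"])
        ]
    elif require_events:
        raise MissingEventsError(f"events sidecar {ev_path} not found")
    else:
        events = []

    lab_path = _sidecar(path, "labels")
    sample_labels = (
        pd.read_csv(lab_path)["label"].to_numpy(dtype=str)
        if lab_path.exists()
        else None
    )
    return Recording(
        samples=df.to_numpy(dtype=float),
        sampling_rate_hz=fs,
        channel_labels=tuple(df.columns),
        events=events,
        sample_labels=sample_labels,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(recording: Recording, path: str | Path) -> None:
    """Minimal EDF+C export: 16-bit signals plus one annotation channel.

    Records are 1 s long; the signal is zero-padded to a whole number
    of records.  Prompt events become EDF+ annotations whose text is
    the movement label.
    """
    path = Path(path)
    fs = recording.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(round(fs))
    x = recording.samples
    n_rec = int(np.ceil(x.shape[0] / fs))
    pad = n_rec * fs - x.shape[0]
    if pad:
        x = np.vstack([x, np.zeros((pad, N_CHANNELS))])

    pmax = float(max(np.abs(x).max(), 1e-6))
    pmin = -pmax
    dmax, dmin = 32767, -32768
    digital = np.round(
        (x - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")

    annots: list[list[bytes]] = [[] for _ in range(n_rec)]
    for r in range(n_rec):
        annots[r].append(f"+{r}\x14\x14\x00".encode("ascii"))  # timekeeping TAL
    for t, lab in recording.events:
        r = min(int(t), n_rec - 1)
        annots[r].append(f"+{t:.3f}\x14{lab}\x14\x00".encode("ascii"))
    ann_bytes = [b"".join(a) for a in annots]
    ann_len = max(len(b) for b in ann_bytes)
    ann_samples = int(np.ceil(ann_len / 2)) + 8  # headroom, 2 bytes/sample

    ns = N_CHANNELS + 1

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),                    # local patient id
            f("Startdate X X X X", 80),          # local recording id
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (ns + 1)), 8),
            f("EDF+C", 44),
            f(str(n_rec), 8),
            f("1", 8),                           # record duration, s
            f(str(ns), 4),
        ]
    )
    labels = [f(lab, 16) for lab in recording.channel_labels]
    labels.append(f("EDF Annotations", 16))
    sig_header = b"".join(
        [
            b"".join(labels),
            b"".join([f("fEMG electrode", 80)] * N_CHANNELS + [f("", 80)]),
            b"".join([f("mV", 8)] * N_CHANNELS + [f("", 8)]),
            b"".join([f(f"{pmin:.6g}", 8)] * N_CHANNELS + [f("-1", 8)]),
            b"".join([f(f"{pmax:.6g}", 8)] * N_CHANNELS + [f("1", 8)]),
            b"".join([f(str(dmin), 8)] * N_CHANNELS + [f(str(dmin), 8)]),
            b"".join([f(str(dmax), 8)] * N_CHANNELS + [f(str(dmax), 8)]),
            b"".join([f("", 80)] * ns),          # prefiltering
            b"".join([f(str(fs), 8)] * N_CHANNELS + [f(str(ann_samples), 8)]),
            b"".join([f("", 32)] * ns),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            digital[r * fs : (r + 1) * fs].T.tofile(fh)
            ann = ann_bytes[r]
            fh.write(ann + b"\x00" * (2 * ann_samples - len(ann)))


def _read_edf_recording(path: Path, require_events: bool) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001
        raise RecordingIOError(f"cannot read EDF {path}: {exc}") from exc
    data = raw.get_data().T  # MNE rescales to SI units (mV -> V)
    if data.shape[1] != N_CHANNELS:
        raise ChannelCountError(
            f"{path}: expected {N_CHANNELS} channels, found {data.shape[1]}"
        )
    events = [
        (float(on), str(desc))
        for on, desc in zip(raw.annotations.onset, raw.annotations.description)
        if str(desc) in LABELS
    ]
    if require_events and not events:
        raise MissingEventsError(f"{path}: no movement annotations found")
    return Recording(
        samples=data * 1e3,  # back to the package's mV-scale units
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names[:N_CHANNELS]),
        events=events,
    )


def read_recording(
    path: str | Path, fmt: str | None = None, require_events: bool = True
) -> Recording:
    """Read a recording from CSV (+ sidecars) or EDF.

    ``fmt`` is inferred from the suffix when omitted.  With
    ``require_events`` (the default) a missing events sidecar or an
    annotation-free EDF raises :class:`MissingEventsError`; disable it
    for continuous online streams.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such file: {path}")
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        return _read_csv_recording(path, require_events)
    if fmt == "edf":
        return _read_edf_recording(path, require_events)
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# feature tables, models, run config
# ---------------------------------------------------------------------------

def config_digest(obj) -> str:
    """Short stable digest of any JSON-serialisable configuration."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_feature_table(fm, path: str | Path, seed: int | None = None) -> None:
    """Feature matrix + label column as CSV with a provenance comment."""
    path = Path(path)
    df = fm.X.copy()
    df["label"] = fm.y
    digest = config_digest({"mode": fm.mode, "columns": list(fm.X.columns)})
    with open(path, "w") as fh:
        fh.write(f"# myoface mode={fm.mode} seed={seed} config={digest}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path: str | Path):
    """Inverse of :func:`write_feature_table` (returns a FeatureMatrix)."""
    from .features import FeatureMatrix

    path = Path(path)
    mode = "AF"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("mode="):
                mode = tok.split("=", 1)[1]
    df = pd.read_csv(path, comment="#")
    if "label" not in df.columns:
        raise RecordingIOError(f"{path}: feature table lacks a label column")
    y = df.pop("label").to_numpy(dtype=str)
    return FeatureMatrix(X=df, y=y, mode=mode)


def save_model(model, path: str | Path, feature_mode: str, columns, seed) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "model": model,
            "feature_mode": feature_mode,
            "columns": list(columns),
            "seed": seed,
        },
        path,
    )


def load_model(path: str | Path) -> dict:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise RecordingIOError(f"{path}: unsupported model format")
    return blob


@dataclass
class RunConfig:
    """Mirror of the YAML run configuration."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    windows: WindowSpec = field(default_factory=WindowSpec)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    profile: CrosstalkProfile = field(default_factory=default_crosstalk_profile)
    feature_mode: str = "EF"
    model: str = "GBC"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "protocol" in raw:
            kw["protocol"] = ProtocolConfig(**raw["protocol"])
        if "filters" in raw:
            kw["filters"] = FilterSpec(**raw["filters"])
        if "windows" in raw:
            kw["windows"] = WindowSpec(**raw["windows"])
        if "decoder" in raw:
            dec = dict(raw["decoder"])
            if dec.get("desktop_rect") is not None:
                (x0, x1), (y0, y1) = dec["desktop_rect"]
                dec["desktop_rect"] = ((x0, x1), (y0, y1))
            kw["decoder"] = DecoderConfig(**dec)
        if "profile" in raw:
            p = dict(raw["profile"])
            gains = {k: np.asarray(v, float) for k, v in p.pop("gains").items()}
            if "burst_band_hz" in p:
                p["burst_band_hz"] = tuple(p["burst_band_hz"])
            kw["profile"] = CrosstalkProfile(gains=gains, **p)
        for key in ("feature_mode", "model"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        out = {
            "protocol": asdict(self.protocol),
            "filters": asdict(self.filters),
            "windows": asdict(self.windows),
            "decoder": asdict(self.decoder),
            "profile": {
                "gains": {k: v.tolist() for k, v in self.profile.gains.items()},
                "burst_band_hz": list(self.profile.burst_band_hz),
                "mains_hz": self.profile.mains_hz,
                "mains_amplitude": self.profile.mains_amplitude,
                "baseline_noise_sd": self.profile.baseline_noise_sd,
            },
            "feature_mode": self.feature_mode,
            "model": self.model,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)

    @property
    def digest(self) -> str:
        return config_digest(
            {
                "protocol": asdict(self.protocol),
                "filters": asdict(self.filters),
                "windows": asdict(self.windows),
                "decoder": asdict(self.decoder),
                "feature_mode": self.feature_mode,
                "model": self.model,
            }
        )
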