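"""Stimulus battery for the Familiar Environmental Sound Test (FEST).

The battery consists of 25 highly identifiable environmental sounds
(doorbell, barking, fog horn, ...).  Each sound appears exactly once in a
set of five contextually *coherent* five-sound sequences (plausible
auditory scenes such as "Waking up") and exactly once in a set of five
contextually *incoherent* sequences — the same 25 sounds rearranged so
that identification differences between conditions cannot be driven by
the individual sounds themselves.  Within a sequence, sounds are
separated by 250 ms of silence.

This module holds the data model and its validation, RMS level
normalisation with silent-pause correction, sequence assembly, and a
deterministic synthetic-audio generator that stands in for the original
recordings (which are not bundled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.io import wavfile as _wav

__all__ = [
    "SoundItem",
    "SequenceSpec",
    "Battery",
    "AudioClip",
    "BatteryValidationError",
    "load_battery",
    "battery_to_frame",
    "save_battery",
    "rms_normalize",
    "assemble_sequence",
    "sequence_duration",
    "make_fixture_audio",
    "read_wav",
    "write_wav",
    "resample_clip",
    "DEFAULT_GAP",
    "DEFAULT_RATE",
]

#: Inter-sound silent interval within a sequence, seconds.
DEFAULT_GAP = 0.250
#: Working sample rate; clips are resampled here before assembly/vocoding.
DEFAULT_RATE = 44100

_COLUMNS = [
    "label",
    "duration_sec",
    "coherent_seq",
    "coherent_pos",
    "incoherent_seq",
    "incoherent_pos",
]


class BatteryValidationError(ValueError):
    """Raised when a battery definition violates a structural invariant.

    ``problems`` lists every offending row/sequence, not just the first.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid battery definition:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class SoundItem:
    """One environmental sound and its placement in both sequence sets."""

    label: str
    duration: float
    coherent_seq: str
    coherent_pos: int
    incoherent_seq: str
    incoherent_pos: int


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered five-sound sequence with a coherence class."""

    name: str
    coherence: str  # "coherent" | "incoherent"
    labels: tuple[str, ...]
    gap: float = DEFAULT_GAP

    def __post_init__(self):
        if self.coherence not in ("coherent", "incoherent"):
            raise ValueError(f"coherence must be coherent|incoherent, got {self.coherence!r}")


@dataclass(frozen=True)
class Battery:
    """The validated 25-sound / 10-sequence battery."""

    sounds: tuple[SoundItem, ...]
    sequences: tuple[SequenceSpec, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sounds)

    def sound(self, label: str) -> SoundItem:
        for s in self.sounds:
            if s.label == label:
                return s
        raise KeyError(f"unknown sound label {label!r}")

    def sequence(self, name: str) -> SequenceSpec:
        for q in self.sequences:
            if q.name == name:
                return q
        raise KeyError(f"unknown sequence {name!r}")

    def sequences_by_coherence(self, coherence: str) -> tuple[SequenceSpec, ...]:
        return tuple(q for q in self.sequences if q.coherence == coherence)


@dataclass
class AudioClip:
    """A mono waveform with its sample rate and (optional) label."""

    samples: np.ndarray
    rate: int
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip expects a 1-D mono waveform")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


# ---------------------------------------------------------------------------
# Loading / validation


def _packaged_battery_path():
    return resources.files("fest.data").joinpath("battery.csv")


def load_battery(source: str | Path | pd.DataFrame | None = None, *, gap: float = DEFAULT_GAP) -> Battery:
    """Load and validate a battery definition.

    Parameters
    ----------
    source
        A CSV path (columns ``label, duration_sec, coherent_seq,
        coherent_pos, incoherent_seq, incoherent_pos``), a JSON path
        written by :func:`save_battery`, a DataFrame with those columns,
        or ``None`` for the packaged 25-sound battery.
    gap
        Inter-sound silence used when deriving sequence specs, seconds.

    Raises
    ------
    BatteryValidationError
        If any structural invariant fails; the message names every
        offending label or sequence.
    """
    if source is None:
        with resources.as_file(_packaged_battery_path()) as p:
            df = pd.read_csv(p)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() == ".json":
            df = pd.DataFrame(json.loads(path.read_text())["sounds"])
        else:
            df = pd.read_csv(path)

    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise BatteryValidationError([f"missing columns: {missing}"])

    problems: list[str] = []
    dup = df["label"][df["label"].duplicated()].unique().tolist()
    for d in dup:
        problems.append(f"duplicate label {d!r}")
    for _, row in df.iterrows():
        if not (row["duration_sec"] > 0):
            problems.append(f"non-positive duration for {row['label']!r}")
        for col in ("coherent_pos", "incoherent_pos"):
            if int(row[col]) not in (1, 2, 3, 4, 5):
                problems.append(f"{row['label']!r}: {col}={row[col]} outside 1-5")

    sequences: list[SequenceSpec] = []
    for coherence, seq_col, pos_col in (
        ("coherent", "coherent_seq", "coherent_pos"),
        ("incoherent", "incoherent_seq", "incoherent_pos"),
    ):
        for name, grp in df.groupby(seq_col, sort=True):
            if len(grp) != 5:
                problems.append(f"sequence {name!r} has {len(grp)} members, expected 5")
                continue
            positions = sorted(int(p) for p in grp[pos_col])
            if positions != [1, 2, 3, 4, 5]:
                problems.append(f"sequence {name!r} positions {positions} are not 1..5")
                continue
            ordered = grp.sort_values(pos_col)["label"].tolist()
            sequences.append(SequenceSpec(str(name), coherence, tuple(ordered), gap=gap))

    if not problems:
        all_labels = set(df["label"])
        for coherence in ("coherent", "incoherent"):
            used = [l for q in sequences if q.coherence == coherence for l in q.labels]
            if sorted(used) != sorted(all_labels):
                problems.append(
                    f"{coherence} sequence set does not cover each of the "
                    f"{len(all_labels)} labels exactly once"
                )

    if problems:
        raise BatteryValidationError(problems)

    sounds = tuple(
        SoundItem(
            label=str(r["label"]),
            duration=float(r["duration_sec"]),
            coherent_seq=str(r["coherent_seq"]),
            coherent_pos=int(r["coherent_pos"]),
            incoherent_seq=str(r["incoherent_seq"]),
            incoherent_pos=int(r["incoherent_pos"]),
        )
        for _, r in df.iterrows()
    )
    return Battery(sounds=sounds, sequences=tuple(sequences))


def battery_to_frame(battery: Battery) -> pd.DataFrame:
    """Battery as the canonical six-column DataFrame."""
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "duration_sec": s.duration,
                "coherent_seq": s.coherent_seq,
                "coherent_pos": s.coherent_pos,
                "incoherent_seq": s.incoherent_seq,
                "incoherent_pos": s.incoherent_pos,
            }
            for s in battery.sounds
        ],
        columns=_COLUMNS,
    )


def save_battery(battery: Battery, path: str | Path) -> None:
    """Write a battery as CSV or JSON depending on the path suffix."""
    path = Path(path)
    df = battery_to_frame(battery)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"sounds": df.to_dict(orient="records")}, indent=2, sort_keys=True))
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Level normalisation

#: Analysis-window length for silent-pause detection, seconds.
SILENCE_WINDOW = 0.010
#: Frames this far (dB) below the peak frame are treated as silent pauses.
SILENCE_THRESHOLD_DB = -60.0


def _active_mask(x: np.ndarray, rate: int, window: float, threshold_db: float) -> np.ndarray:
    """Boolean per-sample mask of frames above the silence threshold."""
    n = len(x)
    win = max(1, int(round(window * rate)))
    nframes = int(np.ceil(n / win))
    pad = np.zeros(nframes * win)
    pad[:n] = x
    frames = pad.reshape(nframes, win)
    frame_rms = np.sqrt(np.mean(np.square(frames), axis=1))
    peak = frame_rms.max()
    if peak == 0:
        return np.zeros(n, dtype=bool)
    active = frame_rms > peak * 10.0 ** (threshold_db / 20.0)
    return np.repeat(active, win)[:n]


def rms_normalize(
    clip: AudioClip,
    target_rms: float,
    *,
    window: float = SILENCE_WINDOW,
    threshold_db: float = SILENCE_THRESHOLD_DB,
) -> AudioClip:
    """Scale a clip so its RMS over non-silent frames equals ``target_rms``.

    Silent pauses are excluded from the level estimate so that leading,
    trailing or internal silence does not bias the normalisation: the
    clip is framed into ``window``-second windows and frames whose RMS
    falls more than ``threshold_db`` below the loudest frame are ignored.
    A single gain is then applied to the whole clip (silence included).
    """
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    if len(clip.samples) == 0:
        raise ValueError("cannot normalize an empty clip")
    mask = _active_mask(clip.samples, clip.rate, window, threshold_db)
    if not mask.any():
        raise ValueError(f"clip {clip.label!r} contains no frames above the silence threshold")
    current = np.sqrt(np.mean(np.square(clip.samples[mask])))
    gain = target_rms / current
    return AudioClip(samples=clip.samples * gain, rate=clip.rate, label=clip.label)


# ---------------------------------------------------------------------------
# Assembly


def resample_clip(clip: AudioClip, rate: int) -> AudioClip:
    """Polyphase resample to ``rate`` (no-op if already there)."""
    if clip.rate == rate:
        return clip
    from math import gcd

    g = gcd(clip.rate, rate)
    y = _sig.resample_poly(clip.samples, rate // g, clip.rate // g)
    return AudioClip(samples=y, rate=rate, label=clip.label)


def assemble_sequence(
    spec: SequenceSpec,
    clips: Mapping[str, AudioClip],
    *,
    rate: int | None = None,
    resample: bool = True,
) -> AudioClip:
    """Concatenate the five member clips with ``spec.gap`` seconds of
    silence between consecutive sounds (no leading/trailing gap).

    Clips at differing sample rates are polyphase-resampled to ``rate``
    (default: the first clip's rate) unless ``resample`` is False, in
    which case mixed rates raise.
    """
    missing = [l for l in spec.labels if l not in clips]
    if missing:
        raise KeyError(f"missing audio for labels: {missing}")
    members = [clips[l] for l in spec.labels]
    if rate is None:
        rate = members[0].rate
    rates = {c.rate for c in members}
    if rates != {rate}:
        if not resample:
            raise ValueError(f"mixed sample rates {sorted(rates)} and resampling disabled")
        members = [resample_clip(c, rate) for c in members]
    gap = np.zeros(int(round(spec.gap * rate)))
    parts: list[np.ndarray] = []
    for i, c in enumerate(members):
        if i:
            parts.append(gap)
        parts.append(c.samples)
    return AudioClip(samples=np.concatenate(parts), rate=rate, label=spec.name)


def sequence_duration(spec: SequenceSpec, battery: Battery) -> float:
    """Nominal sequence duration: member durations plus four gaps, seconds."""
    return sum(battery.sound(l).duration for l in spec.labels) + 4 * spec.gap


# ---------------------------------------------------------------------------
# Synthetic fixture audio

def make_fixture_audio(
    battery: Battery, rate: int = DEFAULT_RATE, seed: int = 0
) -> dict[str, AudioClip]:
    """Deterministic synthetic stand-ins for the original recordings.

    Each label receives a clip of its catalogued duration built from a
    label-specific recipe — a two-partial tone with amplitude modulation
    plus band-limited noise, with per-label frequencies, modulation rate
    and tone/noise mix drawn from a seeded generator — so the 25
    waveforms are pairwise distinct and spectrally varied.  Synthetic
    audio: it exercises the assembly/vocoding pipeline but carries no
    perceptual resemblance to the real sounds.
    """
    root = np.random.SeedSequence([seed, len(battery.sounds)])
    out: dict[str, AudioClip] = {}
    for child, item in zip(root.spawn(len(battery.sounds)), battery.sounds):
        rng = np.random.default_rng(child)
        n = int(round(item.duration * rate))
        t = np.arange(n) / rate
        f0 = rng.uniform(200.0, 2000.0)
        f1 = f0 * rng.uniform(1.5, 3.5)
        am = rng.uniform(2.0, 12.0)
        mix = rng.uniform(0.2, 0.8)
        tone = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(2 * np.pi * f1 * t)
        tone *= 0.5 * (1 + np.sin(2 * np.pi * am * t))
        noise = rng.standard_normal(n)
        # gentle one-pole lowpass to colour the noise differently per label
        alpha = rng.uniform(0.05, 0.9)
        noise = _sig.lfilter([alpha], [1, alpha - 1], noise)
        x = mix * tone + (1 - mix) * noise / max(1e-12, np.std(noise))
        # 5 ms raised-cosine onset/offset ramps to avoid clicks
        ramp = min(n // 2, int(0.005 * rate))
        if ramp > 0:
            w = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            x[:ramp] *= w
            x[-ramp:] *= w[::-1]
        x *= 0.1 / max(1e-12, np.sqrt(np.mean(x**2)))
        out[item.label] = AudioClip(samples=x, rate=rate, label=item.label)
    return out


# ---------------------------------------------------------------------------
# WAV I/O (PCM16 and float32)


def read_wav(path: str | Path, label: str = "") -> AudioClip:
    rate, data = _wav.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:  # average channels to mono
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, rate=int(rate), label=label or Path(path).stem)


def write_wav(clip: AudioClip, path: str | Path, *, subtype: str = "float32") -> None:
    if subtype == "float32":
        _wav.write(str(path), clip.rate, clip.samples.astype(np.float32))
    elif subtype == "pcm16":
        x = np.clip(clip.samples, -1.0, 1.0)
        _wav.write(str(path), clip.rate, (x * 32767.0).round().astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r} (float32|pcm16)")
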