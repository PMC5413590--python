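"""Synthetic signal generators and plain-text trial/feature I/O.

Generators cover two needs: multicomponent AM-FM test signals with
controllable spectral overlap for exercising the wavelet machinery, and
labeled two-class multi-channel trials whose classes differ in band power
on chosen channels (1/f-shaped background, like resting EEG). All
randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ewt import Signal
from .features import FeatureMatrix
from .pipeline import Trial, TrialSet

logger = logging.getLogger(__name__)

__all__ = [
    "AmFmComponent",
    "AmFmSpec",
    "TrialSpec",
    "PlantedEffect",
    "gen_amfm",
    "gen_trials",
    "write_trials",
    "read_trials",
    "write_features",
    "read_features",
]


@dataclass(frozen=True)
class AmFmComponent:
    """One AM-FM component: carrier, bandwidth hint, AM rate, chirp rate."""

    center_hz: float
    bandwidth_hz: float = 0.0
    am_hz: float = 0.0
    chirp_hz_per_s: float = 0.0


@dataclass(frozen=True)
class AmFmSpec:
    components: tuple[AmFmComponent, ...]
    duration_s: float
    rate: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = round(self.duration_s * self.rate)
        if n < 64:
            raise ValueError(f"duration x rate = {n} samples; need >= 64")
        for comp in self.components:
            if not (comp.center_hz < self.rate / 2):
                raise ValueError(
                    f"component at {comp.center_hz} Hz exceeds the Nyquist "
                    f"frequency {self.rate / 2} Hz"
                )


def gen_amfm(spec: AmFmSpec) -> Signal:
    """Sum of AM-FM components plus seeded Gaussian noise.

    Component j contributes ``(1 + 0.5 sin(2 pi am_j t)) cos(2 pi (f_j t +
    c_j t^2 / 2) + phi_j)`` with a seeded random phase.
    """
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration_s * spec.rate)
    t = np.arange(n) / spec.rate
    x = np.zeros(n)
    for comp in spec.components:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        envelope = 1.0 + 0.5 * np.sin(2.0 * np.pi * comp.am_hz * t)
        inst = comp.center_hz * t + 0.5 * comp.chirp_hz_per_s * t**2
        x += envelope * np.cos(2.0 * np.pi * inst + phase)
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal(n)
    return Signal(x, spec.rate)


@dataclass(frozen=True)
class PlantedEffect:
    """Class-dependent band power on one channel.

    Class 2 carries ``power_ratio`` times the band power of class 1 in the
    given frequency band of the given (1-based) channel.
    """

    channel: int
    band_hz: tuple[float, float]
    power_ratio: float

    def __post_init__(self) -> None:
        if not (self.power_ratio > 0):
            raise ValueError("power ratio must be positive")
        lo, hi = self.band_hz
        if not (0 <= lo < hi):
            raise ValueError(f"malformed frequency band {self.band_hz}")


@dataclass(frozen=True)
class TrialSpec:
    channels: int = 6
    rate: float = 250.0
    duration_s: float = 10.0
    class_labels: tuple[str, str] = ("A", "B")
    planted: tuple[PlantedEffect, ...] = ()
    trials_per_class: int = 10
    seed: int = 0
    background_sd: float = 1.0
    effect_sd: float = 1.0
    subject: str = "s1"

    def __post_init__(self) -> None:
        for eff in self.planted:
            if not (1 <= eff.channel <= self.channels):
                raise ValueError(
                    f"planted channel {eff.channel} outside 1..{self.channels}"
                )
        if len(self.class_labels) != 2:
            raise ValueError("exactly two class labels required")


def _pink_noise(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shape[0] = 0.0  # zero-mean background
    x = np.fft.irfft(spectrum * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(
    rng: np.random.Generator, n: int, rate: float, lo: float, hi: float
) -> np.ndarray:
    """Band-limited Gaussian noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {lo}-{hi} Hz covers no FFT bin at n={n}")
    x = np.fft.irfft(spectrum * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_trials(spec: TrialSpec) -> TrialSet:
    """Balanced two-class multi-channel trials with planted band effects."""
    rng = np.random.default_rng(spec.seed)
    n = round(spec.duration_s * spec.rate)
    trials: list[Trial] = []
    for class_idx, label in enumerate(spec.class_labels):
        for _ in range(spec.trials_per_class):
            data = np.empty((n, spec.channels))
            for ch in range(spec.channels):
                x = spec.background_sd * _pink_noise(rng, n, spec.rate)
                for eff in spec.planted:
                    if eff.channel == ch + 1:
                        amp = spec.effect_sd
                        if class_idx == 1:
                            amp *= np.sqrt(eff.power_ratio)
                        lo, hi = eff.band_hz
                        x = x + amp * _band_noise(rng, n, spec.rate, lo, hi)
                data[:, ch] = x
            trials.append(Trial(samples=data, label=label, subject=spec.subject))
    return TrialSet(trials=tuple(trials), rate=spec.rate)


_CHANNEL_RE = re.compile(r"^ch(\d+)$")


def write_trials(ts: TrialSet, directory: str | Path) -> None:
    """One TSV per trial (columns ch1..chK) plus a key: value sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for idx, trial in enumerate(ts.trials):
        stem = directory / f"trial_{idx:04d}"
        frame = pd.DataFrame(
            trial.samples,
            columns=[f"ch{c + 1}" for c in range(trial.samples.shape[1])],
        )
        frame.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False,
                     float_format="%.17g")
        stem.with_suffix(".meta").write_text(
            f"rate: {ts.rate!r}\nlabel: {trial.label}\nsubject: {trial.subject}\n"
        )


def _parse_meta(path: Path) -> dict[str, str]:
    meta = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
    return meta


def read_trials(directory: str | Path) -> TrialSet:
    """Read a directory written by :func:`write_trials`."""
    directory = Path(directory)
    files = sorted(directory.glob("trial_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no trial_*.tsv files in {directory}")
    trials: list[Trial] = []
    rate: float | None = None
    n_channels: int | None = None
    for path in files:
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        bad = [c for c in frame.columns if not _CHANNEL_RE.match(c)]
        if bad:
            raise ValueError(f"{path.name}: unknown columns {bad}")
        if n_channels is None:
            n_channels = frame.shape[1]
        elif frame.shape[1] != n_channels:
            raise ValueError(
                f"{path.name}: {frame.shape[1]} channels, expected {n_channels}"
            )
        meta = _parse_meta(path.with_suffix(".meta"))
        trial_rate = float(meta["rate"])
        if rate is None:
            rate = trial_rate
        elif trial_rate != rate:
            raise ValueError(f"{path.name}: rate {trial_rate} != {rate}")
        cols = sorted(frame.columns, key=lambda c: int(_CHANNEL_RE.match(c).group(1)))
        trials.append(
            Trial(
                samples=frame[cols].to_numpy(dtype=float),
                label=meta.get("label", "?"),
                subject=meta.get("subject", "s1"),
            )
        )
    return TrialSet(trials=tuple(trials), rate=float(rate))


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Full-precision TSV with label (and subject) columns first."""
    frame = pd.DataFrame(fm.values, columns=fm.column_names)
    frame.insert(0, "label", fm.labels)
    if fm.subjects is not None:
        frame.insert(1, "subject", fm.subjects)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features(path: str | Path) -> FeatureMatrix:
    """Read a TSV written by :func:`write_features`."""
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "label" not in frame.columns:
        raise ValueError(f"{path}: missing 'label' column")
    labels = frame["label"].to_numpy()
    subjects = frame["subject"].to_numpy() if "subject" in frame.columns else None
    cols = [c for c in frame.columns if c not in ("label", "subject")]
    return FeatureMatrix(
        values=frame[cols].to_numpy(dtype=float),
        column_names=cols,
        labels=labels,
        subjects=subjects,
    )
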