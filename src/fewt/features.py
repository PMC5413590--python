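"""Band refinement and descriptor coding.

The extraction runs in three steps per channel: decompose with the
empirical wavelet bank, re-partition the frequency axis into
non-overlapping bands by fuzzy-clustering per-bin spectral descriptors,
then summarize each band with eight statistical parameters. Because the
bands partition the frequency bins exactly, the band components always
sum back to the original signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .ewt import (
    EWTDecomposition,
    Signal,
    build_filter_bank,
    detect_boundaries,
    ewt_decompose,
)
from .fcm import FuzzyPartition, fcm_fit

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETER_NAMES",
    "EncodeConfig",
    "BandAssignment",
    "DescriptorSet",
    "FeatureMatrix",
    "refine_bands",
    "compute_descriptors",
    "lz76_complexity",
    "encode_window",
]

#: fixed order of the eight per-band parameters
PARAMETER_NAMES = (
    "rms",
    "lz",
    "entropy",
    "cfreq",
    "maxfreq",
    "var",
    "skew",
    "kurt",
)


@dataclass(frozen=True)
class EncodeConfig:
    """Configuration of the per-window encoder.

    ``supports`` is both the number of wavelet segments and the number of
    refined bands. With ``refine=False`` the wavelet components themselves
    are used as bands (no fuzzy re-partitioning), which serves as the
    unrefined baseline extraction.
    """

    supports: int = 3
    gamma: float = 0.1
    fuzzifier: float = 2.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    fcm_restarts: int = 5
    seed: int = 0
    entropy_bins: int = 16
    refine: bool = True

    def with_seed(self, seed: int) -> "EncodeConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class BandAssignment:
    """A hard partition of the positive-frequency bins into bands.

    ``bin_to_band`` maps every bin index (0 .. n_fft//2) to a band label in
    ``0 .. c-1``, ordered by ascending band frequency. ``band_components``
    are the time-domain signals obtained by masking the spectrum to each
    band's bins; they sum to the original signal.
    """

    bin_to_band: np.ndarray
    band_components: tuple[np.ndarray, ...]

    @property
    def n_bands(self) -> int:
        return len(self.band_components)


@dataclass(frozen=True)
class DescriptorSet:
    """The eight per-band statistical parameters."""

    rms: float
    lz_complexity: float
    shannon_entropy: float
    central_frequency: float
    maximum_frequency: float
    variance: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.rms,
                self.lz_complexity,
                self.shannon_entropy,
                self.central_frequency,
                self.maximum_frequency,
                self.variance,
                self.skewness,
                self.kurtosis,
            ]
        )


@dataclass
class FeatureMatrix:
    """Rows of window descriptors with a class label per row."""

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    subjects: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match value columns")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("one label required per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def lz76_complexity(binary: np.ndarray) -> int:
    """Phrase count of the LZ76 exhaustive parsing of a binary sequence."""
    s = np.asarray(binary).astype(np.uint8)
    n = s.size
    if n == 0:
        return 0
    if n == 1:
        return 1
    # Kaspar-Schuster scan
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def compute_descriptors(
    band: np.ndarray, rate: float, entropy_bins: int = 16
) -> DescriptorSet:
    """Summarize one band component with the eight parameters.

    Frequency descriptors (spectral centroid and peak) come from the
    band's power spectrum; the remaining six are time-domain statistics.
    A constant band yields zero variance, and by convention zero skewness,
    kurtosis and entropy.
    """
    x = np.asarray(band, dtype=float)
    if x.size < 8:
        raise ValueError(f"band length {x.size} below minimum of 8")
    n = x.size

    rms = float(np.sqrt(np.mean(x**2)))
    constant = np.ptp(x) == 0.0
    if constant:
        logger.debug("constant band: skewness/kurtosis/entropy set to 0")
        variance = 0.0
        skewness = 0.0
        kurtosis = 0.0
        entropy = 0.0
    else:
        variance = float(np.var(x, ddof=1))
        centered = x - x.mean()
        m2 = np.mean(centered**2)
        m3 = np.mean(centered**3)
        m4 = np.mean(centered**4)
        if m2 > 0:
            skewness = float(m3 / m2**1.5)
            kurtosis = float(m4 / m2**2)
        else:  # numerically constant
            skewness = 0.0
            kurtosis = 0.0
        counts, _ = np.histogram(x, bins=entropy_bins)
        probs = counts[counts > 0] / n
        entropy = float(-np.sum(probs * np.log2(probs)))

    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    total = power.sum()
    if total > 0:
        central = float(np.sum(freqs * power) / total)
    else:
        central = 0.0
    maximum = float(freqs[int(np.argmax(power))])

    binary = x > np.median(x)
    lz = lz76_complexity(binary) * np.log2(n) / n

    return DescriptorSet(
        rms=rms,
        lz_complexity=float(lz),
        shannon_entropy=entropy,
        central_frequency=central,
        maximum_frequency=maximum,
        variance=variance,
        skewness=skewness,
        kurtosis=kurtosis,
    )


def _bin_weights(spectrum: np.ndarray, n: int) -> np.ndarray:
    """Normalized spectral-power weight per positive-frequency bin."""
    n_bins = n // 2 + 1
    power = np.abs(spectrum[:n_bins]) ** 2
    total = power.sum()
    if total <= 0:  # silent window: uniform weights
        return np.full(n_bins, 1.0 / n_bins)
    return power / total


def _band_masks(bin_to_band: np.ndarray, n: int, c: int) -> list[np.ndarray]:
    """Full-length spectral masks with conjugate-symmetric completion."""
    masks = []
    for b in range(c):
        mask = np.zeros(n)
        bins = np.flatnonzero(bin_to_band == b)
        mask[bins] = 1.0
        mirrored = (n - bins) % n
        mask[mirrored] = 1.0
        masks.append(mask)
    return masks


def refine_bands(
    sig: Signal,
    dec: EWTDecomposition | None,
    c: int,
    config: EncodeConfig | None = None,
) -> BandAssignment:
    """Re-partition the frequency axis into ``c`` non-overlapping bands.

    Fuzzy c-means is run over the normalized bin frequencies, with each
    bin's contribution weighted by its share of the spectral power, so
    cluster centroids settle on the signal's spectral mass. Several seeded
    restarts are taken (lowest final objective wins); every bin goes to
    its maximum-membership cluster, and clusters are relabeled by
    ascending membership-weighted mean frequency. Band components are
    inverse transforms of the spectrum masked to each band.
    """
    config = config or EncodeConfig()
    x = sig.samples
    n = x.size
    n_bins = n // 2 + 1
    if c < 1:
        raise ValueError(f"number of bands must be >= 1, got {c}")
    if c >= n_bins:
        raise ValueError(f"number of bands {c} must be below bin count {n_bins}")
    if dec is not None and dec.n_components != c:
        raise ValueError(
            f"decomposition has {dec.n_components} components but c={c}"
        )

    spectrum = np.fft.fft(x)
    if c == 1:
        bin_to_band = np.zeros(n_bins, dtype=int)
        return BandAssignment(bin_to_band, (x.copy(),))

    omega = 2.0 * np.pi * np.arange(n_bins) / n
    weights = _bin_weights(spectrum, n)
    best: FuzzyPartition | None = None
    for r in range(config.fcm_restarts):
        part = fcm_fit(
            omega[:, None],
            c=c,
            m=config.fuzzifier,
            tol=config.fcm_tol,
            max_iter=config.fcm_max_iter,
            seed=config.seed + r,
            weights=weights,
        )
        if best is None or part.objective < best.objective:
            best = part

    u = best.memberships
    weighted_freq = (u @ omega) / u.sum(axis=1)
    order = np.argsort(weighted_freq, kind="stable")
    relabel = np.empty(c, dtype=int)
    relabel[order] = np.arange(c)
    bin_to_band = relabel[np.argmax(u, axis=0)]

    components = tuple(
        np.fft.ifft(spectrum * mask).real
        for mask in _band_masks(bin_to_band, n, c)
    )
    return BandAssignment(bin_to_band, components)


def encode_window(
    samples: np.ndarray,
    rate: float,
    config: EncodeConfig | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Encode one multi-channel window into a single feature row.

    ``samples`` is shaped ``(n_samples, n_channels)``. Per channel: a
    wavelet bank is fitted to the channel spectrum, the signal decomposed,
    bands refined (unless ``config.refine`` is off), and every band coded
    with the eight parameters. The row is channel-major: channel 1 band 1
    parameters 1-8, channel 1 band 2, ... Returns the row and its column
    names.
    """
    config = config or EncodeConfig()
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, n_channels = x.shape
    min_len = max(16, 4 * config.supports)
    row: list[float] = []
    names: list[str] = []
    for ch in range(n_channels):
        channel = x[:, ch]
        if n < min_len:
            raise ValueError(
                f"channel {ch + 1} has {n} samples, below the minimum of "
                f"{min_len} for {config.supports} supports"
            )
        sig = Signal(channel, rate)
        mag = np.abs(np.fft.rfft(channel))
        seg = detect_boundaries(mag, config.supports, config.gamma)
        bank = build_filter_bank(seg, n)
        dec = ewt_decompose(sig, bank)
        if config.refine:
            ch_config = config.with_seed(config.seed + 10_000 * ch)
            n_bands = dec.n_components
            assignment = refine_bands(sig, dec, n_bands, ch_config)
            bands = assignment.band_components
        else:
            bands = dec.components
        for b, band in enumerate(bands):
            d = compute_descriptors(band, rate, config.entropy_bins)
            row.extend(d.as_array())
            names.extend(
                f"ch{ch + 1}_b{b + 1}_{p}" for p in PARAMETER_NAMES
            )
    return np.asarray(row), names
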