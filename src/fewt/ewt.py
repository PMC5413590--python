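"""Empirical wavelet transform on a data-driven spectrum segmentation.

Everything works in normalized angular frequency: a real signal's spectrum
lives on ``[0, pi]``, segment boundaries are placed between spectral peaks,
and every segment receives a frequency-domain filter with smooth cosine/sine
transition zones. The squared filter magnitudes sum to one at every
frequency (tight frame), which gives exact reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Signal",
    "SpectrumSegmentation",
    "EmpiricalWaveletBank",
    "EWTDecomposition",
    "meyer_beta",
    "detect_boundaries",
    "build_filter_bank",
    "ewt_decompose",
    "ewt_reconstruct",
]


def meyer_beta(x: np.ndarray | float) -> np.ndarray:
    """Meyer transition polynomial ``x^4 (35 - 84x + 70x^2 - 20x^3)``.

    Satisfies ``beta(0) = 0``, ``beta(1) = 1`` and ``beta(x) + beta(1-x) = 1``,
    the symmetry the tight-frame identity of the filter bank relies on.
    Values outside ``[0, 1]`` are clipped to the boundary values.
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units); at least two, all finite.
    rate
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be one-dimensional with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (self.rate > 0):
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "rate", float(self.rate))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class SpectrumSegmentation:
    """A partition of ``[0, pi]`` into contiguous frequency segments.

    ``boundaries`` holds ``w_0 .. w_N`` with ``w_0 = 0`` and ``w_N = pi``;
    ``halfwidths`` holds one transition half-width per *internal* boundary
    (``N - 1`` values). The transition zone around an internal boundary must
    not reach past the midpoints to its neighbours, so that the zones of
    adjacent boundaries never overlap.
    """

    boundaries: np.ndarray
    halfwidths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        bnd = np.asarray(self.boundaries, dtype=float)
        hw = np.asarray(self.halfwidths, dtype=float)
        if bnd.ndim != 1 or bnd.size < 2:
            raise ValueError("need at least the two outer boundaries 0 and pi")
        if not np.isclose(bnd[0], 0.0, atol=1e-12):
            raise ValueError("first boundary must be 0")
        if not np.isclose(bnd[-1], np.pi, atol=1e-12):
            raise ValueError("last boundary must be pi")
        if np.any(np.diff(bnd) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if hw.size != bnd.size - 2:
            raise ValueError(
                f"expected {bnd.size - 2} halfwidths for {bnd.size - 2} internal "
                f"boundaries, got {hw.size}"
            )
        for i, tau in enumerate(hw, start=1):
            left_gap = bnd[i] - bnd[i - 1]
            right_gap = bnd[i + 1] - bnd[i]
            limit = min(left_gap, right_gap) / 2.0
            if not (0.0 < tau < limit):
                raise ValueError(
                    f"halfwidth tau_{i}={tau:.6g} at boundary w_{i}={bnd[i]:.6g} "
                    f"violates 0 < tau < {limit:.6g} (adjacent transition zones "
                    "would overlap)"
                )
        object.__setattr__(self, "boundaries", bnd)
        object.__setattr__(self, "halfwidths", hw)

    @property
    def n_segments(self) -> int:
        return self.boundaries.size - 1


@dataclass(frozen=True)
class EmpiricalWaveletBank:
    """Discretized frequency-domain filters for one segmentation.

    ``scaling`` is the low-pass filter; ``wavelets`` holds one bandpass
    filter per remaining segment. All filters are even in frequency and
    evaluated on the full FFT grid of length ``fft_length``.
    """

    grid: np.ndarray
    scaling: np.ndarray
    wavelets: tuple[np.ndarray, ...]
    segmentation: SpectrumSegmentation
    beta_kind: str = "meyer"

    @property
    def fft_length(self) -> int:
        return self.grid.size

    @property
    def n_components(self) -> int:
        return 1 + len(self.wavelets)


@dataclass(frozen=True)
class EWTDecomposition:
    """Approximation plus detail components of one signal."""

    approx: np.ndarray
    details: tuple[np.ndarray, ...]
    bank: EmpiricalWaveletBank

    @property
    def components(self) -> tuple[np.ndarray, ...]:
        return (self.approx,) + self.details

    @property
    def n_components(self) -> int:
        return 1 + len(self.details)


def _local_maxima(mag: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (both neighbours strictly smaller)."""
    if mag.size < 3:
        return np.empty(0, dtype=int)
    interior = np.arange(1, mag.size - 1)
    mask = (mag[interior] > mag[interior - 1]) & (mag[interior] > mag[interior + 1])
    return interior[mask]


def detect_boundaries(
    spectrum_magnitude: np.ndarray,
    n_supports: int,
    gamma: float = 0.1,
) -> SpectrumSegmentation:
    """Place segment boundaries between the strongest spectral peaks.

    The magnitude spectrum is read on a uniform grid over ``[0, pi]``. The
    ``n_supports`` largest strict local maxima are kept (ties broken toward
    lower frequency) and internal boundaries sit at the midpoints between
    consecutive peaks. Transition half-widths are ``gamma * w_n``, clipped
    so adjacent transition zones cannot overlap.

    Falls back to an equal-width segmentation (with a logged warning) when
    the spectrum does not expose enough distinct local maxima.
    """
    mag = np.asarray(spectrum_magnitude, dtype=float)
    if n_supports < 1:
        raise ValueError(f"n_supports must be >= 1, got {n_supports}")
    if mag.ndim != 1 or mag.size < 2 * n_supports:
        raise ValueError(
            f"spectrum of length {mag.size} too short for {n_supports} supports"
        )
    if np.any(mag < 0):
        raise ValueError("spectrum magnitude must be non-negative")
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")

    if n_supports == 1:
        return SpectrumSegmentation(np.array([0.0, np.pi]))

    omega = np.pi * np.arange(mag.size) / (mag.size - 1)
    peaks = _local_maxima(mag)
    if peaks.size < n_supports:
        logger.warning(
            "only %d local maxima for %d supports; falling back to "
            "equal-width segmentation",
            peaks.size,
            n_supports,
        )
        internal = np.pi * np.arange(1, n_supports) / n_supports
    else:
        # ties broken by lower frequency: stable sort on descending magnitude
        order = np.argsort(-mag[peaks], kind="stable")
        chosen = np.sort(peaks[order[:n_supports]])
        internal = (omega[chosen[:-1]] + omega[chosen[1:]]) / 2.0

    boundaries = np.concatenate(([0.0], internal, [np.pi]))
    gaps = np.diff(boundaries)
    halfwidths = np.empty(internal.size)
    for i in range(internal.size):
        limit = min(gaps[i], gaps[i + 1]) / 2.0
        halfwidths[i] = min(gamma * internal[i], (1.0 - 1e-9) * limit)
    return SpectrumSegmentation(boundaries, halfwidths)


def _transition(w: np.ndarray, center: float, tau: float, kind: str) -> np.ndarray:
    """Evaluate the cosine/sine transition around one internal boundary."""
    arg = (w - center + tau) / (2.0 * tau)
    if kind == "cos":
        return np.cos(np.pi / 2.0 * meyer_beta(arg))
    return np.sin(np.pi / 2.0 * meyer_beta(arg))


def build_filter_bank(
    seg: SpectrumSegmentation, fft_length: int
) -> EmpiricalWaveletBank:
    """Evaluate the scaling and wavelet filters on the discrete FFT grid.

    The filters are even in frequency; the grid carries ``|w|`` for every
    FFT bin so the same expressions cover the negative half-axis. The outer
    boundaries at 0 and ``pi`` have no transition zone.
    """
    if fft_length < 4:
        raise ValueError(f"fft_length must be >= 4, got {fft_length}")
    w = np.abs(2.0 * np.pi * np.fft.fftfreq(fft_length))

    bnd = seg.boundaries
    hw = seg.halfwidths
    n_seg = seg.n_segments

    if n_seg == 1:
        scaling = np.ones(fft_length)
        return EmpiricalWaveletBank(w, scaling, (), seg)

    # low-pass: flat to w1 - tau1, cosine roll-off across the transition
    w1, t1 = bnd[1], hw[0]
    scaling = np.zeros(fft_length)
    flat = w <= w1 - t1
    trans = (~flat) & (w <= w1 + t1)
    scaling[flat] = 1.0
    scaling[trans] = _transition(w[trans], w1, t1, "cos")

    wavelets = []
    for n in range(1, n_seg):
        lo, t_lo = bnd[n], hw[n - 1]
        hi = bnd[n + 1]
        t_hi = hw[n] if n < n_seg - 1 else 0.0
        psi = np.zeros(fft_length)
        rise = (w >= lo - t_lo) & (w <= lo + t_lo)
        psi[rise] = _transition(w[rise], lo, t_lo, "sin")
        if t_hi > 0.0:
            flat = (w > lo + t_lo) & (w < hi - t_hi)
            fall = (w >= hi - t_hi) & (w <= hi + t_hi)
            psi[fall] = _transition(w[fall], hi, t_hi, "cos")
        else:
            flat = (w > lo + t_lo)  # last band extends to pi
        psi[flat] = 1.0
        wavelets.append(psi)

    return EmpiricalWaveletBank(w, scaling, tuple(wavelets), seg)


def ewt_decompose(sig: Signal, bank: EmpiricalWaveletBank) -> EWTDecomposition:
    """Project the signal onto every filter of the bank.

    Each component is the inverse FFT of the signal spectrum multiplied by
    the (real, even) filter; the round-off imaginary residue is discarded.
    """
    x = sig.samples
    if x.size != bank.fft_length:
        raise ValueError(
            f"signal length {x.size} does not match bank grid length "
            f"{bank.fft_length}"
        )
    spectrum = np.fft.fft(x)
    approx = np.fft.ifft(spectrum * bank.scaling).real
    details = tuple(np.fft.ifft(spectrum * psi).real for psi in bank.wavelets)
    return EWTDecomposition(approx, details, bank)


def ewt_reconstruct(dec: EWTDecomposition) -> np.ndarray:
    """Resynthesize the signal from its components (spectral-domain sum)."""
    if dec.bank is None:
        raise ValueError("decomposition carries no filter bank")
    bank = dec.bank
    total = np.fft.fft(dec.approx) * bank.scaling
    for comp, psi in zip(dec.details, bank.wavelets):
        total = total + np.fft.fft(comp) * psi
    return np.fft.ifft(total).real
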