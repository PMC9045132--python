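"""Welch power spectral density and band-power features.

The PSD of each 5-min segment is estimated with Welch's method: 5-s Hamming
windows, 50% overlap, and median averaging across windows to limit the
influence of transient artifacts. Absolute band power is the integral of
the density over each canonical band, total power the integral over
0.5-40 Hz, and relative power the ratio of the two. The spectral feature
block is 13 values: six absolute band powers, the total power, and six
relative powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class WelchParams:
    window_s: float = 5.0
    overlap: float = 0.5
    window: str = "hamming"
    averaging: str = "median"  # "median" or "mean"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.averaging not in ("median", "mean"):
            raise ValueError("averaging must be 'median' or 'mean'")


#: conventional band edges tiling the 0.5-40 Hz total range exactly
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class BandScheme:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    total: tuple[float, float] = (0.5, 40.0)

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        lo, hi = self.total
        if edges[0][0] != lo or edges[-1][1] != hi:
            raise ValueError("bands must span exactly the total range")
        for (a0, a1), (b0, b1) in zip(edges, edges[1:]):
            if a1 != b0:
                raise ValueError("bands must be contiguous and ordered")

    @property
    def names(self) -> list[str]:
        return list(self.bands)


def welch_psd(x, sampling_rate, params: WelchParams | None = None):
    """One-sided Welch PSD. Returns (frequencies Hz, density uV^2/Hz)."""
    params = params or WelchParams()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(params.window_s * sampling_rate))
    if x.size < nperseg:
        raise ValueError("segment shorter than one Welch window")
    noverlap = int(round(params.overlap * nperseg))
    if params.averaging == "mean":
        freqs, psd = sps.welch(x, fs=sampling_rate, window=params.window,
                               nperseg=nperseg, noverlap=noverlap,
                               detrend=False, average="mean")
    else:
        # raw per-window periodograms, aggregated by the plain median
        # (no small-sample bias correction: the relative powers that
        # drive the analysis are unaffected by a common factor)
        freqs, _, spec = sps.spectrogram(
            x, fs=sampling_rate, window=params.window, nperseg=nperseg,
            noverlap=noverlap, detrend=False, scaling="density", mode="psd")
        psd = np.median(spec, axis=-1)
    return freqs, psd


def band_integral(freqs, psd, lo, hi):
    """Trapezoid integral of the density over [lo, hi] with interpolated
    fractional end bins."""
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside PSD grid [{freqs[0]}, {freqs[-1]}]")
    inside = (freqs > lo) & (freqs < hi)
    f = np.r_[lo, freqs[inside], hi]
    p = np.r_[np.interp(lo, freqs, psd), psd[inside], np.interp(hi, freqs, psd)]
    return float(np.trapezoid(p, f))


SPECTRAL_FEATURE_NAMES = (
    ["pow_delta", "pow_theta", "pow_alpha", "pow_sigma", "pow_beta",
     "pow_gamma", "pow_total"]
    + ["relpow_delta", "relpow_theta", "relpow_alpha", "relpow_sigma",
       "relpow_beta", "relpow_gamma"]
)


def band_powers(freqs, psd, scheme: BandScheme | None = None) -> np.ndarray:
    """The 13 spectral features: 6 absolute powers, total power, 6 relative.

    Order matches ``SPECTRAL_FEATURE_NAMES``.
    """
    scheme = scheme or BandScheme()
    lo, hi = scheme.total
    if freqs[0] > lo or freqs[-1] < hi:
        raise ValueError("PSD grid does not cover the total range")
    absolute = np.array([band_integral(freqs, psd, a, b)
                         for a, b in scheme.bands.values()])
    total = band_integral(freqs, psd, lo, hi)
    relative = absolute / total if total > 0 else np.zeros_like(absolute)
    return np.r_[absolute, total, relative]
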