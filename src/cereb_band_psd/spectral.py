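"""Periodogram PSD estimation and band-AUC quantification.

The PSD is a plain one-sided periodogram (rectangular taper, mean
removed), in uV^2/Hz, satisfying Parseval's identity: the PSD summed
over the frequency grid times the bin width equals the mean square of
the detrended trace.

Band AUC is the discrete integral of the PSD over a frequency band.
Bands are half-open ``[f1, f2)`` with the *final* band of a partition
closed at its upper edge, so that contiguous bands partition their range
exactly; an edge-inclusive sum on both sides would double-count PSD bins
that fall exactly on shared band edges.  The normalized band PSD is the
AUC divided by the bandwidth, so a flat spectrum of height ``c``
normalizes to ``c`` for any on-grid band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "PsdEstimate",
    "BandPower",
    "DEFAULT_BANDS",
    "scaled_bands",
    "periodogram",
    "band_auc",
    "normalized_band_psd",
    "band_table",
]

#: The six analysis bands (Hz) of the protocol.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (300.0, 500.0),
    (500.0, 1000.0),
    (1000.0, 1500.0),
    (1500.0, 2000.0),
    (2000.0, 2500.0),
    (2500.0, 3000.0),
)


def scaled_bands(factor: float) -> tuple[tuple[float, float], ...]:
    """The six analysis bands scaled by ``factor`` (for reduced designs)."""
    return tuple((lo * factor, hi * factor) for lo, hi in DEFAULT_BANDS)


@dataclass
class PsdEstimate:
    """One-sided periodogram estimate on a uniform frequency grid."""

    frequencies: np.ndarray  # Hz, strictly increasing, spacing df
    values: np.ndarray  # uV^2 / Hz, >= 0
    df: float  # bin width, fs / n_samples
    n_samples: int
    window: str = "boxcar"

    def total_power(self) -> float:
        """Parseval sum: integral of the PSD over the full grid (uV^2)."""
        return float(self.values.sum() * self.df)


@dataclass
class BandPower:
    """Band-integrated power for one frequency band."""

    band: tuple[float, float]
    auc: float  # uV^2
    normalized_psd: float  # uV^2 / Hz
    fraction: float  # share of the total-range AUC

    @property
    def bandwidth(self) -> float:
        return self.band[1] - self.band[0]


def periodogram(
    x: np.ndarray, fs: float, window: str = "boxcar", detrend: str = "constant"
) -> PsdEstimate:
    """One-sided periodogram PSD of a trace.

    Parameters
    ----------
    x : array
        Trace samples (uV); length >= 2.  The mean is removed before the
        transform.  An all-zero trace yields a valid all-zero PSD.
    fs : float
        Sample rate (Hz).
    window : str
        Taper name; ``"boxcar"`` (plain periodogram) by default.

    Returns
    -------
    PsdEstimate
        Density-scaled (uV^2/Hz) estimate with ``df = fs / len(x)``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    freqs, psd = _sig.periodogram(x, fs=fs, window=window, detrend=detrend, scaling="density")
    return PsdEstimate(
        frequencies=freqs, values=psd, df=fs / x.size, n_samples=x.size, window=window
    )


def _band_mask(psd: PsdEstimate, f1: float, f2: float, closed_right: bool) -> np.ndarray:
    f = psd.frequencies
    # Tolerance so that on-grid edges are classified consistently despite
    # floating-point frequency grids.
    tol = 1e-9 * max(abs(f2), 1.0)
    if closed_right:
        return (f >= f1 - tol) & (f <= f2 + tol)
    return (f >= f1 - tol) & (f < f2 - tol)


def band_auc(psd: PsdEstimate, f1: float, f2: float, closed_right: bool = False) -> float:
    """Discrete band integral: sum of ``PSD(fj) * df`` over ``f1 <= fj < f2``
    (``<= f2`` when ``closed_right``).  An empty bin set returns 0 with a
    warning."""
    if not f1 < f2:
        raise ValueError(f"need f1 < f2, got ({f1}, {f2})")
    mask = _band_mask(psd, f1, f2, closed_right)
    if not mask.any():
        warnings.warn(f"band [{f1}, {f2}) contains no PSD bins", UserWarning, stacklevel=2)
        return 0.0
    return float(psd.values[mask].sum() * psd.df)


def normalized_band_psd(
    psd: PsdEstimate, band: tuple[float, float], closed_right: bool = False
) -> float:
    """Band AUC divided by bandwidth (uV^2/Hz); a flat PSD of height ``c``
    returns ``c`` exactly for on-grid half-open bands."""
    f1, f2 = band
    if f2 <= f1:
        raise ValueError(f"band must have positive width, got {band}")
    return band_auc(psd, f1, f2, closed_right=closed_right) / (f2 - f1)


def band_table(
    psd: PsdEstimate,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
    total_band: tuple[float, float] | None = None,
) -> list[BandPower]:
    """Per-band AUC, normalized PSD and fraction of the total-range AUC.

    ``bands`` must be non-overlapping and increasing; contiguous bands
    partition the total range exactly (half-open bins, last band closed).
    The fraction denominator defaults to the AUC over the full span of
    ``bands``.
    """
    bands = tuple(tuple(b) for b in bands)
    for lo, hi in bands:
        if not lo < hi:
            raise ValueError(f"invalid band ({lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if lo2 < hi1:
            raise ValueError(f"bands overlap or are out of order: ({lo1}, {hi1}) vs ({lo2}, {hi2})")
    if total_band is None:
        total_band = (bands[0][0], bands[-1][1])
    total = band_auc(psd, total_band[0], total_band[1], closed_right=True)

    out = []
    for i, (lo, hi) in enumerate(bands):
        auc = band_auc(psd, lo, hi, closed_right=(i == len(bands) - 1))
        out.append(
            BandPower(
                band=(lo, hi),
                auc=auc,
                normalized_psd=auc / (hi - lo),
                fraction=auc / total if total > 0 else np.nan,
            )
        )
    return out
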