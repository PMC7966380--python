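"""Motility quantification: cross-section series, spectral peak frequency,
rank-sum group comparison, phantom contrast, FWHM, and diameter change.

The spectral estimator is a Hann-windowed periodogram of the detrended
cross-section series; the peak is the argmax of the magnitude spectrum in a
physiological band (default 0.1-2.0 Hz, bracketing both the anesthetized
and free-moving segmentation rates).  The group test is the two-sided
Wilcoxon rank-sum, exact by full enumeration for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .stmap import SpatioTemporalMap


class MetricsError(ValueError):
    pass


@dataclass
class CrossSectionSeries:
    """Average cross-section signal over time at one intestine location."""

    values: np.ndarray
    frame_rate: float
    position_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.frame_rate <= 0:
            raise MetricsError("frame_rate must be positive")


@dataclass
class FrequencyResult:
    peak_frequency: float       # Hz
    frequencies: np.ndarray     # Hz, analysis band
    amplitude: np.ndarray       # magnitude spectrum over the band
    band: tuple[float, float]
    bin_width: float            # Hz


@dataclass
class PhantomMetrics:
    a_background: float
    a_tube: float
    contrast: float
    fwhm: float                 # px


@dataclass
class DiameterChange:
    ratio: float                # fwhm(contracted) / fwhm(resting)
    change: float               # 1 - ratio


# --------------------------------------------------------------------------


def cross_section_series(st_map: SpatioTemporalMap,
                         position_range: tuple[int, int]) -> CrossSectionSeries:
    """Mean over a row range of the ST map, per time column."""
    lo, hi = position_range
    if not (0 <= lo < hi <= st_map.n_positions):
        raise MetricsError(
            f"position range [{lo}, {hi}) outside map rows [0, {st_map.n_positions})")
    return CrossSectionSeries(st_map.values[lo:hi].mean(axis=0),
                              st_map.frame_rate, (lo, hi))


def peak_frequency(series: CrossSectionSeries,
                   band: tuple[float, float] = (0.1, 2.0)) -> FrequencyResult:
    """Dominant frequency of a cross-section series within a band.

    Mean and linear trend are removed, a Hann window applied, and the
    magnitude of the discrete Fourier transform maximized over the band.
    The spectral bin width is frame_rate / n.
    """
    f_lo, f_hi = band
    fs = series.frame_rate
    y = np.asarray(series.values, float)
    n = y.size
    if fs <= 2.0 * f_hi:
        raise MetricsError(
            f"Nyquist violated: band up to {f_hi} Hz requires frame rate > {2 * f_hi} Hz")
    if n / fs < 2.0 / f_lo:
        raise MetricsError(
            f"series too short: need at least {2.0 / f_lo:.1f} s for f_lo = {f_lo} Hz")
    t = np.arange(n)
    y = y - np.polyval(np.polyfit(t, y, 1), t)
    if np.allclose(y, 0.0):
        raise MetricsError("series is constant: no spectral peak in band")
    spec = np.abs(np.fft.rfft(y * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not mask.any():
        raise MetricsError("no spectral bins inside the band")
    fb = freqs[mask]
    sb = spec[mask]
    return FrequencyResult(float(fb[int(np.argmax(sb))]), fb, sb, band, fs / n)


# --------------------------------------------------------------------------
# group comparison


def compare_frequencies(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups of peaks.

    Exact by enumeration of all rank assignments when min(n, m) <= 8
    (ties mid-ranked; p = 2 * min(lower tail, upper tail), capped at 1);
    tie-corrected normal approximation for larger samples.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise MetricsError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    total = n + m
    if min(n, m) <= 8:
        count = c_le = c_ge = 0
        for idx in combinations(range(total), n):
            s = ranks[list(idx)].sum()
            count += 1
            if s <= w_obs + 1e-9:
                c_le += 1
            if s >= w_obs - 1e-9:
                c_ge += 1
        return min(1.0, 2.0 * min(c_le, c_ge) / count)
    mu = n * (total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / (total * (total - 1.0))) if total > 1 else 0.0
    var = n * m / 12.0 * (total + 1.0 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# phantom metrics


def contrast_parameter(a_background: float, a_tube: float) -> float:
    """Contrast = (A_b - A_t) / A_t; darker tube on brighter background is larger."""
    if a_tube <= 0:
        raise MetricsError("tube amplitude must be positive")
    return (a_background - a_tube) / a_tube


def _baseline(profile: np.ndarray) -> float:
    n = profile.size
    k = max(1, int(round(0.1 * n)))
    return float(np.median(np.concatenate([profile[:k], profile[-k:]])))


def profile_fwhm(profile) -> float:
    """Full width at half depth of a single dominant dip (or peak), in px.

    The baseline is the median of the outer 20% of samples; the width is
    measured at half the extremum depth with linear interpolation at the
    crossings.
    """
    p = np.asarray(profile, float)
    if p.size < 3:
        raise MetricsError("profile too short")
    base = _baseline(p)
    # dips (tube shadows) are the native orientation; invert peaks
    d = base - p if (base - p.min()) >= (p.max() - base) else p - base
    i0 = int(np.argmax(d))
    depth = d[i0]
    if depth <= 0:
        raise MetricsError("profile has no extremum relative to baseline")
    half = depth / 2.0
    left = right = None
    for i in range(i0, 0, -1):
        if d[i - 1] < half <= d[i]:
            left = (i - 1) + (half - d[i - 1]) / (d[i] - d[i - 1])
            break
    for i in range(i0, p.size - 1):
        if d[i + 1] < half <= d[i]:
            right = i + (d[i] - half) / (d[i] - d[i + 1])
            break
    if left is None or right is None:
        raise MetricsError("no half-depth crossing on one side of the extremum")
    return float(right - left)


def phantom_metrics(profile) -> PhantomMetrics:
    """Background/tube amplitudes, Contrast = (A_b - A_t)/A_t, and FWHM.

    A_b is the outer-20% baseline; A_t is the mean amplitude inside the
    FWHM interval of the tube shadow.
    """
    p = np.asarray(profile, float)
    a_b = _baseline(p)
    fwhm = profile_fwhm(p)
    i0 = int(np.argmin(p))
    lo = max(0, int(math.floor(i0 - fwhm / 2)))
    hi = min(p.size, int(math.ceil(i0 + fwhm / 2)) + 1)
    a_t = float(p[lo:hi].mean())
    return PhantomMetrics(a_b, a_t, contrast_parameter(a_b, a_t), fwhm)


def diameter_change(resting_profile, contracted_profile) -> DiameterChange:
    """FWHM ratio of contracted to resting cross-sections (diameter proxy)."""
    r = profile_fwhm(resting_profile)
    c = profile_fwhm(contracted_profile)
    ratio = c / r
    return DiameterChange(float(ratio), float(1.0 - ratio))


# --------------------------------------------------------------------------
# motor-pattern discrimination


def spectral_asymmetry(S: np.ndarray) -> float:
    """Directional energy asymmetry of the 2D spectrum of an ST map.

    A traveling (peristaltic) band concentrates spectral energy in one
    diagonal quadrant pair of the (spatial, temporal) frequency plane —
    the Fourier dual of the 2D autocorrelation peak lying off the time
    axis.  A standing (segmentation) rhythm is quadrant-symmetric.
    Returns (E_diag1 - E_diag2) / (E_diag1 + E_diag2) in [-1, 1].
    """
    X = np.asarray(S, float)
    X = X - X.mean(axis=1, keepdims=True)   # remove the static spatial profile
    P = np.abs(np.fft.fftshift(np.fft.fft2(X))) ** 2
    cs, ct = P.shape[0] // 2, P.shape[1] // 2
    e1 = P[cs + 1:, ct + 1:].sum() + P[:cs, :ct].sum()
    e2 = P[cs + 1:, :ct].sum() + P[:cs, ct + 1:].sum()
    if e1 + e2 == 0:
        return 0.0
    return float((e1 - e2) / (e1 + e2))


def classify_motor_pattern(st_map: SpatioTemporalMap | np.ndarray,
                           asymmetry_threshold: float = 0.3) -> str:
    """Label an ST map 'peristalsis' (propagating) or 'segmentation'."""
    S = st_map.values if isinstance(st_map, SpatioTemporalMap) else st_map
    asym = spectral_asymmetry(S)
    return "peristalsis" if abs(asym) > asymmetry_threshold else "segmentation"
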