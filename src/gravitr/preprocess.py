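"""Load-cell denoising: MODWT spike detection, interpolation, differencing.

Raw gravimetric traces mix slow evapotranspiration loss with sharp
irrigation refills and short drainage transients.  The maximal overlap
discrete wavelet transform (MODWT) is shift-invariant and keeps one
coefficient per time index at every level, so a boxplot outlier rule on the
fine-scale detail coefficients pinpoints anomalous samples directly on the
original time axis.  Flagged samples are removed, the gaps linearly
interpolated, and the cleaned weights differenced at lag 1 to give the
15-min evapotranspiration (ETr) profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

SQRT2 = np.sqrt(2.0)


@dataclass
class WaveletDecomposition:
    """Same-length MODWT detail vectors per level plus the level-J smooth."""

    details: list          # details[j-1] is the level-j detail vector
    smooth: np.ndarray     # level-J scaling coefficients
    wavelet: str
    level: int
    n: int

    def __post_init__(self):
        assert len(self.details) == self.level


@dataclass
class OutlierMask:
    """Time indices flagged as anomalous, with the flagging level(s)."""

    flagged: np.ndarray                 # sorted unique time indices
    source_level: dict = field(default_factory=dict)  # index -> set of levels
    n: int = 0

    def __len__(self):
        return self.flagged.size


def _modwt_filters(wavelet: str):
    w = pywt.Wavelet(wavelet)
    # MODWT uses the orthonormal filters rescaled by 1/sqrt(2)
    g = np.asarray(w.dec_lo, dtype=float) / SQRT2
    h = np.asarray(w.dec_hi, dtype=float) / SQRT2
    return g, h


def _circular_filter(v: np.ndarray, f: np.ndarray, stride: int) -> np.ndarray:
    # out[t] = sum_l f[l] * v[(t - stride*l) mod N]
    out = np.zeros_like(v)
    for l, fl in enumerate(f):
        out += fl * np.roll(v, stride * l)
    return out


def _circular_unfilter(w: np.ndarray, f: np.ndarray, stride: int) -> np.ndarray:
    # adjoint: out[t] = sum_l f[l] * w[(t + stride*l) mod N]
    out = np.zeros_like(w)
    for l, fl in enumerate(f):
        out += fl * np.roll(w, -stride * l)
    return out


def min_length_for_level(level: int, wavelet: str = "db2") -> int:
    """Smallest series length for which a level-``level`` MODWT is meaningful.

    The equivalent level-j filter spans (L-1)(2^j - 1) + 1 samples; the
    series must be at least that long.
    """
    L = pywt.Wavelet(wavelet).dec_len
    return (L - 1) * (2 ** level - 1) + 1


def modwt_decompose(x, level: int = 3, wavelet: str = "db2") -> WaveletDecomposition:
    """Periodic MODWT of ``x`` to ``level`` levels.

    Returns one detail vector per level and the final smooth vector, each
    the same length as ``x``.  Energy is preserved:
    ||x||^2 = sum_j ||W_j||^2 + ||V_J||^2.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if np.isnan(x).any():
        raise ValueError("missing values must be interpolated before MODWT")
    need = min_length_for_level(level, wavelet)
    if x.size < need:
        raise ValueError(
            f"series of length {x.size} too short for level {level}; "
            f"need at least {need} samples"
        )
    g, h = _modwt_filters(wavelet)
    v = x.copy()
    details = []
    for j in range(1, level + 1):
        stride = 2 ** (j - 1)
        details.append(_circular_filter(v, h, stride))
        v = _circular_filter(v, g, stride)
    return WaveletDecomposition(details=details, smooth=v, wavelet=wavelet,
                                level=level, n=x.size)


def modwt_reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse MODWT; exact up to floating-point rounding."""
    g, h = _modwt_filters(dec.wavelet)
    v = dec.smooth.copy()
    for j in range(dec.level, 0, -1):
        stride = 2 ** (j - 1)
        v = (_circular_unfilter(dec.details[j - 1], h, stride)
             + _circular_unfilter(v, g, stride))
    return v


def _level_offset(level: int, wavelet: str) -> int:
    """Circular shift aligning level-j coefficients with the time axis.

    A level-j coefficient at index t depends on samples
    t, t-1, ..., t-(L_j - 1) where L_j is the equivalent filter span; the
    centre of that support, (L_j - 1) // 2 samples back, is taken as the
    aligned time index.
    """
    L = pywt.Wavelet(wavelet).dec_len
    span = (L - 1) * (2 ** level - 1) + 1
    return (span - 1) // 2


def detect_spike_outliers(dec: WaveletDecomposition, levels=(1, 2, 3),
                          iqr_multiplier: float = 1.5) -> OutlierMask:
    """Boxplot rule on detail coefficients of the requested levels.

    Per level, coefficients outside [Q1 - k*IQR, Q3 + k*IQR] are flagged;
    each flagged coefficient is mapped to its aligned time index
    (shift-corrected for the filter's support) and the union over levels is
    returned.

    The first L_j - 1 "boundary" coefficients of each level depend on the
    periodic wrap-around of the series; on a trending weight trace the wrap
    is a spurious multi-kilogram step, so boundary coefficients are excluded
    from both the fence computation and the flagging.
    """
    bad = [lev for lev in levels if not (1 <= lev <= dec.level)]
    if bad:
        raise ValueError(f"levels {bad} not in decomposition (1..{dec.level})")
    L = pywt.Wavelet(dec.wavelet).dec_len
    source = {}
    for lev in levels:
        w = dec.details[lev - 1]
        if w.size == 0:
            raise ValueError("empty coefficient vector")
        n_boundary = min((L - 1) * (2 ** lev - 1), w.size - 1)
        w = w[n_boundary:]
        q1, q3 = np.percentile(w, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_multiplier * iqr, q3 + iqr_multiplier * iqr
        idx = np.flatnonzero((w < lo) | (w > hi)) + n_boundary
        off = _level_offset(lev, dec.wavelet)
        times = (idx - off) % dec.n
        for t in times:
            source.setdefault(int(t), set()).add(lev)
    flagged = np.array(sorted(source), dtype=int)
    return OutlierMask(flagged=flagged, source_level=source, n=dec.n)


def remove_and_interpolate(x, mask: OutlierMask) -> np.ndarray:
    """Replace flagged samples by linear interpolation between retained ones.

    Flagged runs at the head or tail of the series are filled with the
    nearest retained value.
    """
    x = np.asarray(x, dtype=float)
    if mask.flagged.size and (mask.flagged.min() < 0 or mask.flagged.max() >= x.size):
        raise ValueError("mask indices outside series range")
    keep = np.ones(x.size, dtype=bool)
    keep[mask.flagged] = False
    if not keep.any():
        raise ValueError("all samples flagged; cannot interpolate")
    out = x.copy()
    idx = np.arange(x.size)
    # np.interp clamps beyond the first/last retained sample -> nearest value
    out[~keep] = np.interp(idx[~keep], idx[keep], x[keep])
    return out


def weights_to_etr(weights) -> np.ndarray:
    """Lag-1 difference of cleaned weights: ETr_t = w_{t-1} - w_t (grams/15 min).

    Weight loss is positive evapotranspiration.  The result has length n-1
    and is timestamped at sample t.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two samples to difference")
    if np.isnan(w).any():
        raise ValueError("weights contain missing values")
    return -np.diff(w)


def grams_to_mm(grams, tray_area_m2: float = 0.24):
    """Convert grams of water over a tray to depth in mm (1 g / 0.24 m2 = 1/240 mm)."""
    if tray_area_m2 <= 0:
        raise ValueError("tray area must be positive")
    return np.asarray(grams, dtype=float) / (1000.0 * tray_area_m2)


def clean_loadcell_series(weights, level: int = 3, wavelet: str = "db2",
                          iqr_multiplier: float = 1.5, levels=(1, 2, 3)):
    """Full first-stage cleaning: MODWT -> boxplot outliers -> interpolation.

    Returns ``(cleaned_weights, mask)``.
    """
    w = np.asarray(weights, dtype=float)
    if np.isnan(w).any():
        idx = np.arange(w.size)
        ok = ~np.isnan(w)
        w = np.where(ok, w, np.interp(idx, idx[ok], w[ok]))
    dec = modwt_decompose(w, level=max(level, max(levels)), wavelet=wavelet)
    mask = detect_spike_outliers(dec, levels=levels, iqr_multiplier=iqr_multiplier)
    cleaned = remove_and_interpolate(w, mask)
    return cleaned, mask
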