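"""Gaussian peak extraction, 1-Da binning and binary fingerprints.

Candidate apexes are local maxima above the relative-intensity threshold;
each candidate gets an independent least-squares Gaussian fit over a window
of about +/-3 estimated half-widths. At most 100 peaks are kept (highest
first, ties to lower m/z), every retained peak is at least 5% of the base
peak, and centroids are confined to 3000-15000 Da. Peaks are then binned to
integer Da and optionally reduced to a presence/absence bit vector — the
character data for all downstream clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

from .errors import ValidationError
from .spectrum_io import MASS_MAX, MASS_MIN, PeakList, Spectrum, default_meta, is_integral

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _gauss(x, height, center, sigma):
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def detect_peaks(
    s: Spectrum,
    max_peaks: int = 100,
    threshold: float = 0.05,
    mass_min: float = MASS_MIN,
    mass_max: float = MASS_MAX,
) -> PeakList:
    """Fit Gaussian peaks to a preprocessed (max-normalized) profile.

    Returns a PeakList sorted by m/z with relative intensities rescaled to
    the largest fitted height. Overlapping peaks are fitted independently,
    which matches the flat resolution of linear-mode data at these masses.
    """
    if s.intensity.size == 0 or not np.any(s.intensity > 0):
        return PeakList(np.array([]), np.array([]), np.array([]), dict(s.meta))
    if abs(float(s.intensity.max()) - 1.0) > 1e-6:
        raise ValidationError(
            "detect_peaks expects a max-normalized spectrum (max intensity 1); "
            f"got max {s.intensity.max():.6f}"
        )
    spacing = float(np.median(np.diff(s.mz)))
    apex_idx, _ = find_peaks(s.intensity, height=threshold)
    if apex_idx.size == 0:
        return PeakList(np.array([]), np.array([]), np.array([]), dict(s.meta))
    widths_pts = peak_widths(s.intensity, apex_idx, rel_height=0.5)[0]

    fitted = []
    n = len(s)
    for idx, w_pts in zip(apex_idx, widths_pts):
        sigma_pts = max(float(w_pts) / _FWHM_TO_SIGMA, 0.5)
        half = max(int(np.ceil(3.0 * sigma_pts)), 3)
        lo, hi = max(0, idx - half), min(n, idx + half + 1)
        x, y = s.mz[lo:hi], s.intensity[lo:hi]
        h0, c0, s0 = float(s.intensity[idx]), float(s.mz[idx]), sigma_pts * spacing
        try:
            popt, _ = curve_fit(
                _gauss,
                x,
                y,
                p0=(h0, c0, s0),
                bounds=(
                    (0.0, x[0], spacing / 10.0),
                    (1.5, x[-1], (x[-1] - x[0]) * 2.0 + spacing),
                ),
                maxfev=400,
            )
            height, center, sigma = map(float, popt)
        except (RuntimeError, ValueError):
            height, center, sigma = h0, c0, s0  # apex fallback when the fit diverges
        if height < threshold or not (mass_min <= center <= mass_max):
            continue
        fitted.append((height, center, abs(sigma)))

    if not fitted:
        return PeakList(np.array([]), np.array([]), np.array([]), dict(s.meta))
    # cap: keep the highest peaks, ties broken toward lower m/z
    fitted.sort(key=lambda p: (-p[0], p[1]))
    fitted = fitted[:max_peaks]
    top = fitted[0][0]
    kept = [(c, h / top, w) for h, c, w in fitted if h / top >= threshold]
    kept.sort(key=lambda p: p[0])
    mz = np.array([p[0] for p in kept])
    rel = np.array([p[1] for p in kept])
    width = np.array([p[2] for p in kept])
    return PeakList(mz, rel, width, dict(s.meta))


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    values = np.asarray(values, dtype=float)
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def bin_peaks(pl: PeakList) -> PeakList:
    """Round centroids to integer Da; merge same-bin peaks keeping the larger.

    Idempotent: already-binned lists pass through unchanged.
    """
    if len(pl) == 0:
        return PeakList(np.array([]), np.array([]), np.array([]), dict(pl.meta))
    binned = round_half_away(pl.mz)
    best: dict[int, tuple[float, float]] = {}
    for m, r, w in zip(binned, pl.rel_intensity, pl.width):
        key = int(m)
        if key not in best or r > best[key][0]:
            best[key] = (float(r), float(w))
    mz = np.array(sorted(best), dtype=float)
    rel = np.array([best[int(m)][0] for m in mz])
    width = np.array([best[int(m)][1] for m in mz])
    return PeakList(mz, rel, width, dict(pl.meta))


@dataclass
class BinaryFingerprint:
    """Presence/absence bit vector over integer-Da bins 3000..15000."""

    bins: np.ndarray
    meta: dict = field(default_factory=default_meta)

    OFFSET = int(MASS_MIN)
    N_BINS = int(MASS_MAX - MASS_MIN) + 1

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=bool)
        if self.bins.size != self.N_BINS:
            raise ValidationError(
                f"fingerprint must have {self.N_BINS} bins, got {self.bins.size}"
            )

    @property
    def set_bins(self) -> np.ndarray:
        """Integer Da values of the set bits."""
        return np.flatnonzero(self.bins) + self.OFFSET

    def __len__(self) -> int:
        return int(self.bins.sum())


def binarize(pl: PeakList) -> BinaryFingerprint:
    """Code a binned peak list as presence (1) / absence (0) bits.

    Intensities are discarded; the result is invariant to any rescaling of
    the input intensities.
    """
    bits = np.zeros(BinaryFingerprint.N_BINS, dtype=bool)
    if len(pl):
        if not is_integral(pl.mz):
            raise ValidationError(
                "binarize requires 1-Da binned centroids; run bin_peaks first"
            )
        idx = np.round(pl.mz).astype(int) - BinaryFingerprint.OFFSET
        bits[idx] = True
    return BinaryFingerprint(bits, dict(pl.meta))
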