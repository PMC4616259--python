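"""Raw-profile conditioning: compression, smoothing, baseline, normalization.

The chain mirrors the conventional linear-mode workflow for whole-cell
protein spectra: block-average compression (factor 10) to suppress
high-frequency spikes, Savitzky-Golay smoothing over a 25 Da frame,
two passes of polygon (minimum-vertex) baseline subtraction, max-norm
scaling so the base peak reads exactly 1, and cropping to the
3000-15000 Da working range. Every stage is deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, ParameterError
from .spectrum_io import Spectrum


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Defaults are the linear-mode whole-cell settings: compression factor 10,
    25 Da Savitzky-Golay frame with a quadratic polynomial, two polygon
    baseline passes with 500 Da windows, and a 3000-15000 Da working range.
    ``mass_min``/``mass_max`` of None disable cropping.
    """

    compression_factor: int = 10
    sg_frame: float = 25.0
    sg_polyorder: int = 2
    baseline_passes: int = 2
    baseline_window: float = 500.0
    mass_min: float | None = 3000.0
    mass_max: float | None = 15000.0

    def __post_init__(self):
        if self.compression_factor < 1:
            raise ParameterError("compression_factor must be >= 1")
        if self.sg_frame <= 0:
            raise ParameterError("sg_frame must be positive")
        if self.baseline_passes < 0:
            raise ParameterError("baseline_passes must be >= 0")
        if (
            self.mass_min is not None
            and self.mass_max is not None
            and self.mass_min >= self.mass_max
        ):
            raise ParameterError("mass_min must be below mass_max")


def compress(s: Spectrum, factor: int) -> Spectrum:
    """Block-average consecutive groups of ``factor`` points.

    Each non-overlapping block is replaced by one point at the block-mean
    m/z with the block-mean intensity; a trailing partial block is averaged
    as-is. Output length is ceil(n / factor).
    """
    if factor < 1:
        raise ParameterError(f"compression factor must be >= 1, got {factor}")
    if factor == 1:
        return s.copy_with()
    n = len(s)
    if n < factor:
        raise ParameterError(f"spectrum of length {n} shorter than factor {factor}")
    n_full = n // factor
    mz_full = s.mz[: n_full * factor].reshape(n_full, factor).mean(axis=1)
    in_full = s.intensity[: n_full * factor].reshape(n_full, factor).mean(axis=1)
    if n % factor:
        mz_full = np.append(mz_full, s.mz[n_full * factor :].mean())
        in_full = np.append(in_full, s.intensity[n_full * factor :].mean())
    return s.copy_with(mz=mz_full, intensity=in_full)


def _frame_to_window(frame_da: float, spacing: float, polyorder: int, n: int) -> int:
    window = int(math.floor(frame_da / spacing + 0.5))
    if window % 2 == 0:
        window += 1
    window = max(window, polyorder + 2)
    if window % 2 == 0:
        window += 1
    if window > n:
        raise ParameterError(
            f"smoothing window of {window} points exceeds spectrum length {n}"
        )
    return window


def smooth(s: Spectrum, frame_da: float = 25.0, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing with the frame given in Da.

    The frame converts to an odd window of points from the median grid
    spacing. Negative filter outputs are clipped to zero (abundances are
    physically non-negative).
    """
    if frame_da <= 0:
        raise ParameterError("frame_da must be positive")
    spacing = np.diff(s.mz)
    med = float(np.median(spacing))
    cv = float(spacing.std() / spacing.mean()) if spacing.mean() > 0 else 0.0
    if cv >= 0.2:
        warnings.warn(
            f"m/z spacing is uneven (CV={cv:.2f}); Savitzky-Golay assumes a "
            "near-uniform grid",
            stacklevel=2,
        )
    window = _frame_to_window(frame_da, med, polyorder, len(s))
    out = savgol_filter(s.intensity, window_length=window, polyorder=polyorder)
    return s.copy_with(intensity=np.clip(out, 0.0, None))


def baseline_correct(s: Spectrum, window_da: float = 500.0, passes: int = 2) -> Spectrum:
    """Polygon baseline subtraction.

    Per pass: partition the m/z axis into contiguous ``window_da``-wide
    windows, place a vertex at each window's intensity minimum, linearly
    interpolate the vertex polygon over the whole grid, subtract, and clip
    negatives to zero.
    """
    if window_da <= 0:
        raise ParameterError("window_da must be positive")
    if passes < 0:
        raise ParameterError("passes must be >= 0")
    mz = s.mz
    intensity = s.intensity.copy()
    for _ in range(passes):
        edges = np.arange(mz[0], mz[-1] + window_da, window_da)
        idx = np.searchsorted(mz, edges[1:-1], side="left")
        vx, vy = [], []
        for lo, hi in zip(np.concatenate([[0], idx]), np.concatenate([idx, [len(mz)]])):
            if hi <= lo:
                continue
            k = lo + int(np.argmin(intensity[lo:hi]))
            vx.append(mz[k])
            vy.append(intensity[k])
        baseline = np.interp(mz, vx, vy)
        intensity = np.clip(intensity - baseline, 0.0, None)
    return s.copy_with(intensity=intensity)


def normalize_max(s: Spectrum) -> Spectrum:
    """Scale intensities so the base peak reads exactly 1."""
    peak = float(s.intensity.max())
    if peak <= 0:
        raise DegenerateInputError("cannot max-normalize an all-zero spectrum")
    return s.copy_with(intensity=s.intensity / peak)


def crop(s: Spectrum, mass_min: float | None, mass_max: float | None) -> Spectrum:
    lo = -np.inf if mass_min is None else mass_min
    hi = np.inf if mass_max is None else mass_max
    mask = (s.mz >= lo) & (s.mz <= hi)
    if mask.sum() < 2:
        raise DegenerateInputError(
            f"fewer than 2 points remain in [{lo:.0f}, {hi:.0f}] Da"
        )
    return s.copy_with(mz=s.mz[mask], intensity=s.intensity[mask])


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full conditioning chain: compress, smooth, baseline, crop, normalize.

    Cropping precedes the final normalization so that the preprocessed
    output always has maximum intensity exactly 1 inside the working range.
    Applied parameters are recorded in the output metadata.
    """
    cfg = cfg or PreprocessConfig()
    out = compress(s, cfg.compression_factor)
    out = smooth(out, cfg.sg_frame, cfg.sg_polyorder)
    out = baseline_correct(out, cfg.baseline_window, cfg.baseline_passes)
    if cfg.mass_min is not None or cfg.mass_max is not None:
        out = crop(out, cfg.mass_min, cfg.mass_max)
    out = normalize_max(out)
    out.meta["preprocess"] = str(asdict(cfg))
    return out
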