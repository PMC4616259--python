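"""Spectral conformity (CCI) and open library log-score identification.

The composite correlation index (CCI) splits the shared m/z range of two
profiles into equal-width intervals, computes the Pearson correlation of the
intensities in each interval, and averages: 1 means identical profiles, values
near 0 a clear diversity.

The log score is an open reimplementation of the familiar 0-3 identification
scale (the commercial score's internals are proprietary): with f1 the matched
fraction of query peaks, f2 the matched fraction of reference peaks and f3 a
rescaled intensity correlation, score = log10(1000 * f1 * f2 * f3) clipped to
[0, 3]. Interpretation bins: < 1.700 no reliable identification, 1.700-1.999
probable genus, 2.000-2.299 secure genus / probable species, 2.300-3.000
secure species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DegenerateInputError, DomainError, ParameterError
from .spectrum_io import PeakList, Spectrum


class ScoreCategory(str, Enum):
    NO_ID = "no_id"
    PROBABLE_GENUS = "probable_genus"
    SECURE_GENUS_PROBABLE_SPECIES = "secure_genus_probable_species"
    SECURE_SPECIES = "secure_species"


@dataclass
class CCIResult:
    value: float
    interval_correlations: np.ndarray
    n_intervals: int

    def __float__(self) -> float:
        return self.value


@dataclass
class ScoreResult:
    log_score: float
    components: dict
    category: ScoreCategory
    matched_pairs: list = field(default_factory=list)

    def __float__(self) -> float:
        return self.log_score


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; 0 when either vector has zero variance."""
    if a.size < 2:
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def cci(
    a: Spectrum, b: Spectrum, n_intervals: int = 10, min_points_per_interval: int = 10
) -> CCIResult:
    """Composite correlation index between two preprocessed profiles.

    ``b`` is linearly interpolated onto ``a``'s grid over the overlapping
    m/z range, which is split into ``n_intervals`` equal-width intervals.
    An interval where either profile has zero variance contributes 0. The
    overlap must hold at least ``min_points_per_interval`` grid points per
    interval (lower it only for hand-sized examples).
    """
    if n_intervals < 1:
        raise ParameterError("n_intervals must be >= 1")
    lo = max(a.mz[0], b.mz[0])
    hi = min(a.mz[-1], b.mz[-1])
    if hi <= lo:
        raise DomainError(
            f"spectra do not overlap ([{a.mz[0]:.0f},{a.mz[-1]:.0f}] vs "
            f"[{b.mz[0]:.0f},{b.mz[-1]:.0f}])"
        )
    mask = (a.mz >= lo) & (a.mz <= hi)
    if int(mask.sum()) < n_intervals * min_points_per_interval:
        raise DomainError(
            f"overlap holds {int(mask.sum())} points; need at least "
            f"{n_intervals * min_points_per_interval} for {n_intervals} intervals"
        )
    grid = a.mz[mask]
    ya = a.intensity[mask]
    yb = np.interp(grid, b.mz, b.intensity)
    edges = np.linspace(lo, hi, n_intervals + 1)
    which = np.clip(np.searchsorted(edges, grid, side="right") - 1, 0, n_intervals - 1)

    def interval_corr(u: np.ndarray, v: np.ndarray) -> float:
        # a flat interval carries no shape information: identical flat
        # segments are perfect conformity (1), flatness in only one
        # spectrum (or differing constants) is a mismatch (0) — this keeps
        # CCI total while preserving cci(s, s) = 1
        if u.size < 2:
            return 0.0
        if u.std() == 0.0 or v.std() == 0.0:
            return 1.0 if np.allclose(u, v, rtol=0.0, atol=1e-12) else 0.0
        return _pearson(u, v)

    corrs = np.array(
        [interval_corr(ya[which == k], yb[which == k]) for k in range(n_intervals)]
    )
    value = float(np.clip(corrs.mean(), 0.0, 1.0))
    return CCIResult(value=value, interval_correlations=corrs, n_intervals=n_intervals)


def replicate_consistency(spectra: list[Spectrum], n_intervals: int = 10) -> float:
    """Mean CCI over all unordered pairs — the per-condition consistency."""
    if len(spectra) < 2:
        raise ParameterError("replicate consistency needs at least 2 spectra")
    values = [
        cci(x, y, n_intervals).value for x, y in itertools.combinations(spectra, 2)
    ]
    return float(np.mean(values))


def categorize_score(x: float) -> ScoreCategory:
    """Map a log score to its interpretation bin (boundaries as printed)."""
    if not (-1e-9 <= x <= 3.0 + 1e-9):
        raise ParameterError(f"log score {x} outside [0, 3]")
    if x < 1.700:
        return ScoreCategory.NO_ID
    if x < 2.000:
        return ScoreCategory.PROBABLE_GENUS
    if x < 2.300:
        return ScoreCategory.SECURE_GENUS_PROBABLE_SPECIES
    return ScoreCategory.SECURE_SPECIES


def _greedy_match(
    query_mz: np.ndarray, ref_mz: np.ndarray, tol_da: float
) -> list[tuple[int, int]]:
    """One-to-one nearest-m/z matching within +/-tol_da (closest pairs first)."""
    pairs = []
    for qi, qm in enumerate(query_mz):
        j0 = np.searchsorted(ref_mz, qm - tol_da, side="left")
        j1 = np.searchsorted(ref_mz, qm + tol_da, side="right")
        for rj in range(int(j0), int(j1)):
            pairs.append((abs(qm - ref_mz[rj]), qm, ref_mz[rj], qi, rj))
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    matches = []
    for _, _, _, qi, rj in pairs:
        if qi in used_q or rj in used_r:
            continue
        used_q.add(qi)
        used_r.add(rj)
        matches.append((qi, rj))
    return matches


def log_score(query: PeakList, ref, tol_da: float = 2.0) -> ScoreResult:
    """Open 0-3 log score of a query peak list against a main spectrum.

    Components: f1 = matched / |query|, f2 = matched / |reference|,
    f3 = (r + 1) / 2 with r the Pearson correlation of matched intensity
    pairs (f3 = 0 with fewer than 3 matches, r = 0 when either side is
    constant). Score = log10(1000 * f1 * f2 * f3), clipped to [0, 3];
    products <= 0.001 score 0.
    """
    if len(query) == 0:
        raise DegenerateInputError("query peak list is empty")
    ref_mz = np.asarray(ref.mz, dtype=float)
    ref_int = np.asarray(ref.mean_rel_intensity, dtype=float)
    if ref_mz.size == 0:
        raise DegenerateInputError("reference main spectrum is empty")
    order = np.argsort(ref_mz, kind="stable")
    ref_mz, ref_int = ref_mz[order], ref_int[order]
    q = query.sorted_by_mz()
    matches = _greedy_match(q.mz, ref_mz, tol_da)
    m = len(matches)
    f1 = m / len(q)
    f2 = m / ref_mz.size
    if m < 3:
        f3 = 0.0
    else:
        qi = np.array([q.rel_intensity[i] for i, _ in matches])
        ri = np.array([ref_int[j] for _, j in matches])
        f3 = (_pearson(qi, ri) + 1.0) / 2.0
    product = f1 * f2 * f3
    score = 0.0 if product <= 1e-3 else float(np.clip(np.log10(1000.0 * product), 0.0, 3.0))
    return ScoreResult(
        log_score=score,
        components={"query_match_frac": f1, "reference_match_frac": f2, "intensity_symmetry": f3},
        category=categorize_score(score),
        matched_pairs=[(float(q.mz[i]), float(ref_mz[j])) for i, j in matches],
    )
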