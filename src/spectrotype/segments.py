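"""Per-kilodalton peptide richness and correspondence analysis.

The working range is divided into 1-kDa segments 3K..14K (segment k covers
[k*1000, (k+1)*1000) Da; the closing boundary 15000 counts in 14K). The
number of distinct 1-Da peaks per segment — "peptide richness" — is
tabulated per condition (growth time, storage state), and the resulting
contingency table is ordinated by classical correspondence analysis:
singular value decomposition of the standardized residuals, with principal
coordinates reported and total inertia equal to chi-square / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .spectrum_io import MASS_MAX, MASS_MIN, PeakList, is_integral

SEGMENT_LABELS = [f"{k}K" for k in range(3, 15)]


def segment_richness(peaklists: dict[str, PeakList]) -> pd.DataFrame:
    """Count distinct integer-Da peaks per 1-kDa segment and condition.

    Rows are segments 3K..14K, columns the condition labels in input order.
    """
    table = pd.DataFrame(
        0, index=SEGMENT_LABELS, columns=list(peaklists), dtype=int
    )
    for condition, pl in peaklists.items():
        if len(pl) == 0:
            continue
        if not is_integral(pl.mz):
            raise ValidationError(
                f"{condition}: peak lists must be 1-Da binned before segmenting"
            )
        mz = np.unique(np.round(pl.mz).astype(int))
        if mz.min() < MASS_MIN or mz.max() > MASS_MAX:
            bad = mz[(mz < MASS_MIN) | (mz > MASS_MAX)]
            raise ValidationError(
                f"{condition}: peaks outside [{MASS_MIN:.0f}, {MASS_MAX:.0f}]: "
                f"{bad[:5].tolist()}"
            )
        seg = np.minimum(mz // 1000, 14)  # 15000 closes segment 14K
        for k in seg:
            table.loc[f"{k}K", condition] += 1
    return table


@dataclass
class CAResult:
    """First two principal dimensions of a correspondence analysis."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float
    dim_inertia_fractions: np.ndarray


def correspondence_analysis(table: pd.DataFrame, n_dims: int = 2) -> CAResult:
    """Classical CA of a non-negative contingency table.

    P = table / n; S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j); SVD of S.
    Principal coordinates: rows diag(1/sqrt(r)) U Sigma, columns
    diag(1/sqrt(c)) V Sigma. Total inertia = sum of squared singular
    values = chi-square / n. All-zero rows and columns are dropped with a
    warning before the analysis.
    """
    t = table.astype(float)
    if (t.to_numpy() < 0).any():
        raise ValidationError("contingency table contains negative cells")
    zero_rows = t.index[(t.sum(axis=1) == 0)]
    zero_cols = t.columns[(t.sum(axis=0) == 0)]
    if len(zero_rows):
        warnings.warn(f"dropping all-zero rows: {list(zero_rows)}", stacklevel=2)
        t = t.drop(index=zero_rows)
    if len(zero_cols):
        warnings.warn(f"dropping all-zero columns: {list(zero_cols)}", stacklevel=2)
        t = t.drop(columns=zero_cols)
    n = float(t.to_numpy().sum())
    if n <= 0 or t.shape[0] < 1 or t.shape[1] < 1:
        raise DegenerateInputError("contingency table has no mass")
    P = t.to_numpy() / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    sv_k = sv[keep]
    total_inertia = float((sv**2).sum())
    k = min(n_dims, sv_k.size)
    dims = [f"Dim{i + 1}" for i in range(k)]
    if k == 0:
        row = np.zeros((t.shape[0], n_dims))
        col = np.zeros((t.shape[1], n_dims))
        dims = [f"Dim{i + 1}" for i in range(n_dims)]
        fractions = np.zeros(n_dims)
        return CAResult(
            pd.DataFrame(row, index=t.index, columns=dims),
            pd.DataFrame(col, index=t.columns, columns=dims),
            sv_k,
            total_inertia,
            fractions,
        )
    row = (U[:, :k] / np.sqrt(r)[:, None]) * sv_k[:k]
    col = (Vt[:k].T / np.sqrt(c)[:, None]) * sv_k[:k]
    fractions = sv_k[:k] ** 2 / total_inertia if total_inertia > 0 else np.zeros(k)
    return CAResult(
        row_coords=pd.DataFrame(row, index=t.index, columns=dims),
        col_coords=pd.DataFrame(col, index=t.columns, columns=dims),
        singular_values=sv_k,
        total_inertia=total_inertia,
        dim_inertia_fractions=fractions,
    )
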