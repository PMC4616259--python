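"""Consensus main spectra, spectral libraries, two-step identification.

A main spectrum (MSP) condenses the replicate peak lists of a taxon into
the peaks that recur in more than a fixed fraction of replicates (strictly
greater than 95% by default, so a peak present in 17 of 18 replicates is
dropped while 18 of 18 is kept). Species-level library entries pool the
replicate lists of every strain in the species; genus-level entries pool
all lists of all species in the genus, keeping the recurrence semantics
uniform at every level.

Blind identification is two-step: the query is scored against every
genus-level MSP first, then against the species library of the winning
genus only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, ValidationError
from .peaks import round_half_away
from .similarity import ScoreCategory, log_score
from .spectrum_io import PeakList, default_meta


@dataclass
class MainSpectrum:
    """Consensus peak set of a strain, species or genus.

    ``sources`` keeps the contributing replicate peak lists in memory so
    higher-level libraries can re-pool them; it is never serialized. A
    library read back from JSON has ``sources=None``, in which case the
    MSP's own peak table stands in as a single source when re-pooled.
    """

    label: str
    level: str
    mz: np.ndarray
    mean_rel_intensity: np.ndarray
    recurrence: np.ndarray
    n_sources: int
    genus: str | None = None
    species: str | None = None
    sources: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=int)
        self.mean_rel_intensity = np.asarray(self.mean_rel_intensity, dtype=float)
        self.recurrence = np.asarray(self.recurrence, dtype=float)
        if self.n_sources < 1:
            raise ValidationError(f"{self.label}: n_sources must be >= 1")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            raise ValidationError(f"{self.label}: consensus peaks must be sorted by m/z")

    def __len__(self) -> int:
        return int(self.mz.size)

    def to_peaklist(self) -> PeakList:
        meta = default_meta(strain_id=self.label)
        if self.genus:
            meta["genus"] = self.genus
        if self.species:
            meta["species"] = self.species
        width = np.full(self.mz.size, 1.0)
        return PeakList(self.mz.astype(float), self.mean_rel_intensity, width, meta)


@dataclass
class Library:
    level: str
    entries: list
    build_params: dict = field(default_factory=dict)

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate library labels: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> MainSpectrum:
        for entry in self.entries:
            if entry.label == label:
                return entry
        raise KeyError(label)


def build_main_spectrum(
    replicates: list[PeakList],
    min_recurrence: float = 0.95,
    tol_da: float = 2.0,
    label: str = "",
    level: str = "strain",
    genus: str | None = None,
    species: str | None = None,
) -> MainSpectrum:
    """Combine replicate peak lists into a consensus main spectrum.

    Peaks are single-linkage clustered across replicates (adjacent peaks
    closer than ``tol_da`` chain into one cluster). A cluster spanning a
    fraction of replicates strictly greater than ``min_recurrence`` emits a
    consensus peak at the intensity-weighted mean m/z (rounded to integer
    Da) with the mean contributing intensity; consensus intensities are
    re-normalized to max 1.
    """
    if len(replicates) < 2:
        raise ParameterError("a main spectrum needs at least 2 replicate peak lists")
    if not (0.0 <= min_recurrence <= 1.0):
        raise ParameterError("min_recurrence must be in [0, 1]")
    n = len(replicates)
    entries = []  # (mz, intensity, replicate index)
    for rep_idx, pl in enumerate(replicates):
        for m, r in zip(pl.mz, pl.rel_intensity):
            entries.append((float(m), float(r), rep_idx))
    entries.sort()
    peaks = []
    cluster: list[tuple[float, float, int]] = []

    def flush(cluster):
        reps = {e[2] for e in cluster}
        frac = len(reps) / n
        if frac > min_recurrence:
            mzs = np.array([e[0] for e in cluster])
            ints = np.array([e[1] for e in cluster])
            center = int(round_half_away(np.average(mzs, weights=ints)))
            peaks.append((center, float(ints.mean()), frac))

    for entry in entries:
        if cluster and entry[0] - cluster[-1][0] > tol_da:
            flush(cluster)
            cluster = []
        cluster.append(entry)
    if cluster:
        flush(cluster)

    if not peaks:
        warn(f"{label or 'main spectrum'}: no peak recurred above {min_recurrence:.0%}",
             stacklevel=2)
        return MainSpectrum(label, level, np.array([], dtype=int), np.array([]),
                            np.array([]), n, genus, species, sources=list(replicates))
    peaks.sort()
    mz = np.array([p[0] for p in peaks], dtype=int)
    inten = np.array([p[1] for p in peaks])
    rec = np.array([p[2] for p in peaks])
    inten = inten / inten.max()
    return MainSpectrum(label, level, mz, inten, rec, n, genus, species,
                        sources=list(replicates))


def build_library(
    msps: list[MainSpectrum],
    level: str,
    min_recurrence: float = 0.95,
    tol_da: float = 2.0,
) -> Library:
    """Assemble a species- or genus-level library from lower-level MSPs.

    Inputs are grouped by the target label and the consensus is re-run over
    the pooled source peak lists of each group, so recurrence is always a
    fraction of individual replicate lists, never of intermediate MSPs.
    """
    if level not in ("species", "genus"):
        raise ParameterError(f"library level must be species or genus, got {level!r}")
    if not msps:
        raise ValidationError("cannot build a library from no main spectra")
    groups: dict[str, list[MainSpectrum]] = {}
    for msp in msps:
        if level == "species":
            if not msp.species or msp.species == "unknown":
                raise ValidationError(f"entry {msp.label!r} has no species label")
            key = msp.species
        else:
            if not msp.genus or msp.genus == "unknown":
                raise ValidationError(f"entry {msp.label!r} has no genus label")
            key = msp.genus
        groups.setdefault(key, []).append(msp)
    entries = []
    for key in sorted(groups):
        pooled: list[PeakList] = []
        for msp in groups[key]:
            pooled.extend(msp.sources if msp.sources else [msp.to_peaklist()])
        genus = groups[key][0].genus
        species = key if level == "species" else None
        entries.append(
            build_main_spectrum(
                pooled, min_recurrence, tol_da,
                label=key, level=level, genus=genus, species=species,
            )
        )
    return Library(level=level, entries=entries,
                   build_params={"min_recurrence": min_recurrence, "tol_da": tol_da})


@dataclass
class IdentificationReport:
    """Two-step blind identification outcome."""

    genus_table: pd.DataFrame
    species_table: pd.DataFrame | None
    final_label: str | None
    final_score: float | None
    final_category: str | None
    reliable_at_genus: bool

    def summary(self) -> str:
        lines = ["Step 1 — genus level:"]
        for _, row in self.genus_table.iterrows():
            lines.append(
                f"  {row['rank']}. {row['label']:<20s} {row['log_score']:.3f} ({row['category']})"
            )
        if not self.reliable_at_genus:
            lines.append("Unreliable at genus level — identification stopped.")
            return "\n".join(lines)
        lines.append("Step 2 — species level:")
        for _, row in self.species_table.iterrows():
            lines.append(
                f"  {row['rank']}. {row['label']:<20s} {row['log_score']:.3f} ({row['category']})"
            )
        lines.append(
            f"Final call: {self.final_label} "
            f"(log score {self.final_score:.3f}, {self.final_category})"
        )
        return "\n".join(lines)


def _score_table(query: PeakList, lib: Library, tol_da: float, step: str) -> pd.DataFrame:
    rows = []
    for msp in lib.entries:
        if len(msp) == 0:
            continue
        res = log_score(query, msp, tol_da)
        rows.append(
            {
                "step": step,
                "label": msp.label,
                "log_score": res.log_score,
                "f1": res.components["query_match_frac"],
                "f2": res.components["reference_match_frac"],
                "f3": res.components["intensity_symmetry"],
                "category": res.category.value,
            }
        )
    if not rows:
        raise DegenerateInputError(f"no scorable entries in the {step} library")
    df = pd.DataFrame(rows).sort_values(
        ["log_score", "label"], ascending=[False, True], kind="stable"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def identify_two_step(
    query: PeakList,
    genus_lib: Library,
    species_libs: dict[str, Library],
    tol_da: float = 2.0,
    top_k: int = 1,
) -> IdentificationReport:
    """Two-step blind identification: genus first, then species within it.

    Stops after step 1 with ``reliable_at_genus=False`` when the best genus
    score falls in the no-identification bin (< 1.700).
    """
    if len(genus_lib) == 0:
        raise ValidationError("genus library is empty")
    genus_table = _score_table(query, genus_lib, tol_da, step="genus")
    top = genus_table.iloc[0]
    if top["category"] == ScoreCategory.NO_ID.value:
        return IdentificationReport(genus_table, None, None, None, None, False)
    species_frames = []
    for _, row in genus_table.head(max(1, top_k)).iterrows():
        genus = row["label"]
        if genus not in species_libs:
            raise ValidationError(f"no species library provided for genus {genus!r}")
        species_frames.append(_score_table(query, species_libs[genus], tol_da, "species"))
    species_table = species_frames[0] if len(species_frames) == 1 else (
        pd.concat(species_frames, ignore_index=True)
        .sort_values(["log_score", "label"], ascending=[False, True], kind="stable")
        .assign(rank=lambda d: np.arange(1, len(d) + 1))
        .reset_index(drop=True)
    )
    best = species_table.iloc[0]
    return IdentificationReport(
        genus_table=genus_table,
        species_table=species_table,
        final_label=str(best["label"]),
        final_score=float(best["log_score"]),
        final_category=str(best["category"]),
        reliable_at_genus=True,
    )
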