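"""End-to-end workflows: library building and blind identification.

Chains preprocessing, peak fitting, consensus main spectra, genus/species
libraries and the dendrogram, writing a machine-readable run manifest
(inputs, parameters, seed) alongside every output so each run is
reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import SpectrotypeError, ValidationError
from .library import build_library, build_main_spectrum, identify_two_step
from .peaks import bin_peaks, detect_peaks
from .preprocess import PreprocessConfig, preprocess
from .spectrum_io import (
    read_peaklist,
    read_spectrum,
    write_library,
    write_newick,
)
from .taxonomy import binary_matrix, bootstrap_support, mean_character_distance, upgma

log = logging.getLogger("spectrotype")


@dataclass
class RunConfig:
    """All tunables of a build/identify run, serialized with the outputs."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_peaks: int = 100
    peak_threshold: float = 0.05
    score_tol_da: float = 2.0
    min_recurrence: float = 0.95
    cluster_tol_da: float = 2.0
    bootstrap_reps: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(preprocess=pre, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_peaklist(path: Path, cfg: RunConfig):
    """Read a peak list, or derive one from a raw spectrum file."""
    if path.suffix == ".tsv":
        pl = read_peaklist(path)
    else:
        s = read_spectrum(path)
        s = preprocess(s, cfg.preprocess)
        pl = detect_peaks(s, cfg.max_peaks, cfg.peak_threshold)
        pl.meta.update(s.meta)
    return bin_peaks(pl)


def _write_manifest(out_dir: Path, cfg: RunConfig, inputs: list[str], outputs: list[str]) -> None:
    manifest = {
        "tool": "spectrotype",
        "version": __version__,
        "config": cfg.to_dict(),
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str) + "\n")


def run_build(input_dir, out_dir, cfg: RunConfig | None = None) -> dict:
    """Build strain MSPs, species/genus libraries and the dendrogram.

    ``input_dir`` holds xy spectra or peak-list TSVs whose metadata headers
    carry strain_id / species / genus. Returns the built objects; writes
    libraries (JSON), the bootstrap-annotated dendrogram (Newick) and a run
    manifest under ``out_dir``.
    """
    cfg = cfg or RunConfig()
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = sorted(
        p for p in input_dir.iterdir() if p.suffix in (".xy", ".txt", ".tsv", ".mzml")
    )
    if not files:
        raise ValidationError(f"{input_dir}: no spectrum or peak-list files found")
    by_strain: dict[str, list] = {}
    strain_tax: dict[str, tuple[str, str]] = {}
    for path in files:
        try:
            pl = _load_peaklist(path, cfg)
        except SpectrotypeError as exc:
            raise type(exc)(f"stage=load file={path.name}: {exc}") from exc
        sid = pl.meta.get("strain_id", "unknown")
        if sid == "unknown":
            raise ValidationError(f"{path.name}: missing strain_id metadata")
        if pl.meta.get("species", "unknown") == "unknown" or pl.meta.get("genus", "unknown") == "unknown":
            raise ValidationError(f"{path.name}: missing species/genus metadata")
        by_strain.setdefault(sid, []).append(pl)
        strain_tax[sid] = (pl.meta["genus"], pl.meta["species"])
        log.info("loaded %s: %d peaks (strain %s)", path.name, len(pl), sid)

    strain_msps = []
    for sid in sorted(by_strain):
        genus, species = strain_tax[sid]
        msp = build_main_spectrum(
            by_strain[sid], cfg.min_recurrence, cfg.cluster_tol_da,
            label=sid, level="strain", genus=genus, species=species,
        )
        strain_msps.append(msp)
        log.info("strain MSP %s: %d consensus peaks from %d lists", sid, len(msp), msp.n_sources)

    species_lib = build_library(strain_msps, "species", cfg.min_recurrence, cfg.cluster_tol_da)
    genus_lib = build_library(strain_msps, "genus", cfg.min_recurrence, cfg.cluster_tol_da)

    outputs = []
    for name, lib in (("species_library.json", species_lib), ("genus_library.json", genus_lib)):
        write_library(lib, out_dir / name)
        outputs.append(name)

    matrix = binary_matrix(strain_msps) if len(strain_msps) >= 2 else None
    tree = None
    if matrix is not None:
        if len(matrix.taxa) >= 3 and cfg.bootstrap_reps >= 1:
            tree = bootstrap_support(matrix, cfg.bootstrap_reps, seed=cfg.seed)
        else:
            tree = upgma(mean_character_distance(matrix))
        write_newick(tree, out_dir / "dendrogram.nwk")
        outputs.append("dendrogram.nwk")

    _write_manifest(out_dir, cfg, [p.name for p in files], outputs)
    return {
        "strain_msps": strain_msps,
        "species_library": species_lib,
        "genus_library": genus_lib,
        "tree": tree,
    }


def run_identify(query_path, genus_lib, species_libs, out_path=None,
                 cfg: RunConfig | None = None):
    """Two-step identification of a query spectrum or peak list.

    ``genus_lib`` / ``species_libs`` are Library objects (species_libs maps
    genus name to its species library). Writes the ranked report as CSV when
    ``out_path`` is given and returns the IdentificationReport.
    """
    cfg = cfg or RunConfig()
    query = _load_peaklist(Path(query_path), cfg)
    report = identify_two_step(query, genus_lib, species_libs, cfg.score_tol_da)
    if out_path is not None:
        frames = [report.genus_table]
        if report.species_table is not None:
            frames.append(report.species_table)
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(out_path, index=False)
    return report


def split_species_libraries(species_lib) -> dict:
    """Partition a flat species library into per-genus libraries."""
    from .library import Library

    by_genus: dict[str, list] = {}
    for msp in species_lib.entries:
        if not msp.genus:
            raise ValidationError(f"species entry {msp.label!r} has no genus label")
        by_genus.setdefault(msp.genus, []).append(msp)
    return {
        genus: Library("species", entries, dict(species_lib.build_params))
        for genus, entries in by_genus.items()
    }
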