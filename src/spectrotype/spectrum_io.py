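"""Readers and writers for every external representation the pipeline touches.

Profile spectra travel either as mzML (read-only, via pyteomics) or as a
plain two-column "xy" text dialect with a ``#``-prefixed metadata header.
Peak lists are TSV, consensus libraries are versioned JSON, dendrograms are
Newick. All writers and readers are mutually inverse on valid objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import FormatError, ValidationError

MASS_MIN = 3000.0
MASS_MAX = 15000.0

#: provenance keys carried by every Spectrum / PeakList
META_KEYS = ("strain_id", "species", "genus", "bio_rep", "tech_rep", "condition")

LIBRARY_SCHEMA = "spectrotype-library/1"


def default_meta(**overrides) -> dict:
    meta = {
        "strain_id": "unknown",
        "species": "unknown",
        "genus": "unknown",
        "bio_rep": 0,
        "tech_rep": 0,
        "condition": "unknown",
    }
    meta.update(overrides)
    return meta


@dataclass
class Spectrum:
    """One acquired continuous profile: ascending m/z grid plus intensities.

    Raw detector output may contain negative intensities (baseline
    undershoot); the reader preserves them and preprocessing removes them.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=default_meta)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValidationError(
                f"mz ({self.mz.size}) and intensity ({self.intensity.size}) "
                "differ in length"
            )
        if self.mz.size < 1:
            raise ValidationError("a spectrum needs at least 1 point")
        if not np.all(np.diff(self.mz) > 0):
            bad = int(np.flatnonzero(np.diff(self.mz) <= 0)[0])
            raise ValidationError(
                f"m/z values must be strictly ascending (violated at index {bad})"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    def copy_with(self, mz=None, intensity=None, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(
            self.mz.copy() if mz is None else np.asarray(mz, dtype=float),
            self.intensity.copy() if intensity is None else np.asarray(intensity, dtype=float),
            meta,
        )


@dataclass
class PeakList:
    """Fitted peaks of one spectrum: centroid m/z, relative intensity, width.

    Invariants: at most 100 peaks, every relative intensity >= 0.05, the
    maximum relative intensity is 1 when non-empty, and every centroid lies
    in the 3000-15000 Da working range.
    """

    mz: np.ndarray
    rel_intensity: np.ndarray
    width: np.ndarray
    meta: dict = field(default_factory=default_meta)

    MAX_PEAKS = 100
    MIN_REL_INTENSITY = 0.05

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.rel_intensity = np.asarray(self.rel_intensity, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.mz.size
        if self.rel_intensity.size != n or self.width.size != n:
            raise ValidationError("peak columns differ in length")
        if n == 0:
            return
        if n > self.MAX_PEAKS:
            raise ValidationError(f"{n} peaks exceed the {self.MAX_PEAKS}-peak cap")
        bad = np.flatnonzero(self.rel_intensity < self.MIN_REL_INTENSITY - 1e-12)
        if bad.size:
            offenders = ", ".join(
                f"{self.mz[i]:.1f} Da ({self.rel_intensity[i]:.4f})" for i in bad[:5]
            )
            raise ValidationError(
                f"peaks below the {self.MIN_REL_INTENSITY:.0%} relative-intensity "
                f"floor: {offenders}"
            )
        if abs(self.rel_intensity.max() - 1.0) > 1e-9:
            raise ValidationError(
                f"maximum relative intensity must be 1, got {self.rel_intensity.max():.6f}"
            )
        out = np.flatnonzero((self.mz < MASS_MIN) | (self.mz > MASS_MAX))
        if out.size:
            offenders = ", ".join(f"{self.mz[i]:.1f}" for i in out[:5])
            raise ValidationError(
                f"peak centroids outside [{MASS_MIN:.0f}, {MASS_MAX:.0f}] Da: {offenders}"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    def sorted_by_mz(self) -> "PeakList":
        order = np.argsort(self.mz, kind="stable")
        return PeakList(
            self.mz[order], self.rel_intensity[order], self.width[order], dict(self.meta)
        )


# ---------------------------------------------------------------------------
# xy text dialect
# ---------------------------------------------------------------------------

def _parse_header(lines: Iterable[str]) -> tuple[dict, int]:
    """Parse leading ``# key: value`` lines; return (meta, n_header_lines)."""
    meta = default_meta()
    n = 0
    for line in lines:
        stripped = line.strip()
        if not stripped.startswith("#"):
            break
        n += 1
        body = stripped.lstrip("#").strip()
        if ":" in body:
            key, _, value = body.partition(":")
            key = key.strip()
            value = value.strip()
            if key in ("bio_rep", "tech_rep"):
                try:
                    meta[key] = int(value)
                except ValueError:
                    raise FormatError(f"header line {n}: {key} must be an integer, got {value!r}")
            elif key:
                meta[key] = value
    return meta, n


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a profile spectrum in the xy text dialect."""
    path = Path(path)
    with path.open("w") as fh:
        for key in META_KEYS:
            fh.write(f"# {key}: {spectrum.meta.get(key, 'unknown')}\n")
        for extra, value in spectrum.meta.items():
            if extra not in META_KEYS:
                fh.write(f"# {extra}: {value}\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r} {float(i)!r}\n")


def _read_xy(path: Path) -> Spectrum:
    lines = path.read_text().splitlines()
    meta, skip = _parse_header(lines)
    mz, inten = [], []
    for lineno, line in enumerate(lines[skip:], start=skip + 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) < 2:
            raise FormatError(f"{path}: line {lineno}: expected two columns, got {stripped!r}")
        try:
            mz.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric value in {stripped!r}")
    if len(mz) < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    return Spectrum(np.array(mz), np.array(inten), meta)


def _decode_binary_array(bda_elem, tag: str, path: Path) -> np.ndarray:
    """Decode one mzML <binaryDataArray> (float32/64, zlib or none)."""
    import base64
    import struct
    import zlib

    def local(elem):
        return elem.tag.rsplit("}", 1)[-1]

    accessions = set()
    binary_text = None
    for child in bda_elem.iter():
        if local(child) == "cvParam":
            accessions.add(child.get("accession", ""))
        elif local(child) == "binary":
            binary_text = child.text or ""
    if binary_text is None:
        raise FormatError(f"{path}: <binaryDataArray> without <binary> ({tag})")
    raw = base64.b64decode(binary_text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    if "MS:1000521" in accessions:  # 32-bit float
        fmt, width = "f", 4
    else:  # MS:1000523 64-bit float (default)
        fmt, width = "d", 8
    n = len(raw) // width
    return np.asarray(struct.unpack(f"<{n}{fmt}", raw[: n * width]), dtype=float)


def _read_mzml(path: Path, index: int) -> Spectrum:
    """Minimal profile-spectrum mzML reader (stdlib XML, read-only).

    Handles uncompressed or zlib-compressed 32/64-bit float arrays; no
    chromatograms, no indexed wrappers beyond skipping them.
    """
    import xml.etree.ElementTree as ET

    def local(elem):
        return elem.tag.rsplit("}", 1)[-1]

    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: unparseable mzML ({exc})") from exc
    spectra = [e for e in root.iter() if local(e) == "spectrum"]
    if index >= len(spectra):
        raise FormatError(f"{path}: no spectrum at index {index} ({len(spectra)} present)")
    spectrum = spectra[index]
    mz = inten = None
    for bda in spectrum.iter():
        if local(bda) != "binaryDataArray":
            continue
        accessions = {
            c.get("accession", "") for c in bda.iter() if local(c) == "cvParam"
        }
        if "MS:1000514" in accessions:  # m/z array
            mz = _decode_binary_array(bda, "m/z array", path)
        elif "MS:1000515" in accessions:  # intensity array
            inten = _decode_binary_array(bda, "intensity array", path)
    if mz is None or inten is None:
        raise FormatError(f"{path}: spectrum {index} lacks m/z or intensity array")
    meta = default_meta()
    meta["source_id"] = spectrum.get("id", f"index={index}")
    order = np.argsort(mz, kind="stable")
    return Spectrum(mz[order], inten[order], meta)


def read_spectrum(path, format: str | None = None, index: int = 0) -> Spectrum:
    """Read a profile spectrum from mzML or xy text.

    ``format`` is inferred from the suffix when omitted. For mzML, the first
    spectrum of the run is returned unless ``index`` selects another.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy"
    if format == "mzml":
        return _read_mzml(path, index)
    if format == "xy":
        return _read_xy(path)
    raise FormatError(f"unknown spectrum format {format!r} (expected mzml or xy)")


# ---------------------------------------------------------------------------
# peak-list TSV
# ---------------------------------------------------------------------------

def write_peaklist(pl: PeakList, path) -> None:
    """Write a peak list as TSV with a ``#`` metadata header.

    Values round-trip exactly at 6 decimal places.
    """
    pl.validate()
    path = Path(path)
    with path.open("w") as fh:
        for key in META_KEYS:
            fh.write(f"# {key}: {pl.meta.get(key, 'unknown')}\n")
        fh.write("mz\trel_intensity\twidth\n")
        for m, r, w in zip(pl.mz, pl.rel_intensity, pl.width):
            fh.write(f"{m:.6f}\t{r:.6f}\t{w:.6f}\n")


def read_peaklist(path) -> PeakList:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    lines = path.read_text().splitlines()
    meta, skip = _parse_header(lines)
    rows = [ln for ln in lines[skip:] if ln.strip()]
    if not rows or rows[0].split("\t")[:3] != ["mz", "rel_intensity", "width"]:
        raise FormatError(f"{path}: missing 'mz\\trel_intensity\\twidth' column header")
    mz, rel, width = [], [], []
    for lineno, line in enumerate(rows[1:], start=2):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: row {lineno}: expected 3 columns")
        try:
            mz.append(float(parts[0]))
            rel.append(float(parts[1]))
            width.append(float(parts[2]))
        except ValueError:
            raise FormatError(f"{path}: row {lineno}: non-numeric value")
    return PeakList(np.array(mz), np.array(rel), np.array(width), meta)


# ---------------------------------------------------------------------------
# library JSON
# ---------------------------------------------------------------------------

def write_library(lib, path) -> None:
    """Serialize a Library as versioned, diffable JSON."""
    doc = {
        "schema": LIBRARY_SCHEMA,
        "level": lib.level,
        "build_params": dict(lib.build_params),
        "entries": [
            {
                "label": msp.label,
                "level": msp.level,
                "genus": msp.genus,
                "species": msp.species,
                "n_sources": msp.n_sources,
                "peaks": [
                    {
                        "mz": int(m),
                        "mean_rel_intensity": float(r),
                        "recurrence": float(f),
                    }
                    for m, r, f in zip(msp.mz, msp.mean_rel_intensity, msp.recurrence)
                ],
            }
            for msp in lib.entries
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_library(path):
    from .library import Library, MainSpectrum

    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    schema = doc.get("schema")
    if schema != LIBRARY_SCHEMA:
        raise FormatError(
            f"{path}: schema {schema!r} does not match expected {LIBRARY_SCHEMA!r}"
        )
    entries = []
    for entry in doc["entries"]:
        peaks = entry["peaks"]
        entries.append(
            MainSpectrum(
                label=entry["label"],
                level=entry["level"],
                mz=np.array([p["mz"] for p in peaks], dtype=int),
                mean_rel_intensity=np.array(
                    [p["mean_rel_intensity"] for p in peaks], dtype=float
                ),
                recurrence=np.array([p["recurrence"] for p in peaks], dtype=float),
                n_sources=int(entry["n_sources"]),
                genus=entry.get("genus"),
                species=entry.get("species"),
            )
        )
    return Library(level=doc["level"], entries=entries, build_params=doc.get("build_params", {}))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _newick_node(node) -> str:
    if not node.children:
        name = node.name or ""
        return f"{name}:{node.length:.6f}"
    inner = ",".join(_newick_node(child) for child in node.children)
    label = ""
    if node.support is not None:
        label = str(int(round(node.support)))
    return f"({inner}){label}:{node.length:.6f}"


def write_newick(tree, path=None) -> str:
    """Serialize a rooted tree as Newick (supports as internal labels).

    Returns the Newick string; writes it to ``path`` when given.
    """
    root = getattr(tree, "root", tree)
    if root is None or (not root.children and root.name is None):
        raise ValidationError("cannot serialize an empty tree")
    _check_acyclic(root)
    if not root.children:
        text = f"{root.name}:{root.length:.6f};"
    else:
        inner = ",".join(_newick_node(child) for child in root.children)
        label = "" if root.support is None else str(int(round(root.support)))
        text = f"({inner}){label};"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _check_acyclic(root) -> None:
    seen: set[int] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if id(node) in seen:
            raise ValidationError("tree structure contains a cycle")
        seen.add(id(node))
        stack.extend(node.children)


def read_newick(path_or_text):
    """Parse Newick into the package's tree nodes (via dendropy)."""
    import dendropy

    from .taxonomy import Node

    text = path_or_text
    p = Path(str(path_or_text))
    if p.exists():
        text = p.read_text()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise FormatError(f"unparseable Newick: {exc}") from exc

    def convert(dnode) -> Node:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon else None
        support = None
        if children and dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = name or dnode.label
        length = dnode.edge.length or 0.0
        node = Node(name=name, children=children, length=float(length), support=support)
        return node

    root = convert(dtree.seed_node)

    def set_heights(node) -> float:
        if not node.children:
            node.height = 0.0
            return 0.0
        node.height = max(set_heights(c) + c.length for c in node.children)
        return node.height

    set_heights(root)
    return root


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------

def write_table(df, path) -> None:
    """Write a results table (scores, CCI, richness, coordinates) as CSV."""
    df.to_csv(path)


def is_integral(values, tol: float = 1e-9) -> bool:
    values = np.asarray(values, dtype=float)
    return bool(np.all(np.abs(values - np.round(values)) <= tol))
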