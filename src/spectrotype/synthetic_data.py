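"""Ground-truthed synthetic whole-cell protein profiles.

The generator emulates the structure the analyses assume: strains nest in
species nest in genera; every species carries shared genus-marker peaks
(identical across the genus), species markers, and strain-specific
constitutive peaks — all in the constitutive 3-8 kDa region — plus
condition-variable peaks concentrated in the 8-15 kDa segments with
occurrence probabilities below 1. Replicates follow the 3 biological x 6
technical design: presence and a biological intensity factor are drawn per
biological replicate, calibration jitter and a technical intensity factor
per technical replicate. Raw profiles are rendered as Gaussian mixtures on
a uniform grid with an exponentially decaying baseline and additive noise;
peak width grows with mass (sigma = m/z / 2000 Da) as linear-mode TOF
resolution worsens.

All randomness flows from a single seed through numpy's splittable
generators, so every dataset is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .peaks import round_half_away
from .spectrum_io import PeakList, Spectrum, default_meta
from .taxonomy import Node


@dataclass
class NoiseModel:
    """Instrument and biological variability of the simulated acquisition.

    mz_jitter_sd: calibration jitter per technical replicate (Da), truncated
        at +/- mz_jitter_max.
    intensity_cv_technical / _biological: lognormal coefficients of
        variation of the per-peak intensity factors.
    baseline_amplitude: baseline height at the low-mass edge, as a fraction
        of the base peak, decaying exponentially with m/z.
    noise_sd: additive Gaussian noise, fraction of the base peak.
    """

    mz_jitter_sd: float = 0.5
    mz_jitter_max: float = 1.0
    intensity_cv_technical: float = 0.15
    intensity_cv_biological: float = 0.30
    baseline_amplitude: float = 0.05
    baseline_decay_da: float = 3000.0
    noise_sd: float = 0.01

    def __post_init__(self):
        for name in (
            "mz_jitter_sd", "mz_jitter_max", "intensity_cv_technical",
            "intensity_cv_biological", "baseline_amplitude",
            "baseline_decay_da", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @staticmethod
    def peak_sigma(mz) -> np.ndarray:
        """Gaussian peak width (Da) as a function of mass."""
        return np.asarray(mz, dtype=float) / 2000.0


@dataclass
class SpeciesTemplate:
    """True peak table of one strain (genus/species/strain labelled).

    origin flags each peak as genus_marker, species_marker, strain_marker
    (all constitutive, occurrence 1) or variable (occurrence < 1,
    concentrated in the high-mass segments).
    """

    genus: str
    species: str
    strain: str
    mz: np.ndarray
    base_intensity: np.ndarray
    occurrence_prob: np.ndarray
    origin: list = field(default_factory=list)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.base_intensity = np.asarray(self.base_intensity, dtype=float)
        self.occurrence_prob = np.asarray(self.occurrence_prob, dtype=float)
        if len(self) > PeakList.MAX_PEAKS:
            raise ParameterError(
                f"template holds {len(self)} peaks, above the {PeakList.MAX_PEAKS} cap"
            )
        constitutive = (self.occurrence_prob >= 1.0).sum()
        if constitutive < 3:
            raise ParameterError("a template needs >= 3 constitutive peaks")

    def __len__(self) -> int:
        return int(self.mz.size)

    def meta(self, **extra) -> dict:
        return default_meta(
            strain_id=self.strain, species=self.species, genus=self.genus, **extra
        )

    def to_peaklist(self) -> PeakList:
        """Noiseless constitutive peak list (occurrence 1 only), max-normalized."""
        mask = self.occurrence_prob >= 1.0
        inten = self.base_intensity[mask]
        return PeakList(
            self.mz[mask], inten / inten.max(),
            NoiseModel.peak_sigma(self.mz[mask]), self.meta(),
        )


# constitutive markers live in 3-8 kDa, variable peaks in 8-15 kDa,
# mirroring the constitutive-vs-variable segment split seen in real profiles
_CONST_LO, _CONST_HI = 3012, 7996
_VAR_LO, _VAR_HI = 8004, 14972
_MIN_SEPARATION = 8  # Da; > 2x the 2-Da match tolerance plus max jitter


def make_taxonomy(
    n_genera: int,
    species_per_genus: int,
    strains_per_species: int,
    seed: int | None = None,
    n_genus_markers: int = 8,
    n_species_markers: int = 6,
    n_strain_markers: int = 3,
    n_variable: int = 6,
) -> tuple[list[SpeciesTemplate], Node]:
    """Draw per-strain peak templates plus the true genus/species/strain tree.

    Genus-marker peak sets are disjoint across genera and identical within a
    genus; species and strain markers are unique to their taxon. Positions
    are drawn without replacement on an 8-Da lattice so no two true peaks
    can collide under the 2-Da match tolerance and +/-1 Da jitter.
    """
    if min(n_genera, species_per_genus, strains_per_species) < 1:
        raise ParameterError("all taxonomy counts must be >= 1")
    per_template = n_genus_markers + n_species_markers + n_strain_markers + n_variable
    if per_template > PeakList.MAX_PEAKS:
        raise ParameterError(
            f"{per_template} peaks per template exceed the {PeakList.MAX_PEAKS} cap"
        )
    rng = np.random.default_rng(seed)
    const_pool = np.arange(_CONST_LO, _CONST_HI, _MIN_SEPARATION)
    var_pool = np.arange(_VAR_LO, _VAR_HI, _MIN_SEPARATION)
    n_const = (
        n_genera * n_genus_markers
        + n_genera * species_per_genus * n_species_markers
        + n_genera * species_per_genus * strains_per_species * n_strain_markers
    )
    n_var = n_genera * species_per_genus * n_variable
    if n_const > const_pool.size or n_var > var_pool.size:
        raise ParameterError(
            "requested taxonomy needs more distinct peak positions than the "
            "working range offers"
        )
    const_positions = iter(rng.choice(const_pool, size=n_const, replace=False))
    var_positions = iter(rng.choice(var_pool, size=n_var, replace=False))

    templates: list[SpeciesTemplate] = []
    genus_nodes = []
    for g in range(n_genera):
        genus = f"Genus{g + 1:02d}"
        genus_mz = np.array([next(const_positions) for _ in range(n_genus_markers)], float)
        genus_int = rng.uniform(0.4, 1.0, size=n_genus_markers)
        species_nodes = []
        for s in range(species_per_genus):
            species = f"{genus}_sp{s + 1:02d}"
            sp_mz = np.array([next(const_positions) for _ in range(n_species_markers)], float)
            sp_int = rng.uniform(0.3, 0.9, size=n_species_markers)
            var_mz = np.array([next(var_positions) for _ in range(n_variable)], float)
            var_int = rng.uniform(0.1, 0.5, size=n_variable)
            var_occ = rng.uniform(0.3, 0.8, size=n_variable)
            strain_nodes = []
            for t in range(strains_per_species):
                strain = f"{species}_st{t + 1:02d}"
                st_mz = np.array([next(const_positions) for _ in range(n_strain_markers)], float)
                st_int = rng.uniform(0.2, 0.6, size=n_strain_markers)
                # small strain-specific expression shift on the shared peaks
                shift = np.exp(rng.normal(0.0, 0.05, size=genus_mz.size + sp_mz.size + var_mz.size))
                mz = np.concatenate([genus_mz, sp_mz, st_mz, var_mz])
                inten = np.concatenate(
                    [
                        np.concatenate([genus_int, sp_int]) * shift[: genus_mz.size + sp_mz.size],
                        st_int,
                        var_int * shift[genus_mz.size + sp_mz.size :],
                    ]
                )
                occ = np.concatenate(
                    [
                        np.ones(n_genus_markers + n_species_markers + n_strain_markers),
                        var_occ,
                    ]
                )
                origin = (
                    ["genus_marker"] * n_genus_markers
                    + ["species_marker"] * n_species_markers
                    + ["strain_marker"] * n_strain_markers
                    + ["variable"] * n_variable
                )
                order = np.argsort(mz, kind="stable")
                templates.append(
                    SpeciesTemplate(
                        genus, species, strain,
                        mz[order], np.clip(inten[order], 0.05, 1.0), occ[order],
                        [origin[i] for i in order],
                    )
                )
                strain_nodes.append(Node(name=strain, length=1.0))
            species_nodes.append(
                Node(name=None, children=strain_nodes, length=1.0, height=1.0)
            )
        genus_nodes.append(
            Node(name=None, children=species_nodes, length=1.0, height=2.0)
        )
    if len(templates) == 1:
        truth = Node(name=templates[0].strain)
    else:
        truth = Node(children=genus_nodes, height=3.0)
    return templates, truth


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multiplicative factor with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_replicates(
    t: SpeciesTemplate,
    n_bio: int = 3,
    n_tech: int = 6,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    condition: str = "unknown",
) -> list[PeakList]:
    """Simulate the 3 biological x 6 technical replicate design.

    Per biological replicate: Bernoulli presence per peak (occurrence
    probability) and a biological intensity factor. Per technical replicate:
    truncated-normal m/z jitter and a technical intensity factor. Each
    replicate is max-normalized, thresholded at 5%, capped at 100 peaks and
    binned to integer Da, so the outputs satisfy the PeakList invariants.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    out: list[PeakList] = []
    npk = len(t)
    for b in range(n_bio):
        present = rng.random(npk) < t.occurrence_prob
        bio = _lognormal_factor(rng, noise.intensity_cv_biological, npk)
        for k in range(n_tech):
            if noise.mz_jitter_sd > 0:
                jitter = np.clip(
                    rng.normal(0.0, noise.mz_jitter_sd, size=npk),
                    -noise.mz_jitter_max,
                    noise.mz_jitter_max,
                )
            else:
                jitter = np.zeros(npk)
            tech = _lognormal_factor(rng, noise.intensity_cv_technical, npk)
            inten = t.base_intensity * bio * tech
            mask = present & (inten > 0)
            mz = t.mz[mask] + jitter[mask]
            inten = inten[mask]
            inten = inten / inten.max()
            keep = inten >= PeakList.MIN_REL_INTENSITY
            mz, inten = mz[keep], inten[keep]
            if mz.size > PeakList.MAX_PEAKS:
                top = np.argsort(-inten, kind="stable")[: PeakList.MAX_PEAKS]
                mz, inten = mz[top], inten[top]
            order = np.argsort(mz, kind="stable")
            mz, inten = round_half_away(mz[order]), inten[order]
            # collapse same-bin collisions, keeping the larger intensity
            best: dict[int, float] = {}
            for m_, i_ in zip(mz, inten):
                key = int(m_)
                if key not in best or i_ > best[key]:
                    best[key] = float(i_)
            mzb = np.array(sorted(best), dtype=float)
            intb = np.array([best[int(m_)] for m_ in mzb])
            out.append(
                PeakList(
                    mzb, intb, NoiseModel.peak_sigma(mzb),
                    t.meta(bio_rep=b + 1, tech_rep=k + 1, condition=condition),
                )
            )
    return out


def render_raw_spectrum(
    pl: PeakList,
    noise: NoiseModel | None = None,
    grid_step: float = 1.0,
    seed: int | None = None,
    mz_min: float = 300.0,
    mz_max: float = 20000.0,
) -> Spectrum:
    """Render a peak list as a raw continuous profile with known truth.

    Sum of Gaussians (height = relative intensity, sigma = m/z / 2000) on a
    uniform grid, plus an exponentially decaying baseline and additive
    Gaussian noise; the result is clipped at zero.
    """
    if grid_step <= 0:
        raise ParameterError("grid_step must be positive")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    grid = np.arange(mz_min, mz_max + grid_step / 2, grid_step)
    y = noise.baseline_amplitude * np.exp(-(grid - mz_min) / noise.baseline_decay_da)
    for m, h in zip(pl.mz, pl.rel_intensity):
        sigma = float(NoiseModel.peak_sigma(m))
        lo = np.searchsorted(grid, m - 6 * sigma)
        hi = np.searchsorted(grid, m + 6 * sigma)
        if hi > lo:
            y[lo:hi] += h * np.exp(-0.5 * ((grid[lo:hi] - m) / sigma) ** 2)
    if noise.noise_sd > 0:
        y = y + rng.normal(0.0, noise.noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(y, 0.0, None), dict(pl.meta))
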