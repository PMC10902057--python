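"""Forward simulation of MSI datacubes from a labelled tissue phantom.

Each tissue pixel renders its region template as Gaussian peaks (constant
FWHM in m/z, default set for a resolving power of ~60,000 at m/z 700) at
the species' [M-H]- masses, scaled by a per-pixel total-signal factor,
mass-shifted by a per-pixel ppm drift, and degraded by multiplicative
log-normal peak noise plus an additive baseline.  Background pixels carry
baseline only.  All latent ground truth (labels, TIC factors, drifts,
jittered templates) is returned so downstream stages can be tested for
recovery.

The m/z axis is sparse: a window of samples around every simulated
species, each window centred exactly on the species m/z so that the
noiseless, drift-free cube reproduces template abundances exactly at the
apex sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import SpectraCube
from .lipids import make_species
from .phantom import BACKGROUND, TissuePhantom, build_phantom, default_geometry, jitter_geometry
from .templates import RegionTemplate, default_region_templates

__all__ = ["NoiseModel", "SimulationTruth", "Section", "simulate_cube",
           "simulate_study", "OutOfWindowError", "NOISELESS"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class OutOfWindowError(ValueError):
    """A template species falls outside the acquisition m/z window."""


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-variability model.

    peak_fwhm_mz      Gaussian peak width in Da (default 700/60000).
    intensity_cv      log-normal CV of each pixel-peak amplitude.
    tic_cv            log-normal CV of the per-pixel total-signal factor.
    drift_ppm_sd      SD of the per-pixel rigid mass shift, in ppm.
    baseline_level    additive background (same intensity units as peaks,
                      where a region template has unit total abundance).
    shot_noise        Poisson count noise (at ``shot_counts`` counts per
                      intensity unit) on top of the continuous model.
    """

    peak_fwhm_mz: float = 700.0 / 60000.0
    intensity_cv: float = 0.15
    tic_cv: float = 0.20
    drift_ppm_sd: float = 3.0
    baseline_level: float = 1e-4
    shot_noise: bool = False
    shot_counts: float = 1e4
    seed: int = 0

    def __post_init__(self):
        for name in ("peak_fwhm_mz", "intensity_cv", "tic_cv", "drift_ppm_sd",
                     "baseline_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISELESS = NoiseModel(intensity_cv=0.0, tic_cv=0.0, drift_ppm_sd=0.0,
                       baseline_level=0.0, shot_noise=False)


@dataclass
class SimulationTruth:
    labels: np.ndarray                  # (h, w) region codes
    tic_factors: np.ndarray             # per retained pixel
    shifts_ppm: np.ndarray              # per retained pixel
    templates: dict                     # region code -> RegionTemplate (after jitter)
    species_mz: dict                    # species name -> [M-H]- m/z
    noise: NoiseModel
    seed: int

    def pixel_labels(self, coords: np.ndarray) -> np.ndarray:
        return self.labels[coords[:, 0], coords[:, 1]]


@dataclass
class Section:
    section_id: int
    cube: SpectraCube
    truth: SimulationTruth
    phantom: TissuePhantom


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _build_axis(mzs: np.ndarray, fwhm: float, grid_ppm: float,
                drift_ppm_sd: float, mz_min: float, mz_max: float) -> np.ndarray:
    """Union of sample windows centred exactly on each species m/z."""
    pts = []
    for mu in mzs:
        half = 4.0 * fwhm + mu * (3.0 * drift_ppm_sd + 5.0) * 1e-6
        step = mu * grid_ppm * 1e-6
        k = int(np.ceil(half / step))
        w = mu + step * np.arange(-k, k + 1)
        pts.append(w[(w >= mz_min) & (w <= mz_max)])
    axis = np.unique(np.concatenate(pts))
    keep = np.ones(len(axis), bool)
    keep[1:] = np.diff(axis) > 1e-9
    return axis[keep]


def simulate_cube(phantom: TissuePhantom, templates: dict | None = None,
                  noise: NoiseModel | None = None,
                  mz_min: float = 550.0, mz_max: float = 1000.0,
                  grid_ppm: float = 4.0):
    """Render a phantom into a SpectraCube; returns ``(cube, truth)``."""
    if templates is None:
        templates = default_region_templates()
    noise = noise if noise is not None else NoiseModel()
    if mz_min >= mz_max:
        raise ValueError("mz_min must be < mz_max")

    regions = sorted(set(np.unique(phantom.labels)) - {BACKGROUND})
    for r in regions:
        if r not in templates:
            raise ValueError(f"no template for region code {r}")

    species = sorted({s for r in regions for s in templates[r].species_abundances
                      if templates[r].species_abundances[s] > 0})
    species_mz = {}
    for s in species:
        mu = make_species(s).mz_mh
        if not (mz_min <= mu <= mz_max):
            raise OutOfWindowError(
                f"species {s} at m/z {mu:.4f} outside window [{mz_min}, {mz_max}]")
        species_mz[s] = mu

    mus = np.array([species_mz[s] for s in species])
    axis = _build_axis(mus, noise.peak_fwhm_mz, grid_ppm, noise.drift_ppm_sd,
                       mz_min, mz_max)

    rng = np.random.default_rng(noise.seed)
    h, w = phantom.labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.column_stack([rr.ravel(), cc.ravel()])
    labels_flat = phantom.labels.ravel()
    n_pix = len(coords)

    tic_factors = _lognormal_factor(rng, noise.tic_cv, n_pix)
    shifts = (rng.normal(0.0, noise.drift_ppm_sd, n_pix)
              if noise.drift_ppm_sd > 0 else np.zeros(n_pix))

    inten = np.zeros((n_pix, len(axis)))
    sigma = noise.peak_fwhm_mz * FWHM_TO_SIGMA
    tissue = labels_flat != BACKGROUND
    tidx = np.flatnonzero(tissue)

    abund = np.zeros((n_pix, len(species)))
    for r in regions:
        vec = templates[r].vector(species)
        abund[labels_flat == r] = vec
    if noise.intensity_cv > 0:
        abund[tidx] *= _lognormal_factor(rng, noise.intensity_cv,
                                         (len(tidx), len(species)))
    amp = abund * tic_factors[:, None]

    for j, mu in enumerate(mus):
        lo = np.searchsorted(axis, mu - 4.5 * noise.peak_fwhm_mz - mu * 50e-6)
        hi = np.searchsorted(axis, mu + 4.5 * noise.peak_fwhm_mz + mu * 50e-6)
        g = axis[lo:hi]
        centers = mu * (1.0 + shifts[tidx] * 1e-6)
        shape = np.exp(-0.5 * ((g[None, :] - centers[:, None]) / sigma) ** 2)
        inten[tidx, lo:hi] += amp[tidx, j][:, None] * shape

    if noise.baseline_level > 0:
        inten += noise.baseline_level
    if noise.shot_noise:
        inten = rng.poisson(inten * noise.shot_counts) / noise.shot_counts

    cube = SpectraCube(mz=axis, intensities=inten, coords=coords, shape=(h, w),
                       pixel_size_um=phantom.pixel_size_um,
                       mz_window=(mz_min, mz_max),
                       metadata={"simulated": True, "seed": noise.seed})
    truth = SimulationTruth(labels=phantom.labels.copy(), tic_factors=tic_factors,
                            shifts_ppm=shifts, templates=templates,
                            species_mz=species_mz, noise=noise, seed=noise.seed)
    return cube, truth


def jitter_templates(templates: dict, rng: np.random.Generator,
                     jitter_cv: float) -> dict:
    """Per-section (inter-animal) log-normal jitter on template abundances."""
    if jitter_cv <= 0:
        return templates
    out = {}
    for r, t in templates.items():
        f = _lognormal_factor(rng, jitter_cv, len(t.species_abundances))
        raw = {s: a * fi for (s, a), fi in zip(t.species_abundances.items(), f)}
        total = sum(raw.values())
        out[r] = RegionTemplate(region=r,
                                species_abundances={s: v / total for s, v in raw.items()},
                                effect_table=dict(t.effect_table))
    return out


def simulate_study(n_sections: int = 9, width: int = 48, height: int = 48,
                   seed: int = 0, noise: NoiseModel | None = None,
                   effect_scale: float = 1.0, jitter_cv: float = 0.10,
                   geometry_jitter: bool = True) -> list[Section]:
    """Simulate a cohort of sections (default nine, one per animal).

    Each section gets its own RNG stream, lesion geometry jitter and
    log-normal template jitter (inter-animal variability).
    """
    base_noise = noise if noise is not None else NoiseModel()
    base_templates = default_region_templates(effect_scale=effect_scale)
    ss = np.random.SeedSequence(seed)
    sections = []
    for i, child in enumerate(ss.spawn(n_sections)):
        rng = np.random.default_rng(child)
        geo = default_geometry(width, height)
        if geometry_jitter:
            for _ in range(10):
                cand = jitter_geometry(geo, rng)
                try:
                    ph = build_phantom(width, height, cand)
                    break
                except Exception:
                    continue
            else:
                ph = build_phantom(width, height, geo)
        else:
            ph = build_phantom(width, height, geo)
        tmpl = jitter_templates(base_templates, rng, jitter_cv)
        sec_seed = int(rng.integers(0, 2**31 - 1))
        nm = NoiseModel(**{**base_noise.__dict__, "seed": sec_seed})
        cube, truth = simulate_cube(ph, tmpl, nm)
        sections.append(Section(section_id=i, cube=cube, truth=truth, phantom=ph))
    return sections
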