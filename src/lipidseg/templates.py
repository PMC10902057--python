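"""Per-region lipid fingerprints for the simulator.

The templates encode the directional changes reported for LPC-induced
demyelination at 14 days post injection: going from uninvolved white
matter through the peri-lesion into the lesion core, total PC and PE
rise, PC ethers fall, sulfatides and PS fall, SM rises, PI 38:4 (the main
arachidonic-acid store) rises strongly together with other putative
AA-containing PI species, PE-ether species remodel (36:2e/40:6e down,
38:6e/38:7e/40:7e up) and PE 36:5e peaks in the peri-lesion.  Grey matter
is PI-rich and poor in myelin lipids (sulfatides, ethers).

Abundances are relative (each template sums to 1).  ``effect_scale``
interpolates every region multiplicatively toward the white-matter
template: 1 reproduces the default effect sizes, 0 makes all regions
identical (used for effect-size monotonicity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import GREY_MATTER, LESION_CORE, PERI_LESION, WHITE_MATTER

__all__ = ["RegionTemplate", "default_region_templates", "MissingClassError",
           "SIMULATED_SPECIES", "REQUIRED_CLASSES", "class_totals"]

REQUIRED_CLASSES = ("PC", "PC-E", "PE", "PE-E", "PI", "PS", "PG", "SM", "ST")


class MissingClassError(ValueError):
    """The species library does not cover a required lipid class."""


# (species, white-matter weight within class)
_CLASS_SPECIES = {
    "PC":   [("PC 32:0", 0.15), ("PC 34:0", 0.10), ("PC 34:1", 0.35),
             ("PC 36:1", 0.25), ("PC 38:4", 0.15)],
    "PC-E": [("PC 32:0e", 0.30), ("PC 34:1e", 0.40), ("PC 36:4e", 0.30)],
    "PE":   [("PE 34:1", 0.20), ("PE 36:1", 0.20), ("PE 36:2", 0.25),
             ("PE 38:4", 0.15), ("PE 40:6", 0.20)],
    "PE-E": [("PE 36:2e", 0.25), ("PE 40:6e", 0.25), ("PE 38:6e", 0.15),
             ("PE 38:7e", 0.10), ("PE 40:7e", 0.10), ("PE 36:5e", 0.15)],
    "PI":   [("PI 36:1", 0.20), ("PI 36:4", 0.12), ("PI 37:4", 0.08),
             ("PI 38:4", 0.25), ("PI 38:5", 0.10), ("PI 38:6", 0.10),
             ("PI 40:6", 0.15)],
    "PS":   [("PS 36:1", 0.40), ("PS 36:2", 0.20), ("PS 38:4", 0.20),
             ("PS 40:6", 0.20)],
    "PG":   [("PG 34:1", 0.40), ("PG 36:2", 0.35), ("PG 38:4", 0.25)],
    "SM":   [("SM 34:1", 0.50), ("SM 36:1", 0.30), ("SM 42:2", 0.20)],
    "ST":   [("ST 40:1", 0.15), ("ST 41:1", 0.10), ("ST 42:1", 0.25),
             ("ST 42:2", 0.35), ("ST 44:1", 0.15)],
}

# white-matter class totals (myelin-rich: high sulfatide)
_CLASS_BASE = {
    "PC": 0.14, "PC-E": 0.07, "PE": 0.12, "PE-E": 0.11, "PI": 0.10,
    "PS": 0.10, "PG": 0.04, "SM": 0.05, "ST": 0.27,
}

# multiplicative change vs white matter, per class: (peri, core, grey)
_CLASS_FACTORS = {
    "PC":   (1.4, 1.9, 1.3),
    "PC-E": (0.7, 0.5, 0.6),
    "PE":   (1.3, 1.6, 1.1),
    "PE-E": (1.0, 1.0, 0.5),
    "PI":   (1.0, 1.0, 1.8),
    "PS":   (0.75, 0.55, 1.1),
    "PG":   (1.0, 1.0, 1.2),
    "SM":   (1.5, 2.2, 1.3),
    "ST":   (0.65, 0.35, 0.25),
}

# species-level overrides (peri, core) for within-class remodelling
_SPECIES_FACTORS = {
    "PE 36:2e": (0.60, 0.35), "PE 40:6e": (0.65, 0.40),
    "PE 38:6e": (1.50, 2.00), "PE 38:7e": (1.40, 1.90), "PE 40:7e": (1.40, 1.80),
    "PE 36:5e": (1.80, 1.00),
    "PI 38:4": (2.20, 3.20),
    "PI 36:4": (1.40, 1.80), "PI 37:4": (1.40, 1.80), "PI 38:5": (1.40, 1.80),
    "PI 38:6": (1.40, 1.80), "PI 40:6": (1.40, 1.80),
    "PG 34:1": (0.80, 0.60), "PG 38:4": (1.30, 1.70),
}

SIMULATED_SPECIES = tuple(name for specs in _CLASS_SPECIES.values()
                          for name, _ in specs)


@dataclass(frozen=True)
class RegionTemplate:
    """Relative lipid abundances of one histological region."""

    region: int
    species_abundances: dict          # species name -> abundance, sums to 1
    effect_table: dict                # species name -> multiplier vs white matter

    def __post_init__(self):
        vals = np.array(list(self.species_abundances.values()))
        if (vals < 0).any():
            raise ValueError("abundances must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {vals.sum()!r}, expected 1")

    def vector(self, species_order) -> np.ndarray:
        return np.array([self.species_abundances.get(s, 0.0) for s in species_order])


def _white_abundances() -> dict:
    out = {}
    for cls, specs in _CLASS_SPECIES.items():
        for name, w in specs:
            out[name] = _CLASS_BASE[cls] * w
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def _region_factor(name: str, cls: str, which: int) -> float:
    if which < 2 and name in _SPECIES_FACTORS:          # peri / core overrides
        return _SPECIES_FACTORS[name][which]
    return _CLASS_FACTORS[cls][which]


def default_region_templates(species_library=None, effect_scale: float = 1.0) -> dict:
    """Templates for white matter, peri-lesion, lesion core and grey matter.

    ``species_library``: optional DataFrame with ``name`` and ``class``
    columns; when given it must cover every required class and every
    simulated species (otherwise :class:`MissingClassError`).
    """
    if species_library is not None:
        have_classes = set(species_library["class"])
        missing = [c for c in REQUIRED_CLASSES if c not in have_classes]
        if missing:
            raise MissingClassError(f"library lacks classes: {missing}")
        have_names = set(species_library["name"])
        absent = [s for s in SIMULATED_SPECIES if s not in have_names]
        if absent:
            raise MissingClassError(f"library lacks species: {absent}")

    white = _white_abundances()
    cls_of = {name: cls for cls, specs in _CLASS_SPECIES.items() for name, _ in specs}

    templates = {}
    for region, which in ((WHITE_MATTER, None), (PERI_LESION, 0),
                          (LESION_CORE, 1), (GREY_MATTER, 2)):
        if which is None:
            effects = {s: 1.0 for s in white}
        else:
            effects = {s: _region_factor(s, cls_of[s], which) ** effect_scale
                       for s in white}
        raw = {s: white[s] * effects[s] for s in white}
        total = sum(raw.values())
        templates[region] = RegionTemplate(
            region=region,
            species_abundances={s: v / total for s, v in raw.items()},
            effect_table=effects,
        )
    return templates


def class_totals(abundances: dict) -> dict:
    """Roll species abundances up to lipid-class totals."""
    cls_of = {name: cls for cls, specs in _CLASS_SPECIES.items() for name, _ in specs}
    out: dict = {}
    for s, v in abundances.items():
        cls = cls_of.get(s)
        if cls is None:
            continue
        out[cls] = out.get(cls, 0.0) + v
    return out
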