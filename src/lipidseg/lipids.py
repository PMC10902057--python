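"""Lipid shorthand parsing, elemental composition and monoisotopic [M-H]- m/z.

Covers the negative-ion-mode glycerophospholipid and sphingolipid classes
relevant to spinal-cord white matter: PC, PE (and their ether variants
PC-E / PE-E), PI, PS, PG, SM and sulfatides (ST).  Species are written in
the usual sum-composition shorthand, e.g. ``PI 38:4`` (38 acyl carbons,
4 double bonds), ``PE 36:2e`` (ether-linked, plasmanyl) or the sn-resolved
form ``PI 18:0/22:6``.

Masses are computed by summing monoisotopic atomic masses of an elemental
formula derived from documented class backbone compositions; the default
deprotonated adduct subtracts a proton (H minus one electron).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "LipidSpecies",
    "LipidParseError",
    "parse_shorthand",
    "format_shorthand",
    "species_formula",
    "formula_mass",
    "formula_to_string",
    "species_mz",
    "make_species",
    "build_default_library",
    "load_library",
    "DEFAULT_LIBRARY_SPECIES",
]

# Monoisotopic atomic masses (Da), CODATA/AME values.
MONOISOTOPIC = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}
ELECTRON_MASS = 0.00054857990907
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

# Head-group atoms added to the diacyl phosphatidic-acid skeleton
# C(c+3) H(2c-2d+5) O8 P for a glycerophospholipid with c carbons and
# d double bonds summed over both chains.
_GPL_HEAD = {
    "PC": {"C": 5, "H": 11, "N": 1},
    "PE": {"C": 2, "H": 5, "N": 1},
    "PG": {"C": 3, "H": 6, "O": 2},
    "PS": {"C": 3, "H": 5, "N": 1, "O": 2},
    "PI": {"C": 6, "H": 10, "O": 5},
}

GLYCEROPHOSPHOLIPID_CLASSES = frozenset(_GPL_HEAD)
ETHER_CAPABLE = frozenset({"PC", "PE"})
SPHINGOLIPID_CLASSES = frozenset({"SM", "ST"})
ALL_CLASSES = ("PC", "PC-E", "PE", "PE-E", "PI", "PS", "PG", "SM", "ST")


class LipidParseError(ValueError):
    """Raised when a shorthand name does not match the grammar."""

    def __init__(self, name: str, position: int, message: str):
        self.name = name
        self.position = position
        super().__init__(f"cannot parse {name!r} at position {position}: {message}")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid species identified by class and sum composition.

    ``lipid_class`` is the annotation-level class code (ether variants get
    their own code, ``PC-E`` / ``PE-E``); ``carbons`` and ``double_bonds``
    are summed over both chains.  ``chains`` holds the sn-resolved
    composition when the name provided one.
    """

    name: str
    lipid_class: str
    carbons: int
    double_bonds: int
    ether: bool = False
    chains: tuple[tuple[int, int], ...] = ()
    formula: dict = field(default_factory=dict)
    neutral_mass: float = 0.0
    mz_mh: float = 0.0


_NAME_RE = re.compile(
    r"^(?P<cls>PC|PE|PI|PS|PG|SM|ST)(?P<ecls>-E)?\s+"
    r"(?P<c1>\d+):(?P<d1>\d+)"
    r"(?:(?P<e>e)|/(?P<c2>\d+):(?P<d2>\d+))?$"
)


def parse_shorthand(name: str) -> LipidSpecies:
    """Parse shorthand into structural fields (no mass computation).

    Accepts ``CLASS C:D``, ``CLASS C:De`` (ether) and ``CLASS C1:D1/C2:D2``
    (sn-resolved; summed for the composition).
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        # locate first offending character for the error position
        probe = re.match(r"^(PC|PE|PI|PS|PG|SM|ST)(-E)?\s+\d*:?\d*", name.strip())
        pos = probe.end() if probe else 0
        raise LipidParseError(name, pos, "expected CLASS C:D[e] or CLASS C1:D1/C2:D2")
    base = m.group("cls")
    ether = bool(m.group("e")) or bool(m.group("ecls"))
    if ether and base not in ETHER_CAPABLE:
        raise LipidParseError(name, m.start("e") if m.group("e") else 2,
                              f"ether variant not defined for class {base}")
    chains: tuple[tuple[int, int], ...] = ()
    c, d = int(m.group("c1")), int(m.group("d1"))
    if m.group("c2") is not None:
        c2, d2 = int(m.group("c2")), int(m.group("d2"))
        chains = ((c, d), (c2, d2))
        c, d = c + c2, d + d2
    if not c > d >= 0:
        raise LipidParseError(name, m.start("c1"),
                              f"require carbons > double bonds >= 0, got {c}:{d}")
    cls = base + "-E" if ether else base
    return LipidSpecies(name=name.strip(), lipid_class=cls, carbons=c,
                        double_bonds=d, ether=ether, chains=chains)


def format_shorthand(species: LipidSpecies) -> str:
    """Canonical sum-composition name (sn information is not preserved)."""
    base = species.lipid_class.removesuffix("-E")
    suffix = "e" if species.ether else ""
    return f"{base} {species.carbons}:{species.double_bonds}{suffix}"


def species_formula(lipid_class: str, carbons: int, double_bonds: int) -> dict:
    """Elemental formula from the class backbone and the sum composition.

    Glycerophospholipids are built as diacyl phosphatidic acid plus the
    class head group; the ether (plasmanyl) variant replaces one ester
    linkage by an ether (-O +2H).  SM uses the d-sphingoid ceramide
    phosphocholine backbone; ST is sulfated galactosylceramide.
    """
    c, d = carbons, double_bonds
    base = lipid_class.removesuffix("-E")
    if base in _GPL_HEAD:
        formula = {"C": c + 3, "H": 2 * c - 2 * d + 5, "O": 8, "P": 1}
        for el, n in _GPL_HEAD[base].items():
            formula[el] = formula.get(el, 0) + n
        if lipid_class.endswith("-E"):
            formula["H"] += 2
            formula["O"] -= 1
        return formula
    if base == "SM":
        return {"C": c + 5, "H": 2 * c - 2 * d + 13, "N": 2, "O": 6, "P": 1}
    if base == "ST":
        return {"C": c + 6, "H": 2 * c - 2 * d + 11, "N": 1, "O": 11, "S": 1}
    raise ValueError(f"unknown lipid class {lipid_class!r}")


def formula_mass(formula: dict | str) -> float:
    """Monoisotopic mass of an elemental formula (dict or string 'C47H83O13P')."""
    if isinstance(formula, str):
        formula = _parse_formula_string(formula)
    return sum(MONOISOTOPIC[el] * n for el, n in formula.items())


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula_string(s: str) -> dict:
    out: dict = {}
    pos = 0
    for m in _FORMULA_RE.finditer(s):
        if m.start() != pos:
            raise ValueError(f"bad formula string {s!r}")
        if not m.group(0):
            break
        el = m.group(1)
        if el not in MONOISOTOPIC:
            raise ValueError(f"unknown element {el!r} in {s!r}")
        out[el] = out.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    return out


def formula_to_string(formula: dict) -> str:
    order = ["C", "H", "N", "O", "P", "S"]
    return "".join(f"{el}{formula[el]}" for el in order if formula.get(el))


def species_mz(species: LipidSpecies, adduct: str = "[M-H]-") -> float:
    """m/z of the species under the given adduct (only [M-H]- is supported)."""
    if adduct not in ("[M-H]-", "[M−H]−"):
        raise ValueError(f"unsupported adduct {adduct!r}")
    formula = species_formula(species.lipid_class, species.carbons, species.double_bonds)
    return formula_mass(formula) - PROTON_MASS


def make_species(name: str) -> LipidSpecies:
    """Parse a shorthand name and fill in formula and masses."""
    s = parse_shorthand(name)
    formula = species_formula(s.lipid_class, s.carbons, s.double_bonds)
    neutral = formula_mass(formula)
    return LipidSpecies(name=s.name, lipid_class=s.lipid_class, carbons=s.carbons,
                        double_bonds=s.double_bonds, ether=s.ether, chains=s.chains,
                        formula=formula, neutral_mass=neutral,
                        mz_mh=neutral - PROTON_MASS)


# Bundled library: every species used by the simulator plus additional
# common white/grey-matter species of the same classes, all with [M-H]-
# inside the 550-1000 Da acquisition window.
DEFAULT_LIBRARY_SPECIES = (
    # PC
    "PC 32:0", "PC 34:0", "PC 34:1", "PC 36:1", "PC 36:4", "PC 38:4", "PC 38:6",
    "PC 40:6",
    # PC ether
    "PC 32:0e", "PC 34:1e", "PC 36:4e", "PC 38:5e",
    # PE
    "PE 34:1", "PE 36:1", "PE 36:2", "PE 38:4", "PE 38:6", "PE 40:6",
    # PE ether
    "PE 36:2e", "PE 36:5e", "PE 38:6e", "PE 38:7e", "PE 40:6e", "PE 40:7e",
    # PI
    "PI 34:1", "PI 36:1", "PI 36:2", "PI 36:4", "PI 37:4", "PI 38:4", "PI 38:5",
    "PI 38:6", "PI 40:6",
    # PS
    "PS 36:1", "PS 36:2", "PS 38:4", "PS 40:4", "PS 40:6",
    # PG
    "PG 34:1", "PG 36:2", "PG 38:4", "PG 40:6",
    # SM
    "SM 34:1", "SM 36:1", "SM 38:1", "SM 42:2",
    # sulfatides
    "ST 40:1", "ST 41:1", "ST 42:1", "ST 42:2", "ST 42:3", "ST 44:1",
)


def build_default_library() -> pd.DataFrame:
    """Recompute the bundled library table from the species name list."""
    rows = []
    for name in DEFAULT_LIBRARY_SPECIES:
        sp = make_species(name)
        rows.append({
            "name": sp.name,
            "class": sp.lipid_class,
            "carbons": sp.carbons,
            "double_bonds": sp.double_bonds,
            "ether": int(sp.ether),
            "formula": formula_to_string(sp.formula),
            "neutral_mass": round(sp.neutral_mass, 6),
            "mz_MH": round(sp.mz_mh, 6),
        })
    return pd.DataFrame(rows).sort_values("mz_MH").reset_index(drop=True)


def load_library(path=None) -> pd.DataFrame:
    """Load the lipid mass library (bundled CSV by default)."""
    if path is not None:
        return pd.read_csv(path)
    with resources.files("lipidseg.data").joinpath("lipid_library.csv").open() as fh:
        return pd.read_csv(fh)
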