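"""Peak annotation against the lipid mass library by [M-H]- m/z matching."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Match", "Annotation", "annotate_peaks", "annotations_to_frame"]

PS_PI_FLAG = "ps_pi_overlap"
MULTI_FLAG = "multiple_candidates"


@dataclass(frozen=True)
class Match:
    name: str
    lipid_class: str
    library_mz: float
    error_ppm: float


@dataclass
class Annotation:
    """All library candidates for one picked peak, sorted by |ppm error|."""

    peak_mz: float
    matches: list[Match] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return len(self.matches) > 0

    @property
    def best(self) -> Match | None:
        return self.matches[0] if self.matches else None


def annotate_peaks(peak_mzs, library: pd.DataFrame, tol_ppm: float = 5.0) -> list[Annotation]:
    """Match each peak m/z against all library [M-H]- masses within ``tol_ppm``.

    Every candidate within tolerance is reported (sorted by absolute ppm
    error).  Peaks with several candidates are flagged; PS candidates are
    additionally flagged when the library holds a PI species of the same
    sum composition, because in-source fragmentation of that PI (loss of
    the anhydroinositol head, 162.0528 Da, against the serine head,
    87.0320 Da) lands exactly on the PS [M-H]- m/z.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(library) == 0:
        raise ValueError("library is empty")
    lib_mz = library["mz_MH"].to_numpy(float)
    names = library["name"].to_numpy(object)
    classes = library["class"].to_numpy(object)

    # sum compositions of PI species, for the PS caution flag
    pi_comps = set()
    for _, row in library.iterrows():
        if row["class"] == "PI":
            pi_comps.add((int(row["carbons"]), int(row["double_bonds"])))

    out: list[Annotation] = []
    for mz in np.atleast_1d(np.asarray(peak_mzs, float)):
        ppm = (mz - lib_mz) / lib_mz * 1e6
        hit = np.flatnonzero(np.abs(ppm) <= tol_ppm)
        order = hit[np.argsort(np.abs(ppm[hit]), kind="stable")]
        matches = [Match(names[k], classes[k], lib_mz[k], float(ppm[k])) for k in order]
        flags = []
        if len(matches) > 1:
            flags.append(MULTI_FLAG)
        for m in matches:
            if m.lipid_class == "PS":
                row = library.loc[library["name"] == m.name].iloc[0]
                if (int(row["carbons"]), int(row["double_bonds"])) in pi_comps:
                    flags.append(PS_PI_FLAG)
                    break
        if any(m.lipid_class == "PS" for m in matches) and any(
                m.lipid_class == "PI" for m in matches) and PS_PI_FLAG not in flags:
            flags.append(PS_PI_FLAG)
        out.append(Annotation(peak_mz=float(mz), matches=matches, flags=flags))
    return out


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Flat table: one row per peak with best match, all candidates and flags."""
    rows = []
    for a in annotations:
        rows.append({
            "peak_mz": a.peak_mz,
            "name": a.best.name if a.best else "",
            "class": a.best.lipid_class if a.best else "",
            "error_ppm": a.best.error_ppm if a.best else np.nan,
            "n_candidates": len(a.matches),
            "candidates": ";".join(m.name for m in a.matches),
            "flags": ";".join(a.flags),
        })
    return pd.DataFrame(rows)
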