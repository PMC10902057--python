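"""Readers and writers: imzML interchange, the internal compressed
container, label rasters and plain-text configuration."""

from __future__ import annotations

import json
import logging
import os
import struct

import numpy as np
import tifffile

from .cube import SpectraCube
from .phantom import REGION_NAMES

__all__ = [
    "IntegrityError", "write_imzml", "read_imzml", "write_cube", "read_cube",
    "write_labels", "read_labels", "write_config", "read_config",
    "write_segment_map", "REGION_LEGEND",
]

log = logging.getLogger(__name__)

REGION_LEGEND = dict(REGION_NAMES)


class IntegrityError(IOError):
    """imzML/ibd pair failed an integrity check."""


def write_imzml(cube: SpectraCube, path: str, mode: str = "processed") -> str:
    """Write the cube as an imzML/ibd pair (profile spectra, negative mode).

    Coordinates are written 1-based as (x, y) = (col+1, row+1).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    if not path.endswith(".imzML"):
        path += ".imzML"
    with ImzMLWriter(path, mode=mode, spec_type="profile",
                     polarity="negative", mz_dtype=np.float64,
                     intensity_dtype=np.float64) as w:
        for i, (r, c) in enumerate(cube.coords):
            w.addSpectrum(cube.mz, cube.intensities[i], (int(c) + 1, int(r) + 1, 1))
    return path


def read_imzml(path: str, pixel_size_um: float = 10.0,
               mz_window=(550.0, 1000.0)) -> SpectraCube:
    """Read an imzML/ibd pair (continuous or processed dialect).

    Ragged per-pixel axes are accepted and resampled onto a shared grid.
    A truncated or unreadable ibd raises :class:`IntegrityError`; missing
    polarity metadata logs a warning and negative mode is assumed.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = str(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if not os.path.exists(ibd):
        raise IntegrityError(f"missing ibd file for {path}")
    try:
        parser = ImzMLParser(path)
        mz_list, int_list, coords = [], [], []
        for i, (x, y, _z) in enumerate(parser.coordinates):
            mzs, ints = parser.getspectrum(i)
            mz_list.append(np.asarray(mzs, float))
            int_list.append(np.asarray(ints, float))
            coords.append((int(y) - 1, int(x) - 1))
    except (struct.error, ValueError, IndexError, EOFError) as e:
        raise IntegrityError(f"corrupt or truncated imzML/ibd pair: {e}") from e
    polarity = None
    try:
        polarity = parser.polarity
    except AttributeError:
        pass
    if not polarity:
        log.warning("imzML lacks polarity metadata; assuming negative mode")
        polarity = "negative"
    coords = np.asarray(coords, int)
    shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
    return SpectraCube.from_ragged(mz_list, int_list, coords, shape,
                                   pixel_size_um=pixel_size_um,
                                   polarity=str(polarity), mz_window=tuple(mz_window),
                                   metadata={"source": path})


def write_cube(cube: SpectraCube, path: str) -> str:
    """Internal container: one compressed npz plus a JSON metadata sidecar."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez_compressed(path, mz=cube.mz, intensities=cube.intensities,
                        coords=cube.coords)
    meta = {"shape": list(cube.shape), "pixel_size_um": cube.pixel_size_um,
            "polarity": cube.polarity, "mz_window": list(cube.mz_window),
            "metadata": {k: v for k, v in cube.metadata.items()
                         if isinstance(v, (str, int, float, bool))}}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_cube(path: str) -> SpectraCube:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path) as z:
        mz, inten, coords = z["mz"], z["intensities"], z["coords"]
    meta_path = path + ".json"
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    shape = tuple(meta.get("shape", (coords[:, 0].max() + 1, coords[:, 1].max() + 1)))
    return SpectraCube(mz=mz, intensities=inten, coords=coords, shape=shape,
                       pixel_size_um=meta.get("pixel_size_um", 10.0),
                       polarity=meta.get("polarity", "negative"),
                       mz_window=tuple(meta.get("mz_window", (550.0, 1000.0))),
                       metadata=meta.get("metadata", {}))


def write_labels(labels: np.ndarray, path: str) -> str:
    """Single-channel integer label raster (TIFF) with a JSON legend."""
    path = str(path)
    if not path.endswith((".tif", ".tiff")):
        path += ".tif"
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint8))
    with open(path + ".json", "w") as fh:
        json.dump({"legend": {str(k): v for k, v in REGION_LEGEND.items()}}, fh, indent=1)
    return path


def read_labels(path: str) -> np.ndarray:
    return tifffile.imread(str(path)).astype(int)


def write_segment_map(smap, path_prefix: str) -> dict:
    """Segment map as integer TIFF + JSON sidecar (tree, colours, sizes)."""
    raster_path = write_labels(np.clip(smap.raster() + 1, 0, 255), path_prefix + "_segments")
    sidecar = {
        "n_segments": smap.n_segments,
        "colors": [float(c) for c in smap.colors] if smap.colors is not None else None,
        "segment_sizes": {str(s): int((smap.labels == s).sum())
                          for s in range(smap.n_segments)},
        "note": "raster codes are segment id + 1; 0 marks excluded pixels",
        "tree": [{"id": nd["id"], "parent": nd["parent"],
                  "children": list(nd["children"]), "n_pixels": len(nd["pixels"])}
                 for nd in smap.tree],
    }
    with open(path_prefix + "_segments.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return {"raster": raster_path, "sidecar": path_prefix + "_segments.json"}


def write_config(params: dict, path: str) -> str:
    """Plain-text ``key = value`` configuration."""
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v}\n")
    return path


def read_config(path: str) -> dict:
    """Parse ``key = value`` lines; values are parsed as JSON scalars when
    possible, else kept as strings.  Lines starting with '#' are comments."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            try:
                out[k] = json.loads(v)
            except json.JSONDecodeError:
                out[k] = v
    return out
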