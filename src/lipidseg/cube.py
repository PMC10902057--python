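"""In-memory MSI datacube container.

A :class:`SpectraCube` holds one mass spectrum per raster pixel.  The fast
path keeps a single m/z axis shared by every pixel with intensities as a
dense ``(n_pixels, n_points)`` array; ragged (processed-imzML-style)
spectra are supported through ``from_ragged`` which resamples onto a
common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SpectraCube"]


@dataclass
class SpectraCube:
    mz: np.ndarray                 # (n_points,) shared, strictly increasing
    intensities: np.ndarray        # (n_pixels, n_points), >= 0
    coords: np.ndarray             # (n_pixels, 2) int (row, col), 0-based
    shape: tuple[int, int]         # (height, width)
    pixel_size_um: float = 10.0
    polarity: str = "negative"
    mz_window: tuple[float, float] = (550.0, 1000.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, float)
        self.intensities = np.asarray(self.intensities, float)
        self.coords = np.asarray(self.coords, int)
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.intensities.shape != (len(self.coords), len(self.mz)):
            raise ValueError("intensities shape mismatch with coords/mz")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def tic(self) -> np.ndarray:
        """Total ion current per pixel (sum of sampled intensities)."""
        return self.intensities.sum(axis=1)

    def copy(self) -> "SpectraCube":
        return replace(self, mz=self.mz.copy(), intensities=self.intensities.copy(),
                       coords=self.coords.copy(), metadata=dict(self.metadata))

    def pixel_index(self) -> dict:
        """(row, col) -> row number in the intensity matrix."""
        return {(int(r), int(c)): i for i, (r, c) in enumerate(self.coords)}

    def image(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-pixel vector back onto the (height, width) raster."""
        img = np.full(self.shape, fill, dtype=float)
        img[self.coords[:, 0], self.coords[:, 1]] = values
        return img

    @classmethod
    def from_ragged(cls, mz_list, intensity_list, coords, shape,
                    grid: np.ndarray | None = None, grid_ppm: float = 4.0,
                    **kw) -> "SpectraCube":
        """Build a shared-axis cube from per-pixel (m/z, intensity) arrays.

        If all pixels already share one axis it is used directly; otherwise
        spectra are linearly interpolated onto ``grid`` (default: a grid
        uniform in ppm spanning the union of the per-pixel axes).
        """
        first = np.asarray(mz_list[0], float)
        shared = all(len(m) == len(first) and np.array_equal(np.asarray(m), first)
                     for m in mz_list)
        if shared and grid is None:
            inten = np.vstack([np.asarray(i, float) for i in intensity_list])
            return cls(mz=first, intensities=inten, coords=coords, shape=shape, **kw)
        if grid is None:
            lo = min(float(np.min(m)) for m in mz_list if len(m))
            hi = max(float(np.max(m)) for m in mz_list if len(m))
            n = int(np.ceil(np.log(hi / lo) / np.log1p(grid_ppm * 1e-6))) + 1
            grid = lo * (1.0 + grid_ppm * 1e-6) ** np.arange(n)
        inten = np.zeros((len(mz_list), len(grid)))
        for i, (m, y) in enumerate(zip(mz_list, intensity_list)):
            if len(m):
                inten[i] = np.interp(grid, np.asarray(m, float),
                                     np.asarray(y, float), left=0.0, right=0.0)
        return cls(mz=grid, intensities=inten, coords=coords, shape=shape, **kw)
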