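"""One-dimensional latitudinal binning of the study area.

The study area is discretised into contiguous latitude bins of equal width
(0.01 degrees by default, roughly 1.1 km of coastline). Bins are half-open,
``[edge_l, edge_{l+1})``, lower edge inclusive, and indexed from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class LatitudeGrid:
    """A regular 1-D grid of latitude bins.

    Parameters
    ----------
    lat_origin : float
        Latitude of the southern edge of bin 1, in decimal degrees.
    bin_width_deg : float
        Width of each bin in degrees of latitude.
    n_bins : int
        Number of bins tiling the study extent.
    """

    lat_origin: float = 44.32
    bin_width_deg: float = 0.01
    n_bins: int = 55

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.bin_width_deg <= 0:
            raise ValueError("bin_width_deg must be positive")

    @property
    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_bins + 1``, strictly increasing."""
        return self.lat_origin + self.bin_width_deg * np.arange(self.n_bins + 1)

    @property
    def centroids(self) -> np.ndarray:
        """Bin centroids: ``lat_origin + (l - 0.5) * bin_width_deg`` for l = 1..n_bins."""
        return self.lat_origin + self.bin_width_deg * (np.arange(1, self.n_bins + 1) - 0.5)

    @property
    def extent(self) -> tuple[float, float]:
        """(southern edge of bin 1, northern edge of bin n_bins)."""
        return (self.lat_origin, self.lat_origin + self.n_bins * self.bin_width_deg)

    def bin_of(self, latitude: np.ndarray) -> np.ndarray:
        """Map latitudes to 1-based bin indices; -1 for out-of-extent values.

        Bins are half-open with the lower edge inclusive, so a latitude lying
        exactly on a shared edge belongs to the more northerly bin.
        """
        lat = np.asarray(latitude, dtype=float)
        # searchsorted against the edge array keeps shared edges exact in
        # floating point, which floor division does not
        idx = np.searchsorted(self.edges, lat, side="right")
        out = (idx < 1) | (idx > self.n_bins)
        return np.where(out, -1, idx)
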