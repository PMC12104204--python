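"""Space use and stressor exposure from posterior samples.

An individual's space use in a year is a normal distribution on latitude,
parameterised by its activity center (mean) and activity range (variance).
Per posterior draw, the *relative occurrence* in a bin is the normal
probability mass between the bin's edges. Occurrence is weighted by the
individual-year residency intercept rescaled to [0, 1], and overlapped with
per-bin stressor intensity layers (scaled to [0, 1]) to give one exposure
value per draw: ``E = (sum_l occ_l * s_l) * R'``.

Stressor layers are either static (one value per bin) or dynamic (one value
per bin, year and month); dynamic layers are annualised by averaging over
months before overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grid import LatitudeGrid
from .model import PosteriorSamples

__all__ = [
    "StressorLayer",
    "relative_occurrence",
    "rescale_residency",
    "space_use_distribution",
    "scale_layer",
    "proximity_proxy",
    "zones_to_bins",
    "annualize_dynamic",
    "exposure_distribution",
    "exposure_summaries",
]


@dataclass
class StressorLayer:
    """Per-bin intensity of an anthropogenic stressor or its proxy.

    Static layers carry ``values`` as a 1-D array over bins. Dynamic layers
    carry a long-format frame with columns ``bin_index, year, month, value``.
    ``scaled`` records whether values have been normalised to [0, 1].
    """

    name: str
    kind: str  # {"static", "dynamic"}
    values: np.ndarray | None = None
    table: pd.DataFrame | None = None
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "static":
            if self.values is None:
                raise ValueError("static layer requires per-bin values")
            self.values = np.asarray(self.values, dtype=float)
            if np.any(self.values < 0):
                raise ValueError("stressor values must be non-negative")
        else:
            if self.table is None:
                raise ValueError("dynamic layer requires a (bin, year, month) table")
            required = {"bin_index", "year", "month", "value"}
            if not required.issubset(self.table.columns):
                raise ValueError(f"dynamic layer table needs columns {sorted(required)}")
            if (self.table["value"] < 0).any():
                raise ValueError("stressor values must be non-negative")

    def max_value(self) -> float:
        if self.kind == "static":
            return float(np.max(self.values))
        return float(self.table["value"].max())


def relative_occurrence(C: float | np.ndarray, sigma2: float | np.ndarray,
                        grid: LatitudeGrid) -> np.ndarray:
    """Normal probability mass of each latitude bin.

    ``occ_l = Phi((edge_{l+1} - C)/sigma) - Phi((edge_l - C)/sigma)``.
    The result sums to at most 1; mass outside the grid extent is truncated,
    not renormalised. Broadcasts over arrays of ``C``/``sigma2`` and returns
    an array with a trailing bin axis.
    """
    C = np.asarray(C, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be strictly positive")
    sigma = np.sqrt(sigma2)
    z = (grid.edges - C[..., None]) / sigma[..., None]
    cdf = norm.cdf(z)
    return cdf[..., 1:] - cdf[..., :-1]


def rescale_residency(R: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Min-max rescale residency intercepts to [0, 1] within one draw.

    The rescaling runs jointly across all present (``A = 1``) individual-years
    of the draw so that years are comparable; absent individual-years map to 0
    (completely absent). If all present values coincide they map to 1 — a lone
    observed individual counts as fully resident. All-absent draws return
    zeros.
    """
    R = np.asarray(R, dtype=float)
    A = np.asarray(A)
    present = A.astype(bool)
    out = np.zeros_like(R, dtype=float)
    if not present.any():
        return out
    vals = R[present]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out[present] = 1.0
    else:
        out[present] = (vals - lo) / (hi - lo)
    return out


def _residency_weights(samples: PosteriorSamples) -> np.ndarray:
    """R' for every flattened draw, shape (n_draws, n_ind, n_years)."""
    R = samples.flat("R")
    A = samples.flat("A")
    return np.stack([rescale_residency(R[m], A[m]) for m in range(R.shape[0])])


def space_use_distribution(samples: PosteriorSamples, grid: LatitudeGrid) -> pd.DataFrame:
    """Posterior-mean residency-weighted occurrence per (individual, year, bin).

    Per retained draw the per-bin occurrence (from that draw's activity center
    and range) is multiplied by the draw's rescaled residency R'; draws with
    A = 0 contribute zeros. The mean over draws is returned long-format with
    columns ``individual_id, year, bin_index, mean_weighted_occurrence``.
    """
    C = samples.flat("C")
    sigma2 = samples.flat("sigma2")
    A = samples.flat("A").astype(bool)
    Rp = _residency_weights(samples)
    n_draws, n_ind, n_years = C.shape
    field = np.zeros((n_ind, n_years, grid.n_bins))
    for m in range(n_draws):
        occ = relative_occurrence(C[m], sigma2[m], grid)  # (ind, year, bins)
        occ *= (Rp[m] * A[m])[..., None]
        field += occ
    field /= n_draws
    rows = []
    for i, ind in enumerate(samples.individuals):
        for t, year in enumerate(samples.years):
            for l in range(grid.n_bins):
                rows.append((ind, year, l + 1, field[i, t, l]))
    return pd.DataFrame(rows, columns=["individual_id", "year", "bin_index",
                                       "mean_weighted_occurrence"])


def scale_layer(layer: StressorLayer) -> StressorLayer:
    """Divide all values by the layer's maximum so that the maximum is 1.

    Dynamic layers are scaled by their single global maximum across bins,
    years and months, preserving relative intensity through time.
    """
    m = layer.max_value()
    if m <= 0:
        raise ValueError(f"layer {layer.name!r} is all zero; cannot scale")
    if layer.kind == "static":
        return StressorLayer(layer.name, "static", values=layer.values / m, scaled=True)
    table = layer.table.copy()
    table["value"] = table["value"] / m
    return StressorLayer(layer.name, "dynamic", table=table, scaled=True)


def proximity_proxy(point_lat: float, grid: LatitudeGrid, name: str = "proximity",
                    form: str = "linear") -> StressorLayer:
    """Static raw layer encoding proximity of each bin to a point source.

    Distance proxies must be inverted so that greater proximity means higher
    intensity. The default linear inversion is ``max_dist - d`` (zero at the
    farthest bin, maximal at the source); ``form='reciprocal'`` uses
    ``1 / (d + bin_width)`` instead.
    """
    if not np.isfinite(point_lat):
        raise ValueError("point latitude must be finite")
    d = np.abs(grid.centroids - point_lat)
    if form == "linear":
        raw = d.max() - d
    elif form == "reciprocal":
        raw = 1.0 / (d + grid.bin_width_deg)
    else:
        raise ValueError(f"unknown proximity form {form!r}")
    return StressorLayer(name, "static", values=raw)


def zones_to_bins(zone_edges: np.ndarray, zone_values: np.ndarray,
                  zone_areas_km2: np.ndarray, grid: LatitudeGrid) -> np.ndarray:
    """Map per-zone totals onto latitude bins by length-weighted overlap.

    Zones are contiguous latitude intervals ``[zone_edges[k], zone_edges[k+1])``
    with a total value (e.g., permitted-vessel count) and an area. Each zone's
    value is first divided by its area to give a density, and each bin receives
    the overlap-length-weighted average of the densities of the zones it
    intersects.
    """
    zone_edges = np.asarray(zone_edges, dtype=float)
    zone_values = np.asarray(zone_values, dtype=float)
    zone_areas_km2 = np.asarray(zone_areas_km2, dtype=float)
    if len(zone_edges) != len(zone_values) + 1:
        raise ValueError("need len(zone_edges) == len(zone_values) + 1")
    density = zone_values / zone_areas_km2
    lo, hi = grid.edges[:-1], grid.edges[1:]
    out = np.zeros(grid.n_bins)
    for k in range(len(zone_values)):
        a, b = zone_edges[k], zone_edges[k + 1]
        overlap = np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)
        out += density[k] * overlap
    out /= grid.bin_width_deg
    return out


def annualize_dynamic(layer: StressorLayer) -> pd.DataFrame:
    """Mean dynamic stressor value across months within each (bin, year).

    Returns a frame ``bin_index, year, value``. Months missing from the table
    simply do not enter the mean; a (bin, year) with no months at all is an
    error because the annual overlap would be undefined there.
    """
    if layer.kind != "dynamic":
        raise ValueError("annualize_dynamic expects a dynamic layer")
    tab = layer.table
    annual = (tab.groupby(["bin_index", "year"], as_index=False)["value"].mean())
    # every (bin, year) pair spanned by the table must be present
    bins = tab["bin_index"].unique()
    years = tab["year"].unique()
    full = {(b, y) for b in bins for y in years}
    have = set(zip(annual["bin_index"], annual["year"]))
    missing = full - have
    if missing:
        raise ValueError(f"dynamic layer {layer.name!r} has no months for {sorted(missing)[:5]}")
    return annual


def _layer_per_year(layer: StressorLayer, years: list, grid: LatitudeGrid) -> np.ndarray:
    """Scaled per-bin values for each requested year, shape (n_years, n_bins)."""
    if not layer.scaled:
        layer = scale_layer(layer)
    if layer.kind == "static":
        return np.tile(layer.values, (len(years), 1))
    annual = annualize_dynamic(layer)
    out = np.zeros((len(years), grid.n_bins))
    for t, year in enumerate(years):
        sub = annual[annual["year"] == year]
        if sub.empty:
            raise ValueError(f"dynamic layer {layer.name!r} has no data for year {year}")
        vals = np.zeros(grid.n_bins)
        vals[sub["bin_index"].to_numpy(int) - 1] = sub["value"].to_numpy()
        out[t] = vals
    return out


def exposure_distribution(samples: PosteriorSamples, layer: StressorLayer,
                          grid: LatitudeGrid) -> np.ndarray:
    """Per-draw exposure values, shape (n_draws, n_ind, n_years).

    Per draw, per individual-year: overlap occurrence with the scaled stressor,
    sum over bins, and weight by rescaled residency. Every value lies in
    [0, 1] because occurrence sums to at most 1, the layer is scaled to at
    most 1, and R' is in [0, 1].
    """
    if layer.kind == "static" and layer.values is not None and len(layer.values) != grid.n_bins:
        raise ValueError("layer and grid bin counts differ")
    C = samples.flat("C")
    sigma2 = samples.flat("sigma2")
    A = samples.flat("A").astype(bool)
    Rp = _residency_weights(samples)
    s = _layer_per_year(layer, samples.years, grid)  # (n_years, n_bins)
    n_draws = C.shape[0]
    out = np.zeros(C.shape)
    for m in range(n_draws):
        occ = relative_occurrence(C[m], sigma2[m], grid)
        overlap = np.einsum("itl,tl->it", occ, s)
        out[m] = overlap * Rp[m] * A[m]
    return out


def exposure_summaries(draws: np.ndarray, samples: PosteriorSamples,
                       stressor: str) -> pd.DataFrame:
    """Summarise per-draw exposures as median/mean and a central 90% interval.

    Returns one row per (individual, year) with columns
    ``individual_id, year, stressor, median, mean, lo90, hi90``.
    """
    rows = []
    for i, ind in enumerate(samples.individuals):
        for t, year in enumerate(samples.years):
            v = draws[:, i, t]
            rows.append((ind, year, stressor, float(np.median(v)), float(np.mean(v)),
                         float(np.quantile(v, 0.05)), float(np.quantile(v, 0.95))))
    return pd.DataFrame(rows, columns=["individual_id", "year", "stressor",
                                       "median", "mean", "lo90", "hi90"])


def exposure_reference_lines(summary: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Annual mean-of-medians and the overall mean of individual median exposure.

    The overall reference is the mean of all individual-year median exposures;
    the annual references are the same mean taken within each year.
    """
    annual = summary.groupby("year", as_index=False)["median"].mean()
    annual = annual.rename(columns={"median": "mean_of_medians"})
    return annual, float(summary["median"].mean())
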