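"""Annual compositing and the 228-feature construction for classification.

A year of daily 7-band reflectance with per-observation quality flags is
reduced to, per grid cell:

* 7 composited band reflectances (most recent good observation of the year,
  searching backward from December 31);
* 13 spectral indices computed from the composited bands;
* 8 time-series statistics per band over the good observations (56 values);
* for each of those 76 base features, the mean and standard deviation over
  a 9 x 9 spatial window (152 values),

for a total of 76 x 3 = 228 features.  Cells with no good observation all
year are flagged nodata and excluded from classification.

The index and statistic sets are pluggable registries: the shipped defaults
are documented normalized differences / ratios and standard order
statistics, and callers may override them (strict-count validation keeps
the 228-feature contract).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "composite_annual",
    "compute_indices",
    "compute_time_series_stats",
    "compute_window_stats",
    "assemble_features",
    "INDEX_REGISTRY",
    "TS_STAT_REGISTRY",
    "BAND_NAMES",
    "feature_names",
    "N_FEATURES",
]

N_BANDS = 7
WINDOW = 9
N_FEATURES = 228

BAND_NAMES = ["b1", "b2", "b3", "b4", "b5", "b6", "b7"]
# conventional MODIS ordering: b1 red, b2 NIR, b3 blue, b4 green,
# b5/b6/b7 shortwave infrared


def _nd(a, b):
    """Normalized difference (a-b)/(a+b); zero denominator -> nan."""
    den = a + b
    out = np.full_like(den, np.nan, dtype=float)
    ok = den != 0
    out[ok] = (a[ok] - b[ok]) / den[ok]
    return out


def _ratio(a, b):
    out = np.full_like(a, np.nan, dtype=float)
    ok = b != 0
    out[ok] = a[ok] / b[ok]
    return out


#: 13 spectral indices of the composited bands (name -> fn(bands[..., 7])).
#: Documented defaults: standard vegetation / water / burn normalized
#: differences, simple ratios, and two soil-adjusted forms.
INDEX_REGISTRY = {
    "ndvi": lambda b: _nd(b[..., 1], b[..., 0]),  # NIR vs red
    "ndwi": lambda b: _nd(b[..., 3], b[..., 1]),  # green vs NIR
    "ndmi": lambda b: _nd(b[..., 1], b[..., 5]),  # NIR vs SWIR1.6
    "nbr": lambda b: _nd(b[..., 1], b[..., 6]),  # NIR vs SWIR2.1
    "nbr2": lambda b: _nd(b[..., 5], b[..., 6]),
    "ndsi": lambda b: _nd(b[..., 3], b[..., 5]),
    "nd_b2b5": lambda b: _nd(b[..., 1], b[..., 4]),
    "sr": lambda b: _ratio(b[..., 1], b[..., 0]),  # simple ratio NIR/red
    "ratio_b5b2": lambda b: _ratio(b[..., 4], b[..., 1]),
    "ratio_b7b2": lambda b: _ratio(b[..., 6], b[..., 1]),
    "evi2": lambda b: 2.5 * (b[..., 1] - b[..., 0]) / (b[..., 1] + 2.4 * b[..., 0] + 1.0),
    "savi": lambda b: 1.5 * (b[..., 1] - b[..., 0]) / (b[..., 1] + b[..., 0] + 0.5),
    "brightness": lambda b: b.mean(axis=-1),
}

#: 8 time-series statistics over the good observations of one band
TS_STAT_REGISTRY = {
    "mean": lambda v: np.mean(v),
    "sd": lambda v: np.std(v),
    "min": lambda v: np.min(v),
    "max": lambda v: np.max(v),
    "median": lambda v: np.median(v),
    "p10": lambda v: np.percentile(v, 10),
    "p90": lambda v: np.percentile(v, 90),
    "range": lambda v: np.max(v) - np.min(v),
}


def composite_annual(refl: np.ndarray, qa_good: np.ndarray):
    """Composite a year of daily observations to one value per cell/band.

    Per cell and band, the value is the most recent good-quality observation
    of the calendar year (backward search from the December 31 reference
    date, i.e. the last column).  Cells with no good day all year enter the
    nodata mask and carry NaN; they are never zero-filled.

    Parameters
    ----------
    refl : (n_cells, n_days, 7) daily reflectance
    qa_good : (n_cells, n_days) bool, True where the observation is usable

    Returns
    -------
    composite : (n_cells, 7) float, NaN on nodata cells
    nodata_mask : (n_cells,) bool
    """
    refl = np.asarray(refl, dtype=float)
    qa_good = np.asarray(qa_good, dtype=bool)
    if refl.ndim != 3 or refl.shape[2] != N_BANDS:
        raise ValueError(f"expected (n_cells, n_days, {N_BANDS}) reflectance")
    if qa_good.shape != refl.shape[:2]:
        raise ValueError("qa shape does not match reflectance")
    if refl.shape[1] == 0:
        raise ValueError("empty daily series")
    n_cells, n_days = qa_good.shape
    has_good = qa_good.any(axis=1)
    # index of the latest good day per cell
    last_good = n_days - 1 - np.argmax(qa_good[:, ::-1], axis=1)
    composite = np.full((n_cells, N_BANDS), np.nan)
    composite[has_good] = refl[np.flatnonzero(has_good), last_good[has_good], :]
    return composite, ~has_good


def compute_indices(composite: np.ndarray, registry: dict | None = None,
                    strict: bool = True) -> np.ndarray:
    """Evaluate the spectral-index registry on composited bands.

    Division by zero yields NaN (treated downstream as nodata for that
    index), never an exception.  ``strict`` enforces exactly 13 indices.
    """
    registry = INDEX_REGISTRY if registry is None else registry
    if strict and len(registry) != 13:
        raise ValueError(f"index registry must hold 13 entries, got {len(registry)}")
    composite = np.asarray(composite, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cols = [np.asarray(fn(composite), dtype=float) for fn in registry.values()]
    return np.stack(cols, axis=-1)


def compute_time_series_stats(
    refl: np.ndarray,
    qa_good: np.ndarray,
    registry: dict | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Per-band statistics over the good observations of the year.

    Returns (n_cells, 8*7) ordered stat-major within band
    (b1.mean, b1.sd, ..., b1.range, b2.mean, ...).  Cells without any good
    observation yield NaN rows.
    """
    registry = TS_STAT_REGISTRY if registry is None else registry
    if strict and len(registry) != 8:
        raise ValueError(f"ts-stat registry must hold 8 entries, got {len(registry)}")
    refl = np.asarray(refl, dtype=float)
    qa_good = np.asarray(qa_good, dtype=bool)
    n_cells = refl.shape[0]
    out = np.full((n_cells, N_BANDS * len(registry)), np.nan)
    fns = list(registry.values())
    for cell in range(n_cells):
        good = qa_good[cell]
        if not good.any():
            continue
        vals = refl[cell, good, :]  # (n_good, 7)
        for b in range(N_BANDS):
            col = vals[:, b]
            base = b * len(fns)
            for j, fn in enumerate(fns):
                out[cell, base + j] = fn(col)
    return out


def compute_window_stats(
    layers: np.ndarray, shape: tuple[int, int], nodata_mask: np.ndarray | None = None
) -> np.ndarray:
    """Mean and SD of each feature layer over a 9 x 9 window per cell.

    NaN values and nodata cells are excluded from the window moments; at
    grid edges the window truncates to the cells that exist (no padding
    values are fabricated).  SD is the population standard deviation over
    the valid window members.

    Parameters
    ----------
    layers : (n_cells, n_features) base feature values
    shape : (height, width) grid shape, with cells in row-major order
    nodata_mask : optional (n_cells,) bool of cells to exclude entirely

    Returns
    -------
    (n_cells, 2*n_features): for each input feature, its window mean then
    window SD, feature-major (f1.mean, f1.sd, f2.mean, f2.sd, ...).
    """
    layers = np.asarray(layers, dtype=float)
    h, w = shape
    n_cells, n_feat = layers.shape
    if h * w != n_cells:
        raise ValueError("grid shape does not match layer length")
    out = np.empty((n_cells, 2 * n_feat))
    kernel = np.ones((WINDOW, WINDOW))
    excluded = np.zeros(n_cells, dtype=bool) if nodata_mask is None else nodata_mask
    for f in range(n_feat):
        grid = layers[:, f].reshape(h, w).copy()
        valid = np.isfinite(grid) & ~excluded.reshape(h, w)
        grid[~valid] = 0.0
        count = ndimage.correlate(valid.astype(float), kernel, mode="constant", cval=0.0)
        s1 = ndimage.correlate(grid, kernel, mode="constant", cval=0.0)
        s2 = ndimage.correlate(grid * grid, kernel, mode="constant", cval=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean = np.where(count > 0, s1 / count, np.nan)
            var = np.where(count > 0, s2 / count - mean * mean, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0))
        out[:, 2 * f] = mean.ravel()
        out[:, 2 * f + 1] = sd.ravel()
    return out


def feature_names(
    index_registry: dict | None = None, ts_registry: dict | None = None
) -> list[str]:
    """The documented, stable ordering of the 228 feature names."""
    idx = list((INDEX_REGISTRY if index_registry is None else index_registry))
    ts = list((TS_STAT_REGISTRY if ts_registry is None else ts_registry))
    base = (
        list(BAND_NAMES)
        + idx
        + [f"{b}_{s}" for b in BAND_NAMES for s in ts]
    )
    names = list(base)
    for name in base:
        names += [f"{name}_w9mean", f"{name}_w9sd"]
    return names


def assemble_features(
    composite: np.ndarray,
    indices: np.ndarray,
    ts_stats: np.ndarray,
    window_stats: np.ndarray,
    nodata_mask: np.ndarray,
):
    """Stack bands, indices, time-series and window statistics per cell.

    Returns ``(valid_cells, X, names)`` where ``X`` is
    (n_valid, 228) with residual NaNs (e.g. zero-denominator indices)
    replaced by 0 so the matrix is classifier-ready, and ``valid_cells``
    indexes the cells outside the nodata mask.
    """
    parts = [composite, indices, ts_stats]
    n_cells = composite.shape[0]
    for part in parts + [window_stats]:
        if part.shape[0] != n_cells:
            raise ValueError("feature blocks disagree on the cell grid")
    base = np.concatenate(parts, axis=1)
    if window_stats.shape[1] != 2 * base.shape[1]:
        raise ValueError("window block must hold mean+sd per base feature")
    x = np.concatenate([base, window_stats], axis=1)
    if x.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {x.shape[1]}")
    valid = np.flatnonzero(~np.asarray(nodata_mask, dtype=bool))
    x = x[valid]
    return valid, np.nan_to_num(x, nan=0.0), feature_names()


def build_feature_matrix(days, refl, qa_good, shape):
    """Convenience: full 228-feature pipeline for one year of observations."""
    composite, nodata = composite_annual(refl, qa_good)
    idx = compute_indices(composite)
    ts = compute_time_series_stats(refl, qa_good)
    base = np.concatenate([composite, idx, ts], axis=1)
    win = compute_window_stats(base, shape, nodata)
    return assemble_features(composite, idx, ts, win, nodata)
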