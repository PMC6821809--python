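"""Occupancy covariates: canopy closure and village kernel density.

Canopy closure — the fraction of sky obscured by vegetation in upward
photographs, a proxy for forest structural integrity — is computed from
binarized single-channel images (dark pixels = vegetation by convention)
and averaged over the five photographs taken per station (grid center plus
four corners).

Village density — a unitless proxy for hunting accessibility — is a
kernel density of village points evaluated at each station with the
quartic (biweight) kernel K(d) = (1 - (d/r)^2)^2 for d < r, zero beyond,
with a 15 km radius. The kernel is deliberately unnormalized: covariates
are z-scored before entering the model, so any constant factor a GIS
package might apply cancels.

Distances are Euclidean on projected planar coordinates in meters.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_KERNEL_RADIUS = 15_000.0  # meters
PHOTOS_PER_STATION = 5


def _load_raster(raster) -> np.ndarray:
    if isinstance(raster, np.ndarray):
        return raster
    import imageio.v3 as iio
    img = iio.imread(raster)
    if img.ndim == 3:  # flatten an RGB(A) save of a binary image
        img = img[..., 0]
    return img


def canopy_fraction(raster, vegetation_is_dark: bool = True) -> float:
    """Fraction of pixels classified as vegetation in a binarized image.

    Parameters
    ----------
    raster : ndarray or path
        Single-channel image with exactly two pixel classes. By convention
        the darker class is vegetation and the brighter class is open sky;
        set ``vegetation_is_dark=False`` to flip.

    Raises
    ------
    ValueError
        If the image holds more than two distinct values (it must be
        binarized before analysis — thresholding is a judgment made when
        the photographs are processed, not here).
    """
    img = np.asarray(_load_raster(raster))
    if img.size == 0:
        raise ValueError("empty raster")
    values = np.unique(img)
    if len(values) > 2:
        raise ValueError(
            f"raster has {len(values)} distinct pixel values; binarize it "
            "to two classes (vegetation, sky) first")
    if len(values) == 1:
        # Degenerate image: decide by comparing the single value to zero.
        is_veg = (values[0] == 0) == vegetation_is_dark
        return 1.0 if is_veg else 0.0
    veg_value = values[0] if vegetation_is_dark else values[1]
    return float(np.mean(img == veg_value))


def station_canopy(rasters, vegetation_is_dark: bool = True) -> float:
    """Mean canopy-closure fraction over a station's photographs.

    The field protocol takes five photographs (center + four grid corners);
    fewer are accepted with a warning and the mean is over those present.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no canopy rasters supplied for station")
    if len(rasters) != PHOTOS_PER_STATION:
        warnings.warn(
            f"expected {PHOTOS_PER_STATION} canopy photos, got {len(rasters)}; "
            "averaging over those present", stacklevel=2)
    fracs = [canopy_fraction(r, vegetation_is_dark) for r in rasters]
    return float(np.mean(fracs))


def quartic_kernel(d: np.ndarray, radius: float) -> np.ndarray:
    """Unnormalized quartic (biweight) kernel, zero outside the radius."""
    u = np.asarray(d, dtype=float) / radius
    out = np.square(1.0 - np.square(u))
    out[u >= 1.0] = 0.0
    return out


def village_density(stations, villages,
                    radius: float = DEFAULT_KERNEL_RADIUS,
                    kernel: str = "quartic") -> np.ndarray:
    """Kernel density of village points evaluated at each station.

    Parameters
    ----------
    stations, villages : DataFrame with ``x``/``y`` columns, or (n, 2) array
        Planar coordinates in meters.
    radius : float
        Kernel support radius in meters (default 15 km — wide enough that
        every station in the survey falls inside some village's halo).

    Returns
    -------
    ndarray of shape (n_stations,)
        Unitless density; 0 for stations with no village within the radius.
    """
    if radius <= 0:
        raise ValueError("kernel radius must be positive")
    if kernel != "quartic":
        raise ValueError(f"unknown kernel {kernel!r}")
    sxy = _xy(stations)
    vxy = _xy(villages)
    if len(vxy) == 0:
        return np.zeros(len(sxy))
    d = cdist(sxy, vxy)
    return quartic_kernel(d, radius).sum(axis=1)


def _xy(obj) -> np.ndarray:
    if isinstance(obj, pd.DataFrame):
        return obj[["x", "y"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(obj, dtype=float))


def normalize(values, groups=None) -> np.ndarray:
    """Z-score values, independently within each group.

    Covariates are scaled independently per landscape so that effect sizes
    are comparable between the two separately fitted models. Uses the
    sample standard deviation (ddof=1).

    Raises
    ------
    ValueError
        If any group has fewer than two distinct values — a constant
        covariate would make its model coefficient unidentifiable.
    """
    x = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(x), dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(x)
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() < 2 or np.unique(x[m]).size < 2:
            raise ValueError(
                f"group {g!r} has fewer than two distinct covariate values; "
                "cannot normalize (coefficient would be unidentifiable)")
        out[m] = (x[m] - x[m].mean()) / x[m].std(ddof=1)
    return out


def subset_match(values, target_mean: float, target_sd: float, n_out: int,
                 seed: int = 0, n_sweeps: int = 200):
    """Pick a subset whose mean and sd approximate given targets.

    Supports the robustness device of re-running an analysis on a subset of
    one landscape's stations chosen so its canopy-closure distribution
    matches the other landscape's (same mean, similar spread), removing the
    objection that a stronger covariate response merely reflects greater
    covariate variation.

    Greedy swap search: start from a random subset of size ``n_out`` and
    repeatedly apply the single in/out swap that most reduces
    ``|mean - target_mean|/target_sd + |sd - target_sd|/target_sd``
    until no swap improves.

    Returns
    -------
    (indices, achieved_mean, achieved_sd)
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not (1 <= n_out <= n):
        raise ValueError(f"n_out must be in [1, {n}], got {n_out}")
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    rng = np.random.default_rng(seed)

    def loss(idx):
        sub = x[idx]
        sd = sub.std(ddof=1) if len(sub) > 1 else 0.0
        return (abs(sub.mean() - target_mean) / target_sd
                + abs(sd - target_sd) / target_sd)

    if n_out == 1:
        best = int(np.argmin(np.abs(x - target_mean)))
        return np.array([best]), float(x[best]), 0.0

    chosen = rng.choice(n, size=n_out, replace=False)
    in_set = np.zeros(n, dtype=bool)
    in_set[chosen] = True
    current = loss(np.flatnonzero(in_set))
    for _ in range(n_sweeps):
        improved = False
        inside = np.flatnonzero(in_set)
        outside = np.flatnonzero(~in_set)
        for i in inside:
            for j in outside:
                in_set[i], in_set[j] = False, True
                trial = loss(np.flatnonzero(in_set))
                if trial < current - 1e-15:
                    current = trial
                    improved = True
                    break
                in_set[i], in_set[j] = True, False
            if improved:
                break
        if not improved:
            break
    idx = np.flatnonzero(in_set)
    sub = x[idx]
    return idx, float(sub.mean()), float(sub.std(ddof=1))


def covariate_table(stations: pd.DataFrame,
                    canopy: np.ndarray,
                    villages: pd.DataFrame,
                    radius: float = DEFAULT_KERNEL_RADIUS) -> pd.DataFrame:
    """Assemble the per-station covariate table with normalized columns.

    Normalization groups are landscapes (``landscape_id``), matching the
    practice of fitting and scaling each landscape independently.
    """
    canopy = np.asarray(canopy, dtype=float)
    if np.any((canopy < 0) | (canopy > 1)):
        raise ValueError("canopy closure must lie in [0, 1]")
    dens = village_density(stations, villages, radius=radius)
    grp = stations["landscape_id"].to_numpy()
    return pd.DataFrame({
        "station_id": stations["station_id"],
        "landscape_id": grp,
        "site_id": stations["site_id"],
        "canopy": canopy,
        "village_density": dens,
        "canopy_z": normalize(canopy, grp),
        "village_density_z": normalize(dens, grp),
    })
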