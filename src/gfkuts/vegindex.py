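"""Vegetation indices over the segmented canopy and their correlations.

Seven NIR-centred indices are computed per pixel from band reflectances
rho_f and averaged over the canopy mask to give one feature vector per
plot.  Band identification for the four-band multispectral camera:
rho_780 / rho_800 -> NIR, rho_670 -> red, rho_500 -> green (red-edge is
used for segmentation guidance only).

    NDVI  = (rho_nir - rho_red) / (rho_nir + rho_red)
    GNDVI = (rho_nir - rho_green) / (rho_nir + rho_green)
    DVI   = rho_nir - rho_red
    CTVI  = sign(NDVI + 0.5) * sqrt(|NDVI + 0.5|)
    SAVI  = (1 + L) (rho_nir - rho_red) / (rho_nir + rho_red + L),  L = 0.5
    MSAVI = (2 rho_nir + 1 - sqrt((2 rho_nir + 1)^2 - 8 (rho_nir - rho_red))) / 2
    SR    = rho_nir / rho_red
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .raster import MultispectralScene

VI_NAMES = ("ndvi", "gndvi", "dvi", "ctvi", "savi", "msavi", "sr")

STAGES = ("vegetative", "reproductive", "ripening")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with zero denominators flagged as NaN."""
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def ndvi(nir: np.ndarray, red: np.ndarray, green=None) -> np.ndarray:
    return _safe_ratio(nir - red, nir + red)


def gndvi(nir: np.ndarray, red=None, green: np.ndarray = None) -> np.ndarray:
    return _safe_ratio(nir - green, nir + green)


def dvi(nir: np.ndarray, red: np.ndarray, green=None) -> np.ndarray:
    return nir - red


def ctvi(nir: np.ndarray, red: np.ndarray, green=None) -> np.ndarray:
    n = ndvi(nir, red)
    return np.sign(n + 0.5) * np.sqrt(np.abs(n + 0.5))


def savi(nir: np.ndarray, red: np.ndarray, green=None, L: float = 0.5) -> np.ndarray:
    return (1.0 + L) * _safe_ratio(nir - red, nir + red + L)


def msavi(nir: np.ndarray, red: np.ndarray, green=None) -> np.ndarray:
    disc = (2 * nir + 1) ** 2 - 8 * (nir - red)
    if np.any(disc < -1e-12):
        raise ValueError("MSAVI discriminant negative; reflectances outside [0, 1]?")
    return 0.5 * (2 * nir + 1 - np.sqrt(np.maximum(disc, 0.0)))


def sr(nir: np.ndarray, red: np.ndarray, green=None) -> np.ndarray:
    return _safe_ratio(nir, red)


_VI_FUNCS = dict(ndvi=ndvi, gndvi=gndvi, dvi=dvi, ctvi=ctvi, savi=savi, msavi=msavi, sr=sr)


def compute_vi(
    scene: MultispectralScene,
    mask: np.ndarray,
    index_name: str,
) -> tuple[np.ndarray, float]:
    """Per-pixel VI raster and its mean over ``mask == 1`` pixels.

    Pixels with undefined values (zero denominators) are excluded from
    the mean.  Raises on an empty mask.
    """
    if index_name not in _VI_FUNCS:
        raise ValueError(f"unknown index {index_name!r}; expected one of {VI_NAMES}")
    mask = np.asarray(mask)
    if mask.shape != scene.shape:
        raise ValueError("mask shape differs from scene")
    if not np.any(mask):
        raise ValueError("empty canopy mask")
    nir = scene.band("nir")
    red = scene.band("red") if "red" in scene.bands else None
    green = scene.band("green") if "green" in scene.bands else None
    raster = _VI_FUNCS[index_name](nir, red, green)
    vals = raster[mask == 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = float(np.nanmean(vals))
    return raster, mean


def feature_table(
    scenes: list[MultispectralScene],
    masks: list[np.ndarray],
    stages: list[str] | None = None,
    extra: pd.DataFrame | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """One row of the 7 canopy-mean indices per scene.

    ``extra`` (indexed like ``scenes``) may carry genotype / production
    system / biomass columns to join onto the features.  Scenes with an
    empty canopy mask are dropped with a warning.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    rows = []
    for i, (scene, mask) in enumerate(zip(scenes, masks)):
        if not np.any(mask):
            warnings.warn(f"scene {scene.scene_id or i}: empty canopy mask, row dropped")
            continue
        row: dict = {"scene_id": scene.scene_id or str(i)}
        if stages is not None:
            row["stage"] = stages[i]
        for name in VI_NAMES:
            raster, mean = compute_vi(scene, mask, name)
            if aggregate == "median":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    mean = float(np.nanmedian(raster[mask == 1]))
            row[name] = mean
        if extra is not None:
            for col in extra.columns:
                row[col] = extra.iloc[i][col]
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.sum(xc * yc) / denom)


def correlation_matrix(features: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Symmetric Pearson matrix over the numeric feature columns.

    Constant columns get NaN off-diagonal entries (undefined marker);
    the diagonal is 1 by convention.
    """
    if columns is None:
        columns = [c for c in features.columns if np.issubdtype(features[c].dtype, np.number)]
    if len(features) < 3:
        raise ValueError("need at least 3 rows")
    k = len(columns)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        mat[i, i] = 1.0
        for j in range(i + 1, k):
            try:
                r = pearson_r(features[columns[i]].to_numpy(), features[columns[j]].to_numpy())
            except ValueError:
                r = np.nan
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=columns, columns=columns)


def vi_stage_variance(features: pd.DataFrame, vis: tuple[str, ...] = VI_NAMES) -> pd.DataFrame:
    """Per-stage mean and variance of each VI across the phenological cycle."""
    if "stage" not in features.columns:
        raise ValueError("feature table lacks a 'stage' column")
    unknown = set(features["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    counts = features.groupby("stage").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 rows per stage")
    g = features.groupby("stage")[list(vis)]
    out = pd.concat({"mean": g.mean(), "var": g.var(ddof=1)}, axis=1)
    return out.reindex([s for s in STAGES if s in counts.index])


def plot_correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Save the correlation matrix as a heatmap image (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(corr), 1 + 0.6 * len(corr)))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
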