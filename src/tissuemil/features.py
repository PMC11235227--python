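"""Per-instance handcrafted and deep features, imputation and normalisation.

Each tissue crop is turned into a fixed-length vector covering every feature
family used for compartment-based renal histology analysis:

* morphology — physical area, perimeter, eccentricity, solidity, the
  enclosed-cavity ("lumen") area found as background holes inside the mask,
  the lumen-to-total *area* ratio (a ratio of areas rather than diameters,
  since most vessel sections are not round), and a urinary-space analogue
  computed as convex-hull area minus mask area;
* colour — per-channel mean/SD inside the compartment plus second-order
  boundary-band vs interior contrasts (how colour is distributed with
  respect to the compartment);
* texture — gradient-magnitude statistics inside the mask;
* nuclei — count, density, nucleus darkness and nucleus-to-boundary
  distances pooled at every tenth percentile (11 values each), which is less
  sensitive to falsely detected nuclei than max-pooling;
* slide level — the total biopsy area and tissue count appended to every
  instance.

Nuclei features are *missing* (NaN), not zero, when no nucleus masks are
available — e.g. under Sirius Red staining, where nuclei are not visible, the
``SR`` profile drops the nuclei group entirely.  Imputation (column means)
and zero-mean/unit-variance normalisation are fitted on the training split
only and applied unchanged elsewhere; a dataset-global mode is available
behind a flag for parity with workflows that pool statistics over all data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

PERCENTILE_GRID = tuple(range(0, 101, 10))  # every tenth percentile, inclusive

_MORPHOLOGY = (
    "area_um2",
    "perimeter_um",
    "eccentricity",
    "solidity",
    "lumen_area_um2",
    "lumen_total_ratio",
    "urinary_space_um2",
)
_COLOUR = tuple(
    f"colour_{stat}_{ch}" for ch in "rgb" for stat in ("mean", "sd")
) + tuple(f"colour_boundary_contrast_{ch}" for ch in "rgb")
_TEXTURE = ("gradmag_mean", "gradmag_sd")
_SLIDE = ("slide_total_area_um2", "slide_tissue_count")


def _nuclei_names(percentiles: Sequence[int]) -> tuple[str, ...]:
    names = ["nuclei_count", "nuclei_density_per_um2"]
    names += [f"nuclei_darkness_p{p}" for p in percentiles]
    names += [f"nuclei_boundary_dist_p{p}" for p in percentiles]
    return tuple(names)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with group membership and stain profile."""

    names: tuple[str, ...]
    groups: dict[str, str]
    stain_profile: str
    percentiles: tuple[int, ...] = PERCENTILE_GRID

    def __len__(self) -> int:
        return len(self.names)

    def names_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.groups[n] == group)


def make_schema(
    stain_profile: str = "PAS",
    percentiles: Sequence[int] = PERCENTILE_GRID,
    deep_width: int = 0,
    include_g: bool = False,
) -> FeatureSchema:
    """Build the feature schema for a stain profile.

    ``PAS`` includes the nuclei group; ``SR`` excludes it (nuclei are not
    visible under Sirius Red).  ``deep_width`` appends that many deep-
    embedding columns; ``include_g`` appends the quality weight as a feature.
    """
    if stain_profile not in ("PAS", "SR"):
        raise ValueError("stain_profile must be 'PAS' or 'SR'")
    names: list[str] = []
    groups: dict[str, str] = {}
    for n in _MORPHOLOGY:
        names.append(n)
        groups[n] = "morphology"
    for n in _COLOUR:
        names.append(n)
        groups[n] = "colour"
    for n in _TEXTURE:
        names.append(n)
        groups[n] = "texture"
    if stain_profile == "PAS":
        for n in _nuclei_names(percentiles):
            names.append(n)
            groups[n] = "nuclei"
    for n in _SLIDE:
        names.append(n)
        groups[n] = "slide_level"
    for d in range(deep_width):
        n = f"deep_{d}"
        names.append(n)
        groups[n] = "deep"
    if include_g:
        names.append("g")
        groups["g"] = "quality"
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    return FeatureSchema(
        names=tuple(names),
        groups=groups,
        stain_profile=stain_profile,
        percentiles=tuple(percentiles),
    )


def handcrafted_features(
    crop: np.ndarray,
    mask: np.ndarray,
    nuclei_masks: Sequence[np.ndarray] = (),
    slide_context: tuple[float, int] = (0.0, 0),
    mpp: float = 0.44,
    stain_profile: str = "PAS",
    boundary_px: int = 3,
    percentiles: Sequence[int] = PERCENTILE_GRID,
) -> pd.Series:
    """Compute the handcrafted feature record for one instance crop.

    Parameters
    ----------
    crop, mask
        RGB crop and the instance mask in crop coordinates (same height and
        width).  The mask must be nonempty.
    nuclei_masks
        Per-nucleus binary masks in crop coordinates; may be empty, in which
        case every nuclei-group value is NaN (missing, not zero).
    slide_context
        ``(total biopsy area in um^2, tissue count)`` appended to the record.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has zero area")
    if crop.shape[:2] != mask.shape:
        raise ValueError("crop and mask shapes differ")
    schema = make_schema(stain_profile, percentiles)
    out: dict[str, float] = {}
    area_scale = mpp * mpp

    props = measure.regionprops(mask.astype(np.uint8))[0]
    filled = ndi.binary_fill_holes(mask)
    lumen = filled & ~mask
    hull = morphology.convex_hull_image(mask)
    out["area_um2"] = float(mask.sum()) * area_scale
    out["perimeter_um"] = float(props.perimeter) * mpp
    out["eccentricity"] = float(props.eccentricity)
    out["solidity"] = float(props.solidity)
    out["lumen_area_um2"] = float(lumen.sum()) * area_scale
    out["lumen_total_ratio"] = float(lumen.sum()) / float(filled.sum())
    out["urinary_space_um2"] = float(hull.sum() - mask.sum()) * area_scale

    img = np.asarray(crop, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    interior = ndi.binary_erosion(mask, iterations=boundary_px)
    boundary = mask & ~interior
    if not interior.any():  # thin shapes: fall back to the whole mask
        interior = mask
    for ci, ch in enumerate("rgb"):
        vals = img[..., ci][mask]
        out[f"colour_mean_{ch}"] = float(vals.mean())
        out[f"colour_sd_{ch}"] = float(vals.std())
        b = img[..., ci][boundary].mean() if boundary.any() else img[..., ci][mask].mean()
        out[f"colour_boundary_contrast_{ch}"] = float(b - img[..., ci][interior].mean())

    gray = img.mean(axis=2)
    gmag = np.hypot(filters.sobel_h(gray), filters.sobel_v(gray))
    out["gradmag_mean"] = float(gmag[mask].mean())
    out["gradmag_sd"] = float(gmag[mask].std())

    if stain_profile == "PAS":
        nuclei_masks = [np.asarray(m, dtype=bool) for m in nuclei_masks if np.asarray(m).any()]
        if not nuclei_masks:
            for n in _nuclei_names(percentiles):
                out[n] = np.nan
        else:
            out["nuclei_count"] = float(len(nuclei_masks))
            out["nuclei_density_per_um2"] = len(nuclei_masks) / out["area_um2"]
            darkness = [float(gray[m].mean()) for m in nuclei_masks]
            dist = ndi.distance_transform_edt(mask)
            centroids = [np.argwhere(m).mean(axis=0) for m in nuclei_masks]
            bdist = [
                float(dist[int(round(cy)), int(round(cx))]) * mpp for cy, cx in centroids
            ]
            for p in percentiles:
                out[f"nuclei_darkness_p{p}"] = float(np.percentile(darkness, p))
                out[f"nuclei_boundary_dist_p{p}"] = float(np.percentile(bdist, p))

    out["slide_total_area_um2"] = float(slide_context[0])
    out["slide_tissue_count"] = float(slide_context[1])
    return pd.Series(out, index=list(schema.names), dtype=float)


def deep_features(
    crop: np.ndarray,
    extractor: Callable[[np.ndarray], np.ndarray],
    min_size: int = 1,
    return_info: bool = False,
):
    """Pool a pluggable extractor's spatial feature map into one vector.

    The crop is fed at native size (no resizing — objects of equal physical
    size should elicit equal filter responses); the extractor must return a
    spatial map ``(H', W', C)`` which is average-pooled over space.  Crops
    smaller than ``min_size`` are padded reflectively and flagged.
    """
    crop = np.asarray(crop)
    padded = False
    if crop.shape[0] < min_size or crop.shape[1] < min_size:
        ph = max(0, min_size - crop.shape[0])
        pw = max(0, min_size - crop.shape[1])
        pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)] + [(0, 0)] * (crop.ndim - 2)
        crop = np.pad(crop, pad, mode="reflect")
        padded = True
    fmap = np.asarray(extractor(crop), dtype=float)
    if fmap.ndim == 2:
        fmap = fmap[..., None]
    if fmap.ndim != 3:
        raise ValueError("extractor must return a spatial map (H, W, C)")
    vec = fmap.mean(axis=(0, 1))
    if return_info:
        return vec, {"padded": padded}
    return vec


@dataclass
class NormalisationStats:
    """Imputation means and zero-mean/unit-variance statistics.

    Fitted on one split and applied unchanged to any other (leakage guard).
    Features with zero variance are flagged constant and pass through as
    zeros after centring.
    """

    impute_means: pd.Series
    means: pd.Series
    sds: pd.Series
    constant: pd.Series
    fitted_on: str = "train"


def fit_impute_normalise(train: pd.DataFrame, fitted_on: str = "train") -> NormalisationStats:
    """Fit imputation and normalisation statistics on the training matrix.

    Column means impute missing entries; normalisation uses the population
    SD (ddof=0) of the imputed training column.  A column with no observed
    training value cannot be imputed and raises.
    """
    if train.empty:
        raise ValueError("training matrix is empty")
    all_missing = train.columns[train.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"features entirely missing in training: {list(all_missing)}")
    impute_means = train.mean(axis=0)
    imputed = train.fillna(impute_means)
    means = imputed.mean(axis=0)
    sds = imputed.std(axis=0, ddof=0)
    constant = sds == 0
    return NormalisationStats(
        impute_means=impute_means,
        means=means,
        sds=sds,
        constant=constant,
        fitted_on=fitted_on,
    )


def apply_impute_normalise(stats: NormalisationStats, matrix: pd.DataFrame) -> pd.DataFrame:
    """Impute then normalise a feature matrix with previously fitted stats."""
    missing_cols = set(stats.means.index) - set(matrix.columns)
    if missing_cols:
        raise ValueError(f"matrix lacks fitted columns: {sorted(missing_cols)}")
    out = matrix[list(stats.means.index)].fillna(stats.impute_means)
    sds = stats.sds.where(~stats.constant, 1.0)
    out = (out - stats.means) / sds
    out.loc[:, stats.constant[stats.constant].index] = 0.0
    return out


def assemble_featureset(
    handcrafted: pd.DataFrame,
    deep: pd.DataFrame | None = None,
    g: pd.Series | None = None,
    include_g: bool = False,
) -> pd.DataFrame:
    """Column-wise concatenation of handcrafted, deep and quality columns.

    Row keys (the index) must align exactly; ``include_g`` appends ``g`` as
    one extra column.
    """
    parts = [handcrafted]
    if deep is not None and deep.shape[1] > 0:
        diff = handcrafted.index.symmetric_difference(deep.index)
        if len(diff):
            raise ValueError(f"instance keys differ between matrices: {list(diff)}")
        parts.append(deep.loc[handcrafted.index])
    if include_g:
        if g is None:
            raise ValueError("include_g requires g")
        diff = handcrafted.index.symmetric_difference(g.index)
        if len(diff):
            raise ValueError(f"instance keys differ for g: {list(diff)}")
        parts.append(g.loc[handcrafted.index].rename("g").to_frame())
    return pd.concat(parts, axis=1)
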