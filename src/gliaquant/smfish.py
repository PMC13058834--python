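"""Per-cell smFISH transcript quantification.

Nuclei are segmented from the DAPI channel (blur → threshold → binarize →
close holes → dilate → watershed → label → size filter); each resulting
ROI is one cell. Transcript puncta are counted per cell either as 3D
connected components above an intensity threshold ("cc3d", the 3D object
counter) or as prominence-filtered maxima on a maximum-intensity
projection after despeckling and rolling-ball background subtraction
("maxima"). Positivity is assigned from molecule-count floors (e.g. ≥ 3
molecules for a marker expressed at low copy number, ≥ 5 for cell-type
markers) or from supervised intensity thresholds placed two standard
deviations from the mean of visually classified reference cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed as _watershed

from .types import ImageVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Nuclei segmentation parameters (voxel units)."""

    blur_sigma: float = 1.0
    threshold: float | str = "otsu"
    close_holes: bool = True
    dilation_radius_xy: int = 2
    dilation_radius_z: int = 0
    use_watershed: bool = True
    seed_min_distance_px: int = 10
    seed_smooth_sigma: float = 2.0
    min_size_voxels: int = 60
    max_size_voxels: int | None = None


@dataclass
class CellROISet:
    """Labelled cell ROIs: 0 = background, k = cell k."""

    labels: np.ndarray
    sizes: dict[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.sizes)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.sizes)


@dataclass
class PunctaParams:
    """Puncta counting parameters for either counting mode."""

    mode: str = "cc3d"  # "cc3d" | "maxima"
    intensity_threshold: float = 0.0
    prominence: float = 600.0
    despeckle_passes: int = 3
    rolling_ball_radius_px: int = 10
    min_punctum_voxels: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("cc3d", "maxima"):
            raise ValueError(f"unknown counting mode {self.mode!r}")
        if self.mode == "maxima" and self.prominence <= 0:
            raise ValueError("prominence must be > 0 in maxima mode")
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")


@dataclass
class ThresholdModel:
    """Supervised intensity threshold at mean ± k·sd of reference cells."""

    mean: float
    sd: float
    k: float
    polarity: str  # "from-negative" (mean + k·sd) | "from-positive" (mean − k·sd)
    threshold: float


def segment_nuclei(
    volume: ImageVolume,
    params: SegmentationParams | None = None,
    dapi_channel: str = "DAPI",
) -> CellROISet:
    """Nuclei-seeded cell segmentation from the DAPI channel.

    Pipeline order is fixed: Gaussian blur, threshold (Otsu by default),
    binarize, close holes, dilate (anisotropic radius), watershed split of
    touching nuclei, label, size filter; ROIs outside the volume's region
    mask are removed. No foreground yields an empty ROI set with a
    warning, not an exception.
    """
    p = params or SegmentationParams()
    img = np.asarray(volume.channel(dapi_channel), dtype=float)
    if p.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma)
    if p.threshold == "otsu":
        if np.ptp(img) == 0:
            thr = np.inf  # flat image: no foreground
        else:
            thr = threshold_otsu(img)
    else:
        thr = float(p.threshold)
    binary = img > thr
    if not binary.any():
        warnings.warn("no foreground after threshold; empty ROI set",
                      stacklevel=2)
        return CellROISet(labels=np.zeros(img.shape, dtype=np.int32), sizes={})
    if p.close_holes:
        binary = ndimage.binary_fill_holes(binary)
    if p.dilation_radius_xy or p.dilation_radius_z:
        rz, rxy = p.dilation_radius_z, p.dilation_radius_xy
        struct = np.zeros((2 * rz + 1, 2 * rxy + 1, 2 * rxy + 1), dtype=bool)
        zz, yy, xx = np.ogrid[-rz : rz + 1, -rxy : rxy + 1, -rxy : rxy + 1]
        struct[
            (zz / max(rz, 1)) ** 2 + (yy / max(rxy, 1)) ** 2
            + (xx / max(rxy, 1)) ** 2
            <= 1.0
        ] = True
        binary = ndimage.binary_dilation(binary, structure=struct)

    if p.use_watershed:
        # anisotropic EDT in xy-pixel units so flat nuclei keep one central
        # peak; smoothing merges plateau maxima before seeding
        x_nm, y_nm, z_nm = volume.voxel_size_nm
        dist = ndimage.distance_transform_edt(
            binary, sampling=(z_nm / x_nm, y_nm / x_nm, 1.0)
        )
        from skimage.feature import peak_local_max

        seed_img = (
            ndimage.gaussian_filter(dist, p.seed_smooth_sigma)
            if p.seed_smooth_sigma > 0 else dist
        )
        peaks = peak_local_max(
            seed_img, min_distance=p.seed_min_distance_px, labels=binary,
            exclude_border=False,
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        for i, c in enumerate(peaks, start=1):
            markers[tuple(c)] = i
        if markers.max() == 0:
            labels, _ = ndimage.label(binary, structure=_CONN26)
        else:
            labels = _watershed(-dist, markers, mask=binary)
    else:
        labels, _ = ndimage.label(binary, structure=_CONN26)

    if volume.region_mask is not None:
        keep_ids = set(np.unique(labels[volume.region_mask])) - {0}
        labels = np.where(np.isin(labels, sorted(keep_ids)), labels, 0)

    sizes = {}
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 0
    for k in np.unique(labels):
        if k == 0:
            continue
        n = int((labels == k).sum())
        if n < p.min_size_voxels:
            continue
        if p.max_size_voxels is not None and n > p.max_size_voxels:
            continue
        next_id += 1
        out[labels == k] = next_id
        sizes[next_id] = n
    return CellROISet(labels=out, sizes=sizes)


def _despeckle(img: np.ndarray, passes: int) -> np.ndarray:
    for _ in range(passes):
        img = ndimage.median_filter(img, size=3)
    return img


def count_puncta(
    volume: ImageVolume,
    rois: CellROISet,
    channel: str,
    params: PunctaParams | None = None,
) -> pd.DataFrame:
    """Per-cell puncta counts and mean intensities for one channel.

    ``cc3d`` counts 26-connected components above the intensity threshold
    (3D object counter); ``maxima`` counts prominence-filtered maxima on a
    despeckled, rolling-ball-subtracted maximum-intensity projection.
    Returns one row per cell with columns ``cell``, ``{channel}_count``,
    ``{channel}_mean_intensity``.
    """
    p = params or PunctaParams()
    img = np.asarray(volume.channel(channel), dtype=float)
    counts = {k: 0 for k in rois.cell_ids}

    if p.mode == "cc3d":
        fg = img > p.intensity_threshold
        labels, n = ndimage.label(fg, structure=_CONN26)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            coms = ndimage.center_of_mass(fg, labels, range(1, n + 1))
            for size, com in zip(sizes, coms):
                if size < p.min_punctum_voxels:
                    continue
                zyx = tuple(int(round(c)) for c in com)
                cell = int(rois.labels[zyx])
                if cell in counts:
                    counts[cell] += 1
    else:  # maxima
        proj = img.max(axis=0)
        proj = _despeckle(proj, p.despeckle_passes)
        if p.rolling_ball_radius_px > 0:
            proj = proj - rolling_ball(proj, radius=p.rolling_ball_radius_px)
        roi2d = rois.labels.max(axis=0)
        peaks = h_maxima(proj, p.prominence)
        peak_labels, n = ndimage.label(peaks, structure=np.ones((3, 3), bool))
        if n:
            coms = ndimage.center_of_mass(peaks, peak_labels, range(1, n + 1))
            for com in coms:
                yx = tuple(int(round(c)) for c in com)
                cell = int(roi2d[yx])
                if cell in counts:
                    counts[cell] += 1

    rows = []
    for k in rois.cell_ids:
        vox = rois.labels == k
        rows.append(
            {
                "cell": k,
                f"{channel}_count": counts[k],
                f"{channel}_mean_intensity": float(img[vox].mean()),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell", f"{channel}_count", f"{channel}_mean_intensity"]
    )


def fit_supervised_threshold(
    intensities, polarity: str, k: float = 2.0
) -> ThresholdModel:
    """Supervised intensity threshold from visually classified cells.

    ``from-negative``: reference cells look negative; threshold is their
    mean plus ``k`` sample standard deviations. ``from-positive``:
    reference cells look positive; threshold is mean minus ``k`` sd.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 labeled intensities (sd undefined)")
    if polarity not in ("from-negative", "from-positive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    thr = mean + k * sd if polarity == "from-negative" else mean - k * sd
    return ThresholdModel(mean=mean, sd=sd, k=k, polarity=polarity,
                          threshold=thr)


def classify_cells(table: pd.DataFrame, rules: dict) -> pd.DataFrame:
    """Add boolean positivity columns per marker.

    ``rules`` maps marker to either an integer molecule-count floor
    (positive iff count ≥ floor) or a ThresholdModel (positive iff mean
    intensity exceeds the threshold: strictly above for ``from-negative``,
    at-or-above for ``from-positive``). Idempotent; an empty table passes
    through.
    """
    out = table.copy()
    for marker, rule in rules.items():
        if isinstance(rule, ThresholdModel):
            col = f"{marker}_mean_intensity"
            if col not in out.columns:
                raise ValueError(f"no intensity column for marker {marker!r}")
            vals = out[col]
            if rule.polarity == "from-negative":
                out[f"{marker}_positive"] = vals > rule.threshold
            else:
                out[f"{marker}_positive"] = vals >= rule.threshold
        else:
            col = f"{marker}_count"
            if col not in out.columns:
                raise ValueError(f"no count column for marker {marker!r}")
            out[f"{marker}_positive"] = out[col] >= int(rule)
    return out


def coexpression_summary(
    table: pd.DataFrame,
    anchor_marker: str,
    comarker: str,
    group_col: str | None = None,
    control_group: str | None = None,
    mean_marker: str | None = None,
) -> dict:
    """Co-expression proportion and (optionally) normalized group means.

    The proportion is the percentage of anchor-positive cells that are
    also positive for the co-marker; with no anchor-positive cells it is
    reported as missing (None) with the count, never as 0%. When a group
    column and control group are given, per-group mean puncta counts of
    ``mean_marker`` (default: the anchor) and fold changes over the
    control mean are included.
    """
    a = table[f"{anchor_marker}_positive"].to_numpy(dtype=bool)
    c = table[f"{comarker}_positive"].to_numpy(dtype=bool)
    n_anchor = int(a.sum())
    result: dict = {
        "n_anchor_positive": n_anchor,
        "n_double_positive": int((a & c).sum()),
        "proportion_pct": (
            100.0 * float((a & c).sum()) / n_anchor if n_anchor else None
        ),
    }
    if group_col is not None:
        marker = mean_marker or anchor_marker
        col = f"{marker}_count"
        means = table.groupby(group_col)[col].mean().to_dict()
        result["group_means"] = {g: float(m) for g, m in means.items()}
        if control_group is not None:
            ctrl = means.get(control_group)
            if ctrl in (None, 0):
                result["fold_change"] = None
            else:
                result["fold_change"] = {
                    g: float(m / ctrl) for g, m in means.items()
                }
    return result


@dataclass
class RegressionFit:
    """OLS fit of one marker's expression on another across cells."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    n: int


def expression_regression(
    table: pd.DataFrame, x_marker: str, y_marker: str,
    value: str = "count",
) -> RegressionFit:
    """Ordinary least squares of y-marker on x-marker across cells."""
    x = table[f"{x_marker}_{value}"].to_numpy(dtype=float)
    y = table[f"{y_marker}_{value}"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("regression needs >= 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        n=len(x),
    )


def compare_slopes(fit_a: RegressionFit, fit_b: RegressionFit) -> dict:
    """Standard-error-based z test on the difference of two slopes."""
    diff = fit_a.slope - fit_b.slope
    se = float(np.hypot(fit_a.slope_se, fit_b.slope_se))
    if se == 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / se
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return {"slope_difference": diff, "z": float(z), "p": float(p)}
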