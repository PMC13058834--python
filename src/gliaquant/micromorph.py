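"""3D morphometry on anisotropic volumes: microglia-synapse contacts,
colocalization, Sholl profiles, and structure-tensor orientation.

Surfaces are voxel objects extracted by intensity threshold. The
microglia-synapse contact rule follows a signed anisotropic Euclidean
distance: for a voxel outside the microglia mask, the distance to the
nearest microglia voxel center (positive); for a voxel inside, minus the
distance to the nearest exterior voxel center. A synaptic object is "in
contact" when its minimal signed distance lies within ±0.07 μm of the
surface; objects deeper inside are classified engulfed and excluded from
contacts. The voxel-center convention is fixed and shared with the
brute-force oracle used to validate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def signed_distance_field(
    mask: np.ndarray, spacing_zyx_um: tuple[float, float, float]
) -> np.ndarray:
    """Signed anisotropic EDT of a binary mask (negative inside), in μm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    if mask.all():
        return np.full(mask.shape, -np.inf)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing_zyx_um)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing_zyx_um)
    return np.where(mask, -d_in, d_out)


@dataclass
class SurfaceObject:
    """One connected component extracted from a channel."""

    label: int
    n_voxels: int
    volume_um3: float
    centroid_zyx: tuple[float, float, float]


@dataclass
class SurfaceObjectSet:
    """26-connected components above an intensity threshold."""

    objects: list[SurfaceObject]
    label_volume: np.ndarray
    channel: str
    threshold: float
    spacing_zyx_um: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.label_volume > 0

    def __len__(self) -> int:
        return len(self.objects)

    @property
    def total_volume_um3(self) -> float:
        return float(sum(o.volume_um3 for o in self.objects))


def preprocess_volume(
    volume: ImageVolume,
    background_um: float = 53.1,
    gaussian_um: float = 0.0707,
) -> ImageVolume:
    """Large-scale background removal followed by fine Gaussian smoothing.

    The background estimate is a Gaussian-smoothed copy at
    ``background_um`` scale, subtracted and clipped at zero; smoothing then
    applies a Gaussian of ``gaussian_um``. Both widths are given in μm and
    converted to anisotropic voxel units; an axis whose voxel pitch
    exceeds the filter width gets no smoothing on that axis (warned).
    """
    spacing = volume.spacing_zyx_um()

    def sigmas(width_um: float) -> tuple[float, ...]:
        out = []
        for ax, pitch in zip("zyx", spacing):
            if width_um < pitch:
                warnings.warn(
                    f"filter width {width_um} μm below voxel pitch "
                    f"{pitch:.4f} μm on axis {ax}; no-op on that axis",
                    stacklevel=3,
                )
                out.append(0.0)
            else:
                out.append(width_um / pitch)
        return tuple(out)

    s_bg = sigmas(background_um)
    s_sm = sigmas(gaussian_um)
    channels = {}
    for name, img in volume.channels.items():
        img = np.asarray(img, dtype=float)
        bg = ndimage.gaussian_filter(img, sigma=s_bg)
        cleaned = np.clip(img - bg, 0.0, None)
        channels[name] = ndimage.gaussian_filter(cleaned, sigma=s_sm)
    return ImageVolume(
        channels=channels,
        voxel_size_nm=volume.voxel_size_nm,
        region_mask=volume.region_mask,
    )


def extract_objects(
    volume: ImageVolume,
    channel: str,
    threshold: float | None = None,
    threshold_factor: float = 1.0,
    min_voxels: int = 1,
) -> SurfaceObjectSet:
    """26-connected components above threshold, with volumes in μm³.

    When ``threshold`` is None it defaults to ``threshold_factor`` times
    the channel mean (surface creation from average signal intensity).
    """
    img = np.asarray(volume.channel(channel), dtype=float)
    if threshold is None:
        threshold = threshold_factor * float(img.mean())
    fg = img > threshold
    labels, n = ndimage.label(fg, structure=_CONN26)
    spacing = volume.spacing_zyx_um()
    vox_vol = volume.voxel_volume_um3
    objects: list[SurfaceObject] = []
    if n:
        counts = np.bincount(labels.ravel())[1:]
        centroids = ndimage.center_of_mass(fg, labels, range(1, n + 1))
        keep_label = 0
        relabeled = np.zeros_like(labels)
        for k, (cnt, com) in enumerate(zip(counts, centroids), start=1):
            if cnt < min_voxels:
                continue
            keep_label += 1
            relabeled[labels == k] = keep_label
            objects.append(
                SurfaceObject(
                    label=keep_label,
                    n_voxels=int(cnt),
                    volume_um3=float(cnt * vox_vol),
                    centroid_zyx=tuple(float(c) for c in com),
                )
            )
        labels = relabeled
    return SurfaceObjectSet(
        objects=objects,
        label_volume=labels,
        channel=channel,
        threshold=float(threshold),
        spacing_zyx_um=spacing,
    )


def classify_contacts(
    synapses: SurfaceObjectSet,
    microglia: SurfaceObjectSet,
    band_um: float = 0.07,
) -> pd.DataFrame:
    """Signed-distance contact classification of synaptic objects.

    Per synaptic object: the minimal signed distance (μm) of its voxels to
    the microglia surface, a ``contact`` flag (within ±``band_um``), and an
    ``engulfed`` flag (deeper than ``band_um`` inside). With no microglia
    objects all distances are undefined and nothing is a contact.
    """
    rows = []
    if len(microglia) == 0:
        for obj in synapses.objects:
            rows.append(
                {
                    "label": obj.label,
                    "min_signed_distance_um": np.nan,
                    "contact": False,
                    "engulfed": False,
                    "volume_um3": obj.volume_um3,
                }
            )
        return pd.DataFrame(
            rows, columns=["label", "min_signed_distance_um", "contact",
                           "engulfed", "volume_um3"]
        )

    sdf = signed_distance_field(microglia.mask, microglia.spacing_zyx_um)
    for obj in synapses.objects:
        vox = synapses.label_volume == obj.label
        d = float(sdf[vox].min())
        rows.append(
            {
                "label": obj.label,
                "min_signed_distance_um": d,
                "contact": bool(-band_um <= d <= band_um),
                "engulfed": bool(d < -band_um),
                "volume_um3": obj.volume_um3,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "min_signed_distance_um", "contact",
                       "engulfed", "volume_um3"]
    )


def contact_summary(table: pd.DataFrame) -> dict:
    """Counts and summed contacted-object volume from a contact table."""
    contacts = table[table["contact"]]
    return {
        "n_objects": int(len(table)),
        "n_contacts": int(len(contacts)),
        "n_engulfed": int(table["engulfed"].sum()),
        "contacted_volume_um3": float(contacts["volume_um3"].sum()),
    }


def colocalize(
    volume: ImageVolume,
    channel_a: str,
    channel_b: str,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
    threshold_factor: float = 1.0,
    min_voxels: int = 1,
) -> dict:
    """Voxelwise AND colocalization between two thresholded channels.

    Returns the number of colocalized 26-connected objects, their summed
    volume in μm³, and the label volume of the colocalization channel.
    """
    a = np.asarray(volume.channel(channel_a), dtype=float)
    b = np.asarray(volume.channel(channel_b), dtype=float)
    ta = threshold_factor * a.mean() if threshold_a is None else threshold_a
    tb = threshold_factor * b.mean() if threshold_b is None else threshold_b
    both = (a > ta) & (b > tb)
    labels, n = ndimage.label(both, structure=_CONN26)
    vox_vol = volume.voxel_volume_um3
    if n:
        counts = np.bincount(labels.ravel())[1:]
        keep = counts >= min_voxels
        n = int(keep.sum())
        total = int(counts[keep].sum())
    else:
        total = 0
    return {
        "n_objects": n,
        "summed_volume_um3": float(total * vox_vol),
        "label_volume": labels,
    }


@dataclass
class ShollProfile:
    """Intersections per concentric shell radius, with the AUC."""

    radii_um: np.ndarray
    intersections: np.ndarray
    auc: float


def sholl_profile(
    cell_mask: np.ndarray,
    center_zyx: tuple[int, int, int],
    spacing_zyx_um: tuple[float, float, float],
    radius_step_um: float = 1.0,
    max_radius_um: float | None = None,
) -> ShollProfile:
    """Sholl analysis: process intersections per concentric shell.

    For each radius r, the intersections are the 26-connected components
    of the mask restricted to a one-voxel-thick spherical shell at r
    (physical units, anisotropic). The AUC is the trapezoid integral of
    intersections over radius.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    cz, cy, cx = center_zyx
    if not mask[int(round(cz)), int(round(cy)), int(round(cx))]:
        raise ValueError("soma center must lie inside the cell mask")
    sz, sy, sx = spacing_zyx_um
    zz, yy, xx = np.meshgrid(
        (np.arange(mask.shape[0]) - cz) * sz,
        (np.arange(mask.shape[1]) - cy) * sy,
        (np.arange(mask.shape[2]) - cx) * sx,
        indexing="ij",
    )
    dist = np.sqrt(zz**2 + yy**2 + xx**2)
    # half the voxel diagonal: thick enough that a 26-connected process
    # cannot step across the shell between two sampled radii
    half_shell = float(np.linalg.norm(spacing_zyx_um)) / 2.0
    if max_radius_um is None:
        max_radius_um = float(dist[mask].max()) + radius_step_um
    radii = np.arange(radius_step_um, max_radius_um + radius_step_um / 2,
                      radius_step_um)
    inter = np.zeros(len(radii), dtype=int)
    for i, r in enumerate(radii):
        shell = mask & (np.abs(dist - r) <= half_shell)
        _, n = ndimage.label(shell, structure=_CONN26)
        inter[i] = n
    auc = float(np.trapezoid(inter, radii)) if len(radii) > 1 else 0.0
    return ShollProfile(radii_um=radii, intersections=inter, auc=auc)


@dataclass
class OrientationResult:
    """Structure-tensor orientation analysis of one 2D image."""

    orientation_deg: np.ndarray
    histogram_bins_deg: np.ndarray
    histogram_weights: np.ndarray
    dominant_angle_deg: float | None
    reported_abs_deg: float | None
    undefined: bool = False
    mean_coherence: float = 0.0


def dominant_orientation(
    image: np.ndarray,
    window_px: float = 20.0,
    n_bins: int = 180,
    coherence_floor: float = 0.2,
) -> OrientationResult:
    """Dominant local orientation from the smoothed structure tensor.

    Per-pixel orientation (degrees in (−90, 90], measured from the
    horizontal, counterclockwise with y pointing up) comes from the
    structure tensor smoothed by a Gaussian of sigma ``window_px``. The
    histogram is weighted by anisotropy energy (eigenvalue difference);
    the dominant angle is its mode and the reported value its absolute
    value. A constant or isotropic image (mean coherence below
    ``coherence_floor``) yields no dominant angle.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dominant_orientation expects a 2D image")
    gy_down, gx = np.gradient(img)
    gy = -gy_down  # image rows grow downward; flip to y-up convention
    jxx = ndimage.gaussian_filter(gx * gx, window_px)
    jyy = ndimage.gaussian_filter(gy * gy, window_px)
    jxy = ndimage.gaussian_filter(gx * gy, window_px)

    # principal gradient direction; the structure runs perpendicular to it
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = np.degrees(phi) + 90.0
    theta = ((theta + 90.0) % 180.0) - 90.0
    theta[theta == -90.0] = 90.0

    energy = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)  # λ1 − λ2
    trace = jxx + jyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, energy / trace, 0.0)
    mean_coh = float(coherence.mean())

    bins = np.linspace(-90.0, 90.0, n_bins + 1)
    weights, _ = np.histogram(theta.ravel(), bins=bins,
                              weights=energy.ravel())
    centers = (bins[:-1] + bins[1:]) / 2.0

    if energy.max() == 0 or mean_coh < coherence_floor:
        return OrientationResult(
            orientation_deg=theta,
            histogram_bins_deg=centers,
            histogram_weights=weights,
            dominant_angle_deg=None,
            reported_abs_deg=None,
            undefined=True,
            mean_coherence=mean_coh,
        )
    dominant = float(centers[int(np.argmax(weights))])
    return OrientationResult(
        orientation_deg=theta,
        histogram_bins_deg=centers,
        histogram_weights=weights,
        dominant_angle_deg=dominant,
        reported_abs_deg=abs(dominant),
        undefined=False,
        mean_coherence=mean_coh,
    )
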