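"""Synthetic smFISH volumes: ellipsoidal nuclei plus Gaussian puncta.

Emulates multiplexed RNAscope acquisitions: a DAPI nuclear channel and any
number of transcript channels in which each mRNA molecule appears as a
diffraction-limited bright spot. Nuclei are placed with disjoint x/y
footprints (optionally with touching pairs to exercise watershed
splitting), and each cell receives a known number of puncta per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import ImageVolume
from .base import GroundTruth, object_rng


class PlacementError(RuntimeError):
    """Requested objects cannot be placed in the given volume."""


@dataclass
class SmfishSpec:
    """Parameters of a synthetic smFISH acquisition.

    ``puncta_per_cell`` maps a transcript channel name to either a list of
    per-cell counts (length ``n_cells``) or a Poisson mean; counts are the
    recorded ground truth either way. ``touching_pairs`` of the ``n_cells``
    nuclei are placed as pairs whose masks overlap by 1–2 voxels.
    """

    n_cells: int = 10
    shape: tuple[int, int, int] = (16, 256, 256)  # (z, y, x)
    voxel_size_nm: tuple[float, float, float] = (200.0, 200.0, 500.0)  # (x, y, z)
    nucleus_radius_um: tuple[float, float] = (3.5, 2.0)  # (xy, z) semi-axes
    touching_pairs: int = 0
    puncta_per_cell: dict[str, list[int] | float] = field(
        default_factory=lambda: {"Fn14": 4.0}
    )
    dapi_channel: str = "DAPI"
    dapi_intensity: float = 1200.0
    punctum_peak: float = 2000.0
    punctum_sigma_px: float = 1.5
    background: float = 100.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sd < 0 or self.background < 0:
            raise ValueError("noise parameters must be >= 0")
        if 2 * self.touching_pairs > self.n_cells:
            raise ValueError("touching_pairs requires 2 cells per pair")


def _ellipsoid_mask(shape, center_zyx, radii_zyx):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center_zyx
    rz, ry, rx = radii_zyx
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _place_centers(spec: SmfishSpec, radii_zyx, rng) -> list[tuple[float, float, float]]:
    nz, ny, nx = spec.shape
    rz, ry, rx = radii_zyx
    if 2 * rx + 2 >= nx or 2 * ry + 2 >= ny or 2 * rz >= nz:
        raise PlacementError(
            f"volume shape {spec.shape} too small for nucleus radii "
            f"(z,y,x)={radii_zyx} voxels"
        )
    # xy footprints must be disjoint (projection-safe) except touching pairs
    min_sep_xy = 2.0 * max(rx, ry) + 3.0
    centers: list[tuple[float, float, float]] = []
    n_pairs = spec.touching_pairs
    n_singles = spec.n_cells - 2 * n_pairs

    def try_place(extra=None, max_tries=4000):
        for _ in range(max_tries):
            cz = rng.uniform(rz, nz - 1 - rz)
            cy = rng.uniform(ry + 1, ny - 2 - ry)
            cx = rng.uniform(rx + 1, nx - 2 - rx)
            cand = [(cy + dy, cx + dx) for dy, dx in (extra or [(0.0, 0.0)])]
            ok = True
            for py, px in cand:
                if not (ry + 1 <= py <= ny - 2 - ry and rx + 1 <= px <= nx - 2 - rx):
                    ok = False
                    break
                for _, ey, ex in centers:
                    if np.hypot(py - ey, px - ex) < min_sep_xy:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return cz, cy, cx
        raise PlacementError(
            f"could not place {spec.n_cells} nuclei with xy separation "
            f">= {min_sep_xy:.1f} px in a {ny}x{nx} field"
        )

    for _ in range(n_pairs):
        # second nucleus offset slightly under two xy radii -> 1-2 voxel overlap
        gap = 2.0 * rx - 1.5
        cz, cy, cx = try_place(extra=[(0.0, 0.0), (0.0, gap)])
        centers.append((cz, cy, cx))
        centers.append((cz, cy, cx + gap))
    for _ in range(n_singles):
        centers.append(try_place())
    return centers


def gen_smfish_volume(spec: SmfishSpec) -> tuple[ImageVolume, GroundTruth]:
    """Generate a synthetic smFISH volume and its ground truth.

    Returns the volume (DAPI plus transcript channels) and a GroundTruth
    holding the nucleus label volume, nucleus centers, per-cell puncta
    counts per channel, and every punctum's (z, y, x) coordinate and peak.
    """
    rng = object_rng(spec.seed, 0)
    x_nm, y_nm, z_nm = spec.voxel_size_nm
    r_xy_um, r_z_um = spec.nucleus_radius_um
    radii_zyx = (
        max(1.0, r_z_um * 1000.0 / z_nm),
        max(1.0, r_xy_um * 1000.0 / y_nm),
        max(1.0, r_xy_um * 1000.0 / x_nm),
    )

    labels = np.zeros(spec.shape, dtype=np.int32)
    centers = _place_centers(spec, radii_zyx, rng) if spec.n_cells else []
    for k, c in enumerate(centers, start=1):
        mask = _ellipsoid_mask(spec.shape, c, radii_zyx)
        labels[mask & (labels == 0)] = k  # first-placed cell keeps overlap voxels

    channels: dict[str, np.ndarray] = {}
    dapi = np.full(spec.shape, spec.background, dtype=np.float64)
    dapi[labels > 0] += spec.dapi_intensity
    channels[spec.dapi_channel] = dapi

    counts_truth: dict[str, np.ndarray] = {}
    puncta_truth: dict[str, list] = {}
    for ci, (ch, per_cell) in enumerate(sorted(spec.puncta_per_cell.items())):
        ch_rng = object_rng(spec.seed, 1, ci)
        if np.isscalar(per_cell):
            counts = ch_rng.poisson(float(per_cell), size=spec.n_cells)
        else:
            counts = np.asarray(per_cell, dtype=int)
            if counts.size != spec.n_cells:
                raise ValueError(
                    f"puncta_per_cell[{ch!r}] has {counts.size} entries for "
                    f"{spec.n_cells} cells"
                )
        img = np.full(spec.shape, spec.background, dtype=np.float64)
        placed: list[dict] = []
        for k in range(1, spec.n_cells + 1):
            cell_rng = object_rng(spec.seed, 1, ci, k)
            cand = np.argwhere(labels == k)
            coords = _pick_spot_coords(cand, int(counts[k - 1]), cell_rng, k)
            for z, y, x in coords:
                _add_spot(img, (z, y, x), spec.punctum_peak, spec.punctum_sigma_px)
                placed.append(
                    {"cell": k, "zyx": (int(z), int(y), int(x)),
                     "peak": spec.punctum_peak}
                )
        channels[ch] = img
        counts_truth[ch] = counts
        puncta_truth[ch] = placed

    if spec.noise_sd > 0:
        noise_rng = object_rng(spec.seed, 2)
        for ch in channels:
            channels[ch] = channels[ch] + noise_rng.normal(
                0.0, spec.noise_sd, spec.shape
            )

    volume = ImageVolume(channels=channels, voxel_size_nm=spec.voxel_size_nm)
    truth = GroundTruth(
        modality="smfish",
        values={
            "labels": labels,
            "centers_zyx": centers,
            "counts": counts_truth,
            "puncta": puncta_truth,
            "dapi_channel": spec.dapi_channel,
        },
    )
    return volume, truth


def _pick_spot_coords(candidates: np.ndarray, n: int, rng, cell: int,
                      min_sep_xy: float = 8.0) -> list[tuple[int, int, int]]:
    """Pick n in-nucleus voxels with pairwise xy separation >= min_sep_xy."""
    if n == 0:
        return []
    if candidates.size == 0:
        raise PlacementError(f"cell {cell} has no interior voxels for puncta")
    order = rng.permutation(len(candidates))
    chosen: list[tuple[int, int, int]] = []
    for idx in order:
        z, y, x = candidates[idx]
        if all(np.hypot(float(y) - cy, float(x) - cx) >= min_sep_xy
               for _, cy, cx in chosen):
            chosen.append((int(z), int(y), int(x)))
            if len(chosen) == n:
                return chosen
    raise PlacementError(
        f"cell {cell}: could not place {n} puncta with xy separation "
        f">= {min_sep_xy} px"
    )


def _add_spot(img: np.ndarray, center_zyx, peak: float, sigma_px: float) -> None:
    """Add a 3D Gaussian spot whose center voxel equals exactly ``peak``."""
    z0, y0, x0 = center_zyx
    r = max(1, int(np.ceil(3 * sigma_px)))
    zs = slice(max(0, z0 - r), min(img.shape[0], z0 + r + 1))
    ys = slice(max(0, y0 - r), min(img.shape[1], y0 + r + 1))
    xs = slice(max(0, x0 - r), min(img.shape[2], x0 + r + 1))
    zz, yy, xx = np.mgrid[zs, ys, xs]
    d2 = (zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2
    spot = peak * np.exp(-d2 / (2.0 * sigma_px**2))
    # max-compose so the center voxel equals exactly ``peak`` and overlapping
    # tails never raise a neighbouring punctum's recorded peak
    np.maximum(img[zs, ys, xs], spot, out=img[zs, ys, xs])
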