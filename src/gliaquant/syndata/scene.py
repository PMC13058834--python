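"""Synthetic 3D microglia-synapse scenes on anisotropic voxel grids.

A branched-tube microglia mask (polyline skeleton dilated to a physical
radius) is rasterized at the acquisition's anisotropic voxel pitch, and
single-voxel synaptic puncta are placed at requested signed distances from
the microglia surface (negative = inside the cell, i.e. engulfed). Because
the grid is discrete, the achieved distance — the signed
nearest-mask-voxel distance of the chosen voxel — is recorded next to the
requested one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..micromorph import signed_distance_field
from ..types import ImageVolume
from .base import GroundTruth, object_rng

# default Y-shaped skeleton, physical μm coordinates as (z, y, x)
def _default_branches(shape, spacing):
    nz, ny, nx = shape
    sz, sy, sx = spacing
    zc = (nz / 2) * sz
    return [
        ((zc, 0.15 * ny * sy, 0.5 * nx * sx), (zc, 0.55 * ny * sy, 0.5 * nx * sx)),
        ((zc, 0.55 * ny * sy, 0.5 * nx * sx), (zc, 0.9 * ny * sy, 0.25 * nx * sx)),
        ((zc, 0.55 * ny * sy, 0.5 * nx * sx), (zc, 0.9 * ny * sy, 0.75 * nx * sx)),
    ]


@dataclass
class MicrogliaSceneSpec:
    """Parameters of a synthetic microglia-synapse scene.

    ``puncta`` maps a synapse channel name (e.g. ``"vGluT1"``, ``"vGaT"``)
    to a list of requested signed distances in μm from the microglia
    surface. ``branches`` is an optional list of skeleton segments in
    physical (z, y, x) μm; a Y-shaped default is used when omitted.
    """

    shape: tuple[int, int, int] = (24, 96, 96)  # (z, y, x)
    voxel_size_nm: tuple[float, float, float] = (70.7, 70.7, 311.0)  # (x, y, z)
    tube_radius_um: float = 0.6
    branches: list | None = None
    puncta: dict[str, list[float]] = field(default_factory=dict)
    microglia_channel: str = "Iba1"
    intensity: float = 1000.0
    background: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tube_radius_um <= 0:
            raise ValueError("tube_radius_um must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _rasterize_tubes(shape, spacing_zyx_um, branches, radius_um) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing_zyx_um[0],
        (np.arange(shape[1]) + 0.5) * spacing_zyx_um[1],
        (np.arange(shape[2]) + 0.5) * spacing_zyx_um[2],
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    mask = np.zeros(shape, dtype=bool)
    for a, b in branches:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = ((pts - a) @ ab) / denom if denom > 0 else np.zeros(shape)
        t = np.clip(t, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(pts - closest, axis=-1)
        mask |= d <= radius_um
    return mask


def gen_microglia_scene(
    spec: MicrogliaSceneSpec,
) -> tuple[ImageVolume, GroundTruth]:
    """Generate a scene plus per-punctum true signed distances in μm."""
    x_nm, y_nm, z_nm = spec.voxel_size_nm
    spacing = (z_nm / 1000.0, y_nm / 1000.0, x_nm / 1000.0)  # (z, y, x) μm
    half_pitch = max(spec.voxel_size_nm) / 1000.0 / 2.0

    branches = spec.branches
    if branches is None:
        branches = _default_branches(spec.shape, spacing)
    mask = _rasterize_tubes(spec.shape, spacing, branches, spec.tube_radius_um)

    sdf = signed_distance_field(mask, spacing)

    channels: dict[str, np.ndarray] = {
        spec.microglia_channel: np.where(mask, spec.intensity, spec.background)
    }
    contacts: list[dict] = []
    taken: set[tuple[int, int, int]] = set()
    flat_sdf = sdf.ravel()
    for ci, (ch, dists) in enumerate(sorted(spec.puncta.items())):
        img = np.full(spec.shape, spec.background, dtype=np.float64)
        rng = object_rng(spec.seed, 3, ci)
        for d in dists:
            if abs(d) < half_pitch:
                warnings.warn(
                    f"requested distance {d} μm is finer than half the largest "
                    f"voxel pitch ({half_pitch:.3f} μm); discretization may "
                    "dominate",
                    stacklevel=2,
                )
            err = np.abs(flat_sdf - d)
            order = np.argsort(err)
            for flat_idx in order[:256]:
                zyx = tuple(int(v) for v in np.unravel_index(flat_idx, spec.shape))
                if zyx not in taken:
                    break
            else:
                raise RuntimeError(f"no free voxel near distance {d} μm")
            taken.add(zyx)
            img[zyx] = spec.intensity
            contacts.append(
                {
                    "channel": ch,
                    "zyx": zyx,
                    "requested_um": float(d),
                    "achieved_um": float(sdf[zyx]),
                }
            )
        channels[ch] = img

    if spec.noise_sd > 0:
        nz_rng = object_rng(spec.seed, 4)
        for ch in channels:
            channels[ch] = channels[ch] + nz_rng.normal(
                0.0, spec.noise_sd, spec.shape
            )

    volume = ImageVolume(channels=channels, voxel_size_nm=spec.voxel_size_nm)
    truth = GroundTruth(
        modality="microglia_scene",
        values={
            "microglia_mask": mask,
            "puncta": contacts,
            "voxel_size_nm": spec.voxel_size_nm,
        },
    )
    return volume, truth
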