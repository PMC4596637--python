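"""Synthetic membrane-labeled primordium generator with exact ground truth.

Emulates confocal stacks of a migrating epithelial cell cluster of the
posterior-lateral-line-primordium type: ~100 tightly packed cells inside an
elongated ellipsoid, with fluorescent cell outlines (membrane channel), an
optional nuclear S-phase channel (EdU-like), and translating time-lapse
series.  Geometry is a centroidal-leaning Voronoi packing; optics are an
anisotropic Gaussian PSF plus additive Gaussian noise.

Because each image is built from a known label field, cell-center list,
EdU-positive set and motion speed, every downstream stage (enhancement,
segmentation, counting, kinetics) can be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import LabelVolume, Volume

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PackingError",
    "generate_primordium",
    "generate_edu_channel",
    "generate_timelapse",
]


class PackingError(RuntimeError):
    """Raised when the requested number of cells cannot be packed."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} cell centers with the required "
            f"minimum separation; achieved {achieved}"
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic primordium acquisition.

    Lengths are µm, axis order ``(z, y, x)`` with x the long
    (anteroposterior) axis.  Defaults model a cluster of about 100
    progenitors in a 32 × 32 × 64 µm field sampled at 1.0 × 0.5 × 0.5 µm,
    membranes ~1 µm wide and several-fold brighter than cytoplasm.
    """

    n_cells: int = 100
    domain_semi_axes: tuple[float, float, float] = (12.0, 13.0, 28.0)
    shape: tuple[int, int, int] = (32, 64, 128)
    voxel_spacing: tuple[float, float, float] = (1.0, 0.5, 0.5)
    membrane_width: float = 1.0
    membrane_peak: float = 100.0
    interior_level: float = 20.0
    background_level: float = 10.0
    psf_sigma: tuple[float, float, float] = (0.8, 0.3, 0.3)
    noise_sigma: float = 10.0
    edu_fraction: float = 0.3
    edu_peak: float = 100.0
    min_separation_factor: float = 0.6
    speed: float = 60.0
    frame_interval: float = 10.0
    n_frames: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be a positive integer")
        for name in ("domain_semi_axes", "voxel_spacing", "psf_sigma"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have 3 components")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        if any(s <= 0 for s in self.domain_semi_axes):
            raise ValueError("domain_semi_axes must be strictly positive")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be non-negative")
        if self.membrane_width <= 0:
            raise ValueError("membrane_width must be positive")
        if not (self.membrane_peak > self.interior_level >= self.background_level >= 0):
            raise ValueError(
                "require membrane_peak > interior_level >= background_level >= 0"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 <= self.edu_fraction <= 1.0:
            raise ValueError("edu_fraction must lie in [0, 1]")
        if self.frame_interval <= 0 or self.n_frames < 1:
            raise ValueError("frame_interval must be positive and n_frames >= 1")
        if self.min_separation_factor <= 0:
            raise ValueError("min_separation_factor must be positive")

    # -- derived geometry -------------------------------------------------
    @property
    def ellipsoid_volume(self) -> float:
        a, b, c = self.domain_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def cell_volume(self) -> float:
        """Expected cell volume in µm³ (ellipsoid volume / n_cells)."""
        return self.ellipsoid_volume / self.n_cells

    @property
    def cell_diameter(self) -> float:
        """Equivalent-sphere cell diameter in µm."""
        return float((6.0 * self.cell_volume / np.pi) ** (1.0 / 3.0))

    def _streams(self):
        """Independent RNG sub-streams so e.g. toggling EdU keeps geometry."""
        ss = np.random.SeedSequence(self.seed)
        place, noise, edu, motion = ss.spawn(4)
        return {
            "placement": np.random.default_rng(place),
            "noise": np.random.default_rng(noise),
            "edu": np.random.default_rng(edu),
            "motion": motion,  # SeedSequence; spawned per frame
        }


@dataclass(frozen=True)
class GroundTruth:
    """Exact truth accompanying a synthetic image."""

    labels: LabelVolume
    centers: np.ndarray  # (n_cells, 3) physical µm, (z, y, x)
    n_cells: int
    edu_positive: frozenset = frozenset()
    true_speed: float | None = None  # µm/hr, time-lapse only

    def __post_init__(self):
        present = np.unique(self.labels.labels)
        present = present[present > 0]
        if len(present) != self.n_cells:
            raise ValueError(
                f"label volume has {len(present)} distinct cells, expected {self.n_cells}"
            )
        if not set(self.edu_positive) <= set(range(1, self.n_cells + 1)):
            raise ValueError("edu_positive must be a subset of {1..n_cells}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grid_coords(shape, spacing):
    """Physical (µm) coordinates of voxel centers, three broadcastable axes."""
    return [
        (np.arange(n) * s).reshape([-1 if i == j else 1 for j in range(3)])
        for i, (n, s) in enumerate(zip(shape, spacing))
    ]


def _ellipsoid_radius2(shape, spacing, center, semi_axes):
    zc, yc, xc = _grid_coords(shape, spacing)
    r2 = np.zeros(shape)
    for c, mu, a in zip((zc, yc, xc), center, semi_axes):
        r2 = r2 + ((c - mu) / a) ** 2
    return r2


def _sample_centers(spec: SyntheticSpec, rng, ellipsoid_center) -> np.ndarray:
    """Rejection-sample cell centers inside the ellipsoid with a minimum
    separation of ``min_separation_factor`` × the equivalent cell diameter
    (the default 0.6 keeps the packing comfortably below the random-
    sequential-addition jamming limit at any density), then relax them
    toward the centroids of their Voronoi regions (two Lloyd steps)."""
    semi = np.asarray(spec.domain_semi_axes)
    center = np.asarray(ellipsoid_center)
    min_sep = spec.min_separation_factor * spec.cell_diameter
    max_stall = 5000  # consecutive rejections before declaring infeasibility

    placed: list[np.ndarray] = []
    stall = 0
    while len(placed) < spec.n_cells and stall < max_stall:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u**2) > 0.9**2:  # keep centers off the very edge
            continue
        p = center + u * semi
        if placed:
            d = np.min(np.linalg.norm(np.asarray(placed) - p, axis=1))
            if d < min_sep:
                stall += 1
                continue
        placed.append(p)
        stall = 0
    if len(placed) < spec.n_cells:
        raise PackingError(spec.n_cells, len(placed))
    centers = np.asarray(placed)

    # centroidal relaxation on the voxel grid
    for _ in range(2):
        labels, inside = _voronoi_labels(spec, centers, ellipsoid_center)
        idx = np.argwhere(labels > 0)
        phys = idx * np.asarray(spec.voxel_spacing)
        lab = labels[labels > 0]
        sums = np.zeros((spec.n_cells, 3))
        counts = np.bincount(lab, minlength=spec.n_cells + 1)[1:]
        for ax in range(3):
            sums[:, ax] = np.bincount(lab, weights=phys[:, ax],
                                      minlength=spec.n_cells + 1)[1:]
        nonempty = counts > 0
        centers[nonempty] = sums[nonempty] / counts[nonempty, None]
        # keep relaxed centers inside the ellipsoid
        u = (centers - center) / semi
        r = np.linalg.norm(u, axis=1)
        out = r > 0.95
        if out.any():
            centers[out] = center + u[out] / r[out, None] * 0.95 * semi
    return centers


def _voronoi_labels(spec: SyntheticSpec, centers, ellipsoid_center):
    """Nearest-center (Voronoi) labeling of voxels inside the ellipsoid."""
    r2 = _ellipsoid_radius2(spec.shape, spec.voxel_spacing, ellipsoid_center,
                            spec.domain_semi_axes)
    inside = r2 < 1.0
    idx = np.argwhere(inside)
    phys = idx * np.asarray(spec.voxel_spacing)
    _, owner = cKDTree(centers).query(phys, k=1)
    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[inside] = owner + 1
    return labels, inside


def _membrane_distance(labels: np.ndarray, inside: np.ndarray, spacing):
    """Physical distance of every inside voxel to the nearest inter-cell or
    cell-exterior boundary voxel."""
    boundary = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        a = np.swapaxes(labels, 0, ax)
        diff = a[1:] != a[:-1]
        b = np.swapaxes(boundary, 0, ax)
        b[1:] |= diff
        b[:-1] |= diff
    boundary &= inside
    if not boundary.any():
        return np.full(labels.shape, np.inf)
    return ndi.distance_transform_edt(~boundary, sampling=spacing)


def _render_membrane(spec: SyntheticSpec, centers, ellipsoid_center):
    """Noise-free, PSF-free membrane intensity image plus truth labels."""
    labels, inside = _voronoi_labels(spec, centers, ellipsoid_center)
    dist = _membrane_distance(labels, inside, spec.voxel_spacing)
    img = np.full(spec.shape, spec.background_level, dtype=np.float64)
    sigma_m = spec.membrane_width / 2.0
    bump = (spec.membrane_peak - spec.interior_level) * np.exp(
        -(dist**2) / (2.0 * sigma_m**2)
    )
    bump[dist > spec.membrane_width] = 0.0  # compact support
    img[inside] = spec.interior_level + bump[inside]
    return img, labels


def _apply_optics(img, spec: SyntheticSpec, rng=None):
    psf_vox = [s / v for s, v in zip(spec.psf_sigma, spec.voxel_spacing)]
    if any(s > 0 for s in psf_vox):
        img = ndi.gaussian_filter(img, sigma=psf_vox, mode="nearest")
    if rng is not None and spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return img


def _default_center(spec: SyntheticSpec):
    ext = [(n - 1) * s for n, s in zip(spec.shape, spec.voxel_spacing)]
    return tuple(e / 2.0 for e in ext)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_primordium(spec: SyntheticSpec) -> tuple[Volume, GroundTruth]:
    """Generate one membrane-channel stack and its ground truth.

    The cluster is the Voronoi partition (restricted to the ellipsoid) of
    ``n_cells`` centers; intensity is ``interior_level`` plus a Gaussian
    membrane ridge peaking at ``membrane_peak`` within ``membrane_width`` of
    any boundary, blurred by the PSF and corrupted by additive Gaussian
    noise.  Ground-truth labels are the noise-free Voronoi labeling.
    """
    streams = spec._streams()
    center = _default_center(spec)
    centers = _sample_centers(spec, streams["placement"], center)
    img, labels = _render_membrane(spec, centers, center)
    img = _apply_optics(img, spec, streams["noise"])
    vol = Volume(img, spec.voxel_spacing)
    gt = GroundTruth(
        labels=LabelVolume(labels, spec.voxel_spacing),
        centers=centers,
        n_cells=spec.n_cells,
    )
    return vol, gt


def generate_edu_channel(
    gt: GroundTruth, spec: SyntheticSpec
) -> tuple[Volume, GroundTruth]:
    """Generate the nuclear S-phase channel for an existing ground truth.

    Each cell is independently positive with probability ``edu_fraction``
    (its own RNG sub-stream, so the same seed gives the same positives
    regardless of noise settings); positive cells carry a Gaussian nuclear
    blob of amplitude ``edu_peak`` at their center.
    """
    streams = spec._streams()
    rng = streams["edu"]
    pos = np.flatnonzero(rng.random(gt.n_cells) < spec.edu_fraction) + 1
    img = np.full(spec.shape, spec.background_level, dtype=np.float64)
    if len(pos):
        sigma_n = 0.25 * spec.cell_diameter
        spacing = np.asarray(spec.voxel_spacing)
        for lbl in pos:  # render each blob only in its ±4σ window
            c = gt.centers[lbl - 1]
            lo = np.maximum(np.floor((c - 4 * sigma_n) / spacing), 0).astype(int)
            hi = np.minimum(np.ceil((c + 4 * sigma_n) / spacing) + 1,
                            spec.shape).astype(int)
            axes = [np.arange(lo[a], hi[a]) * spacing[a] - c[a] for a in range(3)]
            r2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
                  + axes[2][None, None, :] ** 2) / (2 * sigma_n**2)
            img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += spec.edu_peak * np.exp(-r2)
    img = _apply_optics(img, spec, rng)
    vol = Volume(img, spec.voxel_spacing)
    gt_out = replace(gt, edu_positive=frozenset(int(p) for p in pos))
    return vol, gt_out


def generate_timelapse(spec: SyntheticSpec) -> tuple[list[Volume], GroundTruth]:
    """Generate a time-lapse of the primordium translating along +x.

    The noise-free template is shifted by ``speed × frame_interval`` per
    frame (subvoxel shifts by linear interpolation); each frame receives
    independent noise.  The cluster starts at the left of the field; series
    whose total translation would push it out of the field are rejected.
    """
    streams = spec._streams()
    dz, dy, dx = spec.voxel_spacing
    semi = spec.domain_semi_axes
    shift_um = spec.speed * spec.frame_interval / 60.0
    total_shift = shift_um * (spec.n_frames - 1)
    margin = 3.0 * max(spec.psf_sigma) + spec.membrane_width
    ext_x = (spec.shape[2] - 1) * dx
    x0 = semi[2] + margin
    if x0 + semi[2] + total_shift + margin > ext_x:
        raise ValueError(
            f"total translation {total_shift:.1f} µm exceeds the field of view "
            f"({ext_x:.1f} µm along x)"
        )
    center = (_default_center(spec)[0], _default_center(spec)[1], x0)
    centers = _sample_centers(spec, streams["placement"], center)
    template, labels = _render_membrane(spec, centers, center)
    template = _apply_optics(template, spec, rng=None)

    frame_streams = streams["motion"].spawn(spec.n_frames)
    frames = []
    for k in range(spec.n_frames):
        img = ndi.shift(
            template,
            shift=(0.0, 0.0, k * shift_um / dx),
            order=1,
            mode="constant",
            cval=spec.background_level,
        )
        if spec.noise_sigma > 0:
            rng_k = np.random.default_rng(frame_streams[k])
            img = img + rng_k.normal(0.0, spec.noise_sigma, size=img.shape)
        frames.append(Volume(img, spec.voxel_spacing))
    gt = GroundTruth(
        labels=LabelVolume(labels, spec.voxel_spacing),
        centers=centers,
        n_cells=spec.n_cells,
        true_speed=float(spec.speed),
    )
    return frames, gt
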