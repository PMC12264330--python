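"""Synthetic multi-contrast vessel phantoms with controllable label misalignment.

Each phantom is a stack of axial slices containing a tubular lumen inside an
annular vessel wall on a textured background, rendered across seven correlated
contrast channels.  Label noise emulates contours registered from another
modality: either a rigid in-plane shift of whole slices, or — the default —
displacement of only an angular sector of the contour, so that misalignment
affects a portion of the boundary on some slices while the rest stays correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .volume_io import (
    BACKGROUND,
    LUMEN,
    WALL,
    ImageVolume,
    LabelMask,
    Quality,
    normalize_volume,
    onehot_encode,
    write_manifest,
    write_mask,
    write_volume,
)

#: Default class-channel mean intensities, shape (3 classes, 7 channels) with
#: row order (lumen, wall, background).  Channels vary in how informative they
#: are: ch2 cannot separate lumen from wall, ch5/ch6 are near-uninformative —
#: emulating the variable contrast of the seven SNAP-derived modalities.
DEFAULT_CLASS_CHANNEL_MEANS = np.array(
    [
        #  ch0   ch1   ch2   ch3   ch4   ch5   ch6
        [2.0,  0.0,  1.2, -1.0,  0.8,  0.1,  0.0],   # lumen
        [0.5,  1.5,  1.2,  0.5, -0.8,  0.0,  0.1],   # vessel wall
        [0.0,  0.3,  0.0,  0.0,  0.0,  0.0,  0.1],   # background
    ],
    dtype=np.float64,
)


@dataclass
class PhantomConfig:
    """Geometry and intensity model of one phantom volume.

    The centerline drifts sinusoidally in-plane along the slice axis by
    ``centerline_amplitude`` voxels, so consecutive slices see the vessel at
    slightly different positions, as in a curved artery.
    """

    N: int = 12
    H: int = 64
    W: int = 64
    lumen_radius: float = 5.0
    wall_radius: float = 9.0
    centerline_amplitude: float = 3.0
    centerline_phase: float = 0.0
    class_channel_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_CHANNEL_MEANS.copy()
    )
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (self.wall_radius > self.lumen_radius >= 2):
            raise ValueError("require wall_radius > lumen_radius >= 2")
        if self.wall_radius + self.centerline_amplitude >= min(self.H, self.W) / 2:
            raise ValueError("vessel does not fit inside the field of view")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        means = np.asarray(self.class_channel_means)
        if means.shape != (3, 7):
            raise ValueError("class_channel_means must be 3x7")


@dataclass
class MisalignmentSpec:
    """How to corrupt a clean label into a misaligned one.

    ``slice_shift`` translates whole label slices rigidly; ``sector_displace``
    moves only the part of each contour whose polar angle (about the slice's
    label centroid) falls in ``sector``, then re-rasterizes.
    """

    mode: str = "sector_displace"
    shift: tuple[int, int] = (3, 0)
    sector: tuple[float, float] = (0.0, 120.0)
    affected_slices: tuple[int, ...] | None = None
    seed: int = 0

    def validate(self, require_shift: bool = False) -> None:
        if self.mode not in ("slice_shift", "sector_displace"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if require_shift and max(abs(self.shift[0]), abs(self.shift[1])) < 1:
            raise ValueError("shift must be at least 1 voxel")
        span = (self.sector[1] - self.sector[0]) % 360.0
        if span == 0.0:
            span = 360.0 if self.sector[1] != self.sector[0] else 0.0
        if not (0.0 < span <= 360.0):
            raise ValueError("sector span must lie in (0, 360] degrees")


def _centerline(cfg: PhantomConfig) -> np.ndarray:
    """Per-slice (row, col) centre of the vessel."""
    n = np.arange(cfg.N)
    rows = cfg.H / 2 + cfg.centerline_amplitude * np.sin(
        2 * np.pi * n / max(cfg.N, 1) + cfg.centerline_phase
    )
    cols = cfg.W / 2 + cfg.centerline_amplitude * np.cos(
        2 * np.pi * n / max(cfg.N, 1) + cfg.centerline_phase
    )
    return np.stack([rows, cols], axis=1)


def phantom_class_map(cfg: PhantomConfig) -> np.ndarray:
    """Rasterize the geometry: lumen inside ``lumen_radius``, wall in the annulus."""
    centers = _centerline(cfg)
    rr, cc = np.mgrid[0:cfg.H, 0:cfg.W]
    cmap = np.full((cfg.N, cfg.H, cfg.W), BACKGROUND, dtype=np.int8)
    for n in range(cfg.N):
        d = np.hypot(rr - centers[n, 0], cc - centers[n, 1])
        cmap[n][d < cfg.wall_radius] = WALL
        cmap[n][d < cfg.lumen_radius] = LUMEN
    return cmap


def generate_phantom(cfg: PhantomConfig,
                     spacing: tuple[float, float, float] = (0.31, 0.31, 2.0),
                     volume_id: str = "phantom") -> tuple[ImageVolume, LabelMask]:
    """Generate one phantom volume and its exact geometric ground truth.

    Channel ``c`` at a voxel of class ``k`` is drawn from
    ``Normal(class_channel_means[k, c], noise_sd)`` and the volume is then
    per-channel standardized.  Deterministic for a given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cmap = phantom_class_map(cfg)
    means = np.asarray(cfg.class_channel_means, dtype=np.float64)
    data = means[cmap] + rng.normal(0.0, cfg.noise_sd, size=(cfg.N, cfg.H, cfg.W, 7))
    vol = normalize_volume(ImageVolume(data, spacing, volume_id))
    return vol, onehot_encode(cmap)


# ---------------------------------------------------------------------------
# Label corruption
# ---------------------------------------------------------------------------

def _shift_slice(class_slice: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Integer translation with background fill at the edges."""
    out = np.full_like(class_slice, BACKGROUND)
    h, w = class_slice.shape
    r0, r1 = max(drow, 0), min(h + drow, h)
    c0, c1 = max(dcol, 0), min(w + dcol, w)
    out[r0:r1, c0:c1] = class_slice[r0 - drow:r1 - drow, c0 - dcol:c1 - dcol]
    return out


def _angle_in_sector(theta_deg: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    start, end = sector[0] % 360.0, sector[1] % 360.0
    t = theta_deg % 360.0
    if (sector[1] - sector[0]) % 360.0 == 0.0 and sector[1] != sector[0]:
        return np.ones_like(t, dtype=bool)
    if start <= end:
        return (t >= start) & (t < end)
    return (t >= start) | (t < end)


def _region_polygon(mask: np.ndarray, centroid: np.ndarray,
                    n_vertices: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Polar boundary polygon of a star-shaped region about ``centroid``.

    Returns (theta_deg, radius) sampled on a dense angular grid; radius is the
    outermost extent of the region along each ray (0 where the ray misses it).
    """
    rr, cc = np.nonzero(mask)
    dr, dc = rr - centroid[0], cc - centroid[1]
    theta = np.degrees(np.arctan2(dc, dr)) % 360.0
    rad = np.hypot(dr, dc)
    grid = np.linspace(0.0, 360.0, n_vertices, endpoint=False)
    # outer extent per angular bin; + half a voxel so rasterization recovers area
    bin_idx = np.floor(theta / 360.0 * n_vertices).astype(int) % n_vertices
    radius = np.zeros(n_vertices)
    np.maximum.at(radius, bin_idx, rad + 0.5)
    # fill empty bins by nearest occupied neighbour (circular)
    if (radius == 0).any() and (radius > 0).any():
        occ = np.nonzero(radius > 0)[0]
        for i in np.nonzero(radius == 0)[0]:
            j = occ[np.argmin(np.minimum(np.abs(occ - i), n_vertices - np.abs(occ - i)))]
            radius[i] = radius[j]
    return grid, radius


def _displace_sector_slice(class_slice: np.ndarray, spec: MisalignmentSpec) -> np.ndarray:
    """Move the contour sector of both regions by ``spec.shift`` and re-rasterize.

    The outer-wall region (lumen + wall) and the lumen region are each traced
    as polar polygons about the label centroid; vertices inside the sector are
    translated.  Wall is painted first, then lumen, which guarantees a valid
    one-hot topology after displacement.
    """
    fg = class_slice != BACKGROUND
    if not fg.any():
        raise ValueError("affected slice has empty foreground")
    centroid = np.array(np.nonzero(fg)).mean(axis=1)
    out = np.full_like(class_slice, BACKGROUND)
    h, w = class_slice.shape
    for region_mask, cls in (
        (fg, WALL),                       # outer-wall region painted first
        (class_slice == LUMEN, LUMEN),    # lumen painted on top
    ):
        if not region_mask.any():
            continue
        theta, radius = _region_polygon(region_mask, centroid)
        tr = np.radians(theta)
        vr = centroid[0] + radius * np.cos(tr)
        vc = centroid[1] + radius * np.sin(tr)
        sel = _angle_in_sector(theta, spec.sector)
        vr = vr + sel * spec.shift[0]
        vc = vc + sel * spec.shift[1]
        rr, cc = draw_polygon(vr, vc, shape=(h, w))
        out[rr, cc] = cls
    return out


def corrupt_label(label: LabelMask, spec: MisalignmentSpec) -> LabelMask:
    """Produce a misaligned copy of a clean label.

    Slices not in ``spec.affected_slices`` are bit-identical to the input; the
    output carries the ``misaligned`` quality flag.  A zero shift is allowed
    here as a degenerate identity corruption (useful as a control); dataset
    generation requires a real displacement.
    """
    label.validate()
    spec.validate()
    if spec.shift == (0, 0):
        return onehot_encode(label.class_map, Quality.MISALIGNED)
    cmap = label.class_map
    n = cmap.shape[0]
    if spec.affected_slices is None:
        # roughly half the slices, at least one, chosen reproducibly
        rng = np.random.default_rng(spec.seed)
        k = max(1, n // 2)
        affected = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
    else:
        affected = tuple(spec.affected_slices)
    out = cmap.copy()
    for s in affected:
        if not (0 <= s < n):
            raise ValueError(f"affected slice {s} out of range")
        if spec.mode == "slice_shift":
            out[s] = _shift_slice(cmap[s], *spec.shift)
        else:
            out[s] = _displace_sector_slice(cmap[s], spec)
    return onehot_encode(out, Quality.MISALIGNED)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _vary_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> PhantomConfig:
    """Per-volume geometric variability, emulating inter-subject differences."""
    lr = cfg.lumen_radius * rng.uniform(0.8, 1.2)
    wr = max(lr + 2.0, cfg.wall_radius * rng.uniform(0.85, 1.15))
    return replace(
        cfg,
        lumen_radius=lr,
        wall_radius=wr,
        centerline_amplitude=cfg.centerline_amplitude * rng.uniform(0.5, 1.3),
        centerline_phase=rng.uniform(0.0, 2 * np.pi),
    )


def make_cohort(n_clean: int, n_misaligned: int, cfg: PhantomConfig,
                spec: MisalignmentSpec | None = None, seed: int = 0,
                split: str = "train",
                spacing: tuple[float, float, float] = (0.31, 0.31, 2.0)
                ) -> list[tuple[ImageVolume, LabelMask, LabelMask]]:
    """Generate a cohort in memory.

    Returns (volume, served label, clean label) triples; for clean volumes the
    served and clean labels are the same object.  Geometry varies per volume;
    per-volume seeds derive deterministically from ``seed``.
    """
    if n_clean < 0 or n_misaligned < 0:
        raise ValueError("counts must be >= 0")
    spec = spec or MisalignmentSpec()
    if n_misaligned:
        spec.validate(require_shift=True)
    children = np.random.SeedSequence(seed).spawn(n_clean + n_misaligned)
    out = []
    for idx, child in enumerate(children):
        misaligned = idx >= n_clean
        sub = child.generate_state(3)  # independent streams: geometry/noise/corruption
        vid = f"{split}_{idx:03d}"
        vcfg = _vary_geometry(replace(cfg, seed=int(sub[1] % (2 ** 31))),
                              np.random.default_rng(int(sub[0] % (2 ** 31))))
        vol, clean = generate_phantom(vcfg, spacing, vid)
        if misaligned:
            vspec = replace(spec, seed=int(sub[2] % (2 ** 31)))
            served = corrupt_label(clean, vspec)
        else:
            served = clean
        out.append((vol, served, clean))
    return out


def generate_dataset(out_dir: str | Path, n_clean: int, n_misaligned: int,
                     cfg: PhantomConfig, spec: MisalignmentSpec | None = None,
                     seed: int = 0, split: str = "train",
                     spacing: tuple[float, float, float] = (0.31, 0.31, 2.0)) -> list[dict]:
    """Write a cohort of phantoms, labels and manifest rows to ``out_dir``.

    Misaligned volumes are served with corrupted labels; their clean labels are
    additionally written as ``*_clean.nii.gz`` for oracle evaluation only.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol, served, clean in make_cohort(n_clean, n_misaligned, cfg, spec,
                                          seed, split, spacing):
        vid = vol.volume_id
        img_path = out_dir / f"{vid}_img.nii.gz"
        lab_path = out_dir / f"{vid}_lab.nii.gz"
        write_volume(img_path, vol)
        if served is not clean:
            write_mask(out_dir / f"{vid}_clean.nii.gz", clean, spacing)
        write_mask(lab_path, served, spacing)
        rows.append({
            "volume_id": vid,
            "image_path": img_path.name,
            "label_path": lab_path.name,
            "quality": served.quality.value,
            "split": split,
        })
    return rows


def write_benchmark(out_dir: str | Path, cfg: PhantomConfig,
                    spec: MisalignmentSpec | None = None, seed: int = 0,
                    n_train_clean: int = 12, n_train_misaligned: int = 12,
                    n_val: int = 6, n_test: int = 6) -> Path:
    """Write the full synthetic benchmark (train/val/test) and its manifest.

    Validation and test phantoms carry clean labels; the training split mixes
    clean and misaligned volumes.
    """
    out_dir = Path(out_dir)
    ss = np.random.SeedSequence(seed).spawn(3)
    rows = generate_dataset(out_dir, n_train_clean, n_train_misaligned, cfg, spec,
                            seed=int(ss[0].generate_state(1)[0] % (2 ** 31)), split="train")
    rows += generate_dataset(out_dir, n_val, 0, cfg, spec,
                             seed=int(ss[1].generate_state(1)[0] % (2 ** 31)), split="val")
    rows += generate_dataset(out_dir, n_test, 0, cfg, spec,
                             seed=int(ss[2].generate_state(1)[0] % (2 ** 31)), split="test")
    manifest = out_dir / "manifest.csv"
    write_manifest(manifest, rows)
    return manifest
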