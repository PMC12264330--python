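"""Volume containers, intensity normalization, label encoding and slice windowing.

Images are 4D arrays indexed ``(slice, row, col, channel)`` with seven contrast
channels per voxel (the seven SNAP-derived modalities).  Segmentations are
3-class one-hot arrays ``(slice, row, col, 3)`` with channel order
(lumen, vessel wall, background); on disk they are stored as compact integer
class maps (0=lumen, 1=wall, 2=background) in NIfTI files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

N_CHANNELS = 7
N_CLASSES = 3
WINDOW_LEN = 8

LUMEN, WALL, BACKGROUND = 0, 1, 2


class Quality(str, enum.Enum):
    """Registration quality of a manual segmentation."""

    WELL_REGISTERED = "well_registered"
    MISALIGNED = "misaligned"


class DegenerateInputError(ValueError):
    """Raised for inputs the pipeline cannot meaningfully process."""


@dataclass
class ImageVolume:
    """A 7-channel image volume with physical voxel spacing.

    ``data`` has shape ``(N, H, W, 7)``; ``voxel_spacing`` is
    (in-plane row mm, in-plane col mm, slice mm).
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[-1] != N_CHANNELS:
            raise ValueError(
                f"expected (N, H, W, {N_CHANNELS}) image data, got {self.data.shape}"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class LabelMask:
    """One-hot 3-class segmentation aligned to an :class:`ImageVolume`."""

    onehot: np.ndarray
    quality: Quality = Quality.WELL_REGISTERED

    def __post_init__(self) -> None:
        self.onehot = np.asarray(self.onehot)
        if self.onehot.ndim != 4 or self.onehot.shape[-1] != N_CLASSES:
            raise ValueError(
                f"expected (N, H, W, {N_CLASSES}) one-hot labels, got {self.onehot.shape}"
            )
        self.quality = Quality(self.quality)

    @property
    def class_map(self) -> np.ndarray:
        return np.argmax(self.onehot, axis=-1).astype(np.int8)

    def validate(self) -> None:
        vals = np.unique(self.onehot)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("one-hot entries must be 0 or 1")
        if not (self.onehot.sum(axis=-1) == 1).all():
            raise ValueError("exactly one channel must be set at every voxel")


@dataclass
class SliceWindow:
    """A contiguous run of exactly 8 slices of a volume (half-open interval)."""

    start_index: int
    data: np.ndarray
    label: np.ndarray | None = None
    quality: Quality = Quality.WELL_REGISTERED

    def __post_init__(self) -> None:
        if self.data.shape[0] != WINDOW_LEN:
            raise ValueError(f"window must hold {WINDOW_LEN} slices")


def normalize_volume(raw: ImageVolume) -> ImageVolume:
    """Standardize each channel to zero mean, unit variance over the volume.

    Uses the population standard deviation.  A constant channel is rejected:
    its contrast carries no information and division is undefined.
    """
    data = np.asarray(raw.data, dtype=np.float64)
    mean = data.mean(axis=(0, 1, 2), keepdims=True)
    sd = data.std(axis=(0, 1, 2), keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0].tolist()
        raise DegenerateInputError(f"channel(s) {bad} have zero variance")
    out = (data - mean) / sd
    return ImageVolume(out.astype(np.float32), raw.voxel_spacing, raw.volume_id)


def onehot_encode(class_map: np.ndarray, quality: Quality | str = Quality.WELL_REGISTERED) -> LabelMask:
    """Turn an integer class map with values {0,1,2} into a one-hot LabelMask."""
    class_map = np.asarray(class_map)
    if not np.isin(class_map, (LUMEN, WALL, BACKGROUND)).all():
        raise ValueError("class map values must be in {0, 1, 2}")
    onehot = np.eye(N_CLASSES, dtype=np.uint8)[class_map.astype(np.intp)]
    return LabelMask(onehot, Quality(quality))


def onehot_decode(label: LabelMask) -> np.ndarray:
    return label.class_map


def enumerate_windows(vol: ImageVolume, label: LabelMask | None = None,
                      *, permissive: bool = False) -> list[SliceWindow]:
    """Enumerate inference windows: the first and the last 8 slices.

    A volume of exactly 8 slices yields one window; otherwise the windows at
    starts 0 and N-8 together cover every slice, the middle slices once and
    (when N < 16) the overlap twice.  Volumes longer than 16 slices cannot be
    covered by that rule; by default they are rejected, with ``permissive``
    they are tiled at stride 8 plus a final flush window.
    """
    n = vol.n_slices
    if n < WINDOW_LEN:
        raise ValueError(f"volume has {n} slices; at least {WINDOW_LEN} required")
    if n == WINDOW_LEN:
        starts = [0]
    elif n <= 2 * WINDOW_LEN:
        starts = [0, n - WINDOW_LEN]
    elif permissive:
        starts = list(range(0, n - WINDOW_LEN, WINDOW_LEN))
        if starts[-1] != n - WINDOW_LEN:
            starts.append(n - WINDOW_LEN)
    else:
        raise ValueError(
            f"volume has {n} > 16 slices; two windows cannot cover it "
            "(pass permissive=True to tile with stride 8)"
        )
    out = []
    for s in starts:
        lab = label.onehot[s:s + WINDOW_LEN] if label is not None else None
        q = label.quality if label is not None else Quality.WELL_REGISTERED
        out.append(SliceWindow(s, vol.data[s:s + WINDOW_LEN], lab, q))
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O and dataset manifests
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # on-disk axis order is (row, col, slice[, channel])
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(path: str | Path, vol: ImageVolume) -> None:
    """Write a 7-channel volume as a 4D NIfTI (H x W x N x 7 on disk)."""
    arr = np.moveaxis(vol.data, 0, 2)  # (H, W, N, C)
    img = nib.Nifti1Image(arr.astype(np.float32), _affine(vol.voxel_spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, label_path: str | Path | None = None,
                quality: Quality | str = Quality.WELL_REGISTERED,
                volume_id: str = "") -> tuple[ImageVolume, LabelMask | None]:
    """Read a 7-channel NIfTI volume and, optionally, its label class map."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {arr.ndim}D")
    if arr.shape[-1] != N_CHANNELS:
        raise ValueError(
            f"{path}: expected {N_CHANNELS} channels, got {arr.shape[-1]}"
        )
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    vol = ImageVolume(np.moveaxis(arr, 2, 0), spacing, volume_id or Path(path).stem)
    label = read_mask(label_path, quality) if label_path is not None else None
    if label is not None and label.onehot.shape[:3] != vol.shape[:3]:
        raise ValueError(f"{label_path}: label shape does not match image")
    return vol, label


def write_mask(path: str | Path, label: LabelMask,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    """Write a LabelMask as a 3D integer class map NIfTI."""
    arr = np.moveaxis(label.class_map, 0, 2).astype(np.int8)
    img = nib.Nifti1Image(arr, _affine(spacing))
    img.header.set_intent("label")
    nib.save(img, str(path))


def read_mask(path: str | Path, quality: Quality | str = Quality.WELL_REGISTERED) -> LabelMask:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D class map, got {arr.ndim}D")
    return onehot_encode(np.moveaxis(arr, 2, 0), quality)


MANIFEST_COLUMNS = ["volume_id", "image_path", "label_path", "quality", "split"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV; paths are resolved relative to the CSV."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    root = Path(path).parent
    for col in ("image_path", "label_path"):
        df[col] = df[col].map(lambda p: str((root / p)) if not Path(p).is_absolute() else p)
    return df


def write_manifest(path: str | Path, rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + [c for c in (rows[0] if rows else {}) if c not in MANIFEST_COLUMNS])
    df.to_csv(path, index=False)
    return df
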