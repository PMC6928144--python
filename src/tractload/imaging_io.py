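"""Reading, writing and validating binary mask volumes in NIfTI format.

All volumes handled by this package are binary 3D masks on a shared voxel
grid: stroke lesion masks and the per-tract volumes of a corticospinal
sub-pathway template.  Registration and resampling are out of scope -- inputs
must already live on a common grid, and :func:`check_same_grid` verifies that
precondition.

Conventions
-----------
* Voxel values are {0, 1}; any strictly positive value read from disk is
  collapsed to 1 (with a logged warning, since probabilistic inputs lose
  information under binarization).
* After reading, volumes are reoriented to the closest-to-RAS canonical
  orientation, so the third array axis is the axial (z, inferior-superior)
  slice direction.  The slice-weighted lesion-load formula is defined per
  axial slice, so this convention makes the per-slice quantities well
  defined.
* Voxel indices are 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Tract labels of the sensorimotor template, by cortical origin.
TRACT_LABELS = ("M1", "PMD", "PMV", "SMA", "preSMA", "S1")

#: Label for the whole-tract union (all six sub-pathways OR-ed together).
UNION_LABEL = "SMATT"

HEMISPHERES = ("L", "R")

#: Absolute per-element tolerance for affine agreement between grids.
AFFINE_TOL = 1e-4


class MaskIOError(IOError):
    """Raised when a mask file cannot be read or written."""


class DimensionalityError(ValueError):
    """Raised when a volume does not have exactly 3 dimensions."""


class GridMismatchError(ValueError):
    """Raised when two volumes do not share shape and affine."""


class OrientationError(ValueError):
    """Raised when the left-right axis cannot be identified from the affine."""


@dataclass(frozen=True)
class MaskVolume:
    """A binary 3D volume with its voxel-to-world affine (mm).

    Parameters
    ----------
    data
        3D uint8 array with values in {0, 1}.
    affine
        4x4 invertible voxel-to-world transform.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"mask must be 3D, got {data.ndim} dimensions"
            )
        if any(s < 1 for s in data.shape):
            raise DimensionalityError(f"degenerate shape {data.shape}")
        uniq = np.unique(data)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError("mask voxels must be 0 or 1; use read_mask to binarize")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        """Number of set voxels."""
        return int(self.data.sum())

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)


@dataclass
class TractAtlas:
    """Named binary tract volumes on one shared grid, keyed by (label, hemisphere).

    The union tract ``SMATT`` per hemisphere is derived on demand as the
    voxelwise OR of the six sub-pathways.
    """

    tracts: dict[tuple[str, str], MaskVolume] = field(default_factory=dict)

    def __post_init__(self):
        for (label, hemi), vol in self.tracts.items():
            if hemi not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {hemi!r}")
            if label not in TRACT_LABELS:
                raise ValueError(f"unknown tract label {label!r}")
        vols = list(self.tracts.values())
        for v in vols[1:]:
            ok, report = check_same_grid(vols[0], v)
            if not ok:
                raise GridMismatchError(
                    "atlas members disagree on grid: " + "; ".join(report)
                )

    @property
    def grid(self) -> tuple[tuple[int, int, int], np.ndarray]:
        """Shared (shape, affine) of all members."""
        first = next(iter(self.tracts.values()))
        return first.shape, first.affine

    def hemispheres(self) -> list[str]:
        return sorted({h for (_, h) in self.tracts})

    def get(self, label: str, hemisphere: str) -> MaskVolume:
        """Return the mask for ``label`` on ``hemisphere``; ``SMATT`` is the union."""
        if label == UNION_LABEL:
            return self.union(hemisphere)
        return self.tracts[(label, hemisphere)]

    def union(self, hemisphere: str) -> MaskVolume:
        """Voxelwise OR of the six sub-pathways of one hemisphere."""
        members = [
            v for (lab, h), v in self.tracts.items() if h == hemisphere
        ]
        if not members:
            raise KeyError(f"no tracts for hemisphere {hemisphere!r}")
        data = np.zeros(members[0].shape, dtype=np.uint8)
        for m in members:
            data |= m.data
        return MaskVolume(data=data, affine=members[0].affine)


def read_mask(path: str | Path) -> MaskVolume:
    """Read a NIfTI file as a binary mask, reoriented closest-to-RAS.

    Strictly positive voxels become 1, zero or negative voxels become 0;
    if any non-{0,1} value is encountered the binarization is logged.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types
        raise MaskIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3D volume, got {img.ndim}D"
        )
    img = nib.as_closest_canonical(img)
    raw = np.asanyarray(img.dataobj)
    data = (raw > 0).astype(np.uint8)
    nonbinary = np.setdiff1d(np.unique(raw), [0, 1])
    if nonbinary.size:
        logger.warning(
            "%s: %d distinct non-binary values binarized (threshold: value > 0)",
            path, nonbinary.size,
        )
    return MaskVolume(data=data, affine=np.asarray(img.affine, dtype=float))


def write_mask(vol: MaskVolume, path: str | Path) -> Path:
    """Write a mask to NIfTI; round-trips losslessly through :func:`read_mask`."""
    path = Path(path)
    if not path.parent.is_dir():
        raise MaskIOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data.astype(np.uint8), vol.affine)
    try:
        nib.save(img, path)
    except Exception as exc:
        raise MaskIOError(f"cannot write {path}: {exc}") from exc
    return path


def check_same_grid(a: MaskVolume, b: MaskVolume) -> tuple[bool, list[str]]:
    """Check that two volumes share shape and affine (to ``AFFINE_TOL``).

    Returns ``(ok, report)`` where ``report`` lists every mismatch.  The
    check is symmetric in its arguments.
    """
    report: list[str] = []
    if a.shape != b.shape:
        report.append(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a.affine - b.affine)
    if (diff > AFFINE_TOL).any():
        for i, j in zip(*np.nonzero(diff > AFFINE_TOL)):
            report.append(
                f"affine[{i},{j}] differs: {a.affine[i, j]:g} vs "
                f"{b.affine[i, j]:g}"
            )
    return (not report), report


def _lr_axis(affine: np.ndarray) -> int:
    """Array axis most aligned with the world left-right (x) direction."""
    weights = np.abs(affine[0, :3])
    order = np.argsort(weights)[::-1]
    if weights[order[0]] < 1e-12 or (
        weights[order[1]] > 0.999 * weights[order[0]]
    ):
        raise OrientationError(
            "no dominant left-right axis in affine; cannot mirror"
        )
    return int(order[0])


def flip_lr(vol: MaskVolume) -> MaskVolume:
    """Mirror a mask about the midsagittal plane of its grid.

    The left-right array axis is identified from the affine.  Flipping is an
    involution and conserves the set-voxel count.  The affine is kept, i.e.
    the result lives on the same grid with the anatomy mirrored.
    """
    ax = _lr_axis(vol.affine)
    return MaskVolume(data=np.flip(vol.data, axis=ax).copy(), affine=vol.affine)


def load_atlas(source: str | Path | Mapping[tuple[str, str], str | Path]) -> TractAtlas:
    """Load a tract atlas from disk.

    Two on-disk dialects are accepted:

    * a directory containing one binary NIfTI per tract, named
      ``<label>_<hemisphere>.nii[.gz]`` (e.g. ``PMD_L.nii.gz``);
    * a single integer-labelled NIfTI plus a JSON sidecar mapping string
      integer codes to ``"<label>_<hemisphere>"`` names, passed as the path
      of the labelled volume (sidecar: same stem + ``.labels.json``).

    A mapping ``{(label, hemi): path}`` is also accepted directly.
    """
    if isinstance(source, Mapping):
        return TractAtlas(
            tracts={key: read_mask(p) for key, p in source.items()}
        )
    source = Path(source)
    if source.is_dir():
        tracts: dict[tuple[str, str], MaskVolume] = {}
        for p in sorted(source.iterdir()):
            name = p.name
            if not (name.endswith(".nii") or name.endswith(".nii.gz")):
                continue
            stem = name[: -len(".nii.gz")] if name.endswith(".nii.gz") else p.stem
            parts = stem.rsplit("_", 1)
            if len(parts) != 2 or parts[1] not in HEMISPHERES:
                continue
            label, hemi = parts
            if label in TRACT_LABELS:
                tracts[(label, hemi)] = read_mask(p)
        if not tracts:
            raise MaskIOError(f"no tract files found in {source}")
        return TractAtlas(tracts=tracts)
    # single labelled volume + JSON sidecar
    name = source.name
    stem = name[: -len(".nii.gz")] if name.endswith(".nii.gz") else source.stem
    sidecar = source.with_name(stem + ".labels.json")
    if not sidecar.exists():
        raise MaskIOError(f"label-map sidecar not found: {sidecar}")
    label_map = json.loads(sidecar.read_text())
    img = nib.as_closest_canonical(nib.load(source))
    codes = np.asanyarray(img.dataobj).astype(int)
    affine = np.asarray(img.affine, dtype=float)
    tracts = {}
    for code_str, tract_name in label_map.items():
        label, hemi = tract_name.rsplit("_", 1)
        data = (codes == int(code_str)).astype(np.uint8)
        tracts[(label, hemi)] = MaskVolume(data=data, affine=affine)
    return TractAtlas(tracts=tracts)


def save_atlas(atlas: TractAtlas, directory: str | Path) -> list[Path]:
    """Write an atlas as one binary NIfTI per tract into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for (label, hemi), vol in atlas.tracts.items():
        paths.append(write_mask(vol, directory / f"{label}_{hemi}.nii.gz"))
    return paths
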