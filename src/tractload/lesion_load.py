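"""Slice-weighted lesion load within corticospinal tract sub-pathways.

The corticospinal tract narrows as it descends from the sensorimotor cortex
toward the posterior limb of the internal capsule, so a raw lesion-tract
overlap count under-weights damage at levels where the tract is thin even
though a small lesion there can transect the whole pathway.  The weighted
lesion load corrects for this by scaling the lesioned voxels of each axial
slice by the inverse of the tract's relative slice area:

    w-X-LL = sum_x  n(x) * m(x*) / m(x)

where, for tract X, ``n(x)`` is the number of lesion voxels inside the tract
on axial slice ``x``, ``m(x)`` is the tract's area (voxels) on that slice,
and ``m(x*)`` is the tract's largest slice area.  Slices where the tract is
absent contribute nothing (``n(x)`` is defined on the tract's own support),
so no division by zero can arise.  The result is a dimensionless count of
"weighted voxels"; it equals the raw overlap when the tract has constant
slice area and exceeds it otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_io import (
    GridMismatchError,
    MaskVolume,
    TractAtlas,
    TRACT_LABELS,
    UNION_LABEL,
    check_same_grid,
    flip_lr,
)

logger = logging.getLogger(__name__)

#: Tracts reported per subject: the whole-tract union plus the six sub-pathways.
REPORTED_TRACTS = (UNION_LABEL,) + TRACT_LABELS

HEMISPHERE_POLICIES = ("ipsilesional", "flip-to-canonical")


class EmptyTractError(ValueError):
    """Raised when an operation requires a non-empty tract mask."""


class HemispherePolicyError(ValueError):
    """Raised when the affected hemisphere needed by the policy is unknown."""


@dataclass(frozen=True)
class SliceProfile:
    """Per-axial-slice area profile of a tract.

    Attributes
    ----------
    label
        Tract label.
    m
        Area (set-voxel count) per z-slice, full-grid length.
    m_star
        Largest slice area, ``max(m)``.
    z_support
        Indices of slices with ``m > 0``.
    """

    label: str
    m: np.ndarray
    m_star: int
    z_support: np.ndarray


@dataclass(frozen=True)
class LesionLoadRecord:
    """Lesion load of one subject within one tract."""

    subject_id: str
    tract: str
    hemisphere_used: str
    n_by_slice: np.ndarray
    raw_overlap: int
    weighted_ll: float


def slice_profile(tract: MaskVolume, label: str = "") -> SliceProfile:
    """Compute the axial slice-area profile ``m(x)`` and its maximum ``m(x*)``."""
    m = tract.data.sum(axis=(0, 1)).astype(np.int64)
    m_star = int(m.max(initial=0))
    if m_star == 0:
        raise EmptyTractError(f"tract {label or '<unnamed>'} is empty")
    return SliceProfile(
        label=label, m=m, m_star=m_star, z_support=np.nonzero(m)[0]
    )


def weighted_lesion_load(
    lesion: MaskVolume,
    tract: MaskVolume,
    *,
    subject_id: str = "",
    tract_label: str = "",
    hemisphere_used: str = "",
) -> LesionLoadRecord:
    """Weighted lesion load of ``lesion`` within ``tract``.

    Both masks must live on the same grid.  Per axial slice, the number of
    lesion voxels inside the tract is multiplied by the ratio of the tract's
    largest slice area to its area on that slice; the weighted slice lesions
    are summed over the tract's support.
    """
    ok, report = check_same_grid(lesion, tract)
    if not ok:
        raise GridMismatchError("; ".join(report))
    prof = slice_profile(tract, label=tract_label)
    n = (lesion.data & tract.data).sum(axis=(0, 1)).astype(np.int64)
    support = prof.m > 0
    weights = np.zeros_like(prof.m, dtype=float)
    weights[support] = prof.m_star / prof.m[support]
    weighted = float((n[support] * weights[support]).sum())
    return LesionLoadRecord(
        subject_id=subject_id,
        tract=tract_label,
        hemisphere_used=hemisphere_used,
        n_by_slice=n,
        raw_overlap=int(n.sum()),
        weighted_ll=weighted,
    )


def lesion_load_table(
    lesions: dict[str, MaskVolume],
    atlas: TractAtlas,
    affected_hemisphere: dict[str, str] | None = None,
    policy: str = "ipsilesional",
    canonical_hemisphere: str = "L",
) -> pd.DataFrame:
    """Score every subject against every reported tract.

    Parameters
    ----------
    lesions
        Mapping subject id -> lesion mask (all on the atlas grid).
    atlas
        The tract template.
    affected_hemisphere
        Mapping subject id -> "L"/"R".  Required by both policies (it names
        the tract hemisphere to score, or the side to mirror from).
    policy
        ``"ipsilesional"`` scores each lesion against the tracts of the
        subject's affected hemisphere.  ``"flip-to-canonical"`` mirrors
        lesions of the non-canonical hemisphere onto ``canonical_hemisphere``
        and scores everyone against that single template side.
    Returns
    -------
    Long-format DataFrame with one row per subject x tract:
    ``subject_id, tract, hemisphere_used, raw_overlap_voxels, weighted_ll``.
    """
    if policy not in HEMISPHERE_POLICIES:
        raise ValueError(f"unknown hemisphere policy {policy!r}")
    affected_hemisphere = affected_hemisphere or {}
    rows = []
    for sid, lesion in lesions.items():
        hemi = affected_hemisphere.get(sid)
        if hemi not in ("L", "R"):
            raise HemispherePolicyError(
                f"subject {sid!r}: affected hemisphere unknown; required by "
                f"policy {policy!r}"
            )
        if policy == "ipsilesional":
            score_hemi, score_lesion = hemi, lesion
        else:
            score_hemi = canonical_hemisphere
            score_lesion = lesion if hemi == canonical_hemisphere else flip_lr(lesion)
        for tract_label in REPORTED_TRACTS:
            rec = weighted_lesion_load(
                score_lesion,
                atlas.get(tract_label, score_hemi),
                subject_id=sid,
                tract_label=tract_label,
                hemisphere_used=score_hemi,
            )
            rows.append(
                {
                    "subject_id": sid,
                    "tract": tract_label,
                    "hemisphere_used": score_hemi,
                    "raw_overlap_voxels": rec.raw_overlap,
                    "weighted_ll": rec.weighted_ll,
                }
            )
    return pd.DataFrame(rows)


def lesion_load_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long lesion-load table to one ``w-<TRACT>-LL`` column per tract."""
    wide = table.pivot(index="subject_id", columns="tract", values="weighted_ll")
    wide = wide[[t for t in REPORTED_TRACTS if t in wide.columns]]
    wide.columns = [f"w-{t}-LL" for t in wide.columns]
    return wide.reset_index()


def lesion_overlay_map(lesions: list[MaskVolume]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise sum of binary lesion masks (the lesion-frequency overlay map).

    Returns ``(counts, affine)``; the maximum count is at most the number of
    subjects.
    """
    if not lesions:
        raise ValueError("no lesions supplied")
    first = lesions[0]
    total = np.zeros(first.shape, dtype=np.int32)
    for les in lesions:
        ok, report = check_same_grid(first, les)
        if not ok:
            raise GridMismatchError("; ".join(report))
        total += les.data
    return total, first.affine
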