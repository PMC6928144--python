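"""Synthetic tract templates, lesions, and clinical cohorts.

No public dataset accompanies the analysis this package implements, so this
module generates inputs with the statistical structure the pipeline assumes:

* tube-like corticospinal sub-pathway masks that narrow as they descend from
  the cortical mantle toward the internal capsule (so slice-weighting is
  non-trivial), with residual overlap between adjacent tracts;
* ellipsoidal ischemic lesions of varying size and position, concentrated in
  the deep middle-cerebral-artery territory where the sub-pathways run;
* a cohort in which the six-month upper-limb Fugl-Meyer score (FM-UE, integer
  0-66) is a linear function of the one-week FM-UE, the weighted premotor
  dorsal (PMD) lesion load, and an age>=70 indicator, plus Gaussian noise,
  rounded to the integer scale and clamped to [0, 66].

Every draw comes from a seeded generator; subject ``i`` uses a substream
keyed by ``(seed, i)`` so that subject-level data are reproducible
independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import MaskVolume, TractAtlas, TRACT_LABELS, UNION_LABEL
from .lesion_load import REPORTED_TRACTS, slice_profile

#: Default simulation grid: 64x64x40 voxels, 2 mm isotropic, RAS affine.
DEFAULT_SHAPE = (64, 64, 40)


def default_affine(shape: Sequence[int] = DEFAULT_SHAPE, voxel_mm: float = 2.0) -> np.ndarray:
    """RAS affine centring the grid on the world origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    return aff


class GeometryError(ValueError):
    """Raised when a synthetic shape does not fit inside the grid."""


@dataclass(frozen=True)
class TractSpec:
    """Geometric description of one synthetic tract.

    The tract occupies contiguous axial slices ``z_min..z_max`` (inclusive);
    on slice ``z`` it is the filled disc of radius ``radius_profile[z-z_min]``
    centred at ``centerline[z-z_min]`` (in-plane voxel coordinates).  Radii
    decrease from the cortical (top) slices toward the capsular (bottom)
    slices, emulating the narrowing of the descending pyramidal pathway.
    """

    label: str
    hemisphere: str
    z_min: int
    centerline: tuple[tuple[float, float], ...]
    radius_profile: tuple[float, ...]

    def __post_init__(self):
        if len(self.centerline) != len(self.radius_profile):
            raise ValueError("centerline and radius_profile lengths differ")
        if not self.radius_profile or min(self.radius_profile) <= 0:
            raise ValueError("radius_profile must be strictly positive")

    @property
    def z_max(self) -> int:
        return self.z_min + len(self.radius_profile) - 1


# Cortical origin (x offset from midline, y) and capsule convergence point per
# tract.  y grows anterior: preSMA most anterior, S1 most posterior; PMD/PMV
# lateral premotor, SMA/preSMA medial.
_CORTICAL_SEED = {
    "preSMA": (6.0, 44.0),
    "SMA": (8.0, 40.0),
    "PMD": (16.0, 38.0),
    "PMV": (20.0, 34.0),
    "M1": (18.0, 30.0),
    "S1": (18.0, 26.0),
}
_CAPSULE_OFFSET = (10.0, 31.0)  # (x offset from midline, y)


def default_tract_specs(
    shape: Sequence[int] = DEFAULT_SHAPE,
    hemispheres: Sequence[str] = ("L", "R"),
    z_min: int = 8,
    z_max: int = 35,
    r_top: float = 4.5,
    r_bottom: float = 2.0,
) -> list[TractSpec]:
    """Six-per-hemisphere tract geometry for the default grid.

    Centerlines run linearly from a cortical seed on the top slice to a
    shared capsular point on the bottom slice; radii shrink linearly from
    ``r_top`` to ``r_bottom``, so slice areas decrease toward the capsule
    and adjacent tracts overlap near their convergence point.
    """
    midline = (shape[0] - 1) / 2.0
    nz = z_max - z_min + 1
    specs = []
    for hemi in hemispheres:
        sign = -1.0 if hemi == "L" else 1.0
        cap_x = midline + sign * _CAPSULE_OFFSET[0]
        cap_y = _CAPSULE_OFFSET[1]
        for label in TRACT_LABELS:
            dx, cy = _CORTICAL_SEED[label]
            cort_x = midline + sign * dx
            # slice index 0 = z_min (capsule), last = z_max (cortex)
            frac = np.linspace(0.0, 1.0, nz)  # 0 at capsule, 1 at cortex
            xs = cap_x + (cort_x - cap_x) * frac
            ys = cap_y + (cy - cap_y) * frac
            radii = r_bottom + (r_top - r_bottom) * frac
            specs.append(
                TractSpec(
                    label=label,
                    hemisphere=hemi,
                    z_min=z_min,
                    centerline=tuple(zip(xs.tolist(), ys.tolist())),
                    radius_profile=tuple(radii.tolist()),
                )
            )
    return specs


def _fill_disc(plane: np.ndarray, cx: float, cy: float, r: float) -> None:
    nx, ny = plane.shape
    if cx - r < -0.5 or cx + r > nx - 0.5 or cy - r < -0.5 or cy + r > ny - 0.5:
        raise GeometryError(
            f"disc (center=({cx:.1f},{cy:.1f}), r={r:.1f}) exceeds grid "
            f"bounds {nx}x{ny}"
        )
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    plane[(x - cx) ** 2 + (y - cy) ** 2 <= r**2] = 1


def make_tract_template(
    specs: Sequence[TractSpec],
    shape: Sequence[int] = DEFAULT_SHAPE,
    affine: np.ndarray | None = None,
) -> TractAtlas:
    """Rasterize tract specs into a binary atlas (union of per-slice discs)."""
    if affine is None:
        affine = default_affine(shape)
    tracts = {}
    for spec in specs:
        if spec.z_min < 0 or spec.z_max >= shape[2]:
            raise GeometryError(
                f"{spec.label}_{spec.hemisphere}: z-support "
                f"[{spec.z_min},{spec.z_max}] outside grid depth {shape[2]}"
            )
        data = np.zeros(shape, dtype=np.uint8)
        for i, ((cx, cy), r) in enumerate(zip(spec.centerline, spec.radius_profile)):
            _fill_disc(data[:, :, spec.z_min + i], cx, cy, r)
        tracts[(spec.label, spec.hemisphere)] = MaskVolume(data=data, affine=affine)
    return TractAtlas(tracts=tracts)


def make_lesion(
    center: Sequence[float],
    radii: Sequence[float],
    shape: Sequence[int] = DEFAULT_SHAPE,
    affine: np.ndarray | None = None,
) -> MaskVolume:
    """Ellipsoidal lesion: voxels with sum(((v-c)/r)^2) <= 1, clipped to the grid."""
    if affine is None:
        affine = default_affine(shape)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError(f"radii must be positive, got {radii.tolist()}")
    center = np.asarray(center, dtype=float)
    data = np.zeros(shape, dtype=np.uint8)
    lo = np.maximum(np.floor(center - radii).astype(int), 0)
    hi = np.minimum(np.ceil(center + radii).astype(int) + 1, shape)
    if (lo >= hi).any():
        return MaskVolume(data=data, affine=affine)
    xs = np.arange(lo[0], hi[0])[:, None, None]
    ys = np.arange(lo[1], hi[1])[None, :, None]
    zs = np.arange(lo[2], hi[2])[None, None, :]
    d2 = (
        ((xs - center[0]) / radii[0]) ** 2
        + ((ys - center[1]) / radii[1]) ** 2
        + ((zs - center[2]) / radii[2]) ** 2
    )
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= 1.0
    return MaskVolume(data=data, affine=affine)


@dataclass
class CohortParams:
    """Generative parameters of the synthetic clinical cohort.

    The six-month outcome is
    ``fmue_m6 = beta0 + beta_fm*fmue_wk1 + beta_ll*wPMDLL + beta_age*1[age>=age_cut] + eps``
    with ``eps ~ N(0, sigma_noise^2)``, rounded to integers and clamped to
    the 0-66 instrument range.  Defaults are sized so the three effects are
    clearly separated on the standardized scale (initial impairment
    strongest, lesion load intermediate, the age step smallest) and so the
    linear predictor stays about three noise SDs inside the instrument
    range, keeping clamping a rare edge effect rather than a source of
    bias.
    """

    n_subjects: int = 27
    beta0: float = 27.0
    beta_fm: float = 0.45
    beta_ll: float = -0.05
    beta_age: float = -3.5
    sigma_noise: float = 3.0
    age_cut: float = 70.0
    age_mean: float = 68.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (30.0, 95.0)
    p_right_hemisphere: float = 0.7
    lesion_center_sd: tuple[float, float] = (4.0, 5.0)
    lesion_center_x_offset: float = 16.0
    lesion_z_range: tuple[int, int] = (8, 34)
    lesion_radius_range: tuple[float, float] = (2.0, 5.0)
    fmue1_beta_shape: tuple[float, float] = (0.6, 0.8)
    clamp: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def simulate_cohort(
    params: CohortParams,
    atlas: TractAtlas,
) -> tuple[pd.DataFrame, dict[str, MaskVolume], dict]:
    """Simulate a cohort of lesioned subjects against ``atlas``.

    Returns ``(cohort, lesions, truth)``: the cohort table (one row per
    subject with clinical variables and one ``w-<TRACT>-LL`` column per
    reported tract), the per-subject lesion masks, and a sidecar dict with
    the generating coefficients.  Lesion loads in the table are computed with
    the package's own slice-weighted scorer against the supplied atlas, so
    the stored ``w-PMD-LL`` used in the outcome equation is exactly what the
    analysis stage will recompute from the emitted masks.
    """
    shape, affine = atlas.grid
    midline = (shape[0] - 1) / 2.0
    hemis = atlas.hemispheres()

    # Pre-stack tract data and slice profiles per hemisphere for speed.
    stacks: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    for h in hemis:
        vols = [atlas.get(t, h) for t in REPORTED_TRACTS]
        stacks[h] = np.stack([v.data for v in vols])
        w = np.zeros((len(vols), shape[2]))
        for k, v in enumerate(vols):
            prof = slice_profile(v, label=REPORTED_TRACTS[k])
            sup = prof.m > 0
            w[k, sup] = prof.m_star / prof.m[sup]
        weights[h] = w

    rows = []
    lesions: dict[str, MaskVolume] = {}
    for i in range(params.n_subjects):
        rng = np.random.default_rng([params.seed, i])
        sid = f"sub-{i + 1:03d}"
        age = _truncated_normal(rng, params.age_mean, params.age_sd,
                                *params.age_range)
        age_ge = int(age >= params.age_cut)
        hemi = "R" if rng.random() < params.p_right_hemisphere else "L"
        if hemi not in hemis:  # single-hemisphere atlas
            hemi = hemis[0]
        sign = 1.0 if hemi == "R" else -1.0
        cx = rng.normal(midline + sign * params.lesion_center_x_offset,
                        params.lesion_center_sd[0])
        cy = rng.normal(midline, params.lesion_center_sd[1])
        cz = rng.uniform(*params.lesion_z_range)
        radii = rng.uniform(*params.lesion_radius_range, size=3)
        lesion = make_lesion((cx, cy, cz), radii, shape, affine)
        lesions[sid] = lesion

        n_by_slice = (stacks[hemi] & lesion.data).sum(axis=(1, 2))
        wll = (n_by_slice * weights[hemi]).sum(axis=1)
        loads = dict(zip(REPORTED_TRACTS, wll.astype(float)))

        fmue1 = int(round(66 * rng.beta(*params.fmue1_beta_shape)))
        nihss = int(rng.poisson(9))
        eps = rng.normal(0.0, params.sigma_noise) if params.sigma_noise > 0 else 0.0
        m6 = (
            params.beta0
            + params.beta_fm * fmue1
            + params.beta_ll * loads["PMD"]
            + params.beta_age * age_ge
            + eps
        )
        m6 = int(round(m6))
        if params.clamp:
            m6 = int(np.clip(m6, 0, 66))
        row = {
            "subject_id": sid,
            "age": round(age, 1),
            "age_ge70": age_ge,
            "fmue_wk1": fmue1,
            "fmue_m6": m6,
            "nihss": nihss,
            "hemisphere": hemi,
        }
        row.update({f"w-{t}-LL": loads[t] for t in REPORTED_TRACTS})
        rows.append(row)

    cohort = pd.DataFrame(rows)
    truth = {
        "model": "fmue_m6 ~ beta0 + beta_fm*fmue_wk1 + beta_ll*w-PMD-LL"
                 " + beta_age*1[age>=age_cut] + N(0, sigma_noise^2)",
        "params": asdict(params),
    }
    if cohort["fmue_wk1"].nunique() <= 1 or cohort["w-PMD-LL"].nunique() <= 1:
        import warnings

        warnings.warn("degenerate cohort: a generative predictor is constant",
                      stacklevel=2)
    return cohort, lesions, truth
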