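"""End-to-end orchestration: lesion load -> associations -> dominance -> model.

A single :class:`RunConfig` drives the whole analysis with a fixed seed;
rerunning with the same config and seed reproduces every numeric output
byte for byte.  Each stage writes its tables under the output directory and
a run manifest records the config echo, package version, seed and warnings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix, matrix_pivot, univariate_table
from .dominance import (
    all_subsets_r2,
    bootstrap_reproducibility,
    conditional_table,
    dominance_stats,
)
from .imaging_io import MaskVolume, TractAtlas, load_atlas, read_mask, save_atlas
from .lesion_load import (
    REPORTED_TRACTS,
    lesion_load_table,
    lesion_load_wide,
    lesion_overlay_map,
)
from .prediction import (
    bootstrap_coefficients,
    diagnostics,
    dichotomize_age,
    squared_semipartial,
    stepwise_regression,
)
from .synthetic import (
    CohortParams,
    default_tract_specs,
    make_tract_template,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

LOAD_COLUMNS = [f"w-{t}-LL" for t in REPORTED_TRACTS]


class ConfigError(ValueError):
    """Raised when a run configuration is invalid or incomplete."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    In synthetic mode the template, lesions and cohort are generated from
    ``seed``; otherwise ``template_path``, ``lesions_dir`` and
    ``cohort_path`` must point at existing inputs on a shared grid.
    """

    output_dir: str = "tractload-run"
    synthetic: bool = True
    n_subjects: int = 27
    template_path: str | None = None
    lesions_dir: str | None = None
    cohort_path: str | None = None
    hemisphere_policy: str = "ipsilesional"
    age_cut: float = 70.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    dominance_bootstrap: int = 1000
    coefficient_bootstrap: int = 1000
    seed: int = 0
    munro_bands: list | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("template_path", "lesions_dir", "cohort_path"):
                if getattr(self, name) is None:
                    raise ConfigError(
                        f"non-synthetic mode requires config field {name!r}"
                    )
        if (self.dominance_bootstrap > 0 or self.coefficient_bootstrap > 0) \
                and self.seed is None:
            raise ConfigError("seed required whenever bootstrapping is enabled")
        if self.p_enter >= self.p_remove:
            raise ConfigError("p_enter must be < p_remove")


def make_demo_dataset(seed: int, output_dir: str | Path,
                      n_subjects: int = 27) -> dict:
    """Emit a complete synthetic dataset: template, lesions, cohort, truth.

    Writes one binary NIfTI per tract, one lesion NIfTI per subject, the
    cohort CSV, and a JSON sidecar with the generating coefficients.
    Defaults to a 27-subject cohort, the size of the motivating study.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    atlas = make_tract_template(default_tract_specs())
    params = CohortParams(n_subjects=n_subjects, seed=seed)
    cohort, lesions, truth = simulate_cohort(params, atlas)

    template_dir = output_dir / "template"
    save_atlas(atlas, template_dir)
    lesions_dir = output_dir / "lesions"
    lesions_dir.mkdir(exist_ok=True)
    from .imaging_io import write_mask

    for sid, vol in lesions.items():
        write_mask(vol, lesions_dir / f"{sid}_lesion.nii.gz")
    cohort_path = output_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    (output_dir / "generative_params.json").write_text(
        json.dumps(truth, indent=2)
    )
    return {
        "template_dir": str(template_dir),
        "lesions_dir": str(lesions_dir),
        "cohort_path": str(cohort_path),
        "n_subjects": n_subjects,
    }


def _load_inputs(config: RunConfig):
    if config.synthetic:
        atlas = make_tract_template(default_tract_specs())
        params = CohortParams(n_subjects=config.n_subjects,
                              age_cut=config.age_cut, seed=config.seed)
        cohort, lesions, truth = simulate_cohort(params, atlas)
        return atlas, lesions, cohort.drop(columns=LOAD_COLUMNS)
    atlas = load_atlas(config.template_path)
    cohort = pd.read_csv(config.cohort_path)
    if "subject_id" not in cohort.columns:
        raise ConfigError("cohort table must have a subject_id column")
    lesions = {}
    lesions_dir = Path(config.lesions_dir)
    for sid in cohort["subject_id"]:
        matches = sorted(lesions_dir.glob(f"{sid}*.nii*"))
        if not matches:
            raise ConfigError(f"no lesion file for subject {sid!r} in "
                              f"{lesions_dir}")
        lesions[sid] = read_mask(matches[0])
    return atlas, lesions, cohort


def run_full(config: RunConfig) -> dict:
    """Execute the complete analysis; returns a manifest of written artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)

    # ---- lesion load -------------------------------------------------
    stage("lesion_load")
    atlas, lesions, clinical = _load_inputs(config)
    hemi_map = dict(zip(clinical["subject_id"], clinical["hemisphere"]))
    long = lesion_load_table(lesions, atlas, hemi_map,
                             policy=config.hemisphere_policy)
    wide = lesion_load_wide(long)
    cohort = clinical.merge(wide, on="subject_id", validate="1:1")
    long.to_csv(out / "lesion_loads_long.csv", index=False)
    wide.to_csv(out / "lesion_loads_wide.csv", index=False)
    cohort.to_csv(out / "cohort_with_loads.csv", index=False)
    overlay, affine = lesion_overlay_map(list(lesions.values()))
    nib.save(nib.Nifti1Image(overlay.astype(np.int16), affine),
             out / "lesion_overlay.nii.gz")

    # ---- association statistics -------------------------------------
    stage("association_stats")
    if "age_ge70" not in cohort.columns:
        cohort["age_ge70"] = dichotomize_age(
            cohort["age"].to_numpy(), cut=config.age_cut
        )
    usable = [c for c in LOAD_COLUMNS if cohort[c].nunique() > 1]
    dropped = sorted(set(LOAD_COLUMNS) - set(usable))
    if dropped:
        msg = (f"constant lesion-load predictors excluded from regression "
               f"stages: {dropped}")
        logger.warning(msg)
        warnings_log.append(msg)
    corr_vars = ["fmue_wk1"] + LOAD_COLUMNS
    tidy = correlation_matrix(cohort, corr_vars)
    tidy.to_csv(out / "correlations_tidy.csv", index=False)
    matrix_pivot(tidy, "rho").to_csv(out / "correlations_rho.csv")
    matrix_pivot(tidy, "p_value").to_csv(out / "correlations_p.csv")
    uni = univariate_table(cohort, usable, "fmue_m6")
    uni.to_csv(out / "univariate_regressions.csv", index=False)

    # ---- dominance analysis -----------------------------------------
    stage("dominance")
    Ximg = cohort[usable]
    y = cohort["fmue_m6"].to_numpy(dtype=float)
    r2map = all_subsets_r2(Ximg, y)
    dstats = dominance_stats(r2map)
    conditional_table(dstats).to_csv(out / "dominance_conditional.csv",
                                     index=False)
    pd.DataFrame(
        [{"predictor_1": a, "predictor_2": b, "level": lv or "none"}
         for (a, b), lv in dstats.pairwise.items()]
    ).to_csv(out / "dominance_matrix.csv", index=False)
    pd.DataFrame(
        {"predictor": list(dstats.general),
         "general_weight": list(dstats.general.values())}
    ).to_csv(out / "dominance_general_weights.csv", index=False)
    repro = bootstrap_reproducibility(
        Ximg, y, B=config.dominance_bootstrap, seed=config.seed
    )
    repro.to_csv(out / "dominance_reproducibility.csv", index=False)

    # the neuroimaging predictor with the largest general weight enters the
    # multivariable model
    dominant = max(dstats.general, key=dstats.general.get)

    # ---- prediction model -------------------------------------------
    stage("prediction_model")
    candidates = pd.DataFrame({
        "fmue_wk1": cohort["fmue_wk1"].to_numpy(dtype=float),
        dominant: cohort[dominant].to_numpy(dtype=float),
        "age_ge70": cohort["age_ge70"].to_numpy(dtype=float),
    })
    sw = stepwise_regression(candidates, y, p_enter=config.p_enter,
                             p_remove=config.p_remove)
    sw.steps.to_csv(out / "stepwise_steps.csv", index=False)
    if sw.model is not None:
        sw.coefficients.to_csv(out / "stepwise_coefficients.csv")
        Xsel = candidates[sw.selected]
        report = diagnostics(sw.model, Xsel, y)
        report.bootstrap_cis = bootstrap_coefficients(
            Xsel, y, B=max(config.coefficient_bootstrap, 100),
            seed=config.seed + 1,
        )
        semi = {p: squared_semipartial(Xsel, p, y) for p in sw.selected}
        diag = report.to_dict()
        diag["squared_semipartial"] = semi
        (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))
        report.homoscedasticity_points.to_csv(
            out / "residual_plot_points.csv", index=False
        )
    else:
        warnings_log.append("stepwise model empty: " + sw.status)

    # Fig-4-shaped scatter data: dominant load vs outcome, grouped by age
    pd.DataFrame({
        dominant: cohort[dominant],
        "fmue_m6": cohort["fmue_m6"],
        "age_group": np.where(cohort["age_ge70"] == 1, ">=70", "<70"),
    }).to_csv(out / "outcome_by_load_age.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "dominant_predictor": dominant,
        "selected_predictors": sw.selected,
        "full_model_r_squared": sw.r_squared,
        "warnings": warnings_log,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
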