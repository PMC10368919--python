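"""Self-contained simulation studies built on the synthetic scene generator.

Three reusable experiments, each deterministic given a seed:

* deviation-score calibration — patient-like maps drawn from a prediction's
  own mean and uncertainty should score 1;
* family-wise error of the max-T permutation test under a global null;
* internal/external reliability as a function of lesion size, the desk-scale
  analogue of plotting reliability against lesion volume in a patient cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SelectionMode, aggregate_prediction, select_damaged, visitation_map
from .io import VolumeGrid
from .lsm import GroupDesign, gaussian_smooth, permutation_ttest
from .reliability import (
    UndefinedCorrelationError,
    external_reliability,
    fisher_mean,
    internal_reliability,
)
from .synth import (
    BundleSpec,
    DatabaseSpec,
    calibration_mask,
    default_grid,
    make_brain_mask,
    make_database,
    make_lesion,
    make_patient_like_map,
    make_patient_tractogram,
    predict_from_scene,
    two_bundle_scene,
)

__all__ = [
    "deviation_calibration",
    "null_fwe_rate",
    "lesion_size_curves",
    "LesionSizeResult",
]


def deviation_calibration(seed: int = 0, n_replicates: int = 100, n_subjects: int = 30,
                          noise_scale: float = 1.0) -> dict:
    """Mean deviation-score of patient-like maps drawn from the prediction.

    Builds the standard two-bundle scene, runs the full prediction pipeline,
    then draws ``n_replicates`` synthetic patients from the prediction's own
    mean and total deviation and scores each against it. Scoring is
    restricted to voxels where the mean sits well above zero in units of
    the predicted deviation, so the nonnegativity truncation of count maps
    cannot bias the calibration. The theoretical value is ``noise_scale``
    (1 by default).
    """
    from .reliability import deviation_score

    scene = two_bundle_scene(n_subjects=n_subjects, seed=seed)
    pred = predict_from_scene(scene)
    cal = calibration_mask(pred, scene["brain_mask"])
    rng = np.random.SeedSequence([seed, 1]).generate_state(n_replicates)
    scores = [
        deviation_score(pred, make_patient_like_map(pred, noise_scale, int(s)),
                        cal, scene["lesion"]).score
        for s in rng
    ]
    return {
        "mean_score": float(np.mean(scores)),
        "sd_score": float(np.std(scores)),
        "scores": scores,
        "n_voxels": int(cal.data.sum()),
        "n_replicates": n_replicates,
    }


def null_fwe_rate(seed: int = 0, n_simulations: int = 200, n_per_group: int = 10,
                  grid_n: int = 20, n_permutations: int = 1000,
                  alpha: float = 0.05, fwhm_mm: float = 4.0) -> dict:
    """Empirical family-wise error rate of the max-T permutation test.

    Each simulation draws two groups of smoothed Gaussian-noise maps from
    one distribution (a global null), runs the one-sided permutation test,
    and records whether any voxel reached FWE significance. The returned
    rate estimates P(any false positive), which the max-statistic
    construction controls at ``alpha``.
    """
    grid = default_grid(grid_n, 2.0)
    brain = grid.like(np.ones(grid.shape, dtype=bool))
    ss = np.random.SeedSequence([seed, 2])
    sim_seeds = ss.generate_state(2 * n_simulations).reshape(n_simulations, 2)
    n_any = 0
    for k in range(n_simulations):
        rng = np.random.default_rng(sim_seeds[k, 0])
        maps = [
            gaussian_smooth(grid.like(rng.standard_normal(grid.shape)), fwhm_mm)
            for _ in range(2 * n_per_group)
        ]
        labels = np.array([1] * n_per_group + [0] * n_per_group)
        design = GroupDesign(maps=maps, labels=labels,
                             n_permutations_max=n_permutations, alpha=alpha,
                             seed=int(sim_seeds[k, 1]))
        res = permutation_ttest(design, brain)
        if res.significant_mask.data.any():
            n_any += 1
    return {
        "fwe_rate": n_any / n_simulations,
        "n_simulations": n_simulations,
        "n_any_significant": n_any,
        "alpha": alpha,
    }


@dataclass
class LesionSizeResult:
    radii_mm: list
    lesion_volumes_ml: list
    internal_mean: list
    external_mean: list


def _size_scene_bundles(n_streamlines: int, jitter_sd_mm: float):
    extent = 26.0
    a = BundleSpec([[-8.0, -extent, 0.0], [-8.0, extent, 0.0]],
                   n_streamlines=n_streamlines, radial_jitter_sd_mm=jitter_sd_mm)
    b = BundleSpec([[-extent, 0.0, 14.0], [extent, 0.0, 14.0]],
                   n_streamlines=n_streamlines, radial_jitter_sd_mm=jitter_sd_mm)
    return [a, b]


def lesion_size_curves(seed: int = 0, radii_mm=(1.5, 2.5, 5.0), n_replicates: int = 20,
                       n_subjects: int = 10, n_patients: int = 5,
                       n_streamlines: int = 30, jitter_sd_mm: float = 4.0,
                       translation_sd_mm: float = 0.5) -> LesionSizeResult:
    """Reliability against lesion size on the flank of a fanning bundle.

    The lesion sits one lateral standard deviation off the bundle axis, so
    a misaligned patient can miss the smallest lesion's streamlines
    entirely — the small-lesion regime where indirect predictions lose
    reliability. Per replicate a fresh database is generated; internal
    reliability is the leave-one-out Fisher mean, external reliability the
    Fisher mean over ``n_patients`` independently misaligned patients,
    where a patient whose damage map is empty contributes zero agreement
    (dropping such patients would overstate external reliability exactly
    where predictions fail).
    """
    lesion_center = (-4.0, 0.0, 0.0)
    grid = default_grid(33, 2.0)
    int_means, ext_means, volumes = [], [], []
    for r in radii_mm:
        ints, exts = [], []
        for rep in range(n_replicates):
            db_seed = int(np.random.SeedSequence([seed, 3, rep, int(10 * r)]).generate_state(1)[0])
            spec = DatabaseSpec(
                bundles=_size_scene_bundles(n_streamlines, jitter_sd_mm),
                n_subjects=n_subjects,
                subject_translation_sd_mm=translation_sd_mm, seed=db_seed,
            )
            tracts = make_database(spec)
            lesion = make_lesion(grid, lesion_center, r)
            brain = make_brain_mask(grid, tracts, 4.0)
            maps = [visitation_map(select_damaged(t, lesion), grid) for t in tracts]
            pred = aggregate_prediction(maps)
            try:
                ints.append(internal_reliability(
                    maps, brain, lesion, include_lesion=False).mean_r)
            except UndefinedCorrelationError:
                continue
            patient_rs = []
            for j in range(n_patients):
                pt = make_patient_tractogram(spec, seed=db_seed + 7919 * (j + 1))
                sel = select_damaged(pt, lesion, SelectionMode("patient", 2.0))
                if sel.n_streamlines == 0:
                    patient_rs.append(0.0)
                    continue
                try:
                    patient_rs.append(external_reliability(
                        pred, visitation_map(sel, grid), brain, lesion,
                        include_lesion=False).mean_r)
                except UndefinedCorrelationError:
                    patient_rs.append(0.0)
            exts.append(fisher_mean(patient_rs))
        int_means.append(float(np.mean(ints)))
        ext_means.append(float(np.mean(exts)))
        lesion = make_lesion(grid, lesion_center, r)
        volumes.append(float(lesion.data.sum() * lesion.voxel_volume_mm3 / 1000.0))
    return LesionSizeResult(
        radii_mm=list(radii_mm), lesion_volumes_ml=volumes,
        internal_mean=int_means, external_mean=ext_means,
    )
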