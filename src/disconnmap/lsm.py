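"""Voxel-wise nonparametric group comparison of disconnection maps.

Implements the group-level lesion-symptom-mapping pipeline: left-right
harmonization (x-flip), Gaussian smoothing of patient-derived maps, a
one-sided two-sample pooled-variance t-test with family-wise error control
via the permutation distribution of the maximum t statistic, and summary
metrics (significant volume, mean -log10 p, pairwise Dice overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import VolumeGrid

__all__ = [
    "GroupDesign",
    "LSMResult",
    "flip_x",
    "gaussian_smooth",
    "permutation_ttest",
    "lsm_summary",
    "fwhm_to_sigma",
]


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class GroupDesign:
    """Two-group design for the permutation test.

    labels: 1 for the deficit group, 0 for no-deficit; the test is one-sided
    in the deficit > no-deficit direction. flip_flags marks maps to mirror
    over the x-axis before testing (harmonizing left/right deficits).
    """

    maps: list[VolumeGrid]
    labels: np.ndarray
    flip_flags: np.ndarray | None = None
    n_permutations_max: int = 5000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.maps):
            raise ValueError("labels length must match maps length")
        if not (np.any(self.labels == 1) and np.any(self.labels == 0)):
            raise ValueError("both groups must be nonempty")
        if self.flip_flags is not None:
            self.flip_flags = np.asarray(self.flip_flags, dtype=bool)
            if len(self.flip_flags) != len(self.maps):
                raise ValueError("flip_flags length must match maps length")


@dataclass
class LSMResult:
    t_map: VolumeGrid
    fwe_p_map: VolumeGrid
    significant_mask: VolumeGrid
    n_permutations_used: int
    exhaustive: bool = False
    seed: int | None = None
    alpha: float = 0.05
    name: str = ""
    null_max_t: np.ndarray = field(default=None, repr=False)


def _x_axis(affine: np.ndarray) -> int:
    """Voxel axis carrying world x; errors on oblique affines."""
    col_x = affine[:3, :3][0]
    j = int(np.argmax(np.abs(col_x)))
    aligned = (
        abs(affine[1, j]) < 1e-6 and abs(affine[2, j]) < 1e-6
        and all(abs(affine[0, k]) < 1e-6 for k in range(3) if k != j)
    )
    if not aligned:
        raise ValueError(
            "grid is oblique in world x; resample to an axis-aligned grid before flipping"
        )
    return j


def flip_x(grid: VolumeGrid, flip_plane_x: float = 0.0) -> VolumeGrid:
    """Mirror a map over the left/right (world x) axis.

    The grid must be axis-aligned in x and symmetric about the flip plane
    (default world x = 0), so that mirroring voxel data along the x axis
    realizes the world-space reflection with the affine unchanged.
    Flipping twice is the identity.
    """
    j = _x_axis(grid.affine)
    n = grid.shape[j]
    center = grid.affine[0, 3] + grid.affine[0, j] * (n - 1) / 2.0
    if abs(center - flip_plane_x) > 1e-4:
        raise ValueError(
            f"grid is not symmetric about x = {flip_plane_x} (center {center:.4f}); "
            "provide flip_plane_x or resample"
        )
    return VolumeGrid(np.flip(grid.data, axis=j).copy(), grid.affine.copy())


def gaussian_smooth(grid: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Isotropic (in mm) Gaussian smoothing; sigma = FWHM / (2*sqrt(2 ln 2)).

    Reflecting boundaries conserve the total map sum; FWHM 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return VolumeGrid(grid.data.copy(), grid.affine.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / grid.voxel_sizes
    out = ndimage.gaussian_filter(grid.data.astype(np.float64), sigma_vox, mode="reflect")
    return VolumeGrid(out, grid.affine.copy())


def _t_for_labelsets(X, member, n1, n2):
    """Pooled-variance two-sample t for many labelings at once.

    X: (n_subj, n_vox); member: (n_labelings, n_subj) bool for group 1.
    Single-precision throughout (the permutation null only needs ~4 decimal
    digits and the matmul dominates runtime). Zero pooled variance gives
    t = 0.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    X2 = X * X
    M = member.astype(np.float32)
    sum1 = M @ X
    sumsq1 = M @ X2
    sum2 = X.sum(axis=0) - sum1
    sumsq2 = X2.sum(axis=0) - sumsq1
    m1, m2 = sum1 / n1, sum2 / n2
    ss1 = sumsq1 - sum1**2 / n1
    ss2 = sumsq2 - sum2**2 / n2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    np.clip(sp2, 0.0, None, out=sp2)
    denom = np.sqrt(sp2 * np.float32(1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    t[denom == 0] = 0.0
    return t


def _labelings(n, n1, observed_idx, n_max, rng):
    """Group-1 index sets: exhaustive if C(n, n1) <= n_max, else a seeded
    sample without replacement that always includes the observed labeling."""
    total = math.comb(n, n1)
    if total <= n_max:
        return [tuple(c) for c in combinations(range(n), n1)], True
    chosen = {tuple(observed_idx)}
    idx = np.arange(n)
    while len(chosen) < n_max:
        pick = tuple(sorted(rng.choice(idx, size=n1, replace=False)))
        chosen.add(pick)
    sets = [tuple(observed_idx)] + sorted(chosen - {tuple(observed_idx)})
    return sets, False


def permutation_ttest(design: GroupDesign, brain_mask: VolumeGrid) -> LSMResult:
    """One-sided max-statistic permutation t-test with FWE control.

    The voxel-wise statistic is the pooled-variance two-sample t
    (deficit > no-deficit). The null distribution is the maximum t over
    in-mask voxels across group relabelings — all of them when the number
    of distinct assignments is within the permutation budget, otherwise a
    seeded sample including the observed labeling. fwe_p(v) is the
    proportion of null maxima >= t(v); a voxel is significant when
    fwe_p <= alpha.
    """
    mask = brain_mask.data.astype(bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    labels = design.labels
    n1 = int((labels == 1).sum())
    n2 = int((labels == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups must have >= 2 members")
    ref = design.maps[0]
    # center each voxel across subjects (t is shift-invariant); this keeps the
    # single-precision sums free of large-offset cancellation
    X = np.stack([m.data[mask].astype(np.float64) for m in design.maps])
    X -= X.mean(axis=0)
    X = X.astype(np.float32)
    n = len(design.maps)
    observed_idx = tuple(np.flatnonzero(labels == 1))
    rng = np.random.default_rng(design.seed)
    sets, exhaustive = _labelings(n, n1, observed_idx, design.n_permutations_max, rng)

    member = np.zeros((len(sets), n), dtype=bool)
    for i, s in enumerate(sets):
        member[i, list(s)] = True
    T = _t_for_labelsets(X, member, n1, n2)
    t_obs = T[sets.index(observed_idx)]
    null_max = T.max(axis=1)

    n_perm = len(sets)
    fwe_p = (null_max[None, :] >= t_obs[:, None]).mean(axis=1)

    t_map = np.zeros(mask.shape)
    t_map[mask] = t_obs
    p_map = np.ones(mask.shape)
    p_map[mask] = fwe_p
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = fwe_p <= design.alpha
    return LSMResult(
        t_map=ref.like(t_map), fwe_p_map=ref.like(p_map),
        significant_mask=ref.like(sig), n_permutations_used=n_perm,
        exhaustive=exhaustive, seed=design.seed, alpha=design.alpha,
        null_max_t=null_max,
    )


def lsm_summary(results: list[LSMResult], alpha: float = 0.05):
    """Summary metrics across parallel analyses sharing one grid.

    Per result: significant volume (cm^3), mean -log10 FWE p over its own
    significant voxels, and over the union of every result's significant
    voxels; plus the pairwise Dice overlap of significant masks. Undefined
    means (empty masks) are reported as NaN.
    """
    ref = results[0].t_map
    for r in results[1:]:
        if not ref.same_grid(r.t_map):
            raise ValueError("results must share a grid")
    vox_ml = ref.voxel_volume_mm3 / 1000.0
    sigs = [r.significant_mask.data.astype(bool) for r in results]
    union = np.any(sigs, axis=0)
    rows = []
    for r, sig in zip(results, sigs):
        logp = -np.log10(np.clip(r.fwe_p_map.data, 1e-300, None))
        rows.append({
            "name": r.name or f"result_{len(rows)}",
            "significant_volume_cm3": float(sig.sum() * vox_ml),
            "mean_neglog10p_own": float(logp[sig].mean()) if sig.any() else float("nan"),
            "mean_neglog10p_union": float(logp[union].mean()) if union.any() else float("nan"),
            "n_significant_voxels": int(sig.sum()),
        })
    names = [row["name"] for row in rows]
    dice = pd.DataFrame(np.eye(len(results)), index=names, columns=names)
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            a, b = sigs[i], sigs[j]
            denom = a.sum() + b.sum()
            d = 2.0 * np.logical_and(a, b).sum() / denom if denom else float("nan")
            dice.iloc[i, j] = dice.iloc[j, i] = d
    return pd.DataFrame(rows), dice
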