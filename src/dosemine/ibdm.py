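"""Voxel-wise image-based data-mining of Δdose maps.

Per-patient Δdose maps are resampled to a common reference lattice
(here via exactly known affine transforms), blurred with a Gaussian
whose width represents spatial-normalisation uncertainty, and compared
between one-year survivors and non-survivors voxel by voxel. The voxel
statistic is the group mean difference scaled by the standard deviation
of that difference over random label permutations; global inference
uses the permutation distribution of the maximum statistic (maxT),
which controls family-wise error and yields a single cohort-level
p-value. The significant region is the connected component, at 80% of
the maximum t, containing the peak voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose_accum import DoseGrid, shift_dose

__all__ = [
    "ReferenceTransform",
    "TStatMap",
    "Region",
    "map_to_reference",
    "blur_map",
    "permutation_test",
    "extract_region",
    "region_dose_summary",
]


@dataclass
class ReferenceTransform:
    """Affine x_ref = matrix @ x_patient + translation (world mm).

    ``heart_com_deviation`` is the registration QA metric: the distance
    between the transformed patient heart centre and the reference
    heart centre. Patients failing QA are excluded from the analysis,
    mirroring visual rejection of failed registrations.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    heart_com_deviation: float = 0.0
    qa_tolerance: float = 10.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("singular reference transform")

    @property
    def qa_passed(self) -> bool:
        return self.heart_com_deviation <= self.qa_tolerance

    @classmethod
    def from_patient_offset(cls, offset, heart_com_deviation: float = 0.0,
                            qa_tolerance: float = 10.0) -> "ReferenceTransform":
        """Transform undoing a rigid patient setup offset (x_ref = x_pat − offset)."""
        return cls(np.eye(3), -np.asarray(offset, dtype=float),
                   heart_com_deviation, qa_tolerance)


def map_to_reference(dmap: DoseGrid, transform: ReferenceTransform,
                     fill: float = 0.0, compute_valid: bool = True) -> tuple:
    """Resample a patient-frame map onto the reference lattice.

    Returns ``(mapped, valid)`` where ``valid`` marks reference voxels
    whose sample point lay inside the patient grid (None when
    ``compute_valid`` is off). Trilinear interpolation; pure
    translations take an exact fast path shared with the dose-shifting
    code.
    """
    t = transform.translation
    if np.allclose(transform.matrix, np.eye(3)):
        # x_ref = x_pat + t  =>  value_ref(x) = map(x − t)
        mapped = shift_dose(dmap, -t)
        if compute_valid:
            # sample index i − t/spacing must lie in [0, n−1] per axis
            valid = np.ones(dmap.shape, dtype=bool)
            tv = -t / dmap.spacing
            for a in range(3):
                n = dmap.shape[a]
                idx = np.arange(n) + tv[a]
                ax_ok = (idx >= 0) & (idx <= n - 1)
                sl = [None, None, None]
                sl[a] = slice(None)
                valid &= ax_ok[tuple(sl)]
        else:
            valid = None
    else:
        inv = np.linalg.inv(transform.matrix)
        # index-space matrix: idx_pat = inv @ (spacing*idx_ref − t) / spacing
        sp = dmap.spacing
        m = inv * sp[None, :] / sp[:, None]
        off = -(inv @ t) / sp
        vals = ndimage.affine_transform(
            dmap.values.astype(np.float64), m, offset=off, order=1, cval=fill
        )
        vmask = ndimage.affine_transform(
            np.ones(dmap.shape), m, offset=off, order=1, cval=0.0
        )
        mapped = DoseGrid(vals.astype(np.float32), dmap.spacing.copy(), dmap.origin.copy())
        valid = vmask >= 0.999
    if fill != 0.0 and valid is not None:
        mapped.values[~valid] = fill
    return mapped, valid


def blur_map(dmap: DoseGrid, sigma_mm) -> DoseGrid:
    """Separable Gaussian blur with per-axis sigma in mm (reflect boundary)."""
    sigma_mm = np.broadcast_to(np.asarray(sigma_mm, dtype=float), (3,))
    if np.any(sigma_mm < 0):
        raise ValueError(f"blur sigma must be >= 0, got {sigma_mm}")
    if np.all(sigma_mm == 0):
        return DoseGrid(dmap.values.copy(), dmap.spacing.copy(), dmap.origin.copy())
    sigma_vox = sigma_mm / dmap.spacing
    out = ndimage.gaussian_filter(dmap.values, sigma_vox, mode="reflect")
    return DoseGrid(out, dmap.spacing.copy(), dmap.origin.copy())


@dataclass
class TStatMap:
    t_values: np.ndarray  # 0 where perm_sd == 0 or outside mask
    diff_map: np.ndarray  # mean(dead) − mean(alive), Gy
    perm_sd: np.ndarray
    analysis_mask: np.ndarray  # voxels entering max-t / region extraction
    max_t: float
    global_p: float
    n_perm: int
    argmax_index: tuple | None
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 4.0))


def permutation_test(maps, labels_dead, n_perm: int = 1000, seed=0,
                     analysis_mask: np.ndarray | None = None) -> TStatMap:
    """Voxel-wise two-group comparison with maxT permutation inference.

    Parameters
    ----------
    maps : sequence of ndarray or DoseGrid, all on the reference lattice
        One Δdose map per patient (indeterminate-status patients must
        already be excluded).
    labels_dead : boolean array
        True for patients dead at one year.
    n_perm : int
        Number of random label permutations (group sizes preserved).
    analysis_mask : boolean ndarray, optional
        Voxels to analyse; defaults to the whole grid.

    The observed statistic at each voxel is the group mean difference
    (dead − alive) divided by the standard deviation of that difference
    over the permutations; the global p-value is the add-one estimate
    of how often the permuted maximum |t| reaches the observed maximum.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    arrs = [m.values if isinstance(m, DoseGrid) else np.asarray(m) for m in maps]
    spacing = maps[0].spacing if isinstance(maps[0], DoseGrid) else np.full(3, 4.0)
    shape = arrs[0].shape
    labels = np.asarray(labels_dead, dtype=bool)
    n = len(arrs)
    if labels.shape != (n,):
        raise ValueError("labels must match the number of maps")
    n1 = int(labels.sum())
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each outcome group needs >= 2 patients (got {n1} dead, {n0} alive)")
    if analysis_mask is None:
        analysis_mask = np.ones(shape, dtype=bool)
    flat_idx = np.flatnonzero(analysis_mask.ravel())
    X = np.stack([a.ravel()[flat_idx] for a in arrs]).astype(np.float32)  # (n, V)

    w_dead, w_alive = 1.0 / n1, -1.0 / n0
    w_obs = np.where(labels, w_dead, w_alive).astype(np.float32)
    diff = w_obs @ X

    rng = np.random.default_rng(seed)
    perm_labels = np.tile(labels, (n_perm, 1))
    perm_labels = rng.permuted(perm_labels, axis=1)
    W = np.where(perm_labels, w_dead, w_alive).astype(np.float32)
    perm_diffs = W @ X  # (n_perm, V)
    perm_sd = perm_diffs.std(axis=0, ddof=1)

    ok = perm_sd > 0
    t = np.zeros_like(diff)
    t[ok] = diff[ok] / perm_sd[ok]

    if not np.any(ok):
        max_t, global_p, argmax_index = 0.0, 1.0, None
    else:
        j = int(np.argmax(np.where(ok, t, -np.inf)))
        max_t = float(t[j])
        argmax_index = tuple(int(v) for v in np.unravel_index(flat_idx[j], shape))
        perm_t = np.abs(perm_diffs[:, ok]) / perm_sd[ok]
        perm_max = perm_t.max(axis=1)
        global_p = float((1 + np.sum(perm_max >= max_t)) / (n_perm + 1))

    def unflatten(v):
        full = np.zeros(shape, dtype=np.float32)
        full.ravel()[flat_idx] = v
        return full

    return TStatMap(
        t_values=unflatten(t),
        diff_map=unflatten(diff),
        perm_sd=unflatten(perm_sd),
        analysis_mask=analysis_mask & unflatten(ok.astype(np.float32)).astype(bool),
        max_t=max_t,
        global_p=global_p,
        n_perm=n_perm,
        argmax_index=argmax_index,
        spacing=np.asarray(spacing, dtype=float),
    )


@dataclass
class Region:
    mask: np.ndarray
    threshold_t: float
    connectivity: int = 26


def extract_region(tmap: TStatMap, fraction: float = 0.8,
                   connectivity: int = 26) -> Region:
    """Connected suprathreshold region containing the peak t voxel.

    The threshold is ``fraction`` of the maximum t (default 80%); the
    region is the single connected component of the suprathreshold set
    that contains the argmax voxel.
    """
    if not np.all(np.isfinite(tmap.t_values)):
        raise ValueError("non-finite t map")
    if tmap.max_t <= 0 or tmap.argmax_index is None:
        raise ValueError(f"region extraction needs max_t > 0, got {tmap.max_t}")
    threshold = fraction * tmap.max_t
    supra = (tmap.t_values >= threshold) & tmap.analysis_mask
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labeled, _ = ndimage.label(supra, structure=structure)
    comp = labeled[tmap.argmax_index]
    assert comp != 0  # argmax is suprathreshold by construction
    return Region(mask=labeled == comp, threshold_t=float(threshold), connectivity=connectivity)


def region_dose_summary(region: Region, delta_maps, planned_maps,
                        patient_ids=None, valid_masks=None) -> pd.DataFrame:
    """Per-patient mean Δdose and planned dose over the mined region."""
    if not np.any(region.mask):
        raise ValueError("empty region")
    n = len(delta_maps)
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]
    idx = region.mask
    rows = []
    for i in range(n):
        if valid_masks is not None and not np.any(valid_masks[i] & idx):
            raise ValueError(f"region lies fully outside patient {patient_ids[i]}'s valid field")
        d = delta_maps[i].values if isinstance(delta_maps[i], DoseGrid) else np.asarray(delta_maps[i])
        p = planned_maps[i].values if isinstance(planned_maps[i], DoseGrid) else np.asarray(planned_maps[i])
        rows.append(
            dict(
                patient_id=patient_ids[i],
                mean_delta_region_gy=float(d[idx].mean()),
                mean_planned_region_gy=float(p[idx].mean()),
            )
        )
    return pd.DataFrame(rows)
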