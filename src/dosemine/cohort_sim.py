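"""Synthetic NSCLC-like cohort generator.

Produces fully reproducible cohorts with the statistical structure the
downstream analysis assumes: parametric anatomy (ellipsoidal body and
heart, spherical tumour at a randomised position), a multi-beam
Gaussian-profile planned dose normalised to the prescription over the
tumour, clinical covariates, per-fraction setup errors filtered through
an image-guidance protocol, and survival times whose hazard depends on
the dose delivered to a planted "sensitive" subregion at the heart
base. The sensitive region is fixed in reference coordinates for every
patient, so the voxel-wise data-mining stage has a known ground truth
to recover.

Anatomy is parametric rather than CT-derived, which makes the spatial
normalisation step an exactly known (and exactly invertible) rigid
translation per patient: each patient's frame is the reference frame
shifted by a random offset.

Survival model
--------------
Times are drawn from a proportional-hazards Weibull (exponential by
default) with linear predictor

    β_Δ · Δdose_region · 1[planned_region ∈ window]
    + β_plan · planned_region + β_age (age − 70)
    + β_ecog[ECOG] + β_gtv (ln GTV − ln 30)

The Δdose effect is gated to a planned-dose window (default 16–24 Gy)
so the octile threshold analysis has a recoverable planted boundary.
Default effect sizes are hazard ratios typical for this disease
setting: 1.216/Gy for region Δdose, 1.013/Gy for planned region dose,
1.013/year of age, 1.456 per ln-cm³ of tumour volume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_accum import DoseGrid
from .setup_errors import (
    IGRTProtocol,
    apply_igrt_protocol,
    sample_fraction_errors,
    summarise_course,
    weekly_imaging_fractions,
)

__all__ = [
    "SimConfig",
    "AnatomyModel",
    "ClinicalCovariates",
    "SurvivalOutcome",
    "BeamPlan",
    "gtv_radius_mm",
    "make_anatomy",
    "make_beam_plan",
    "make_planned_dose",
    "sample_covariates",
    "simulate_survival",
    "simulate_patient",
    "generate_cohort",
]

LN2 = float(np.log(2.0))

# Reference-frame geometry (mm). The body/heart/sensitive-region layout is
# identical for all patients in reference coordinates; the per-patient frame
# is this layout translated by a random setup offset.
BODY_CENTER_REF = np.array([128.0, 128.0, 96.0])
BODY_SEMIAXES = np.array([110.0, 90.0, 85.0])
HEART_OFFSET = np.array([-30.0, 10.0, -20.0])  # from body centre
HEART_SEMIAXES = np.array([35.0, 30.0, 30.0])
SENSITIVE_OFFSET = np.array([4.0, 0.0, -6.0])  # from heart centre (heart base)
SENSITIVE_SEMIAXES = np.array([26.0, 20.0, 16.0])
# Tumour placement relative to the heart centre: either lung, any lobe
# (mild superior bias), with a wide range of target-to-heart distances.
GTV_LATERAL_RANGE = (10.0, 60.0)  # |dx|, sign random (left/right lung)
GTV_AP_RANGE = (-25.0, 25.0)  # dy
GTV_SI_RANGE = (-35.0, 55.0)  # dz; positive = superior to the heart
PATIENT_OFFSET_MAX = 8.0  # mm, uniform per axis
BEAM_GANTRY_DEG = (0.0, 72.0, 144.0, 216.0, 288.0)  # five-field, axial plane
BEAM_JITTER_DEG = 30.0  # per-beam gantry jitter; every plan is patient-specific
BEAM_TILT_DEG = 20.0  # per-beam out-of-plane (couch) tilt
BEAM_SIGMA_MARGIN = 6.0  # beam sigma = 0.7 * GTV radius + margin, mm
AIR_FACTOR = 0.02  # dose scale outside the body


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 120
    prescription_dose: float = 55.0
    n_fractions: int = 20
    systematic_sd: float = 3.5  # mm per axis (population setup error, pre-correction)
    random_sd: float = 3.5  # mm per axis
    action_threshold: float = 5.0
    threshold_rule: str = "per_axis"
    estimate_unimaged: str = "truth"
    effect_beta_delta: float = float(np.log(1.216))  # per Gy region Δdose
    effect_beta_planned: float = float(np.log(1.013))  # per Gy planned region dose
    beta_age: float = float(np.log(1.013))  # per year, centred at 70
    beta_ecog: tuple = (0.0, float(np.log(1.314)), float(np.log(1.769)),
                        float(np.log(1.490)), float(np.log(3.291)))
    beta_lngtv: float = float(np.log(1.456))  # per ln cm³, centred at ln 30
    dose_threshold_window: tuple = (16.0, 24.0)  # Gy; Δdose effect active inside
    baseline_median_days: float = 548.0  # 18 months
    weibull_shape: float = 1.0  # 1 = exponential baseline
    censoring_horizon_days: float = 1826.0  # 5 years administrative censoring
    grid_shape: tuple = (64, 64, 48)
    spacing: float = 4.0  # mm isotropic
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be > 0")
        if self.systematic_sd < 0 or self.random_sd < 0:
            raise ValueError("error SDs must be >= 0")

    def protocol(self) -> IGRTProtocol:
        return IGRTProtocol(
            action_threshold=self.action_threshold,
            imaging_fractions=weekly_imaging_fractions(self.n_fractions),
            threshold_rule=self.threshold_rule,
            estimate_unimaged=self.estimate_unimaged,
        )

    def rng_for(self, patient_index: int, stage: int) -> np.random.Generator:
        """Documented seed scheme: child stream of (master_seed, patient, stage)."""
        ss = np.random.SeedSequence([int(self.master_seed), int(patient_index), int(stage)])
        return np.random.default_rng(ss)


# stage codes for the per-patient substreams
_STAGE_COVARIATES = 0
_STAGE_ANATOMY = 1
_STAGE_ERRORS = 2
_STAGE_SURVIVAL = 3
_STAGE_PLAN = 4


@dataclass
class AnatomyModel:
    grid_shape: tuple
    spacing: np.ndarray
    body_mask: np.ndarray
    heart_mask: np.ndarray
    gtv_mask: np.ndarray
    sensitive_mask: np.ndarray
    heart_com: np.ndarray  # world mm, patient frame
    gtv_com: np.ndarray
    body_center: np.ndarray
    gtv_radius: float
    patient_offset: np.ndarray  # patient frame = reference frame + offset


@dataclass
class ClinicalCovariates:
    age: float
    ecog_ps: int
    gtv_volume: float  # cm³
    overall_stage: int
    t_stage: int
    n_stage: int
    histology: str
    gender: str

    def __post_init__(self) -> None:
        if self.age <= 0 or self.gtv_volume <= 0:
            raise ValueError("age and gtv_volume must be positive")
        if self.ecog_ps not in (0, 1, 2, 3, 4):
            raise ValueError(f"ecog_ps must be 0..4, got {self.ecog_ps}")


@dataclass
class SurvivalOutcome:
    time: float  # days
    event: bool
    one_year_status: str  # 'alive' | 'dead' | 'indeterminate'


def gtv_radius_mm(volume_cm3: float) -> float:
    """Radius of a sphere with the given volume (cm³ in, mm out)."""
    return float((3.0 * volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _ellipsoid_mask(centers, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    cx, cy, cz = centers
    q = (
        ((cx[:, None, None] - center[0]) / semiaxes[0]) ** 2
        + ((cy[None, :, None] - center[1]) / semiaxes[1]) ** 2
        + ((cz[None, None, :] - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def make_anatomy(config: SimConfig, patient_index: int, rng=None,
                 gtv_volume_cm3: float | None = None) -> AnatomyModel:
    """Build one patient's parametric anatomy on the dose grid.

    The body, heart and sensitive subregion sit at fixed reference
    positions translated by a random patient offset; the spherical GTV
    is placed at a randomised offset from the heart so the
    target-to-heart distance varies across the cohort.
    """
    shape = tuple(int(s) for s in config.grid_shape)
    if any(s < 8 for s in shape):
        raise ValueError(f"degenerate grid {shape}: every axis needs >= 8 voxels")
    spacing = np.full(3, float(config.spacing))
    rng = config.rng_for(patient_index, _STAGE_ANATOMY) if rng is None else np.random.default_rng(rng)

    offset = rng.uniform(-PATIENT_OFFSET_MAX, PATIENT_OFFSET_MAX, size=3)
    side = 1.0 if rng.uniform() < 0.5 else -1.0
    gtv_delta = np.array([
        side * rng.uniform(*GTV_LATERAL_RANGE),
        rng.uniform(*GTV_AP_RANGE),
        rng.uniform(*GTV_SI_RANGE),
    ])
    if gtv_volume_cm3 is None:
        gtv_volume_cm3 = _draw_gtv_volume(rng)
    r_gtv = gtv_radius_mm(gtv_volume_cm3)

    body_c = BODY_CENTER_REF + offset
    heart_c = body_c + HEART_OFFSET
    sens_c = heart_c + SENSITIVE_OFFSET
    gtv_c = heart_c + gtv_delta

    centers = tuple(spacing[a] * np.arange(shape[a]) for a in range(3))
    body = _ellipsoid_mask(centers, body_c, BODY_SEMIAXES)
    heart = _ellipsoid_mask(centers, heart_c, HEART_SEMIAXES) & body
    sens = _ellipsoid_mask(centers, sens_c, SENSITIVE_SEMIAXES) & heart
    gtv = _ellipsoid_mask(centers, gtv_c, np.full(3, r_gtv)) & body

    return AnatomyModel(
        grid_shape=shape,
        spacing=spacing,
        body_mask=body,
        heart_mask=heart,
        gtv_mask=gtv,
        sensitive_mask=sens,
        heart_com=heart_c,
        gtv_com=gtv_c,
        body_center=body_c,
        gtv_radius=r_gtv,
        patient_offset=offset,
    )


def _draw_gtv_volume(rng) -> float:
    return float(np.clip(np.exp(rng.normal(np.log(30.0), 0.8)), 2.0, 300.0))


@dataclass
class BeamPlan:
    """Analytic multi-beam Gaussian dose model for one patient.

    ``dose_at`` evaluates the planned dose at arbitrary world points,
    which doubles as the ground truth for delivered dose at shifted
    positions (the shift-invariance assumption made exact).
    """

    gtv_com: np.ndarray
    sigma: float
    directions: np.ndarray  # (n_beams, 3) unit vectors
    weights: np.ndarray
    norm: float  # Gy per unit raw profile
    body_center: np.ndarray
    body_semiaxes: np.ndarray
    air_factor: float = AIR_FACTOR

    def raw_profile(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        v = pts - self.gtv_com
        prof = np.zeros(len(pts))
        for u, w in zip(self.directions, self.weights):
            along = v @ u
            d2 = np.einsum("ij,ij->i", v, v) - along**2
            prof += w * np.exp(-d2 / (2.0 * self.sigma**2))
        return prof

    def dose_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        prof = self.raw_profile(pts)
        q = np.sum(((pts - self.body_center) / self.body_semiaxes) ** 2, axis=1)
        factor = np.where(q <= 1.0, 1.0, self.air_factor)
        return self.norm * prof * factor


def make_beam_plan(anatomy: AnatomyModel, config: SimConfig,
                   rng=None) -> BeamPlan:
    """Build the patient's beam arrangement and fit its normalisation.

    Three equispaced coplanar beams intersect at the tumour; the whole
    arrangement is rotated by a random per-patient offset (every
    clinical plan has its own beam angles), and the normalisation is
    set so the mean GTV dose equals the prescription.
    """
    rng = np.random.default_rng(rng)
    rotation = rng.uniform(0.0, 360.0)
    jitter = rng.uniform(-BEAM_JITTER_DEG, BEAM_JITTER_DEG, size=len(BEAM_GANTRY_DEG))
    angles = np.deg2rad(np.asarray(BEAM_GANTRY_DEG) + rotation + jitter)
    tilt = np.deg2rad(rng.uniform(-BEAM_TILT_DEG, BEAM_TILT_DEG, size=len(angles)))
    dirs = np.column_stack([
        np.sin(angles) * np.cos(tilt),
        np.cos(angles) * np.cos(tilt),
        np.sin(tilt),
    ])
    weights = np.full(len(dirs), 1.0 / len(dirs))
    plan = BeamPlan(
        gtv_com=anatomy.gtv_com,
        sigma=0.7 * anatomy.gtv_radius + BEAM_SIGMA_MARGIN,
        directions=dirs,
        weights=weights,
        norm=1.0,
        body_center=anatomy.body_center,
        body_semiaxes=BODY_SEMIAXES.copy(),
    )
    gtv_pts = _mask_voxel_centers(anatomy, anatomy.gtv_mask)
    if len(gtv_pts) == 0:
        raise ValueError("empty GTV mask: cannot normalise the plan")
    mean_raw = float(plan.raw_profile(gtv_pts).mean())
    plan.norm = config.prescription_dose / mean_raw
    return plan


def _mask_voxel_centers(anatomy: AnatomyModel, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx * anatomy.spacing


def make_planned_dose(anatomy: AnatomyModel, config: SimConfig,
                      plan: BeamPlan | None = None) -> DoseGrid:
    """Sample the analytic beam model on the full dose grid.

    Equivalent to ``plan.dose_at`` at every voxel centre, but evaluated
    with broadcast 1-D axis arrays in float32 for speed.
    """
    if plan is None:
        plan = make_beam_plan(anatomy, config)
    shape = anatomy.grid_shape
    ax = [
        (anatomy.spacing[a] * np.arange(shape[a], dtype=np.float32) - plan.gtv_com[a])
        for a in range(3)
    ]
    vx, vy, vz = (ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :])
    v2 = vx**2 + vy**2 + vz**2
    prof = np.zeros(shape, dtype=np.float32)
    inv2s2 = np.float32(1.0 / (2.0 * plan.sigma**2))
    for u, w in zip(plan.directions.astype(np.float32), plan.weights):
        along = u[0] * vx + u[1] * vy + u[2] * vz
        d2 = v2 - along**2
        prof += np.float32(w) * np.exp(-d2 * inv2s2)
    bx = [
        ((anatomy.spacing[a] * np.arange(shape[a], dtype=np.float32)
          - plan.body_center[a]) / plan.body_semiaxes[a]) ** 2
        for a in range(3)
    ]
    q = bx[0][:, None, None] + bx[1][None, :, None] + bx[2][None, None, :]
    factor = np.where(q <= 1.0, np.float32(1.0), np.float32(plan.air_factor))
    vals = np.float32(plan.norm) * prof * factor
    return DoseGrid(vals, anatomy.spacing.copy(), np.zeros(3))


def sample_covariates(config: SimConfig, patient_index: int, rng=None) -> ClinicalCovariates:
    rng = config.rng_for(patient_index, _STAGE_COVARIATES) if rng is None else np.random.default_rng(rng)
    return ClinicalCovariates(
        age=float(np.clip(rng.normal(70.0, 8.0), 40.0, 90.0)),
        ecog_ps=int(rng.choice(5, p=[0.20, 0.45, 0.25, 0.08, 0.02])),
        gtv_volume=_draw_gtv_volume(rng),
        overall_stage=int(rng.choice([1, 2, 3, 4], p=[0.10, 0.20, 0.50, 0.20])),
        t_stage=int(rng.choice([1, 2, 3, 4], p=[0.15, 0.30, 0.30, 0.25])),
        n_stage=int(rng.choice([0, 1, 2, 3], p=[0.25, 0.20, 0.35, 0.20])),
        histology=str(rng.choice(["squamous", "adenocarcinoma", "other"], p=[0.40, 0.40, 0.20])),
        gender=str(rng.choice(["M", "F"], p=[0.55, 0.45])),
    )


def linear_predictor(clin: ClinicalCovariates, planned_region_dose: float,
                     delta_region_dose: float, config: SimConfig) -> float:
    lo, hi = config.dose_threshold_window
    gate = 1.0 if lo <= planned_region_dose <= hi else 0.0
    lp = (
        config.effect_beta_delta * delta_region_dose * gate
        + config.effect_beta_planned * planned_region_dose
        + config.beta_age * (clin.age - 70.0)
        + config.beta_ecog[clin.ecog_ps]
        + config.beta_lngtv * (np.log(clin.gtv_volume) - np.log(30.0))
    )
    if not np.isfinite(lp):
        raise ValueError(f"non-finite linear predictor: {lp}")
    return float(lp)


def simulate_survival(clin: ClinicalCovariates, planned_region_dose: float,
                      delta_region_dose: float, config: SimConfig, rng) -> SurvivalOutcome:
    """Draw one survival time from the proportional-hazards model.

    Baseline is Weibull with shape ``weibull_shape`` (exponential when
    1) and median ``baseline_median_days``; administrative censoring at
    the configured horizon.
    """
    rng = np.random.default_rng(rng)
    lp = linear_predictor(clin, planned_region_dose, delta_region_dose, config)
    k = config.weibull_shape
    # scale so that the baseline (lp = 0) median equals the configured value
    lam = LN2 ** (1.0 / k) / config.baseline_median_days
    u = rng.uniform()
    t = (-np.log(u) / np.exp(lp)) ** (1.0 / k) / lam
    t = max(float(t), 1e-9)
    horizon = config.censoring_horizon_days
    event = t <= horizon
    time = t if event else horizon
    if event and time < 365.25:
        status = "dead"
    elif time >= 365.25:
        status = "alive"
    else:
        status = "indeterminate"
    return SurvivalOutcome(time=time, event=bool(event), one_year_status=status)


@dataclass
class PatientBundle:
    patient_id: str
    anatomy: AnatomyModel
    covariates: ClinicalCovariates
    records: list  # FractionRecord with residuals filled
    outcome: SurvivalOutcome
    plan: BeamPlan
    planned_region_dose: float  # ground-truth mean planned dose, sensitive region
    delta_region_dose: float  # ground-truth mean Δdose, sensitive region
    planned_dose: DoseGrid | None = None

    @property
    def residuals(self) -> np.ndarray:
        return np.array([r.residual for r in self.records])


def _region_doses(anatomy: AnatomyModel, plan: BeamPlan, residuals: np.ndarray) -> tuple:
    """Ground-truth mean planned and Δ dose over the sensitive region.

    Evaluates the analytic beam model at the (shifted) sensitive-region
    voxel centres, bypassing grid interpolation.
    """
    pts = _mask_voxel_centers(anatomy, anatomy.sensitive_mask)
    planned_mean = float(plan.dose_at(pts).mean())
    acc = 0.0
    uniq, counts = np.unique(residuals, axis=0, return_counts=True)
    for r, c in zip(uniq, counts):
        acc += c * float(plan.dose_at(pts + r).mean())
    acc /= len(residuals)
    return planned_mean, acc - planned_mean


def simulate_patient(config: SimConfig, patient_index: int,
                     with_grids: bool = True) -> PatientBundle:
    """Generate one fully seeded patient (anatomy, plan, errors, outcome)."""
    clin = sample_covariates(config, patient_index)
    anatomy = make_anatomy(config, patient_index, gtv_volume_cm3=clin.gtv_volume)
    plan = make_beam_plan(anatomy, config, config.rng_for(patient_index, _STAGE_PLAN))
    records = sample_fraction_errors(
        config.systematic_sd, config.random_sd, config.n_fractions,
        config.rng_for(patient_index, _STAGE_ERRORS),
    )
    records = apply_igrt_protocol(records, config.protocol())
    residuals = np.array([r.residual for r in records])
    planned_region, delta_region = _region_doses(anatomy, plan, residuals)
    outcome = simulate_survival(
        clin, planned_region, delta_region, config,
        config.rng_for(patient_index, _STAGE_SURVIVAL),
    )
    planned_dose = make_planned_dose(anatomy, config, plan) if with_grids else None
    return PatientBundle(
        patient_id=f"P{patient_index:04d}",
        anatomy=anatomy,
        covariates=clin,
        records=records,
        outcome=outcome,
        plan=plan,
        planned_region_dose=planned_region,
        delta_region_dose=delta_region,
        planned_dose=planned_dose,
    )


def reference_anatomy(config: SimConfig) -> AnatomyModel:
    """The zero-offset anatomy defining the reference lattice and masks."""
    shape = tuple(int(s) for s in config.grid_shape)
    spacing = np.full(3, float(config.spacing))
    centers = tuple(spacing[a] * np.arange(shape[a]) for a in range(3))
    body_c = BODY_CENTER_REF.copy()
    heart_c = body_c + HEART_OFFSET
    sens_c = heart_c + SENSITIVE_OFFSET
    body = _ellipsoid_mask(centers, body_c, BODY_SEMIAXES)
    heart = _ellipsoid_mask(centers, heart_c, HEART_SEMIAXES) & body
    sens = _ellipsoid_mask(centers, sens_c, SENSITIVE_SEMIAXES) & heart
    return AnatomyModel(
        grid_shape=shape, spacing=spacing, body_mask=body, heart_mask=heart,
        gtv_mask=np.zeros(shape, dtype=bool), sensitive_mask=sens,
        heart_com=heart_c, gtv_com=body_c, body_center=body_c,
        gtv_radius=0.0, patient_offset=np.zeros(3),
    )


def clinical_frame(patients: list) -> pd.DataFrame:
    """Cohort clinical/survival table, one row per patient."""
    rows = []
    for p in patients:
        c, o = p.covariates, p.outcome
        rows.append(
            dict(
                patient_id=p.patient_id, age=c.age, gender=c.gender,
                ecog_ps=c.ecog_ps, overall_stage=c.overall_stage,
                t_stage=c.t_stage, n_stage=c.n_stage, histology=c.histology,
                gtv_cm3=c.gtv_volume, surv_days=o.time, event=int(o.event),
                one_year_status=o.one_year_status,
                true_planned_region_gy=p.planned_region_dose,
                true_delta_region_gy=p.delta_region_dose,
                mean_heart_shift_mm=summarise_course(
                    p.records, p.anatomy.gtv_com, p.anatomy.heart_com
                ).mean_heart_shift,
            )
        )
    return pd.DataFrame(rows)


def fraction_frame(patients: list) -> pd.DataFrame:
    rows = []
    for p in patients:
        for r in p.records:
            rows.append(
                dict(
                    patient_id=p.patient_id, fraction=r.fraction_index,
                    ex_mm=r.setup_error[0], ey_mm=r.setup_error[1], ez_mm=r.setup_error[2],
                    imaged=int(r.imaged), corrected=int(r.corrected),
                    rx_mm=r.residual[0], ry_mm=r.residual[1], rz_mm=r.residual[2],
                )
            )
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig, out_dir: str | Path | None = None,
                    with_grids: bool = True) -> dict:
    """Generate the full cohort; optionally write it to disk.

    Returns a bundle with the patient list, the reference anatomy, the
    clinical table and the per-fraction error table. When ``out_dir``
    is given, writes NIfTI volumes, the two CSV tables, and a
    provenance JSON recording the config, seed and planted effects.
    """
    if config.n_patients < 8:
        raise ValueError("n_patients must be >= 8")
    patients = [
        simulate_patient(config, i, with_grids=with_grids)
        for i in range(config.n_patients)
    ]
    ref = reference_anatomy(config)
    bundle = dict(
        config=config,
        patients=patients,
        reference=ref,
        clinical=clinical_frame(patients),
        fractions=fraction_frame(patients),
    )
    if out_dir is not None:
        _write_cohort(bundle, Path(out_dir))
    return bundle


def _write_cohort(bundle: dict, out_dir: Path) -> None:
    from .io_cli import write_volume  # local import; io_cli imports this module

    out_dir.mkdir(parents=True, exist_ok=True)
    config: SimConfig = bundle["config"]
    ref: AnatomyModel = bundle["reference"]
    try:
        bundle["clinical"].to_csv(out_dir / "clinical.csv", index=False)
        bundle["fractions"].to_csv(out_dir / "fractions.csv", index=False)
        write_volume(
            DoseGrid(ref.sensitive_mask.astype(np.uint8), ref.spacing),
            out_dir / "reference_sensitive_mask.nii", is_mask=True,
        )
        write_volume(
            DoseGrid(ref.heart_mask.astype(np.uint8), ref.spacing),
            out_dir / "reference_heart_mask.nii", is_mask=True,
        )
        for p in bundle["patients"]:
            if p.planned_dose is not None:
                write_volume(p.planned_dose, out_dir / f"{p.patient_id}_planned.nii")
        prov = dict(
            config={
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            master_seed=config.master_seed,
            planted_effects=dict(
                beta_delta_per_gy=config.effect_beta_delta,
                beta_planned_per_gy=config.effect_beta_planned,
                dose_threshold_window_gy=list(config.dose_threshold_window),
            ),
            sensitive_region_file="reference_sensitive_mask.nii",
        )
        (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out_dir}: {exc}") from exc
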