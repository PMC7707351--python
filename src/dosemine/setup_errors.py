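"""IGRT setup-error simulation and residual-error bookkeeping.

Per-fraction patient setup errors follow the standard decomposition
into a systematic component (drawn once per patient) and random
components (drawn independently per fraction), per axis. An image
guidance protocol images a subset of fractions; at an imaged fraction
the measured error triggers an online couch correction only when it
exceeds the action threshold (5 mm by default), so small errors remain
as residuals. Non-imaged fractions carry the full setup error.

The heart-shift summary quantifies whether a residual error moves the
heart towards the high-dose target region: it is the change in the
distance between target and heart centres of mass when the residual is
applied, negative when the heart ends up closer to the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IGRTProtocol",
    "FractionRecord",
    "CourseSummary",
    "weekly_imaging_fractions",
    "sample_fraction_errors",
    "apply_igrt_protocol",
    "heart_shift_metric",
    "summarise_course",
]


def weekly_imaging_fractions(n_fractions: int, per_week: int = 5) -> frozenset:
    """Imaging at fractions 1-3, then the first fraction of each later week.

    For a 20-fraction course at 5 fractions/week this yields {1,2,3,8,13,18}.
    """
    days = {1, 2, 3}
    f = 3 + per_week
    while f <= n_fractions:
        days.add(f)
        f += per_week
    return frozenset(d for d in days if d <= n_fractions)


@dataclass(frozen=True)
class IGRTProtocol:
    """Imaging schedule and correction rule.

    threshold_rule 'per_axis' corrects when any axis exceeds the action
    threshold; 'vector_norm' compares the 3-D error magnitude instead.
    estimate_unimaged 'truth' uses the actual setup error at non-imaged
    fractions; 'locf' carries the most recent imaged residual forward,
    mimicking what is observable clinically with weekly imaging.
    """

    action_threshold: float = 5.0
    imaging_fractions: frozenset = field(default_factory=lambda: weekly_imaging_fractions(20))
    threshold_rule: str = "per_axis"
    estimate_unimaged: str = "truth"

    def __post_init__(self) -> None:
        if self.action_threshold <= 0:
            raise ValueError("action_threshold must be > 0")
        if self.threshold_rule not in ("per_axis", "vector_norm"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.estimate_unimaged not in ("truth", "locf"):
            raise ValueError(f"unknown estimate_unimaged {self.estimate_unimaged!r}")

    def exceeds(self, error: np.ndarray) -> bool:
        if self.threshold_rule == "per_axis":
            return bool(np.any(np.abs(error) > self.action_threshold))
        return bool(np.linalg.norm(error) > self.action_threshold)


@dataclass
class FractionRecord:
    """One fraction's setup error and what the protocol did with it."""

    fraction_index: int
    setup_error: np.ndarray
    imaged: bool = False
    corrected: bool = False
    residual: np.ndarray | None = None


@dataclass
class CourseSummary:
    mean_residual: np.ndarray
    mean_heart_shift: float


def sample_fraction_errors(systematic_sd, random_sd, n_fractions: int, rng) -> list:
    """Draw per-fraction setup errors Σ + δ_f.

    Σ ~ N(0, systematic_sd²) once per patient; δ_f ~ N(0, random_sd²)
    i.i.d. per fraction; independent per axis. SDs are mm, scalar or
    per-axis 3-vectors.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    sys_sd = np.broadcast_to(np.asarray(systematic_sd, dtype=float), (3,))
    rand_sd = np.broadcast_to(np.asarray(random_sd, dtype=float), (3,))
    if np.any(sys_sd < 0) or np.any(rand_sd < 0):
        raise ValueError("error SDs must be >= 0")
    rng = np.random.default_rng(rng)
    systematic = rng.normal(0.0, sys_sd)
    random_part = rng.normal(0.0, rand_sd, size=(n_fractions, 3))
    return [
        FractionRecord(fraction_index=f + 1, setup_error=systematic + random_part[f])
        for f in range(n_fractions)
    ]


def apply_igrt_protocol(records: list, protocol: IGRTProtocol) -> list:
    """Fill imaged/corrected/residual on a fraction series.

    At imaged fractions a correction is applied only when the error
    exceeds the action threshold; correction is assumed perfect
    (residual exactly zero) and purely online (no carry-over to later
    fractions). Non-imaged fractions keep the full setup error as
    residual ('truth' mode) or the last imaged residual ('locf').
    """
    n = len(records)
    if any(f > n or f < 1 for f in protocol.imaging_fractions):
        raise ValueError(
            f"imaging fractions {sorted(protocol.imaging_fractions)} out of range 1..{n}"
        )
    out = []
    last_imaged_residual = np.zeros(3)
    for rec in sorted(records, key=lambda r: r.fraction_index):
        err = np.asarray(rec.setup_error, dtype=float)
        if rec.fraction_index in protocol.imaging_fractions:
            corrected = protocol.exceeds(err)
            residual = np.zeros(3) if corrected else err.copy()
            last_imaged_residual = residual
            out.append(replace(rec, imaged=True, corrected=corrected, residual=residual))
        else:
            if protocol.estimate_unimaged == "locf":
                residual = last_imaged_residual.copy()
            else:
                residual = err.copy()
            out.append(replace(rec, imaged=False, corrected=False, residual=residual))
    return out


def heart_shift_metric(target_com, heart_com, residual) -> float:
    """Signed change (mm) in target–heart distance under a residual error.

    Returns |heart + residual − target| − |heart − target|; negative
    values mean the residual brings the heart closer to the high-dose
    region around the target.
    """
    target_com = np.asarray(target_com, dtype=float)
    heart_com = np.asarray(heart_com, dtype=float)
    residual = np.asarray(residual, dtype=float)
    baseline = np.linalg.norm(heart_com - target_com)
    if baseline == 0:
        raise ValueError("target and heart centres of mass coincide")
    return float(np.linalg.norm(heart_com + residual - target_com) - baseline)


def summarise_course(records: list, target_com, heart_com) -> CourseSummary:
    """Per-axis mean residual and mean heart shift over all fractions."""
    if not records:
        raise ValueError("summarise_course requires at least one record")
    residuals = np.array([r.residual for r in records], dtype=float)
    if residuals.ndim != 2 or np.any([r.residual is None for r in records]):
        raise ValueError("records must have residuals filled (run apply_igrt_protocol)")
    shifts = [heart_shift_metric(target_com, heart_com, r) for r in residuals]
    return CourseSummary(
        mean_residual=residuals.mean(axis=0),
        mean_heart_shift=float(np.mean(shifts)),
    )
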