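"""Shift-invariant dose accumulation.

Delivered dose under a rigid residual setup error is approximated by
translating the planned dose distribution relative to the patient
("shift invariance"): an anatomy point displaced by ``r`` receives the
planned dose at its shifted room position, ``D'(x) = D(x + r)``. The
course dose is the equal-weight average of the per-fraction shifted
grids, and the Δdose map is accumulated minus planned (positive means
more dose delivered than planned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "shift_dose", "accumulate", "delta_dose"]


@dataclass
class DoseGrid:
    """A 3-D scalar field on a regular lattice with world geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Dose in Gy (signed for Δdose maps).
    spacing : ndarray, shape (3,)
        Voxel size in mm per axis.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.array([4.0, 4.0, 4.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"DoseGrid expects a 3-D array, got ndim={self.values.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DoseGrid values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def same_geometry(self, other: "DoseGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def voxel_centers(self) -> tuple:
        """World coordinates of voxel centres, one 1-D array per axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


def _slices_for(shape, k) -> tuple | None:
    """(dst, src) slice tuples realising out[i] = arr[i + k], or None if empty."""
    src, dst = [], []
    for a in range(3):
        n = shape[a]
        ka = int(k[a])
        if ka >= n or ka <= -n:
            return None
        if ka >= 0:
            src.append(slice(ka, n))
            dst.append(slice(0, n - ka))
        else:
            src.append(slice(0, n + ka))
            dst.append(slice(-ka, n))
    return tuple(dst), tuple(src)


def _shift_values(vals: np.ndarray, spacing: np.ndarray, shift_mm: np.ndarray,
                  out: np.ndarray | None = None, weight: float = 1.0) -> np.ndarray:
    """Trilinear ``out += weight * vals(x + shift)`` with zero fill outside.

    The interpolation is the weighted sum of the 8 integer shifts
    surrounding the fractional voxel shift, accumulated in place.
    """
    t = shift_mm / spacing  # shift in voxel units
    n = np.floor(t).astype(int)
    f = t - n
    if out is None:
        out = np.zeros_like(vals)
    for cx in (0, 1):
        wx = (1.0 - f[0]) if cx == 0 else f[0]
        for cy in (0, 1):
            wy = (1.0 - f[1]) if cy == 0 else f[1]
            for cz in (0, 1):
                wz = (1.0 - f[2]) if cz == 0 else f[2]
                w = weight * wx * wy * wz
                if w == 0.0:
                    continue
                sl = _slices_for(vals.shape, (n[0] + cx, n[1] + cy, n[2] + cz))
                if sl is None:
                    continue
                dst, src = sl
                out[dst] += vals[src] * vals.dtype.type(w)
    return out


def shift_dose(dose: DoseGrid, shift_mm) -> DoseGrid:
    """Sample the dose at positions displaced by ``shift_mm``.

    Returns a grid with ``out(x) = dose(x + shift_mm)`` via trilinear
    interpolation; positions outside the grid sample 0 Gy. ``shift_mm``
    is the patient displacement in world mm.
    """
    shift_mm = np.asarray(shift_mm, dtype=float)
    if shift_mm.shape != (3,) or not np.all(np.isfinite(shift_mm)):
        raise ValueError(f"shift must be a finite 3-vector, got {shift_mm}")
    vals = dose.values if np.issubdtype(dose.values.dtype, np.floating) \
        else dose.values.astype(np.float32)
    out = _shift_values(vals, dose.spacing, shift_mm)
    return DoseGrid(out, dose.spacing.copy(), dose.origin.copy())


def accumulate(planned: DoseGrid, residuals) -> DoseGrid:
    """Average the planned grid shifted by each fraction's residual error.

    ``residuals`` is an ordered sequence of per-fraction 3-vectors (mm).
    Each fraction delivers 1/n of the course, so the accumulated course
    dose is the mean of the per-fraction shifted grids.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if residuals.size == 0:
        raise ValueError("accumulate requires at least one residual")
    if residuals.shape[1] != 3:
        raise ValueError(f"residuals must be (n, 3), got {residuals.shape}")
    vals = planned.values if np.issubdtype(planned.values.dtype, np.floating) \
        else planned.values.astype(np.float32)
    # Aggregate the trilinear corner weights of every fraction onto the
    # integer-offset lattice first: residuals span only a few voxels, so the
    # whole course collapses to a handful of integer shifts of the grid.
    corner_w: dict = {}
    for r in residuals:
        t = r / planned.spacing
        n = np.floor(t).astype(int)
        f = t - n
        for cx in (0, 1):
            wx = (1.0 - f[0]) if cx == 0 else f[0]
            for cy in (0, 1):
                wy = (1.0 - f[1]) if cy == 0 else f[1]
                for cz in (0, 1):
                    wz = (1.0 - f[2]) if cz == 0 else f[2]
                    w = wx * wy * wz
                    if w == 0.0:
                        continue
                    key = (n[0] + cx, n[1] + cy, n[2] + cz)
                    corner_w[key] = corner_w.get(key, 0.0) + w
    total = np.zeros(planned.shape, dtype=vals.dtype)
    nfrac = float(residuals.shape[0])
    for key, w in corner_w.items():
        sl = _slices_for(planned.shape, key)
        if sl is None:
            continue
        dst, src = sl
        # per-key division keeps w == n exactly 1, so zero residuals
        # reproduce the planned grid bit for bit
        total[dst] += vals[src] * vals.dtype.type(w / nfrac)
    return DoseGrid(total, planned.spacing.copy(), planned.origin.copy())


def delta_dose(accumulated: DoseGrid, planned: DoseGrid) -> DoseGrid:
    """Δdose = accumulated − planned, voxel-wise, on identical geometry.

    Positive values mean a higher delivered dose than planned.
    """
    if not accumulated.same_geometry(planned):
        raise ValueError(
            "delta_dose requires identical geometry: "
            f"shapes {accumulated.shape} vs {planned.shape}, "
            f"spacing {accumulated.spacing} vs {planned.spacing}"
        )
    vals = accumulated.values - planned.values
    return DoseGrid(vals, planned.spacing.copy(), planned.origin.copy())
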