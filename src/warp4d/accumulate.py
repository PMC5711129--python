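"""Dose warping, path-integrated accumulation, AIP and dose-difference stats.

The core 4D computation: each phase's dose distribution is morphed back to
the reference (end-expiration) phase through that phase's DVF, and the
warped doses are combined with equal weights (the phases are equal time
bins of the breathing cycle), giving the path-integrated cumulative dose —
a closer estimate of delivered dose than the static 3D calculation.

Reduced-phase accumulation uses the standard subset schemes: p2 (the two
extreme phases), p3, p5even, p5odd and the full p10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import (
    ScalarVolume,
    StructureMask,
    VectorField,
    _require_same_grid,
)

__all__ = [
    "PhaseDoseSet",
    "PhaseSubset",
    "PHASE_SUBSETS",
    "warp_dose",
    "accumulate",
    "phase_subset",
    "average_intensity_projection",
    "dose_difference_map",
    "max_point_difference_pct",
]

PHASE_SUBSETS: dict[str, tuple[str, ...]] = {
    "p2": ("0%", "50%"),
    "p3": ("30%", "60%", "90%"),
    "p5even": ("0%", "20%", "40%", "60%", "80%"),
    "p5odd": ("10%", "30%", "50%", "70%", "90%"),
    "p10": tuple(f"{10 * k}%" for k in range(10)),
}


@dataclass(frozen=True)
class PhaseSubset:
    """A named phase-sampling scheme for reduced-phase accumulation."""

    name: str
    members: tuple[str, ...]

    @property
    def weights(self) -> np.ndarray:
        return np.full(len(self.members), 1.0 / len(self.members))


def phase_subset(name: str) -> PhaseSubset:
    if name not in PHASE_SUBSETS:
        raise ValueError(
            f"unknown phase subset {name!r}; expected one of {sorted(PHASE_SUBSETS)}")
    return PhaseSubset(name, PHASE_SUBSETS[name])


@dataclass
class PhaseDoseSet:
    """Per-phase doses on the reference grid with accumulation weights."""

    phases: list[str]
    doses: list[ScalarVolume]
    weights: np.ndarray | None = None

    def __post_init__(self):
        if len(self.phases) != len(self.doses) or not self.doses:
            raise ValueError("need one dose per phase (and at least one phase)")
        if self.weights is None:
            self.weights = np.full(len(self.doses), 1.0 / len(self.doses))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.doses),):
            raise ValueError("need one weight per phase")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.weights.sum()!r}")
        for d in self.doses[1:]:
            _require_same_grid(self.doses[0], d, "phase doses")


def warp_dose(dose: ScalarVolume, dvf: VectorField) -> ScalarVolume:
    """Morph a phase dose back to the reference anatomy through a DVF.

    output(x) = dose(x + u(x)) by trilinear sampling (pull-back convention);
    points displaced outside the dose grid contribute 0 Gy.
    """
    _require_same_grid(dose, dvf, "dose/DVF")
    dose.require_nonnegative()
    spacing = np.asarray(dose.grid.spacing)
    idx = np.indices(dose.grid.shape, dtype=np.float64)
    for a in range(3):
        idx[a] += dvf.displacements[..., a] / spacing[a]
    warped = ndimage.map_coordinates(dose.values, idx, order=1,
                                     mode="constant", cval=0.0)
    return ScalarVolume(dose.grid, np.maximum(warped, 0.0), unit="Gy")


def accumulate(dose_set: PhaseDoseSet) -> ScalarVolume:
    """Weighted voxel-wise sum of the warped phase doses."""
    acc = np.zeros(dose_set.doses[0].grid.shape, dtype=np.float64)
    for w, d in zip(dose_set.weights, dose_set.doses):
        acc += w * d.values
    return ScalarVolume(dose_set.doses[0].grid, acc, unit="Gy")


def average_intensity_projection(phase_cts: list[ScalarVolume]) -> ScalarVolume:
    """Voxel-wise mean of the phase CTs — the static planning image (AIP)."""
    if not phase_cts:
        raise ValueError("need at least one phase CT")
    for ct in phase_cts[1:]:
        _require_same_grid(phase_cts[0], ct, "phase CTs")
    mean = np.mean([ct.values for ct in phase_cts], axis=0)
    return ScalarVolume(phase_cts[0].grid, mean, unit=phase_cts[0].unit)


def dose_difference_map(a: ScalarVolume, b: ScalarVolume) -> ScalarVolume:
    """Voxel-wise dose difference a - b in Gy (hot/cold spot map)."""
    _require_same_grid(a, b, "dose volumes")
    return ScalarVolume(a.grid, a.values - b.values, unit="Gy")


def max_point_difference_pct(diff: ScalarVolume, roi: StructureMask,
                             reference_scale_gy: float) -> float:
    """Maximum |dose difference| inside a ROI, as % of a reference dose.

    The reference scale defaults (by convention of the callers) to the
    prescription dose; pass a local dose value for local normalization.
    """
    _require_same_grid(diff, roi, "difference map/ROI")
    if roi.is_empty():
        raise ValueError("ROI is empty")
    if reference_scale_gy <= 0:
        raise ValueError("reference scale must be positive")
    return float(np.max(np.abs(diff.values[roi.member])) / reference_scale_gy * 100.0)
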