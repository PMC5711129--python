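"""Dose-volume histograms and plan-quality statistics.

Implements the metrics used to compare static 3D and accumulated 4D dose
distributions: cumulative DVHs, Dx percentile doses (D2 near-maximum, D98
near-minimum, D95 coverage, D50 median), mean dose, the homogeneity index
HI = D2/D98 (unity = perfectly homogeneous), the DVH-based biologically
effective dose

    BED_i = n d_i (1 + d_i / (alpha/beta)),   d_i = (bin dose) / n,

with alpha/beta = 10 Gy for tumor and 2 Gy for late normal-liver toxicity,
the 3D-to-4D homogeneity ratio HI3D/HI4D (%), fractional-volume ratio
curves over the D98-D50 sub-range (the reduced-phase convergence
diagnostic), and the GTV-centroid motion vector r3D.

Conventions (treatment-planning-system binning is vendor-specific, so they
are fixed here): bin width 0.01 Gy; Dx means "at least x% of the volume
receives >= Dx", linearly interpolated between bin edges; Dmean is the
voxel mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ScalarVolume, StructureMask, _require_same_grid

__all__ = [
    "DVHCurve",
    "FractionationScheme",
    "TargetMetrics",
    "compute_dvh",
    "dose_at_volume",
    "mean_dose",
    "homogeneity_index",
    "hi_ratio_percent",
    "bed_from_dvh",
    "bed_uniform",
    "dvh_fractional_volume_ratio",
    "motion_vector",
]

DEFAULT_BIN_WIDTH_GY = 0.01


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``cumulative_fraction[i]`` is the fraction of the structure volume
    receiving at least ``bin_edges[i]`` Gy; starts at 1 (every voxel
    receives >= 0 Gy) and is non-increasing.
    """

    bin_edges: np.ndarray
    cumulative_fraction: np.ndarray
    structure_name: str = ""
    total_volume_cc: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float)
        if self.bin_edges.shape != self.cumulative_fraction.shape:
            raise ValueError("bin_edges and cumulative_fraction differ in length")
        if self.cumulative_fraction.size == 0:
            raise ValueError("empty DVH")
        if abs(self.cumulative_fraction[0] - 1.0) > 1e-12:
            raise ValueError("cumulative DVH must start at fraction 1")
        if np.any(np.diff(self.cumulative_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def fraction_at(self, dose_gy) -> np.ndarray:
        """Fractional volume receiving at least the given dose(s)."""
        return np.interp(dose_gy, self.bin_edges, self.cumulative_fraction)


@dataclass(frozen=True)
class FractionationScheme:
    """Number of fractions and tissue alpha/beta for BED conversion."""

    n_fractions: int
    alpha_beta_gy: float
    per_fraction_reference_gy: float | None = None

    def __post_init__(self):
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha/beta must be positive")


def compute_dvh(dose: ScalarVolume, mask: StructureMask,
                bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> DVHCurve:
    """Cumulative DVH of a dose distribution over a structure."""
    _require_same_grid(dose, mask, "dose/structure")
    if mask.is_empty():
        raise ValueError(f"structure {mask.name!r} is empty")
    if bin_width_gy <= 0:
        raise ValueError("bin width must be positive")
    dose.require_nonnegative()
    voxel_doses = np.sort(dose.values[mask.member])
    dmax = voxel_doses[-1]
    n_bins = int(np.ceil(dmax / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    # voxels receiving >= edge
    frac = (voxel_doses.size
            - np.searchsorted(voxel_doses, edges, side="left")) / voxel_doses.size
    frac[0] = 1.0
    return DVHCurve(edges, frac, structure_name=mask.name,
                    total_volume_cc=mask.volume_cc)


def dose_at_volume(dvh: DVHCurve, x_percent: float) -> float:
    """Dx: the largest dose received by at least x% of the volume."""
    if not 0.0 < x_percent <= 100.0:
        raise ValueError(f"x must be in (0, 100], got {x_percent}")
    f = x_percent / 100.0
    frac = dvh.cumulative_fraction
    edges = dvh.bin_edges
    # largest edge whose fraction still covers f (frac[0] = 1 >= f always)
    i = int(np.nonzero(frac >= f)[0][-1])
    if i == frac.size - 1 or frac[i] == f:
        return float(edges[i])
    # interpolate within the bin where the curve crosses f
    return float(edges[i] + (frac[i] - f) / (frac[i] - frac[i + 1])
                 * (edges[i + 1] - edges[i]))


def mean_dose(dose: ScalarVolume, mask: StructureMask) -> float:
    """Unweighted mean dose over member voxels (Gy)."""
    _require_same_grid(dose, mask, "dose/structure")
    if mask.is_empty():
        raise ValueError(f"structure {mask.name!r} is empty")
    return float(dose.values[mask.member].mean())


def homogeneity_index(d2_gy: float, d98_gy: float) -> float:
    """HI = D2/D98; unity implies perfect homogeneity."""
    if d98_gy <= 0:
        raise ValueError(f"D98 must be positive, got {d98_gy}")
    return float(d2_gy) / float(d98_gy)


def hi_ratio_percent(hi_3d: float, hi_4d: float) -> float:
    """HI3D/4D% = 100 * HI_3D / HI_4D (3D homogeneity overestimate)."""
    if hi_4d <= 0:
        raise ValueError(f"4D HI must be positive, got {hi_4d}")
    return 100.0 * float(hi_3d) / float(hi_4d)


def bed_uniform(total_dose_gy: float, scheme: FractionationScheme) -> float:
    """BED of a uniform total dose D: D (1 + D / (n * alpha/beta))."""
    d = total_dose_gy / scheme.n_fractions
    return scheme.n_fractions * d * (1.0 + d / scheme.alpha_beta_gy)


def bed_from_dvh(dvh: DVHCurve, scheme: FractionationScheme) -> dict:
    """DVH-based BED: apply the fractionation correction bin by bin.

    Each differential-DVH bin carries total dose D_i (bin center), i.e.
    per-fraction dose d_i = D_i/n, and contributes its fractional volume at
    BED_i = n d_i (1 + d_i/(alpha/beta)). Returns the BED-transformed
    cumulative curve and the volume-weighted BEDmean.
    """
    frac = dvh.cumulative_fraction
    edges = dvh.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    diff_vol = frac[:-1] - frac[1:]
    bed_centers = np.array([bed_uniform(c, scheme) for c in centers])
    bedmean = float(np.sum(diff_vol * bed_centers))  # diff_vol sums to 1 - frac[-1]
    bedmean += float(frac[-1]) * bed_uniform(float(edges[-1]), scheme)
    bed_edges = np.array([bed_uniform(e, scheme) for e in edges])
    bed_curve = DVHCurve(bed_edges, frac.copy(),
                         structure_name=f"{dvh.structure_name} (BED)",
                         total_volume_cc=dvh.total_volume_cc)
    return {"bed_curve": bed_curve, "BEDmean": bedmean}


def dvh_fractional_volume_ratio(test: DVHCurve, reference: DVHCurve) -> dict:
    """Ratio of fractional volumes over the reference D98-D50 dose sub-range.

    Samples test/reference on the reference bin grid restricted to
    [D98_ref, D50_ref]; the scalar summary is max |ratio - 1| over the
    range. Used to judge how well a reduced-phase accumulation matches the
    full 10-phase curve (and how far the 3D curve sits from the 4D one).
    """
    lo = dose_at_volume(reference, 98.0)
    hi = dose_at_volume(reference, 50.0)
    sel = (reference.bin_edges >= lo) & (reference.bin_edges <= hi)
    if not np.any(sel):  # degenerate range (uniform dose): use nearest edge
        sel = np.zeros(reference.bin_edges.size, dtype=bool)
        sel[np.argmin(np.abs(reference.bin_edges - lo))] = True
    doses = reference.bin_edges[sel]
    ref_frac = reference.cumulative_fraction[sel]
    if np.any(ref_frac <= 0):
        raise ValueError("reference fractional volume vanishes inside D98-D50")
    test_frac = test.fraction_at(doses)
    ratio = test_frac / ref_frac
    return {
        "dose_gy": doses,
        "ratio": ratio,
        "max_abs_deviation": float(np.max(np.abs(ratio - 1.0))),
    }


def motion_vector(centroid_phase_a, centroid_phase_b) -> dict:
    """Per-axis centroid displacement (mm) and its 3D magnitude r3D.

    Axis order of the inputs is the package convention (x=LR, y=AP, z=SI).
    """
    a = np.asarray(centroid_phase_a, dtype=float)
    b = np.asarray(centroid_phase_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("centroids must be 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("centroids must be finite")
    d = np.abs(a - b)
    return {
        "LR": float(d[0]),
        "AP": float(d[1]),
        "SI": float(d[2]),
        "r3D": float(np.linalg.norm(d)),
    }


@dataclass
class TargetMetrics:
    """Per-structure plan-quality summary under one calculation scheme."""

    structure_name: str
    calculation_tag: str  # 3DREF | 3DAIP | 4D | 4D_p2 | ...
    volume_cc: float
    Dmean: float
    D2: float
    D50: float
    D95: float
    D98: float
    HI: float
    BEDmean: float

    @classmethod
    def compute(cls, dose: ScalarVolume, mask: StructureMask,
                scheme: FractionationScheme, tag: str,
                bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> "TargetMetrics":
        dvh = compute_dvh(dose, mask, bin_width_gy)
        d2 = dose_at_volume(dvh, 2.0)
        d98 = dose_at_volume(dvh, 98.0)
        return cls(
            structure_name=mask.name,
            calculation_tag=tag,
            volume_cc=mask.volume_cc,
            Dmean=mean_dose(dose, mask),
            D2=d2,
            D50=dose_at_volume(dvh, 50.0),
            D95=dose_at_volume(dvh, 95.0),
            D98=d98,
            HI=homogeneity_index(d2, d98) if d98 > 0 else float("nan"),
            BEDmean=bed_from_dvh(dvh, scheme)["BEDmean"],
        )

    def as_dict(self) -> dict:
        return {
            "structure": self.structure_name,
            "calculation": self.calculation_tag,
            "volume_cc": self.volume_cc,
            "Dmean": self.Dmean,
            "D2": self.D2,
            "D50": self.D50,
            "D95": self.D95,
            "D98": self.D98,
            "HI": self.HI,
            "BEDmean": self.BEDmean,
        }
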