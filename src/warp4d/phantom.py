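"""Deformable digital liver phantom with analytic ground-truth motion.

Emulates a 10-phase respiratory-correlated CT study: a soft-tissue body
ellipsoid containing a liver ellipsoid and an embedded spherical tumor,
breathing with a dominant superior-inferior displacement (clinically 7-17 mm
for liver lesions) plus minor AP/LR components. Phase 50% (end-expiration)
is the reference: displacement there is zero, maximal at phase 0%
(end-inspiration).

The phase-k deformation of a reference point ``x`` is

    phi_k(x) = x + w_k * e(x) * A

with ``w_k`` a scalar waveform (1 at 0%, 0 at 50%), ``e`` a smooth spatial
envelope (1 in the liver region, falling smoothly to 0 at the body surface,
so the couch/body edge stays fixed), and ``A`` the per-axis amplitude in mm.
The map is an analytic diffeomorphism (the envelope gradient keeps
``|d(w e A)/dx| < 1``), so phase images and masks are generated by exact
pull-back through its numerically-inverted fixed point, and every pipeline
estimate can be compared against noise-free analytic ground truth.

A static conformal dose cloud stands in for a per-phase dose-engine
recalculation: the dose distribution is held fixed in room coordinates
across phases. For liver (small density changes) this preserves the
motion-versus-dose-gradient interplay being quantified; see the methods
note for the fidelity discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid3D, ScalarVolume, StructureMask, VectorField, sample_trilinear

__all__ = [
    "PHASE_LABELS",
    "LESION_PRESETS",
    "LesionPreset",
    "MotionModel",
    "PhantomSpec",
    "DoseModel",
    "cosine_waveform",
    "cos4_waveform",
    "forward_displacement",
    "true_dvf",
    "generate_phase_ct",
    "generate_phase_masks",
    "generate_phase",
    "generate_static_dose",
    "ground_truth_accumulated_dose",
]

PHASE_LABELS: tuple[str, ...] = tuple(f"{10 * k}%" for k in range(10))
REFERENCE_PHASE = "50%"


def normalize_phase(phase, n_phases: int = 10) -> str:
    """Canonicalize a phase given as '30%', '30' or 3 (bin index)."""
    if isinstance(phase, (int, np.integer)):
        label = f"{10 * int(phase)}%"
    else:
        label = str(phase).strip()
        if not label.endswith("%"):
            label += "%"
    valid = tuple(f"{100 * k // n_phases}%" for k in range(n_phases))
    if label not in valid:
        raise ValueError(f"unknown phase label {phase!r}; expected one of {valid}")
    return label


def phase_index(phase, n_phases: int = 10) -> int:
    return int(normalize_phase(phase, n_phases).rstrip("%")) * n_phases // 100


def cosine_waveform(k: int, n: int = 10) -> float:
    """w_k = (1 + cos(2 pi k / n)) / 2: 1 at phase 0%, 0 at 50%."""
    return (1.0 + np.cos(2.0 * np.pi * k / n)) / 2.0


def cos4_waveform(k: int, n: int = 10) -> float:
    """Squared cosine bell; mimics the longer dwell near end-expiration."""
    return cosine_waveform(k, n) ** 2


@dataclass(frozen=True)
class LesionPreset:
    """Amplitudes and prescription of one study lesion (SI/AP/LR in mm)."""

    amplitude_mm: tuple[float, float, float]  # (LR, AP, SI)
    d95_gy: float
    dose_per_fraction_gy: float
    n_fractions: int
    gtv_cc: float


# Measured patient characteristics: per-lesion centroid displacement between
# the extreme respiratory phases, the achieved D95 and fractionation.
LESION_PRESETS: dict[str, LesionPreset] = {
    "A": LesionPreset((0.9, 4.6, 7.5), 43.7, 7.28, 6, 22.7),
    "B": LesionPreset((1.0, 0.5, 10.5), 41.7, 6.95, 6, 12.4),
    "C": LesionPreset((0.1, 0.0, 7.5), 46.3, 7.72, 6, 54.5),
    "D": LesionPreset((1.2, 1.8, 16.5), 54.5, 10.9, 5, 6.7),
    "E": LesionPreset((1.1, 1.6, 10.5), 44.5, 7.42, 6, 86.2),
}


@dataclass
class MotionModel:
    """Analytic respiratory deformation model.

    amplitude_mm : (A_LR, A_AP, A_SI) peak displacement at envelope = 1.
    waveform : maps phase bin k to w_k in [0, 1]; w = 0 at the reference
        phase (end-expiration, 50%) and 1 at phase 0% (end-inspiration).
    envelope : callable (N, 3) mm points -> weights in [0, 1]; defaults to
        1 everywhere (rigid shift). Phantom factories bind a body-shaped
        envelope via :meth:`PhantomSpec.motion_model`.
    """

    amplitude_mm: tuple[float, float, float] = LESION_PRESETS["E"].amplitude_mm
    n_phases: int = 10
    reference_phase: str = REFERENCE_PHASE
    waveform: Callable[[int, int], float] = cosine_waveform
    envelope: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        self.amplitude_mm = tuple(float(a) for a in self.amplitude_mm)
        k_ref = phase_index(self.reference_phase, self.n_phases)
        if abs(self.waveform(k_ref, self.n_phases)) > 1e-12:
            raise ValueError("waveform must vanish at the reference phase")
        wmax = max(self.waveform(k, self.n_phases) for k in range(self.n_phases))
        if abs(wmax - 1.0) > 1e-9:
            raise ValueError(f"waveform maximum must be 1, got {wmax}")

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(f"{100 * k // self.n_phases}%" for k in range(self.n_phases))

    def weight(self, phase) -> float:
        return float(self.waveform(phase_index(phase, self.n_phases), self.n_phases))

    def envelope_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.envelope is None:
            return np.ones(pts.shape[0])
        return np.asarray(self.envelope(pts), dtype=float)

    def displacement(self, points: np.ndarray, phase) -> np.ndarray:
        """Forward displacement u_k(x) = w_k * e(x) * A at reference points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        w = self.weight(phase)
        return w * self.envelope_at(pts)[:, None] * np.asarray(self.amplitude_mm)

    def pull_back(self, points: np.ndarray, phase, tol: float = 1e-4,
                  max_iter: int = 60) -> np.ndarray:
        """Invert the forward map: reference locations of phase-grid points.

        Solves x = y - w e(x) A by fixed-point iteration; the envelope
        Lipschitz bound makes the iteration a contraction.
        """
        y = np.atleast_2d(np.asarray(points, dtype=float))
        w = self.weight(phase)
        if w == 0.0:
            return y.copy()
        amp = np.asarray(self.amplitude_mm)
        x = y.copy()
        for _ in range(max_iter):
            x_new = y - w * self.envelope_at(x)[:, None] * amp
            delta = np.max(np.abs(x_new - x))
            x = x_new
            if delta < tol:
                break
        return x


def forward_displacement(model: MotionModel, phase, points: np.ndarray) -> np.ndarray:
    """Ground-truth displacement (mm) of reference points at a phase."""
    return model.displacement(points, phase)


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the digital liver phantom.

    Ellipsoid centers/radii in mm world coordinates; the grid is centered
    on the body by default (96^3 voxels at 3 mm, mirroring a typical
    abdominal dose-grid resolution). Tissue HU: air -1000, soft tissue 40,
    liver 60, tumor 100, plus seeded Gaussian noise (SD 10 HU default).
    """

    grid: Grid3D = None
    body_center: tuple = (0.0, 0.0, 0.0)
    body_radii: tuple = (125.0, 105.0, 135.0)
    liver_center: tuple = (32.0, 8.0, 18.0)
    liver_radii: tuple = (68.0, 55.0, 72.0)
    tumor_center: tuple = (40.0, 8.0, 8.0)
    tumor_radius_mm: float = 18.0
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_liver: float = 60.0
    hu_tumor: float = 100.0
    noise_sd_hu: float = 10.0
    envelope_plateau: float = 0.60  # body-fraction radius where motion is full

    def __post_init__(self):
        if self.grid is None:
            shape = (96, 96, 96)
            spacing = (3.0, 3.0, 3.0)
            origin = tuple(
                self.body_center[a] - (shape[a] - 1) * spacing[a] / 2.0
                for a in range(3)
            )
            self.grid = Grid3D(shape, spacing, origin)
        for v in (self.hu_air, self.hu_soft, self.hu_liver, self.hu_tumor):
            if not -1024.0 <= v <= 3071.0:
                raise ValueError(f"HU value {v} outside [-1024, 3071]")
        self._check_nesting()

    def _check_nesting(self):
        # tumor sphere inside liver ellipsoid inside body ellipsoid
        tc = np.asarray(self.tumor_center, float)
        lc = np.asarray(self.liver_center, float)
        lr = np.asarray(self.liver_radii, float)
        rho = np.linalg.norm((tc - lc) / lr)
        if rho + self.tumor_radius_mm / lr.min() > 1.0:
            raise ValueError("tumor sphere is not contained in the liver ellipsoid")
        bc = np.asarray(self.body_center, float)
        br = np.asarray(self.body_radii, float)
        if np.linalg.norm((lc - bc) / (br - lr.max())) > 1.0:
            raise ValueError("liver ellipsoid is not contained in the body ellipsoid")

    # -- analytic geometry -------------------------------------------------
    def body_rho(self, pts: np.ndarray) -> np.ndarray:
        """Normalized elliptical radius: 0 at body center, 1 at surface."""
        p = np.atleast_2d(pts)
        return np.sqrt(np.sum(((p - np.asarray(self.body_center))
                               / np.asarray(self.body_radii)) ** 2, axis=1))

    def tissue_hu(self, pts: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(pts)
        hu = np.full(p.shape[0], self.hu_air)
        in_body = self.body_rho(p) <= 1.0
        hu[in_body] = self.hu_soft
        lrho = np.sqrt(np.sum(((p - np.asarray(self.liver_center))
                               / np.asarray(self.liver_radii)) ** 2, axis=1))
        hu[lrho <= 1.0] = self.hu_liver
        trho = np.linalg.norm(p - np.asarray(self.tumor_center), axis=1)
        hu[trho <= self.tumor_radius_mm] = self.hu_tumor
        return hu

    def in_structure(self, pts: np.ndarray, name: str) -> np.ndarray:
        p = np.atleast_2d(pts)
        if name == "body":
            return self.body_rho(p) <= 1.0
        if name == "liver":
            lrho = np.sqrt(np.sum(((p - np.asarray(self.liver_center))
                                   / np.asarray(self.liver_radii)) ** 2, axis=1))
            return lrho <= 1.0
        if name == "GTV":
            return np.linalg.norm(p - np.asarray(self.tumor_center), axis=1) \
                <= self.tumor_radius_mm
        raise ValueError(f"unknown structure {name!r}")

    def envelope(self, pts: np.ndarray) -> np.ndarray:
        """Smoothstep motion weight: 1 inside the liver-bearing core,
        decaying to 0 at the body surface (and beyond)."""
        rho = self.body_rho(pts)
        t = np.clip((rho - self.envelope_plateau) / (1.0 - self.envelope_plateau),
                    0.0, 1.0)
        return 1.0 - (3.0 * t**2 - 2.0 * t**3)

    def motion_model(self, amplitude_mm=None, waveform=cosine_waveform,
                     n_phases: int = 10) -> MotionModel:
        """Motion model with the phantom's body-shaped envelope bound in."""
        if amplitude_mm is None:
            amplitude_mm = LESION_PRESETS["E"].amplitude_mm
        return MotionModel(amplitude_mm=tuple(amplitude_mm), n_phases=n_phases,
                           waveform=waveform, envelope=self.envelope)


@dataclass
class DoseModel:
    """Conformal static dose cloud parameters.

    The prescription is delivered at the covering isodose (default 80%,
    so Dmax = prescription / 0.8, i.e. a 125% hot center typical of SBRT);
    the penumbra falls off as a Gaussian of width ``penumbra_sigma`` mm
    outside a high-dose core so that the steep-gradient/ motion interplay
    is observable at the target edge.
    """

    prescription_gy: float = 42.0
    covering_isodose: float = 0.80
    penumbra_sigma_mm: float = 5.0
    covering_volume_pct: float = 95.0  # D at this % of PTV equals prescription

    def __post_init__(self):
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if not 0.0 < self.covering_isodose <= 1.0:
            raise ValueError("covering isodose must be in (0, 1]")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be positive")

    @property
    def dmax_gy(self) -> float:
        return self.prescription_gy / self.covering_isodose


def _phase_seed(seed: int, phase_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), phase_idx]))


def _grid_points(grid: Grid3D) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


def generate_phase_ct(spec: PhantomSpec, model: MotionModel, phase,
                      seed: int = 0) -> ScalarVolume:
    """CT-like phase volume: tissue HU pulled back through the phase map,
    plus seeded Gaussian noise. Deterministic given (spec, model, phase, seed)."""
    ct, _ = generate_phase(spec, model, phase, seed, masks=False)
    return ct


def generate_phase_masks(spec: PhantomSpec, model: MotionModel,
                         phase) -> dict[str, StructureMask]:
    """Analytic GTV / liver / body masks under the phase deformation."""
    _, masks = generate_phase(spec, model, phase, seed=0, ct=False)
    return masks


def generate_phase(spec: PhantomSpec, model: MotionModel, phase, seed: int = 0,
                   ct: bool = True, masks: bool = True):
    """Generate CT and/or masks for one phase with a single pull-back solve."""
    label = normalize_phase(phase, model.n_phases)
    grid = spec.grid
    pts = _grid_points(grid)
    ref_pts = model.pull_back(pts, label)

    ct_vol = None
    if ct:
        hu = spec.tissue_hu(ref_pts).reshape(grid.shape)
        if spec.noise_sd_hu > 0:
            rng = _phase_seed(seed, phase_index(label, model.n_phases))
            hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=grid.shape)
        ct_vol = ScalarVolume(grid, hu, unit="HU")

    mask_dict = None
    if masks:
        mask_dict = {}
        for name in ("GTV", "liver", "body"):
            member = spec.in_structure(ref_pts, name).reshape(grid.shape)
            mask_dict[name] = StructureMask(grid, member, name=name)
    return ct_vol, mask_dict


def true_dvf(model: MotionModel, grid: Grid3D, phase) -> VectorField:
    """Ground-truth pull-back DVF on the reference grid for one phase.

    In the pull-back convention the field at a reference voxel x points to
    that tissue element's location in the phase image, which is exactly the
    forward displacement u_k(x).
    """
    pts = _grid_points(grid)
    disp = model.displacement(pts, phase)
    return VectorField(grid, disp.reshape(grid.shape + (3,)))


def generate_static_dose(spec: PhantomSpec, dose_model: DoseModel,
                         ptv: StructureMask) -> ScalarVolume:
    """Conformal static dose: flat high-dose core, Gaussian penumbra.

    dose(x) = Dmax * G(x) with G = exp(-max(0, s(x) + t)^2 / (2 sigma^2)),
    where s is the signed Euclidean distance to the PTV surface (negative
    inside) and the core depth t is calibrated so the covering isodose
    surface passes through the PTV at the covering volume percentage:
    D95(PTV) equals the prescription by construction (up to voxelization).
    """
    if ptv.is_empty():
        raise ValueError("PTV mask is empty")
    grid = ptv.grid
    d_out = ndimage.distance_transform_edt(~ptv.member, sampling=grid.spacing)
    d_in = ndimage.distance_transform_edt(ptv.member, sampling=grid.spacing)
    signed = d_out - d_in
    sigma = dose_model.penumbra_sigma_mm
    c = dose_model.covering_isodose
    d_c = sigma * np.sqrt(2.0 * np.log(1.0 / c)) if c < 1.0 else 0.0
    s_q = np.percentile(signed[ptv.member], dose_model.covering_volume_pct)
    core_depth = d_c - s_q
    g = np.exp(-np.maximum(0.0, signed + core_depth) ** 2 / (2.0 * sigma**2))
    return ScalarVolume(grid, dose_model.dmax_gy * g, unit="Gy")


def ground_truth_accumulated_dose(model: MotionModel, static_dose: ScalarVolume,
                                  phases: Sequence = PHASE_LABELS,
                                  weights: Sequence[float] | None = None,
                                  ) -> ScalarVolume:
    """Noise-free oracle accumulation using the analytic displacements.

    At each reference voxel x: sum_k w_k * D(x + u_k(x)), sampling the
    static dose trilinearly at the analytically displaced points. This is
    the ground truth every registration-based estimate is compared against.
    """
    phases = [normalize_phase(p, model.n_phases) for p in phases]
    if weights is None:
        weights = np.full(len(phases), 1.0 / len(phases))
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    grid = static_dose.grid
    pts = _grid_points(grid)
    acc = np.zeros(grid.shape, dtype=np.float64)
    for w, ph in zip(weights, phases):
        disp = model.displacement(pts, ph)
        vals = sample_trilinear(static_dose, pts + disp, out_of_grid=0.0)
        acc += w * vals.reshape(grid.shape)
    return ScalarVolume(grid, acc, unit="Gy")
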