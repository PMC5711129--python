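"""End-to-end study workflow: phantom -> DIR -> warp/accumulate -> metrics.

Reproduces the comparison arms of a 4D plan-evaluation study on the
synthetic phantom (or on externally supplied phase volumes):

* 3DREF  - static dose evaluated with reference-phase contours
           (normal liver = liver minus GTV);
* 3DAIP  - the same static dose evaluated with AIP-workflow contours
           (target = ITV/PTV, normal liver = liver minus ITV);
* 4D     - path-integrated accumulated dose from DIR-warped phase doses
           (equal weights), plus reduced-phase variants p2/p3/p5even/p5odd.

Under the static dose-cloud approximation the 3DREF and 3DAIP arms share
the dose volume and differ only in structures, which is documented in the
methods note. Every stage is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .accumulate import (
    PHASE_SUBSETS,
    PhaseDoseSet,
    accumulate as accumulate_doses,
    average_intensity_projection,
    dose_difference_map,
    max_point_difference_pct,
    phase_subset,
    warp_dose,
)
from . import dvh as dvhm
from . import phantom as ph
from . import registration as reg
from .grid import ScalarVolume, StructureMask, VectorField, centroid, \
    build_targets, mask_boolean

__all__ = ["StudyConfig", "StudyResult", "run_study", "subset_convergence_study"]

log = logging.getLogger("warp4d.study")

TUMOR_ALPHA_BETA = 10.0  # Gy, tumor
LIVER_ALPHA_BETA = 2.0   # Gy, late normal-liver toxicity


@dataclass
class StudyConfig:
    """Everything needed to run one deterministic phantom study."""

    seed: int = 0
    lesion_preset: str = "E"           # Table of per-lesion motion amplitudes
    amplitude_mm: tuple | None = None  # overrides the preset when given
    grid_shape: tuple = (96, 96, 96)
    grid_spacing_mm: tuple = (3.0, 3.0, 3.0)
    noise_sd_hu: float = 10.0
    waveform: str = "cosine"           # cosine | cos4
    prescription_gy: float = 42.0
    n_fractions: int = 6
    covering_isodose: float = 0.80
    penumbra_sigma_mm: float = 5.0
    ptv_margin_mm: float = 5.0
    itv_mode: str = "union"
    registration: reg.RegistrationParams = dc_field(
        default_factory=reg.RegistrationParams)
    subsets: tuple = ("p2", "p3", "p5even", "p5odd")
    dvh_bin_width_gy: float = dvhm.DEFAULT_BIN_WIDTH_GY
    outdir: str | None = None
    save_volumes: bool = False
    save_plots: bool = False

    def build_models(self):
        from .grid import Grid3D
        shape = tuple(int(s) for s in self.grid_shape)
        spacing = tuple(float(s) for s in self.grid_spacing_mm)
        origin = tuple(-(shape[a] - 1) * spacing[a] / 2.0 for a in range(3))
        spec = ph.PhantomSpec(grid=Grid3D(shape, spacing, origin),
                              noise_sd_hu=self.noise_sd_hu)
        amp = self.amplitude_mm
        if amp is None:
            amp = ph.LESION_PRESETS[self.lesion_preset].amplitude_mm
        waveform = {"cosine": ph.cosine_waveform, "cos4": ph.cos4_waveform}[self.waveform]
        motion = spec.motion_model(amplitude_mm=amp, waveform=waveform)
        dose_model = ph.DoseModel(
            prescription_gy=self.prescription_gy,
            covering_isodose=self.covering_isodose,
            penumbra_sigma_mm=self.penumbra_sigma_mm,
        )
        return spec, motion, dose_model

    def to_manifest(self) -> dict:
        # output destination and save switches are not scientific parameters
        skip = ("registration", "outdir", "save_volumes", "save_plots")
        d = {k: v for k, v in self.__dict__.items() if k not in skip}
        d["registration"] = dict(self.registration.__dict__)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class StudyResult:
    """All artifacts of one study run, kept in memory."""

    config: StudyConfig
    spec: ph.PhantomSpec
    motion: ph.MotionModel
    dose_model: ph.DoseModel
    structures: dict[str, StructureMask]
    static_dose: ScalarVolume
    aip: ScalarVolume
    dvfs: dict[str, VectorField]
    warped_doses: dict[str, ScalarVolume]
    accumulated: dict[str, ScalarVolume]       # subset name -> dose
    ground_truth_4d: ScalarVolume
    registration_reports: dict[str, dict]
    max_point_diff_pct: dict[str, float]  # per phase, |warped - static| in liver
    motion_vector: dict
    metrics: list[dvhm.TargetMetrics]

    # -- derived tables ----------------------------------------------------
    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.metrics])

    def metric(self, structure: str, calculation: str) -> dvhm.TargetMetrics:
        for m in self.metrics:
            if m.structure_name == structure and m.calculation_tag == calculation:
                return m
        raise KeyError(f"no metrics for {structure!r}/{calculation!r}")

    def percent_differences(self) -> pd.DataFrame:
        """(3D - 4D)/4D x 100 per structure and quantity, plus HI3D/4D%."""
        rows = []
        pairs = [("GTV", "3DREF"), ("GTV+5mm", "3DREF"),
                 ("ITV", "3DAIP"), ("PTV", "3DAIP"),
                 ("normal_liver_REF", "3DREF"), ("normal_liver_AIP", "3DAIP")]
        for structure, arm in pairs:
            try:
                m3 = self.metric(structure, arm)
                m4 = self.metric(structure, "4D")
            except KeyError:
                continue
            row = {"structure": structure, "arm_3d": arm}
            for q in ("Dmean", "D2", "D98", "BEDmean", "HI"):
                v3, v4 = getattr(m3, q), getattr(m4, q)
                row[f"{q}_pct_diff"] = (v3 - v4) / v4 * 100.0 if v4 else np.nan
            row["HI3D4D_pct"] = dvhm.hi_ratio_percent(m3.HI, m4.HI)
            rows.append(row)
        return pd.DataFrame(rows)

    def report_dict(self) -> dict:
        return {
            "config": self.config.to_manifest(),
            "motion_vector_mm": self.motion_vector,
            "max_point_dose_diff_pct_of_prescription": self.max_point_diff_pct,
            "registration": self.registration_reports,
            "metrics": [m.as_dict() for m in self.metrics],
            "percent_differences": self.percent_differences().to_dict("records"),
        }

    def save(self, outdir: str):
        os.makedirs(outdir, exist_ok=True)
        self.metrics_frame().to_csv(
            os.path.join(outdir, "metrics.csv"), index=False, float_format="%.6f")
        self.percent_differences().to_csv(
            os.path.join(outdir, "percent_differences.csv"),
            index=False, float_format="%.6f")
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, sort_keys=True)
        if self.config.save_plots:
            from . import dvh as dvhm_
            from .accumulate import dose_difference_map
            from .plots import plot_difference_slice, plot_dvh_comparison
            bw = self.config.dvh_bin_width_gy
            ptv = self.structures["PTV"]
            curves = {"3D static": dvhm_.compute_dvh(self.static_dose, ptv, bw)}
            for name, dose in self.accumulated.items():
                curves[f"4D {name}"] = dvhm_.compute_dvh(dose, ptv, bw)
            plot_dvh_comparison(curves, os.path.join(outdir, "dvh_ptv.png"),
                                title="PTV dose-volume histograms")
            diff = dose_difference_map(self.static_dose, self.accumulated["p10"])
            plot_difference_slice(diff, os.path.join(outdir, "dose_diff_coronal.png"),
                                  axis="AP", roi=ptv,
                                  title="3D static minus 4D accumulated (Gy)")
        if self.config.save_volumes:
            from . import io as vio
            vio.write_volume(self.static_dose,
                             os.path.join(outdir, "dose_static.nrrd"))
            vio.write_volume(self.aip, os.path.join(outdir, "ct_aip.nrrd"))
            for name, dose in self.accumulated.items():
                vio.write_volume(dose, os.path.join(outdir, f"dose_4d_{name}.nrrd"))
            for phase, dvf in self.dvfs.items():
                tag = phase.rstrip("%").zfill(2)
                vio.write_vector_field(
                    dvf, os.path.join(outdir, f"dvf_phase_{tag}.nrrd"))
            for name, m in self.structures.items():
                vio.write_mask(m, os.path.join(outdir, f"mask_{name}.nrrd"))


def _fractionation(structure: str, cfg: StudyConfig) -> dvhm.FractionationScheme:
    ab = LIVER_ALPHA_BETA if "liver" in structure.lower() else TUMOR_ALPHA_BETA
    return dvhm.FractionationScheme(cfg.n_fractions, ab)


def run_study(config: StudyConfig | None = None) -> StudyResult:
    """Execute the full workflow; deterministic given ``config.seed``."""
    cfg = config or StudyConfig()
    spec, motion, dose_model = cfg.build_models()
    grid = spec.grid
    phases = motion.phases
    ref = motion.reference_phase

    log.info("generating %d phantom phases", len(phases))
    phase_cts: dict[str, ScalarVolume] = {}
    phase_masks: dict[str, dict] = {}
    for p in phases:
        ct, masks = ph.generate_phase(spec, motion, p, seed=cfg.seed)
        phase_cts[p] = ct
        phase_masks[p] = masks

    aip = average_intensity_projection([phase_cts[p] for p in phases])

    # -- contours and plan -------------------------------------------------
    gtv_ref = phase_masks[ref]["GTV"]
    gtv_insp = phase_masks["0%"]["GTV"]
    liver = phase_masks[ref]["liver"]
    targets = build_targets(gtv_ref, gtv_insp, cfg.ptv_margin_mm, cfg.itv_mode)
    itv, ptv = targets["ITV"], targets["PTV"]
    from .grid import expand_margin
    gtv5 = expand_margin(gtv_ref, cfg.ptv_margin_mm)
    gtv5.name = "GTV+5mm"
    nl_ref = mask_boolean(liver, gtv_ref, "difference")
    nl_ref.name = "normal_liver_REF"
    nl_aip = mask_boolean(liver, itv, "difference")
    nl_aip.name = "normal_liver_AIP"
    structures = {"GTV": gtv_ref, "ITV": itv, "PTV": ptv, "GTV+5mm": gtv5,
                  "liver": liver, "normal_liver_REF": nl_ref,
                  "normal_liver_AIP": nl_aip}

    static_dose = ph.generate_static_dose(spec, dose_model, ptv)

    # -- motion vector (extreme-phase GTV centroids) -----------------------
    mv = dvhm.motion_vector(centroid(gtv_insp), centroid(gtv_ref))

    # -- registration of the 9 non-reference phases ------------------------
    dvfs: dict[str, VectorField] = {ref: VectorField.zero(grid)}
    reg_reports: dict[str, dict] = {}
    for p in phases:
        if p == ref:
            continue
        log.info("registering phase %s -> %s", p, ref)
        result = reg.register(phase_cts[p], phase_cts[ref], cfg.registration)
        dvfs[p] = result.dvf
        reg_reports[p] = result.as_report()

    # -- dose warping and accumulation -------------------------------------
    # static dose cloud: the per-phase dose equals the planned static dose
    warped = {p: warp_dose(static_dose, dvfs[p]) for p in phases}
    # per-phase maximum point-dose difference inside the liver, as a
    # percentage of the prescription (warped phase dose vs static dose)
    max_diff = {
        p: max_point_difference_pct(
            dose_difference_map(warped[p], static_dose), liver,
            dose_model.prescription_gy)
        for p in phases}
    accumulated: dict[str, ScalarVolume] = {}
    for name in ("p10",) + tuple(cfg.subsets):
        subset = phase_subset(name)
        dose_set = PhaseDoseSet(
            phases=list(subset.members),
            doses=[warped[p] for p in subset.members])
        accumulated[name] = accumulate_doses(dose_set)

    ground_truth = ph.ground_truth_accumulated_dose(motion, static_dose, phases)

    # -- metrics ------------------------------------------------------------
    metrics: list[dvhm.TargetMetrics] = []
    arms = {"3DREF": static_dose, "3DAIP": static_dose, "4D": accumulated["p10"]}
    for name in cfg.subsets:
        arms[f"4D_{name}"] = accumulated[name]
    for sname, mask in structures.items():
        scheme = _fractionation(sname, cfg)
        for tag, dose in arms.items():
            metrics.append(dvhm.TargetMetrics.compute(
                dose, mask, scheme, tag, cfg.dvh_bin_width_gy))

    result = StudyResult(
        config=cfg, spec=spec, motion=motion, dose_model=dose_model,
        structures=structures, static_dose=static_dose, aip=aip,
        dvfs=dvfs, warped_doses=warped, accumulated=accumulated,
        ground_truth_4d=ground_truth, registration_reports=reg_reports,
        max_point_diff_pct=max_diff, motion_vector=mv, metrics=metrics)
    if cfg.outdir:
        result.save(cfg.outdir)
    return result


def subset_convergence_study(result: StudyResult,
                             structures: tuple = ("PTV", "normal_liver_AIP"),
                             ) -> pd.DataFrame:
    """Max D98-D50 fractional-volume-ratio deviation of each subset vs p10."""
    rows = []
    for sname in structures:
        mask = result.structures[sname]
        ref_dvh = dvhm.compute_dvh(result.accumulated["p10"], mask,
                                   result.config.dvh_bin_width_gy)
        for name in ("p2", "p3", "p5even", "p5odd", "p10"):
            if name not in result.accumulated:
                continue
            test_dvh = dvhm.compute_dvh(result.accumulated[name], mask,
                                        result.config.dvh_bin_width_gy)
            ratio = dvhm.dvh_fractional_volume_ratio(test_dvh, ref_dvh)
            rows.append({
                "structure": sname,
                "subset": name,
                "n_phases": len(PHASE_SUBSETS[name]),
                "max_abs_deviation": ratio["max_abs_deviation"],
            })
    frame = pd.DataFrame(rows)
    for sname in structures:  # monotonicity is expected, warn when violated
        sub = frame[frame.structure == sname].sort_values("n_phases")
        dev = sub.max_abs_deviation.to_numpy()
        if np.any(np.diff(dev) > 1e-9):
            log.warning("subset convergence not monotone for %s: %s",
                        sname, dev.tolist())
    return frame
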