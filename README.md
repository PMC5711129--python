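# warp4d

Quasi-4D path-integrated dose accumulation for respiratory-phase CT:
deformable image registration (multi-resolution optical flow), DVF-based
dose warping, equal-weighted accumulation over the breathing cycle, and the
DVH plan-quality metrics used to compare 4D-accumulated against
conventional static (3D) dose evaluation in liver SBRT.

Intended for medical-physics researchers evaluating how organ motion
degrades nominally conformal plans: the package quantifies how much a
static calculation overestimates target coverage/homogeneity and
underestimates normal-liver dose, and how many respiratory phases an
accumulation actually needs.

## The method

A 4D CT provides phase volumes at 0%, 10%, …, 90% of the breathing cycle;
end-expiration (50%) is the reference. Each phase is registered to the
reference with Horn–Schunck optical flow, giving a pull-back deformation
vector field `u_k` (`x_source = x + u_k(x)`). Each phase's dose is warped
back to the reference anatomy through its DVF and the warped doses are
averaged with equal weights (equal-time phase bins):

    D_4D(x) = (1/N) Σ_k D_k(x + u_k(x))

Plan quality is read off cumulative DVHs: Dx (D2 near-maximum, D98
near-minimum, D95 coverage), Dmean, the homogeneity index HI = D2/D98
(1 = perfectly homogeneous), and the biologically effective dose per DVH
bin, `BED_i = n·d_i·(1 + d_i/(α/β))` with α/β = 10 Gy for tumor and 2 Gy
for late normal-liver toxicity. Reduced-phase accumulations (p = 2, 3,
5even, 5odd) are compared with the full 10-phase result through the ratio
of fractional volumes over the D98–D50 dose range.

Because clinical 4D CT is not redistributable, the package ships a
deformable digital liver phantom with analytic, invertible ground-truth
motion (dominant superior–inferior amplitude, presets matching published
per-lesion liver excursions of 7.5–16.5 mm) and a conformal static dose
cloud with a steep Gaussian penumbra. The analytic motion yields a
noise-free ground-truth accumulated dose that every registration-based
estimate is validated against. See `docs/methods.md` for the model,
parameter and fidelity details.

## Worked example

```python
import warp4d as w

result = w.run_study(w.StudyConfig(seed=1))       # ~4 min on one CPU
frame = result.metrics_frame()
print(frame.query("structure == 'PTV'")[
    ["structure", "calculation", "Dmean", "D2", "D98", "HI", "BEDmean"]
      ].to_string(index=False))
print({k: round(v, 2) for k, v in result.motion_vector.items()})
```

prints (default phantom: 10.5 mm superior-inferior motion preset, 42 Gy
in 6 fractions prescribed to the 80% covering isodose):

```
structure calculation  Dmean    D2   D98   HI  BEDmean
      PTV       3DREF  48.80 52.51 42.00 1.25    88.85
      PTV       3DAIP  48.80 52.51 42.00 1.25    88.85
      PTV          4D  43.84 52.51 14.45 3.63    78.07
      PTV       4D_p2  43.61 52.51 21.82 2.41    77.15
      PTV       4D_p3  44.23 52.51 14.88 3.53    78.85
      PTV   4D_p5even  43.74 52.51 14.69 3.57    77.86
      PTV    4D_p5odd  43.93 52.51 14.22 3.69    78.28
{'LR': 1.15, 'AP': 1.6, 'SI': 10.43, 'r3D': 10.61}
```

Reading it: the static (3D) evaluation believes the PTV near-minimum dose
is 42 Gy; accumulating the dose actually sampled by moving tissue drops
D98 sharply and inflates HI = D2/D98 — the 3D calculation overestimates
coverage and homogeneity at the PTV edge, while the normal-liver mean dose
goes the other way (1.27 Gy static vs 1.36 Gy accumulated in the same
run). The GTV, which the dose cloud covers throughout its excursion, is
barely affected — the clinically reassuring part of the picture. The
reduced-phase rows converge toward the full 10-phase accumulation as the
phase count grows. The motion vector is the GTV-centroid displacement
between the extreme phases recovered from the generated masks (10.6 mm
r3D, matching the preset amplitudes).

The same workflow is scriptable from the shell:

```bash
warp4d phantom --outdir phantom_out --seed 1 --lesion E
warp4d register --source phantom_out/ct_phase_00.nrrd \
                --target phantom_out/ct_phase_50.nrrd --out dvf00.nrrd
warp4d study --seed 1 --outdir study_out      # full pipeline + CSV/JSON report
```

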